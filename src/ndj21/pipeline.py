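"""Pipeline orchestration: simulate -> QC -> phenotype -> associate -> report.

A run is driven by a flat YAML configuration; every stage writes TSV tables
into the run directory and the manifest records seeds, a configuration hash
and per-stage accounting (families and variants in/out, group sizes), which
must reconcile exactly:

    input families = MI + MII + mitotic excluded + undetermined
                     + excluded for having neither parent genotyped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, io, phenotype, qc, simulate
from .cohort import (COMPLETE, FATHER_ONLY, MI, MII, MITOTIC, MOTHER_ONLY,
                     Cohort, default_genetic_map)

log = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "run",
    "simulate": {
        "n_families": 700,
        "n_background": 5000,
        "n_chr21_markers": 200,
        "arm_length_cM": 45.0,
        "centromere_bp": 13_000_000,
        "stage_probs": [0.75, 0.23, 0.02],
        "parent_pattern_probs": [0.85, 0.13, 0.02],
        "genotype_error_rate": 0.0,
        "missing_rate": 0.0,
        "n_subpops": 1,
        "subpop_weights": [1.0],
        "fst": 0.0,
        "beta_a": 1.0,
        "beta_b": 1.0,
        "risk": [],
        "write_files": False,
    },
    "input": None,
    "qc": {},
    "pca": {
        "missing_max": 0.05,
        "maf_min": 0.05,
        "ld_r2_max": 0.1,
        "window": 50,
        "step": 5,
        "exclusion_regions": [],
    },
    "phenotype": {"window_k": 10, "min_evidence": 3, "min_support": 1},
    "contrasts": list(assoc.CONTRAST_NAMES),
    "candidate_loci": None,
    "top_hits": {"p_threshold": 1e-5, "window_bp": 20_000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(_merge(DEFAULT_CONFIG, d or {}))
        if not cfg.raw.get("contrasts"):
            raise ValueError("contrast list is empty; nothing to compute")
        unknown = set(cfg.raw["contrasts"]) - set(assoc.CONTRAST_NAMES)
        if unknown:
            raise ValueError(f"unknown contrasts: {sorted(unknown)}")
        inp = cfg.raw.get("input")
        if inp:
            for key in ("genotype", "pedigree", "trisomic", "map"):
                if key not in inp:
                    raise ValueError(f"input section missing {key!r}")
                if not Path(inp[key]).exists():
                    raise FileNotFoundError(inp[key])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        scientific = {k: v for k, v in self.raw.items() if k != "out_dir"}
        dump = yaml.safe_dump(scientific, sort_keys=True)
        return hashlib.sha256(dump.encode()).hexdigest()[:16]

    def sim_config(self) -> simulate.SimConfig:
        s = self.raw["simulate"]
        gmap = default_genetic_map(
            n_markers=int(s["n_chr21_markers"]),
            length_cM=float(s["arm_length_cM"]),
            centromere_bp=int(s["centromere_bp"]),
        )
        pop = simulate.PopulationModel(
            n_subpops=int(s["n_subpops"]),
            subpop_weights=tuple(s["subpop_weights"]),
            beta_a=float(s["beta_a"]),
            beta_b=float(s["beta_b"]),
            fst=float(s["fst"]),
        )
        risk = None
        if s.get("risk"):
            risk = simulate.RiskModel(
                effects=tuple((r["variant_id"], float(r["beta"])) for r in s["risk"]),
                baseline_logit=float(s.get("baseline_logit", -3.0)),
            )
        return simulate.SimConfig(
            n_families=int(s["n_families"]),
            stage_probs=tuple(s["stage_probs"]),
            parent_pattern_probs=tuple(s["parent_pattern_probs"]),
            genotype_error_rate=float(s["genotype_error_rate"]),
            missing_rate=float(s["missing_rate"]),
            seed=self.seed,
            genetic_map=gmap,
            pop=pop,
            risk=risk,
            n_background=int(s["n_background"]),
        )

    def qc_thresholds(self) -> qc.QcThresholds:
        return qc.QcThresholds(**self.raw["qc"])


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    families: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def check_family_accounting(self) -> None:
        f = self.families
        total = (
            f["mi"] + f["mii"] + f["mitotic_excluded"]
            + f["undetermined"] + f["excluded_no_parent"]
        )
        if total != f["input"]:
            raise ValueError(
                f"family accounting does not reconcile: {total} != {f['input']}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def load_cohort(config: RunConfig):
    """Simulate or read the input cohort; returns (cohort, truth or None,
    number of families excluded at read time)."""
    if config.raw.get("input"):
        inp = config.raw["input"]
        cohort = io.read_trio_cohort(
            inp["genotype"], inp["pedigree"], inp["trisomic"], inp["map"],
            centromere_bp=int(inp.get("centromere_bp", 13_000_000)),
        )
        return cohort, None, len(cohort.exclusions)
    sim = simulate.simulate_cohort(config.sim_config())
    return sim.cohort, sim.truth, 0


def run_pipeline(config: RunConfig, out_dir=None) -> RunManifest:
    """Execute every stage in order, writing all output tables."""
    out = Path(out_dir if out_dir is not None else config.raw["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), version=__version__,
                           seed=config.seed)

    log.info("stage 1/6: load cohort")
    cohort, truth, n_excluded_read = load_cohort(config)
    if truth is not None:
        simulate.write_truth(truth, out / "truth.tsv")
        if config.raw["simulate"].get("write_files"):
            io.write_cohort(cohort, out, prefix="cohort")
    n_input = cohort.n_families + n_excluded_read

    log.info("stage 2/6: variant QC")
    thresholds = config.qc_thresholds()
    cohort_f, report = qc.apply_variant_filters(cohort, thresholds)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest.variants = {
        "input": cohort.n_variants,
        "removed": len(report),
        "retained": cohort_f.n_variants,
        "removed_by_reason": report["reason"].value_counts().to_dict(),
    }
    if manifest.variants["removed"] + manifest.variants["retained"] != manifest.variants["input"]:
        raise ValueError("variant accounting does not reconcile")

    log.info("stage 3/6: phenotype (origin + stage)")
    ph_cfg = config.raw["phenotype"]
    complete_calls = []
    for trio in cohort_f.trios:
        if trio.availability != COMPLETE:
            continue
        origin, _, _ = phenotype.infer_parent_of_origin(
            trio, cohort_f, ph_cfg["min_evidence"]
        )
        if origin != phenotype.MATERNAL:
            continue
        profile = phenotype.build_reduction_profile(trio, cohort_f)
        call = phenotype.call_stage_complete(profile, trio.family_id,
                                             ph_cfg["min_support"])
        complete_calls.append((trio, call.stage))
    threshold = None
    trainable = [(t, s) for t, s in complete_calls if s in (MI, MII)]
    if len(trainable) >= 2:
        threshold = phenotype.optimize_ratio_threshold(
            trainable, cohort_f, ph_cfg["window_k"]
        )
        with open(out / "ratio_threshold.json", "w") as fh:
            json.dump(threshold.__dict__, fh, indent=2)
    result = phenotype.phenotype_cohort(
        cohort_f, threshold, ph_cfg["window_k"],
        ph_cfg["min_evidence"], ph_cfg["min_support"],
    )
    result.calls.to_csv(out / "origin_calls.tsv", sep="\t", index=False)
    for name, members in result.groups.items():
        pd.Series(members, name="id").to_csv(out / f"group_{name}.tsv",
                                             sep="\t", index=False)
    calls = result.calls
    n_mitotic = int((calls["stage"] == MITOTIC).sum())
    n_mi = int((calls["stage"] == MI).sum())
    n_mii = int((calls["stage"] == MII).sum())
    n_undet = len(calls) - n_mitotic - n_mi - n_mii
    manifest.families = {
        "input": n_input,
        "excluded_no_parent": n_excluded_read,
        "mitotic_excluded": n_mitotic,
        "mi": n_mi,
        "mii": n_mii,
        "undetermined": n_undet,
    }
    manifest.groups = {k: len(v) for k, v in result.groups.items()}
    manifest.check_family_accounting()

    log.info("stage 4/6: ancestry PCs")
    pca_cfg = config.raw["pca"]
    parents = cohort_f.sample_ids("mother") + cohort_f.sample_ids("father")
    snps = assoc.select_pca_snps(
        cohort_f,
        parents,
        missing_max=pca_cfg["missing_max"],
        maf_min=pca_cfg["maf_min"],
        ld_r2_max=pca_cfg["ld_r2_max"],
        window=pca_cfg["window"],
        step=pca_cfg["step"],
        exclusion_regions=[tuple(r) for r in pca_cfg["exclusion_regions"]],
    )
    pcs = assoc.compute_ancestry_pcs(cohort_f, snps, parents)
    pcs.coords.to_csv(out / "ancestry_pcs.tsv", sep="\t")

    log.info("stage 5/6: association contrasts")
    results = {}
    contrasts = {c.name: c for c in assoc.make_contrasts(result.groups)}
    for name in config.raw["contrasts"]:
        if name == "tdt":
            res = assoc.tdt_scan(cohort_f, result.groups["tdt_families"])
        else:
            res = assoc.logistic_snp_scan(cohort_f, contrasts[name], pcs)
        res.to_csv(out / f"results_{name}.tsv", sep="\t", index=False)
        results[name] = res
        ok = res[res["p"].notna()]
        if len(ok):
            lam = assoc.genomic_lambda(ok["p"])
            manifest.groups[f"lambda_{name}"] = round(lam, 4)
        # QQ / Manhattan data tables
        ok = ok.sort_values("p")
        qq = pd.DataFrame(
            {
                "expected_logp": -np.log10((np.arange(len(ok)) + 0.5) / len(ok)),
                "observed_logp": -np.log10(ok["p"].to_numpy()),
            }
        )
        qq.to_csv(out / f"qq_{name}.tsv", sep="\t", index=False)

    log.info("stage 6/6: candidate loci and top hits")
    if config.raw.get("candidate_loci"):
        loci = pd.read_csv(config.raw["candidate_loci"], sep="\t",
                           dtype={"chrom": str})
        logi = {k: v for k, v in results.items() if k != "tdt"}
        cand = assoc.candidate_gene_analysis(
            logi, loci, cohort_f, result.groups["fathers"]
        )
        cand.to_csv(out / "candidate_loci.tsv", sep="\t", index=False)
    th_cfg = config.raw["top_hits"]
    lookup = assoc.top_hits_cross_lookup(
        results, th_cfg["p_threshold"], th_cfg["window_bp"]
    )
    for name, tab in lookup.items():
        tab.to_csv(out / f"top_hits_{name}.tsv", sep="\t", index=False)

    manifest.to_json(out / "manifest.json")
    return manifest


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Miniature cohort for the test suite: 50 families, 300 chr21 markers,
    1000 genome-wide SNPs, with at least one family of each parent
    availability pattern; regenerated files are identical for a fixed seed."""
    gmap = default_genetic_map(n_markers=300)
    cfg = simulate.SimConfig(
        n_families=50,
        parent_pattern_probs=(0.8, 0.14, 0.06),
        seed=seed,
        genetic_map=gmap,
        n_background=1000,
    )
    sim = simulate.simulate_cohort(cfg)
    # guarantee every availability pattern appears (deterministically)
    present = {t.availability for t in sim.cohort.trios}
    want = [COMPLETE, MOTHER_ONLY, FATHER_ONLY]
    complete_idx = [i for i, t in enumerate(sim.cohort.trios)
                    if t.availability == COMPLETE]
    for pattern in want:
        if pattern in present:
            continue
        i = complete_idx.pop()
        t = sim.cohort.trios[i]
        t.availability = pattern
        if pattern == MOTHER_ONLY:
            t.father_geno, t.father_id = None, None
        elif pattern == FATHER_ONLY:
            t.mother_geno, t.mother_id = None, None
    paths = io.write_cohort(sim.cohort, out_dir, prefix="fixture")
    truth_path = Path(out_dir) / "fixture.truth.tsv"
    simulate.write_truth(sim.truth, truth_path)
    paths["truth"] = truth_path
    return paths
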