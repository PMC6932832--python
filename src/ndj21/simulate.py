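"""Synthetic trisomy-21 trio cohorts with known nondisjunction ground truth.

The generator emulates the statistical structure the downstream inference
assumes: biallelic SNPs with Balding–Nichols subpopulation structure, a
chromosome-21q marker panel on a centimorgan map, maternal meiosis simulated
at the tetrad (four-chromatid) level with Haldane (no-interference)
crossovers, and the three transmission patterns that produce a trisomic
child — meiosis I (both homologs retained), meiosis II (both sister
chromatids of one homolog retained) and post-zygotic mitotic duplication of
a single chromatid.  Optional maternal risk loci act on the log-odds of a
family being ascertained as a nondisjunction trio, enriching risk alleles
among mothers while fathers remain a random draw from the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    AVAILABILITIES,
    COMPLETE,
    FATHER_ONLY,
    MI,
    MII,
    MISSING,
    MITOTIC,
    MOTHER_ONLY,
    STAGES,
    Cohort,
    GeneticMap,
    TrioRecord,
    default_genetic_map,
)

_FREQ_EPS = 1e-6
_BACKGROUND_CHROMS = tuple(str(c) for c in list(range(1, 21)) + [22])


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class PopulationModel:
    """Balding–Nichols population with ``n_subpops`` demes at a common Fst.

    Ancestral allele frequencies are Beta(``beta_a``, ``beta_b``); each
    subpopulation draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral value p.
    """

    n_subpops: int = 1
    subpop_weights: tuple = (1.0,)
    beta_a: float = 1.0
    beta_b: float = 1.0
    fst: float = 0.0

    def __post_init__(self):
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        w = np.asarray(self.subpop_weights, dtype=float)
        if w.size != self.n_subpops or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("subpop_weights must be a simplex of length n_subpops")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1); fst = 1 is degenerate")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")

    def draw_frequencies(self, n_variants: int, rng) -> tuple:
        """Draw (ancestral freqs, per-subpop freq matrix) once for a panel."""
        rng = _as_rng(rng)
        p = rng.beta(self.beta_a, self.beta_b, size=n_variants)
        p = np.clip(p, _FREQ_EPS, 1 - _FREQ_EPS)
        if self.fst == 0.0:
            sub = np.tile(p, (self.n_subpops, 1))
        else:
            ratio = (1.0 - self.fst) / self.fst
            sub = rng.beta(p * ratio, (1.0 - p) * ratio, size=(self.n_subpops, n_variants))
            sub = np.clip(sub, _FREQ_EPS, 1 - _FREQ_EPS)
        return p, sub


@dataclass(frozen=True)
class RiskModel:
    """Maternal risk loci: log-odds per maternal B allele on the liability of
    being ascertained as a nondisjunction family."""

    effects: tuple = ()
    baseline_logit: float = -3.0

    def __post_init__(self):
        for vid, beta in self.effects:
            if not np.isfinite(beta):
                raise ValueError(f"non-finite effect for {vid}")
        if not np.isfinite(self.baseline_logit):
            raise ValueError("non-finite baseline_logit")


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 700
    stage_probs: tuple = (0.75, 0.23, 0.02)
    parent_pattern_probs: tuple = (0.85, 0.13, 0.02)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    genetic_map: GeneticMap = field(default_factory=default_genetic_map)
    pop: PopulationModel = field(default_factory=PopulationModel)
    risk: Optional[RiskModel] = None
    n_background: int = 1000
    #: Beta law for chr21 q-arm marker frequencies.  The phenotyping panel
    #: emulates markers selected for informativeness (heterozygosity ~0.46),
    #: unlike the genome-wide panel which follows ``pop``'s frequency law.
    chr21_freq_beta: tuple = (5.0, 5.0)

    def __post_init__(self):
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        for name, probs, k in (
            ("stage_probs", self.stage_probs, 3),
            ("parent_pattern_probs", self.parent_pattern_probs, 3),
        ):
            p = np.asarray(probs, dtype=float)
            if p.size != k or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a simplex of length {k}")
        for name, r in (
            ("genotype_error_rate", self.genotype_error_rate),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class FounderSample:
    """Phased founder haplotypes: (n, 2, n_variants) int8, with subpop labels
    and the per-subpop frequencies they were drawn from."""

    haplotypes: np.ndarray
    subpop: np.ndarray
    subpop_freqs: np.ndarray
    ancestral_freqs: np.ndarray

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1, dtype=np.int8)


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: pd.DataFrame

    def __post_init__(self):
        fam_t = set(self.truth["family_id"])
        fam_c = {t.family_id for t in self.cohort.trios}
        if fam_t != fam_c:
            raise ValueError("truth family ids do not match cohort trios")


def build_panel(gmap: GeneticMap, n_background: int) -> pd.DataFrame:
    """Variant table: chr21 q-arm markers from the map plus independent
    background SNPs spread over the other autosomes."""
    rows = {
        "id": list(gmap.ids),
        "chrom": [gmap.chromosome] * gmap.n_markers,
        "pos_bp": list(gmap.position_bp),
        "pos_cM": list(gmap.position_cM),
    }
    if n_background:
        per = int(np.ceil(n_background / len(_BACKGROUND_CHROMS)))
        chroms, pos = [], []
        for i in range(n_background):
            chroms.append(_BACKGROUND_CHROMS[i % len(_BACKGROUND_CHROMS)])
            pos.append(1_000_000 * (i // len(_BACKGROUND_CHROMS) + 1))
        rows["id"] += [f"bg_{i:06d}" for i in range(n_background)]
        rows["chrom"] += chroms
        rows["pos_bp"] += pos
        rows["pos_cM"] += [np.nan] * n_background
    df = pd.DataFrame(rows)
    df["allele_a"] = "A"
    df["allele_b"] = "B"
    df["info_score"] = 1.0
    df["source"] = "genotyped"
    return df


def sample_founder_haplotypes(
    pop: PopulationModel,
    n_individuals: int,
    n_variants: int,
    rng_seed,
    subpop_freqs: Optional[np.ndarray] = None,
    ancestral_freqs: Optional[np.ndarray] = None,
) -> FounderSample:
    """Draw phased founder haplotypes under the Balding–Nichols model.

    Per-subpopulation frequencies are drawn once (or passed in, so that a
    cohort's batches share them) and every individual of a subpopulation
    samples alleles Bernoulli(freq) independently per haplotype.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = _as_rng(rng_seed)
    if subpop_freqs is None:
        ancestral_freqs, subpop_freqs = pop.draw_frequencies(n_variants, rng)
    subpop_freqs = np.asarray(subpop_freqs, dtype=float)
    if subpop_freqs.shape != (pop.n_subpops, n_variants):
        raise ValueError("subpop_freqs has wrong shape")
    labels = rng.choice(pop.n_subpops, size=n_individuals, p=np.asarray(pop.subpop_weights))
    freqs = subpop_freqs[labels]  # (n, V)
    haps = (rng.random((n_individuals, 2, n_variants)) < freqs[:, None, :]).astype(np.int8)
    if ancestral_freqs is None:
        ancestral_freqs = subpop_freqs.mean(axis=0)
    return FounderSample(haps, labels, subpop_freqs, np.asarray(ancestral_freqs, dtype=float))


def simulate_maternal_tetrad(
    mother_haplotypes: np.ndarray,
    gmap: GeneticMap,
    stage: str,
    rng_seed,
) -> tuple:
    """Simulate one maternal meiosis at the tetrad level and return the two
    transmitted chromatids plus crossover positions (bp).

    Four chromatids are built (two sisters per homolog).  Crossover count is
    Poisson with mean 2 x (arm length in Morgans) — the tetrad-level rate
    giving an expected gamete map length equal to the genetic map — with each
    event placed uniformly on the cM scale and exchanged between a uniformly
    chosen non-sister chromatid pair (Haldane model, no interference).
    Transmission: MI keeps one chromatid of each homolog; MII keeps both
    sisters of one homolog; mitotic duplicates a single chromatid.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    rng = _as_rng(rng_seed)
    h = np.asarray(mother_haplotypes, dtype=np.int8)
    if h.shape != (2, gmap.n_markers):
        raise ValueError("mother_haplotypes must have shape (2, n_markers)")
    # chromatids 0,1 are sisters with centromere of homolog 0; 2,3 of homolog 1
    chromatids = np.vstack([h[0], h[0], h[1], h[1]]).copy()
    L = gmap.length_cM
    n_xo = rng.poisson(2.0 * L / 100.0) if L > 0 else 0
    xo_cm = np.sort(rng.uniform(0.0, L, size=n_xo)) if n_xo else np.empty(0)
    for cm in xo_cm:
        i = rng.integers(2)          # sister of homolog 0
        j = 2 + rng.integers(2)      # sister of homolog 1
        distal = gmap.position_cM > cm
        tmp = chromatids[i, distal].copy()
        chromatids[i, distal] = chromatids[j, distal]
        chromatids[j, distal] = tmp
    if stage == MI:
        pair = chromatids[[rng.integers(2), 2 + rng.integers(2)]]
    elif stage == MII:
        k = 2 * rng.integers(2)
        pair = chromatids[[k, k + 1]]
    else:  # mitotic: post-zygotic duplication of the one transmitted chromatid
        k = rng.integers(4)
        pair = np.vstack([chromatids[k], chromatids[k]])
    xo_bp = gmap.cm_to_bp(xo_cm) if n_xo else np.empty(0, dtype=np.int64)
    return pair.astype(np.int8), xo_bp


def recombine_gamete(haplotypes: np.ndarray, gmap: GeneticMap, rng_seed) -> np.ndarray:
    """One disomic gamete from a parent's two chr21 haplotypes (Haldane)."""
    rng = _as_rng(rng_seed)
    h = np.asarray(haplotypes, dtype=np.int8)
    L = gmap.length_cM
    n_xo = rng.poisson(L / 100.0) if L > 0 else 0
    cuts = np.sort(rng.uniform(0.0, L, size=n_xo)) if n_xo else np.empty(0)
    phase = (rng.integers(2) + np.searchsorted(cuts, gmap.position_cM, side="right")) % 2
    return h[phase, np.arange(gmap.n_markers)]


def _draw_mothers(config: SimConfig, variants: pd.DataFrame, sub_freqs, anc_freqs, rng):
    """Mothers of ascertained nondisjunction families.

    Without a risk model this is a plain population draw; with one, candidate
    women are drawn in batches and retained with probability
    expit(baseline + sum beta * B-dosage), which enriches risk alleles among
    mothers while leaving fathers unconditioned.
    """
    n = config.n_families
    V = len(variants)
    if config.risk is None:
        return sample_founder_haplotypes(config.pop, n, V, rng, sub_freqs, anc_freqs)
    vid_index = pd.Index(variants["id"])
    idx, betas = [], []
    for vid, beta in config.risk.effects:
        i = vid_index.get_loc(vid) if vid in vid_index else -1
        if i == -1:
            raise KeyError(f"risk variant {vid!r} absent from simulated panel")
        idx.append(i)
        betas.append(beta)
    idx = np.asarray(idx, dtype=int)
    betas = np.asarray(betas, dtype=float)
    haps_parts, label_parts = [], []
    n_have = 0
    while n_have < n:
        batch = max(1000, 2 * (n - n_have))
        cand = sample_founder_haplotypes(config.pop, batch, V, rng, sub_freqs, anc_freqs)
        dos = cand.haplotypes[:, :, idx].sum(axis=1)
        liab = config.risk.baseline_logit + dos @ betas
        keep = rng.random(batch) < expit(liab)
        haps_parts.append(cand.haplotypes[keep])
        label_parts.append(cand.subpop[keep])
        n_have += int(keep.sum())
    haps = np.concatenate(haps_parts)[:n]
    labels = np.concatenate(label_parts)[:n]
    return FounderSample(haps, labels, sub_freqs, anc_freqs)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a cohort of maternal trisomy-21 trios with truth labels."""
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_f, rng_m, rng_mei, rng_assign, rng_obs = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    gmap = config.genetic_map
    variants = build_panel(gmap, config.n_background)
    V = len(variants)
    chr21_idx = np.flatnonzero((variants["chrom"] == gmap.chromosome).to_numpy())
    bg_idx = np.flatnonzero((variants["chrom"] != gmap.chromosome).to_numpy())
    anc, sub = config.pop.draw_frequencies(V, rng_freq)
    # chr21 phenotyping markers: informativeness-selected frequency law
    a21, b21 = config.chr21_freq_beta
    pop21 = PopulationModel(
        n_subpops=config.pop.n_subpops,
        subpop_weights=config.pop.subpop_weights,
        beta_a=a21,
        beta_b=b21,
        fst=config.pop.fst,
    )
    anc21, sub21 = pop21.draw_frequencies(chr21_idx.size, rng_freq)
    anc[chr21_idx] = anc21
    sub[:, chr21_idx] = sub21

    fathers = sample_founder_haplotypes(config.pop, config.n_families, V, rng_f, sub, anc)
    mothers = _draw_mothers(config, variants, sub, anc, rng_m)

    n = config.n_families
    stages = rng_assign.choice(STAGES, size=n, p=np.asarray(config.stage_probs))
    patterns = rng_assign.choice(
        AVAILABILITIES, size=n, p=np.asarray(config.parent_pattern_probs)
    )

    # background transmission: one uniformly chosen allele per marker per parent
    nb = bg_idx.size
    pick_m = rng_mei.integers(2, size=(n, nb))
    pick_f = rng_mei.integers(2, size=(n, nb))
    rows = np.arange(n)[:, None]
    child_bg = (
        mothers.haplotypes[rows, pick_m, bg_idx[None, :]]
        + fathers.haplotypes[rows, pick_f, bg_idx[None, :]]
    ).astype(np.int8)

    trios, truth_rows = [], []
    for i in range(n):
        fam = f"fam{i:05d}"
        pair, xo_bp = simulate_maternal_tetrad(
            mothers.haplotypes[i][:, chr21_idx], gmap, stages[i], rng_mei
        )
        pat_gamete = recombine_gamete(fathers.haplotypes[i][:, chr21_idx], gmap, rng_mei)
        tris = (pair.sum(axis=0) + pat_gamete).astype(np.int8)

        child_geno = np.full(V, MISSING, dtype=np.int8)
        child_geno[bg_idx] = child_bg[i]
        mother_geno = mothers.haplotypes[i].sum(axis=0, dtype=np.int8)
        father_geno = fathers.haplotypes[i].sum(axis=0, dtype=np.int8)
        avail = patterns[i]
        trios.append(
            TrioRecord(
                family_id=fam,
                child_id=f"{fam}_c",
                mother_id=f"{fam}_m" if avail != FATHER_ONLY else None,
                father_id=f"{fam}_f" if avail != MOTHER_ONLY else None,
                availability=avail,
                mother_geno=mother_geno if avail != FATHER_ONLY else None,
                father_geno=father_geno if avail != MOTHER_ONLY else None,
                child_geno=child_geno,
                child_tris=tris,
            )
        )
        truth_rows.append(
            {
                "family_id": fam,
                "stage": stages[i],
                "origin": "maternal",
                "n_crossovers": len(xo_bp),
                "crossover_bp": ";".join(str(int(b)) for b in xo_bp),
                "mother_subpop": int(mothers.subpop[i]),
                "father_subpop": int(fathers.subpop[i]),
            }
        )

    cohort = Cohort(variants=variants, trios=trios, genetic_map=gmap)
    sim = SimulatedCohort(cohort=cohort, truth=pd.DataFrame(truth_rows))
    if config.genotype_error_rate > 0 or config.missing_rate > 0:
        sim = apply_observation_model(
            sim, config.genotype_error_rate, config.missing_rate, rng_obs
        )
    return sim


def _perturb(arr: np.ndarray, n_states: int, error_rate: float, missing_rate: float, rng):
    """Independently perturb non-missing calls to a different valid state and
    then set calls missing; operates in place."""
    present = arr != MISSING
    if error_rate > 0:
        hit = present & (rng.random(arr.shape) < error_rate)
        shift = rng.integers(1, n_states, size=arr.shape).astype(np.int8)
        arr[hit] = (arr[hit] + shift[hit]) % n_states
    if missing_rate > 0:
        drop = present & (rng.random(arr.shape) < missing_rate)
        arr[drop] = MISSING


def apply_observation_model(
    sim: SimulatedCohort,
    genotype_error_rate: float,
    missing_rate: float,
    rng_seed,
) -> SimulatedCohort:
    """Add genotyping error and missingness to every call; truth untouched."""
    for name, r in (("genotype_error_rate", genotype_error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _as_rng(rng_seed)
    cohort = sim.cohort.copy()
    for t in cohort.trios:
        for g in (t.mother_geno, t.father_geno, t.child_geno):
            if g is not None:
                _perturb(g, 3, genotype_error_rate, missing_rate, rng)
        _perturb(t.child_tris, 4, genotype_error_rate, missing_rate, rng)
    return SimulatedCohort(cohort=cohort, truth=sim.truth.copy())


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"crossover_bp": str}, keep_default_na=False)
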