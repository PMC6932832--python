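"""Variant- and sample-level quality control.

Implements the study's filters: minor allele frequency (computed on parents
only for chromosome 21, on all available samples elsewhere), an exact
Hardy-Weinberg equilibrium test, imputation info-score cutoffs (0.3 at the
imputation stage, 0.5 at the analysis stage), masking of low-confidence
imputed calls before frequency computation, and Mendelian-consistency
screening including a chromosome-level uniparental-transmission flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import MISSING, Cohort, GeneticMap


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    info_min_imputation: float = 0.3
    info_min_analysis: float = 0.5
    confidence_min: float = 0.90
    sample_missing_max: float = 0.02

    def __post_init__(self):
        for name in (
            "maf_min", "hwe_p_min", "info_min_imputation",
            "info_min_analysis", "confidence_min", "sample_missing_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def minor_allele_frequency(dosages) -> float:
    """MAF of a disomic dosage vector; missing calls (-1) are ignored."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    if d.size == 0:
        raise ValueError("all calls missing; MAF undefined")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def _maf_vector(G: np.ndarray) -> np.ndarray:
    """Per-variant MAF over a (samples x variants) matrix; NaN if all missing."""
    present = G != MISSING
    n = present.sum(axis=0)
    total = np.where(present, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, total / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    The p-value is the total probability, conditional on the allele counts,
    of heterozygote counts no more probable than the observed one.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts) or any(c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logw = hets * np.log(2.0) - gammaln(hets + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1)
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_ab)[0]]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def sample_missing_rates(cohort: Cohort) -> pd.Series:
    """Disomic missing-call rate per genotyped sample (child chr21 excluded)."""
    rates = {}
    non21 = ~cohort.chr21_mask
    for t in cohort.trios:
        if t.has_mother:
            rates[t.mother_id] = float((t.mother_geno == MISSING).mean())
        if t.has_father:
            rates[t.father_id] = float((t.father_geno == MISSING).mean())
        rates[t.child_id] = float((t.child_geno[non21] == MISSING).mean())
    return pd.Series(rates, name="missing_rate")


def subset_variants(cohort: Cohort, keep: np.ndarray) -> Cohort:
    """New cohort restricted to the variants where ``keep`` is True."""
    keep = np.asarray(keep, dtype=bool)
    variants = cohort.variants.loc[keep].reset_index(drop=True)
    chr21_keep = keep[cohort.chr21_index]
    chr_rows = variants[variants["chrom"] == cohort.genetic_map.chromosome]
    if len(chr_rows):
        gmap = GeneticMap(
            chromosome=cohort.genetic_map.chromosome,
            ids=tuple(chr_rows["id"]),
            position_bp=chr_rows["pos_bp"].to_numpy(),
            position_cM=chr_rows["pos_cM"].to_numpy(dtype=float),
            centromere_bp=cohort.genetic_map.centromere_bp,
        )
    else:
        gmap = cohort.genetic_map
    trios = []
    import copy as _copy

    for t in cohort.trios:
        t2 = _copy.copy(t)
        t2.mother_geno = t.mother_geno[keep] if t.has_mother else None
        t2.father_geno = t.father_geno[keep] if t.has_father else None
        t2.child_geno = t.child_geno[keep]
        t2.child_tris = t.child_tris[chr21_keep]
        trios.append(t2)
    return Cohort(variants=variants, trios=trios, genetic_map=gmap,
                  exclusions=list(cohort.exclusions))


def mask_low_confidence(
    cohort: Cohort, confidences: dict, confidence_min: float
) -> Cohort:
    """Set imputed calls with confidence below the cutoff to missing.

    ``confidences`` maps sample id -> per-variant call confidence in [0, 1].
    Only variants with source == 'imputed' are affected.
    """
    cohort = cohort.copy()
    imputed = (cohort.variants["source"] == "imputed").to_numpy()
    if not imputed.any():
        return cohort
    for t in cohort.trios:
        for sid, g in ((t.mother_id, t.mother_geno), (t.father_id, t.father_geno),
                       (t.child_id, t.child_geno)):
            if g is None or sid not in confidences:
                continue
            conf = np.asarray(confidences[sid], dtype=float)
            g[imputed & (conf < confidence_min)] = MISSING
    return cohort


def apply_variant_filters(
    cohort: Cohort,
    thresholds: QcThresholds = QcThresholds(),
    reference_group=None,
    stage: str = "analysis",
    confidences: dict = None,
):
    """Remove variants failing MAF, HWE and info-score rules.

    MAF is computed on ``reference_group`` when given; otherwise on parents
    only for chromosome-21 variants and on all genotyped samples elsewhere.
    HWE uses parental genotypes (the founders).  Low-confidence imputed calls
    are set missing before any frequency is computed.  Returns the filtered
    cohort and a per-variant report (one row per removal, with the reason).
    """
    if stage not in ("imputation", "analysis"):
        raise ValueError("stage must be 'imputation' or 'analysis'")
    if confidences:
        cohort = mask_low_confidence(cohort, confidences, thresholds.confidence_min)

    parents = cohort.sample_ids("mother") + cohort.sample_ids("father")
    if not parents:
        raise ValueError("no genotyped parents; QC reference group empty")
    Gp = cohort.genotype_matrix(parents)
    if reference_group is not None:
        if not len(reference_group):
            raise ValueError("reference_group is empty")
        Gref = cohort.genotype_matrix(reference_group)
        maf = _maf_vector(Gref)
    else:
        Gall = cohort.genotype_matrix(parents + cohort.sample_ids("child"))
        maf = _maf_vector(Gall)
        maf21 = _maf_vector(Gp)
        c21 = cohort.chr21_mask
        maf[c21] = maf21[c21]

    n_aa = ((Gp == 0).sum(axis=0)).astype(int)
    n_ab = ((Gp == 1).sum(axis=0)).astype(int)
    n_bb = ((Gp == 2).sum(axis=0)).astype(int)
    hwe_p = np.ones(cohort.n_variants)
    for j in range(cohort.n_variants):
        if n_aa[j] + n_ab[j] + n_bb[j] > 0:
            hwe_p[j] = hwe_exact_test(n_aa[j], n_ab[j], n_bb[j])

    info_min = (thresholds.info_min_imputation if stage == "imputation"
                else thresholds.info_min_analysis)
    imputed = (cohort.variants["source"] == "imputed").to_numpy()
    info = cohort.variants["info_score"].to_numpy(dtype=float)

    fail_maf = np.nan_to_num(maf, nan=0.0) < thresholds.maf_min
    fail_hwe = hwe_p < thresholds.hwe_p_min
    fail_info = imputed & (info < info_min)

    report_rows = []
    ids = cohort.variants["id"].to_numpy()
    for j in range(cohort.n_variants):
        if fail_maf[j]:
            report_rows.append((ids[j], "MAF", "maf", maf[j]))
        elif fail_hwe[j]:
            report_rows.append((ids[j], "HWE", "hwe_p", hwe_p[j]))
        elif fail_info[j]:
            report_rows.append((ids[j], "info", "info_score", info[j]))
    report = pd.DataFrame(report_rows, columns=["variant_id", "reason", "statistic", "value"])
    keep = ~(fail_maf | fail_hwe | fail_info)
    return subset_variants(cohort, keep), report


# transmissible allele-count sets per disomic dosage (missing -> {0, 1})
def _transmit_sets(g: np.ndarray):
    lo = np.where(g == 2, 1, 0)
    hi = np.where(g == 0, 0, 1)
    return lo, hi


def mendelian_check(
    trio,
    variants: pd.DataFrame,
    chr21_label: str = "21",
    uniparental_min_count: int = 3,
    uniparental_min_frac: float = 0.01,
):
    """Mendelian screening of a complete trio's disomic genotypes.

    Returns (list of inconsistent variant ids, chromosome-level flags).  A
    chromosome is flagged as uniparental when the child shares zero alleles
    with one parent at many informative markers — e.g. both copies derived
    from the mother show up as parent hom-A / child hom-B mismatches against
    the father.
    """
    if not (trio.has_mother and trio.has_father):
        raise ValueError("mendelian_check requires a complete trio")
    m, f, c = trio.mother_geno, trio.father_geno, trio.child_geno
    usable = (m != MISSING) & (f != MISSING) & (c != MISSING)
    usable &= (variants["chrom"] != chr21_label).to_numpy()
    m_lo, m_hi = _transmit_sets(m)
    f_lo, f_hi = _transmit_sets(f)
    inconsistent = usable & ((c < m_lo + f_lo) | (c > m_hi + f_hi))
    ids = variants["id"].to_numpy()
    bad_ids = list(ids[inconsistent])

    flags = {}
    chroms = variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom == chr21_label:
            continue
        on = usable & (chroms == chrom)
        n_inf = int(on.sum())
        if n_inf == 0:
            continue
        zero_f = int((on & (((f == 0) & (c == 2)) | ((f == 2) & (c == 0)))).sum())
        zero_m = int((on & (((m == 0) & (c == 2)) | ((m == 2) & (c == 0)))).sum())
        thr = max(uniparental_min_count, uniparental_min_frac * n_inf)
        if zero_f >= thr and zero_f > 2 * zero_m:
            flags[chrom] = "uniparental_maternal"
        elif zero_m >= thr and zero_m > 2 * zero_f:
            flags[chrom] = "uniparental_paternal"
    return bad_ids, flags
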