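"""Parental origin and meiotic-stage inference from trisomic trio genotypes.

Each chromosome-21q marker of a maternal-origin trisomy is scored as
*reduced to homozygosity* (R — the mother transmitted two identical alleles)
or *not reduced* (N — she transmitted both her alleles).  The scoring
enumerates every decomposition of the child's allele triple into a maternal
pair plus one paternal allele that is consistent with the parental
genotypes; a marker is informative only when the mother is heterozygous and
every consistent decomposition agrees on the pair's zygosity.

The stage call follows the zygosity nearest the centromere: N means the two
homologs were retained (meiosis I error), R means two sister chromatids were
retained (meiosis II error).  When every informative marker along 21q is R
the trisomy is attributed to a post-zygotic mitotic duplication and the case
is excluded — with the documented caveat that an MII error without any
crossover leaves the same all-R signature.

Families with only the mother genotyped are classified with a
pericentromeric information ratio (fraction of definitely-reduced markers
among the partially informative markers nearest the centromere), whose
cutoff is trained by masking the father in complete trios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    COMPLETE,
    FATHER_ONLY,
    MI,
    MII,
    MISSING,
    MITOTIC,
    MOTHER_ONLY,
    UNDETERMINED,
    Cohort,
    TrioRecord,
)

# marker class codes
UNINFORMATIVE, R, N, AMBIGUOUS = 0, 1, 2, 3
_CLASS_NAMES = {UNINFORMATIVE: "uninformative", R: "R", N: "N", AMBIGUOUS: "ambiguous"}
# origin-evidence codes
EV_NONE, EV_MATERNAL, EV_PATERNAL = 0, 1, 2
_EV_NAMES = {EV_NONE: "none", EV_MATERNAL: "maternal", EV_PATERNAL: "paternal"}

MATERNAL = "maternal"
PATERNAL = "paternal"


@dataclass(frozen=True)
class TransmissionClass:
    value: str                 # R / N / ambiguous / uninformative
    origin_evidence: str       # maternal / paternal / none


@dataclass
class ReductionProfile:
    """Ordered per-marker classes along 21q, proximal to distal."""

    entries: pd.DataFrame  # variant_id, distance_bp, cls (codes), evidence

    def __post_init__(self):
        d = self.entries["distance_bp"].to_numpy()
        if len(d) and (np.any(d <= 0) or np.any(np.diff(d) < 0)):
            raise ValueError("profile must be q-arm only, sorted by distance")

    @property
    def informative_classes(self) -> np.ndarray:
        cls = self.entries["cls"].to_numpy()
        return cls[(cls == R) | (cls == N)]


@dataclass
class OriginCall:
    family_id: str
    parent_of_origin: str = UNDETERMINED   # maternal / paternal / undetermined
    stage: str = UNDETERMINED              # MI / MII / mitotic / undetermined
    method: str = "complete_trio"          # complete_trio / single_parent_ratio
    n_R: int = 0
    n_N: int = 0
    pericentromeric_ratio: Optional[float] = None
    excluded: bool = False
    flags: tuple = ()

    def __post_init__(self):
        if self.excluded != (self.stage == MITOTIC):
            raise ValueError("excluded must be set exactly for mitotic calls")


@dataclass(frozen=True)
class RatioThreshold:
    cutoff: float
    window_k: int
    training_accuracy: float

    def __post_init__(self):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")


# ------------------------------------------------------------ marker scoring

def _pair_range(g: np.ndarray):
    """Possible transmitted-pair B dosages from a parent's disomic genotype."""
    lo = np.where(g == 2, 2, 0)
    hi = np.where(g == 0, 0, 2)
    hi = np.where(g == MISSING, 2, hi)
    return lo, hi


def _single_range(g: np.ndarray):
    """Possible single transmitted-allele B dosages."""
    lo = np.where(g == 2, 1, 0)
    hi = np.where(g == 0, 0, 1)
    hi = np.where(g == MISSING, 1, hi)
    return lo, hi


def classify_markers(m: np.ndarray, f: np.ndarray, c: np.ndarray):
    """Vectorised marker classification under assumed maternal origin.

    Returns (class codes, origin-evidence codes).  ``m``/``f`` are parental
    disomic dosages (MISSING allowed, e.g. an ungenotyped father), ``c`` the
    child's trisomic B dosage.
    """
    m = np.asarray(m)
    f = np.asarray(f)
    c = np.asarray(c)
    pa_lo, pa_hi = _single_range(f)

    def feasible(d):
        p = c - d
        return (p >= pa_lo) & (p <= pa_hi) & (c != MISSING)

    r_possible = feasible(0) | feasible(2)
    n_possible = feasible(1)
    informative = (m == 1) & (c != MISSING)
    cls = np.full(m.shape, UNINFORMATIVE, dtype=np.int8)
    cls[informative & r_possible & ~n_possible] = R
    cls[informative & n_possible & ~r_possible] = N
    cls[informative & r_possible & n_possible] = AMBIGUOUS

    # origin evidence: consistency under maternal (2 maternal + 1 paternal)
    # vs paternal (1 maternal + 2 paternal) transmission models
    mp_lo, mp_hi = _pair_range(m)
    fp_lo, fp_hi = _pair_range(f)
    ms_lo, ms_hi = _single_range(m)
    mat_ok = (np.maximum(pa_lo, c - mp_hi) <= np.minimum(pa_hi, c - mp_lo)) & (c != MISSING)
    pat_ok = (np.maximum(ms_lo, c - fp_hi) <= np.minimum(ms_hi, c - fp_lo)) & (c != MISSING)
    ev = np.full(m.shape, EV_NONE, dtype=np.int8)
    ev[mat_ok & ~pat_ok] = EV_MATERNAL
    ev[pat_ok & ~mat_ok] = EV_PATERNAL
    return cls, ev


def classify_marker(mother_g: int, father_g: int, child_g: int) -> TransmissionClass:
    """Scalar marker classification; see :func:`classify_markers`."""
    cls, ev = classify_markers(
        np.array([mother_g]), np.array([father_g]), np.array([child_g])
    )
    return TransmissionClass(_CLASS_NAMES[int(cls[0])], _EV_NAMES[int(ev[0])])


def _chr21_arrays(trio: TrioRecord, cohort: Cohort, mask_father: bool = False):
    idx = cohort.chr21_index
    m = trio.mother_geno[idx] if trio.has_mother else np.full(idx.size, MISSING, dtype=np.int8)
    if trio.has_father and not mask_father:
        f = trio.father_geno[idx]
    else:
        f = np.full(idx.size, MISSING, dtype=np.int8)
    return m, f, trio.child_tris


# ----------------------------------------------------------- origin & stage

def infer_parent_of_origin(trio: TrioRecord, cohort: Cohort, min_count: int = 3):
    """Majority vote over markers with parent-of-origin evidence.

    Returns (origin, n_maternal_evidence, n_paternal_evidence); origin is
    undetermined unless one side both outnumbers the other and reaches
    ``min_count`` markers.
    """
    m, f, c = _chr21_arrays(trio, cohort)
    if c.size == 0:
        raise ValueError("no chromosome-21 markers")
    _, ev = classify_markers(m, f, c)
    n_mat = int((ev == EV_MATERNAL).sum())
    n_pat = int((ev == EV_PATERNAL).sum())
    if n_mat > n_pat and n_mat >= min_count:
        return MATERNAL, n_mat, n_pat
    if n_pat > n_mat and n_pat >= min_count:
        return PATERNAL, n_mat, n_pat
    return UNDETERMINED, n_mat, n_pat


def build_reduction_profile(
    trio: TrioRecord, cohort: Cohort, mask_father: bool = False
) -> ReductionProfile:
    """Classify every q-arm marker, sorted by distance from the centromere."""
    idx = cohort.chr21_index
    if idx.size == 0:
        raise ValueError("cohort has no chromosome-21 markers")
    m, f, c = _chr21_arrays(trio, cohort, mask_father=mask_father)
    cls, ev = classify_markers(m, f, c)
    gmap = cohort.genetic_map
    dist = gmap.position_bp - gmap.centromere_bp
    entries = pd.DataFrame(
        {"variant_id": list(gmap.ids), "distance_bp": dist, "cls": cls, "evidence": ev}
    )
    return ReductionProfile(entries)


def call_stage_complete(
    profile: ReductionProfile, family_id: str = "", min_support: int = 1
) -> OriginCall:
    """Stage call from a complete-trio reduction profile.

    The most centromere-proximal informative run decides: N -> MI, R -> MII.
    All-R profiles are attributed to a mitotic (post-zygotic) error and
    excluded.  A single proximal R followed by N's remains a valid MII call
    even when ``min_support`` > 1; calls resting on a single marker carry a
    ``single_marker_support`` flag.
    """
    seq = profile.informative_classes
    n_r = int((seq == R).sum())
    n_n = int((seq == N).sum())
    if seq.size == 0:
        return OriginCall(family_id, MATERNAL, UNDETERMINED, "complete_trio", 0, 0)
    if n_n == 0:
        return OriginCall(family_id, MATERNAL, MITOTIC, "complete_trio",
                          n_r, 0, excluded=True)
    # run-length encode the informative sequence
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [seq.size]))
    runs = [(int(seq[s]), int(e - s)) for s, e in zip(starts, ends)]

    flags = []
    stage_cls = None
    if runs[0][0] == R and runs[0][1] == 1 and len(runs) > 1 and runs[1][0] == N:
        # single well-genotyped proximal R followed by a series of N's
        stage_cls = R
        flags.append("single_marker_support")
    else:
        for cls_code, length in runs:
            if length >= min_support:
                stage_cls = cls_code
                break
        if stage_cls is None:
            stage_cls = runs[0][0]
            flags.append("low_support")
        if runs[0][1] == 1 and stage_cls == runs[0][0]:
            flags.append("single_marker_support")
    stage = MII if stage_cls == R else MI
    return OriginCall(family_id, MATERNAL, stage, "complete_trio",
                      n_r, n_n, flags=tuple(flags))


# ----------------------------------------------- single-parent ratio method

def pericentromeric_ratio(
    trio: TrioRecord, cohort: Cohort, window_k: int = 10
) -> Optional[float]:
    """R-information fraction near the centromere with the father masked.

    Over the ``window_k`` most centromere-proximal markers that are partially
    informative (mother heterozygous with at least one consistent
    decomposition), returns the fraction whose every consistent decomposition
    is reduced to homozygosity.  None when no such marker exists.
    """
    if not trio.has_mother:
        return None
    profile = build_reduction_profile(trio, cohort, mask_father=True)
    cls = profile.entries["cls"].to_numpy()
    partial = cls[(cls == R) | (cls == N) | (cls == AMBIGUOUS)][:window_k]
    if partial.size == 0:
        return None
    return float((partial == R).mean())


def optimize_ratio_threshold(
    trios_with_stage, cohort: Cohort, window_k: int = 10
) -> RatioThreshold:
    """Train the MI/MII ratio cutoff by masking the father in complete trios.

    ``trios_with_stage`` is an iterable of (TrioRecord, stage) with stage the
    complete-trio call (MI or MII).  Candidate cutoffs are midpoints between
    consecutive distinct observed ratios; the cutoff maximising agreement
    (predict MII when ratio >= cutoff) is returned, ties toward the smaller
    cutoff.
    """
    ratios, labels = [], []
    for trio, stage in trios_with_stage:
        if stage not in (MI, MII):
            continue
        r = pericentromeric_ratio(trio, cohort, window_k)
        if r is not None:
            ratios.append(r)
            labels.append(stage == MII)
    if not ratios:
        raise ValueError("no trio yields a finite pericentromeric ratio")
    ratios = np.asarray(ratios)
    labels = np.asarray(labels)
    uniq = np.unique(ratios)
    if uniq.size == 1:
        grid = uniq
    else:
        grid = (uniq[:-1] + uniq[1:]) / 2.0
    best_cut, best_acc = None, -1.0
    for cut in grid:
        acc = float(((ratios >= cut) == labels).mean())
        if acc > best_acc + 1e-12:
            best_cut, best_acc = float(cut), acc
    return RatioThreshold(cutoff=best_cut, window_k=window_k, training_accuracy=best_acc)


def classify_dyad(
    trio: TrioRecord, cohort: Cohort, threshold: RatioThreshold
) -> OriginCall:
    """Stage call for a mother-only family via the trained ratio rule.

    Parent of origin is assumed maternal (the genotyped mother), as the
    markers cannot confirm origin without the father.
    """
    ratio = pericentromeric_ratio(trio, cohort, threshold.window_k)
    if ratio is None:
        return OriginCall(trio.family_id, MATERNAL, UNDETERMINED,
                          "single_parent_ratio", 0, 0)
    stage = MII if ratio >= threshold.cutoff else MI
    return OriginCall(trio.family_id, MATERNAL, stage, "single_parent_ratio",
                      0, 0, pericentromeric_ratio=ratio)


# ------------------------------------------------------------- cohort level

@dataclass
class PhenotypeResult:
    calls: pd.DataFrame
    groups: dict
    origin_calls: list = field(default_factory=list)


def phenotype_cohort(
    cohort: Cohort,
    threshold: Optional[RatioThreshold] = None,
    window_k: int = 10,
    min_evidence: int = 3,
    min_support: int = 1,
) -> PhenotypeResult:
    """Phenotype every family and assemble the five analysis groups.

    Complete trios get a full reduction-profile stage call; mother-only
    families use the ratio rule (stage undetermined when no threshold is
    supplied); father-only families can have maternal origin confirmed but
    not staged.  Mitotic calls are excluded entirely.  Groups returned:
    ``mothers_all``, ``mothers_mi``, ``mothers_mii`` (maternal sample ids),
    ``fathers`` (paternal sample ids of retained nondisjunction families)
    and ``tdt_families`` (family ids of retained complete trios).
    """
    calls = []
    for trio in cohort.trios:
        if trio.availability == COMPLETE:
            origin, n_mat, n_pat = infer_parent_of_origin(trio, cohort, min_evidence)
            if origin == MATERNAL:
                profile = build_reduction_profile(trio, cohort)
                call = call_stage_complete(profile, trio.family_id, min_support)
            else:
                call = OriginCall(trio.family_id, origin, UNDETERMINED, "complete_trio")
        elif trio.availability == MOTHER_ONLY:
            if threshold is not None:
                call = classify_dyad(trio, cohort, threshold)
            else:
                call = OriginCall(trio.family_id, MATERNAL, UNDETERMINED,
                                  "single_parent_ratio")
        else:  # father_only: origin may be confirmed, stage cannot
            origin, n_mat, n_pat = infer_parent_of_origin(trio, cohort, min_evidence)
            call = OriginCall(trio.family_id, origin, UNDETERMINED,
                              "single_parent_ratio", n_mat, n_pat)
        calls.append(call)

    by_family = {t.family_id: t for t in cohort.trios}
    groups = {"mothers_all": [], "mothers_mi": [], "mothers_mii": [],
              "fathers": [], "tdt_families": []}
    for call in calls:
        trio = by_family[call.family_id]
        if call.excluded or call.parent_of_origin not in (MATERNAL,):
            continue
        if trio.has_mother:
            groups["mothers_all"].append(trio.mother_id)
            if call.stage == MI:
                groups["mothers_mi"].append(trio.mother_id)
            elif call.stage == MII:
                groups["mothers_mii"].append(trio.mother_id)
        if trio.has_father:
            groups["fathers"].append(trio.father_id)
        if trio.availability == COMPLETE:
            groups["tdt_families"].append(trio.family_id)

    table = pd.DataFrame(
        {
            "family_id": [c.family_id for c in calls],
            "origin": [c.parent_of_origin for c in calls],
            "stage": [c.stage for c in calls],
            "method": [c.method for c in calls],
            "n_R": [c.n_R for c in calls],
            "n_N": [c.n_N for c in calls],
            "ratio": [c.pericentromeric_ratio for c in calls],
            "excluded": [c.excluded for c in calls],
        }
    )
    return PhenotypeResult(calls=table, groups=groups, origin_calls=calls)
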