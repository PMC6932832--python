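"""Core in-memory containers shared across the pipeline.

Genotypes are stored as B-allele dosages in ``int8`` arrays:

* disomic calls: 0, 1, 2; missing is ``-1``;
* trisomic chromosome-21 calls (the child's three alleles, unordered over
  {A, B}): 0..3; missing is ``-1``.

A trisomic trio consists of a child with three copies of chromosome 21 and
its genotyped parents.  Children carry ordinary disomic calls everywhere
except chromosome 21, where only the trisomic triple is stored (the disomic
slot is left missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1

#: nondisjunction stage labels
MI = "MI"
MII = "MII"
MITOTIC = "mitotic"
UNDETERMINED = "undetermined"
STAGES = (MI, MII, MITOTIC)

#: availability patterns for the two parents of a family
COMPLETE = "complete"
MOTHER_ONLY = "mother_only"
FATHER_ONLY = "father_only"
AVAILABILITIES = (COMPLETE, MOTHER_ONLY, FATHER_ONLY)

#: canonical variant-table columns used throughout the package
VARIANT_COLUMNS = (
    "id",
    "chrom",
    "pos_bp",
    "pos_cM",
    "allele_a",
    "allele_b",
    "info_score",
    "source",
)


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map of the modeled chromosome-21 q-arm markers.

    cM positions are measured from the centromere (0 cM at the centromere);
    all markers lie on the q arm, distal to ``centromere_bp``.
    """

    chromosome: str
    ids: tuple
    position_bp: np.ndarray
    position_cM: np.ndarray
    centromere_bp: int
    arm: str = "q"

    def __post_init__(self):
        bp = np.asarray(self.position_bp, dtype=np.int64)
        cm = np.asarray(self.position_cM, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or len(self.ids) != bp.size:
            raise ValueError("ids, position_bp and position_cM must be 1-D and equal length")
        if bp.size == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("position_bp must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("position_cM must be non-decreasing")
        if np.any(cm < 0):
            raise ValueError("position_cM must be non-negative")
        if np.any(bp <= self.centromere_bp):
            raise ValueError("all q-arm markers must lie distal to the centromere")
        object.__setattr__(self, "position_bp", bp)
        object.__setattr__(self, "position_cM", cm)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n_markers(self) -> int:
        return self.position_bp.size

    @property
    def length_cM(self) -> float:
        """Genetic length of the arm from the centromere to the last marker."""
        return float(self.position_cM[-1])

    def cm_to_bp(self, cm: np.ndarray) -> np.ndarray:
        """Interpolate genetic positions (cM from centromere) to bp."""
        xp = np.concatenate(([0.0], self.position_cM))
        fp = np.concatenate(([float(self.centromere_bp)], self.position_bp.astype(float)))
        return np.interp(np.asarray(cm, dtype=float), xp, fp).astype(np.int64)


def default_genetic_map(
    n_markers: int = 200,
    length_cM: float = 45.0,
    chromosome: str = "21",
    centromere_bp: int = 13_000_000,
    arm_end_bp: int = 46_700_000,
) -> GeneticMap:
    """Evenly spaced q-arm marker map with a uniform recombination rate.

    The default arm length (45 cM) is a configuration choice for the bundled
    map, not an estimate of the female chromosome-21q map.
    """
    bp = np.linspace(centromere_bp + 200_000, arm_end_bp, n_markers).astype(np.int64)
    bp = np.unique(bp)
    cm = (bp - bp[0]) / (bp[-1] - bp[0]) * length_cM if len(bp) > 1 else np.zeros(1)
    ids = tuple(f"c21q_{i:04d}" for i in range(len(bp)))
    return GeneticMap(chromosome, ids, bp, cm, centromere_bp)


@dataclass
class TrioRecord:
    """One family: disomic parental calls, the child's trisomic chr21 calls,
    and the child's disomic calls elsewhere."""

    family_id: str
    child_id: str
    mother_id: Optional[str]
    father_id: Optional[str]
    availability: str
    #: disomic B-dosage over the full variant panel (None when unavailable)
    mother_geno: Optional[np.ndarray]
    father_geno: Optional[np.ndarray]
    #: child disomic B-dosage; chr21 entries are MISSING (child is trisomic there)
    child_geno: np.ndarray
    #: child trisomic B-dosage (0..3) over the chr21 q-arm markers
    child_tris: np.ndarray

    def __post_init__(self):
        if self.availability not in AVAILABILITIES:
            raise ValueError(f"unknown availability pattern {self.availability!r}")
        if self.availability in (COMPLETE, MOTHER_ONLY) and self.mother_geno is None:
            raise ValueError(f"family {self.family_id}: mother genotypes required")
        if self.availability in (COMPLETE, FATHER_ONLY) and self.father_geno is None:
            raise ValueError(f"family {self.family_id}: father genotypes required")

    @property
    def has_mother(self) -> bool:
        return self.mother_geno is not None

    @property
    def has_father(self) -> bool:
        return self.father_geno is not None


@dataclass
class Cohort:
    """A set of trisomic trios over a shared variant panel."""

    variants: pd.DataFrame
    trios: list
    genetic_map: GeneticMap
    #: families dropped at read time, as (family_id, reason)
    exclusions: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("duplicated variant ids")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_families(self) -> int:
        return len(self.trios)

    @property
    def chr21_mask(self) -> np.ndarray:
        return (self.variants["chrom"] == self.genetic_map.chromosome).to_numpy()

    @property
    def chr21_index(self) -> np.ndarray:
        return np.flatnonzero(self.chr21_mask)

    def variant_index(self, ids) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(ids))
        if np.any(idx < 0):
            bad = [v for v, i in zip(ids, idx) if i < 0]
            raise KeyError(f"variant ids not in panel: {bad[:5]}")
        return idx

    def sample_ids(self, role: str) -> list:
        """Ids of genotyped members with the given role (mother/father/child)."""
        out = []
        for t in self.trios:
            if role == "mother" and t.has_mother:
                out.append(t.mother_id)
            elif role == "father" and t.has_father:
                out.append(t.father_id)
            elif role == "child":
                out.append(t.child_id)
        return out

    def genotype_matrix(self, sample_ids) -> np.ndarray:
        """Stack disomic genotype vectors (samples x variants) by sample id."""
        by_id = {}
        for t in self.trios:
            if t.has_mother:
                by_id[t.mother_id] = t.mother_geno
            if t.has_father:
                by_id[t.father_id] = t.father_geno
            by_id[t.child_id] = t.child_geno
        try:
            rows = [by_id[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return np.vstack(rows)

    def copy(self) -> "Cohort":
        import copy as _copy

        return Cohort(
            variants=self.variants.copy(),
            trios=[_copy.deepcopy(t) for t in self.trios],
            genetic_map=self.genetic_map,
            exclusions=list(self.exclusions),
        )


def triple_to_dosage(a1: str, a2: str, a3: str) -> int:
    """Unordered allele triple over {A,B} -> B dosage; '.' anywhere -> missing."""
    alleles = (a1, a2, a3)
    if "." in alleles:
        return MISSING
    bad = set(alleles) - {"A", "B"}
    if bad:
        raise ValueError(f"trisomic alleles outside {{A,B,.}}: {sorted(bad)}")
    return sum(a == "B" for a in alleles)


def dosage_to_triple(d: int) -> tuple:
    if d == MISSING:
        return (".", ".", ".")
    if not 0 <= d <= 3:
        raise ValueError(f"invalid trisomic dosage {d}")
    return tuple(["A"] * (3 - d) + ["B"] * d)
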