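import numpy as np
import pytest

from ndj21 import phenotype as ph
from ndj21 import simulate as sim


@pytest.fixture(scope="session")
def complete_cohort():
    """Error-free cohort of complete trios with truth labels."""
    cfg = sim.SimConfig(
        n_families=400,
        n_background=300,
        seed=42,
        parent_pattern_probs=(1.0, 0.0, 0.0),
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Error-free cohort with all three parent-availability patterns."""
    cfg = sim.SimConfig(
        n_families=120,
        n_background=200,
        seed=43,
        parent_pattern_probs=(0.7, 0.2, 0.1),
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def staged_pairs(complete_cohort):
    """(trio, complete-trio stage call) pairs for the masking experiment."""
    cohort = complete_cohort.cohort
    pairs = []
    for trio in cohort.trios:
        profile = ph.build_reduction_profile(trio, cohort)
        call = ph.call_stage_complete(profile, trio.family_id)
        pairs.append((trio, call.stage))
    return pairs


def make_trio(mother, father, child_tris, cohort, family_id="famX"):
    """Hand-built trio over an existing cohort's chr21 panel."""
    from ndj21.cohort import COMPLETE, MISSING, MOTHER_ONLY, TrioRecord

    V = cohort.n_variants
    idx = cohort.chr21_index
    m = np.full(V, MISSING, dtype=np.int8)
    f = np.full(V, MISSING, dtype=np.int8)
    m[idx] = mother
    if father is not None:
        f[idx] = father
    return TrioRecord(
        family_id=family_id,
        child_id=f"{family_id}_c",
        mother_id=f"{family_id}_m",
        father_id=f"{family_id}_f" if father is not None else None,
        availability=COMPLETE if father is not None else MOTHER_ONLY,
        mother_geno=m,
        father_geno=f if father is not None else None,
        child_geno=np.full(V, MISSING, dtype=np.int8),
        child_tris=np.asarray(child_tris, dtype=np.int8),
    )
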