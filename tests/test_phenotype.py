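"""Origin inference: marker scoring, stage calls, the ratio classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndj21 import phenotype as ph
from ndj21 import simulate as sim
from ndj21.cohort import MI, MII, MISSING, MITOTIC, UNDETERMINED
from tests.conftest import make_trio


class TestClassifyMarker:
    # (mother, father, child dosage) -> expected class, expected evidence
    @pytest.mark.parametrize(
        "m,f,c,cls,ev",
        [
            (1, 0, 2, "R", "maternal"),      # A/B x A/A, child A/B/B: mother gave B,B
            (1, 2, 2, "N", "none"),          # A/B x B/B, child A/B/B: mother gave A,B
            (1, 1, 1, "ambiguous", "none"),  # A/B x A/B, child A/A/B
            (0, 1, 1, "uninformative", "none"),  # mother homozygous
            (2, 0, 2, "uninformative", "maternal"),  # B/B x A/A, child A/B/B
            (1, MISSING, 3, "R", "none"),    # ungenotyped father, extreme dosage
            (MISSING, 0, 1, "uninformative", "none"),
        ],
    )
    def test_examples(self, m, f, c, cls, ev):
        out = ph.classify_marker(m, f, c)
        assert out.value == cls
        assert out.origin_evidence == ev

    @given(st.integers(-1, 2), st.integers(-1, 2), st.integers(-1, 3))
    @settings(derandomize=True, max_examples=200)
    def test_allele_label_symmetry(self, m, f, c):
        """Swapping A and B everywhere leaves class and evidence unchanged."""
        a = ph.classify_marker(m, f, c)
        m2 = m if m == MISSING else 2 - m
        f2 = f if f == MISSING else 2 - f
        c2 = c if c == MISSING else 3 - c
        b = ph.classify_marker(m2, f2, c2)
        assert a == b


class TestOriginInference:
    def test_error_free_maternal_cohort_all_called_maternal(self, complete_cohort):
        cohort = complete_cohort.cohort
        calls = [ph.infer_parent_of_origin(t, cohort)[0] for t in cohort.trios]
        assert all(c == ph.MATERNAL for c in calls)

    def test_no_evidence_gives_undetermined(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        trio = make_trio(np.zeros(n21, np.int8), np.zeros(n21, np.int8),
                         np.zeros(n21, np.int8), cohort)
        origin, n_mat, n_pat = ph.infer_parent_of_origin(trio, cohort)
        assert origin == UNDETERMINED and n_mat == 0 and n_pat == 0


class TestStageCall:
    def _call(self, cohort, mother, father, child, **kw):
        trio = make_trio(mother, father, child, cohort)
        profile = ph.build_reduction_profile(trio, cohort)
        return ph.call_stage_complete(profile, trio.family_id, **kw)

    def test_proximal_n_run_calls_mi(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        mother = np.ones(n21, np.int8)
        father = np.zeros(n21, np.int8)
        child = np.ones(n21, np.int8)           # N everywhere
        child[n21 // 2:] = 2                    # R distal half
        call = self._call(cohort, mother, father, child)
        assert call.stage == MI and not call.excluded

    def test_single_proximal_r_followed_by_ns_calls_mii(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        mother = np.ones(n21, np.int8)
        father = np.zeros(n21, np.int8)
        child = np.ones(n21, np.int8)
        child[0] = 2                            # single proximal R, then N's
        call = self._call(cohort, mother, father, child)
        assert call.stage == MII and call.n_R == 1
        assert "single_marker_support" in call.flags
        # the exception survives a stricter run-support requirement
        call2 = self._call(cohort, mother, father, child, min_support=3)
        assert call2.stage == MII

    def test_all_reduced_is_mitotic_and_excluded(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        mother = np.ones(n21, np.int8)
        father = np.zeros(n21, np.int8)
        child = np.full(n21, 2, np.int8)        # R at every informative marker
        call = self._call(cohort, mother, father, child)
        assert call.stage == MITOTIC and call.excluded

    def test_no_informative_markers_undetermined(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        call = self._call(cohort, np.zeros(n21, np.int8), np.zeros(n21, np.int8),
                          np.zeros(n21, np.int8))
        assert call.stage == UNDETERMINED and not call.excluded

    def test_error_free_stage_recovery(self, complete_cohort):
        cohort = complete_cohort.cohort
        truth = complete_cohort.truth.set_index("family_id")
        agree_mi = tot_mi = 0
        for trio in cohort.trios:
            profile = ph.build_reduction_profile(trio, cohort)
            call = ph.call_stage_complete(profile, trio.family_id)
            t = truth.loc[trio.family_id]
            if t["stage"] == MI:
                tot_mi += 1
                agree_mi += call.stage == MI
            elif t["stage"] == MII and t["n_crossovers"] == 0:
                # indistinguishable from a mitotic error by construction
                assert call.stage == MITOTIC
        assert agree_mi / tot_mi > 0.97

    def test_miscall_rate_decreases_with_marker_density(self):
        rates = []
        for n_markers in (20, 100, 500):
            gmap = sim.default_genetic_map(n_markers=n_markers)
            cfg = sim.SimConfig(n_families=600, n_background=10, seed=77,
                                parent_pattern_probs=(1.0, 0, 0),
                                genetic_map=gmap)
            s = sim.simulate_cohort(cfg)
            res = ph.phenotype_cohort(s.cohort)
            m = res.calls.merge(s.truth, on="family_id")
            informative = m[(m["stage_y"].isin([MI, MII]))
                            & ~((m["stage_y"] == MII) & (m["n_crossovers"] == 0))]
            rates.append((informative["stage_x"] != informative["stage_y"]).mean())
        assert rates[0] >= rates[1] - 0.01 >= rates[2] - 0.02
        assert rates[2] < rates[0]


class TestRatioClassifier:
    def test_all_reduced_window_gives_one(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        child = np.where(np.arange(n21) % 2 == 0, 0, 3).astype(np.int8)
        trio = make_trio(np.ones(n21, np.int8), None, child, cohort)
        assert ph.pericentromeric_ratio(trio, cohort, 10) == 1.0

    def test_unreduced_window_gives_zero(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        trio = make_trio(np.ones(n21, np.int8), None, np.ones(n21, np.int8), cohort)
        assert ph.pericentromeric_ratio(trio, cohort, 10) == 0.0

    def test_uninformative_mother_gives_none(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        trio = make_trio(np.zeros(n21, np.int8), None, np.zeros(n21, np.int8), cohort)
        assert ph.pericentromeric_ratio(trio, cohort, 10) is None

    def test_masked_ratio_finite_for_most_trios(self, staged_pairs, complete_cohort):
        cohort = complete_cohort.cohort
        finite = [
            ph.pericentromeric_ratio(t, cohort, 10) is not None
            for t, s in staged_pairs if s in (MI, MII)
        ]
        assert np.mean(finite) >= 0.9

    def test_perfectly_separated_ratios(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        mi_trio = make_trio(np.ones(n21, np.int8), np.zeros(n21, np.int8),
                            np.ones(n21, np.int8), cohort, "famMI")
        child_r = np.where(np.arange(n21) % 2 == 0, 0, 3).astype(np.int8)
        mii_trio = make_trio(np.ones(n21, np.int8), np.zeros(n21, np.int8),
                             child_r, cohort, "famMII")
        thr = ph.optimize_ratio_threshold(
            [(mi_trio, MI), (mii_trio, MII)], cohort, 10
        )
        assert thr.training_accuracy == 1.0
        assert thr.cutoff == pytest.approx(0.5)

    def test_masking_experiment_accuracy(self, staged_pairs, complete_cohort):
        cohort = complete_cohort.cohort
        thr = ph.optimize_ratio_threshold(staged_pairs, cohort)
        assert thr.training_accuracy >= 0.95

    def test_label_inversion_symmetry(self, staged_pairs, complete_cohort):
        """Inverting MI/MII labels mirrors the accuracy at any fixed cutoff."""
        cohort = complete_cohort.cohort
        pairs = [(t, s) for t, s in staged_pairs if s in (MI, MII)]
        ratios = np.array([ph.pericentromeric_ratio(t, cohort, 10) for t, _ in pairs])
        labels = np.array([s == MII for _, s in pairs])
        cut = 0.1
        acc = ((ratios >= cut) == labels).mean()
        acc_inv = ((ratios >= cut) == ~labels).mean()
        assert acc + acc_inv == pytest.approx(1.0)

    def test_no_finite_ratio_is_an_error(self, complete_cohort):
        cohort = complete_cohort.cohort
        n21 = cohort.chr21_index.size
        trio = make_trio(np.zeros(n21, np.int8), np.zeros(n21, np.int8),
                         np.zeros(n21, np.int8), cohort)
        with pytest.raises(ValueError):
            ph.optimize_ratio_threshold([(trio, MI), (trio, MII)], cohort, 10)


class TestPhenotypeCohort:
    def test_group_sizes_match_stage_mix(self, complete_cohort):
        cohort = complete_cohort.cohort
        res = ph.phenotype_cohort(cohort)
        truth = complete_cohort.truth
        n = len(truth)
        # expected mitotic calls: true mitotic + MII without crossover
        mii_noxo = ((truth["stage"] == MII) & (truth["n_crossovers"] == 0)).sum()
        expected_mitotic = (truth["stage"] == MITOTIC).sum() + mii_noxo
        n_mitotic = (res.calls["stage"] == MITOTIC).sum()
        assert abs(n_mitotic - expected_mitotic) <= 3 * np.sqrt(expected_mitotic) + 3
        assert len(res.groups["mothers_mi"]) + len(res.groups["mothers_mii"]) \
            <= len(res.groups["mothers_all"])

    def test_father_only_family_excluded_from_tdt_but_counts_father(self, mixed_cohort):
        cohort = mixed_cohort.cohort
        res = ph.phenotype_cohort(cohort)
        father_only = [t for t in cohort.trios if t.availability == "father_only"]
        assert father_only, "fixture should contain father_only families"
        tdt = set(res.groups["tdt_families"])
        for t in father_only:
            assert t.family_id not in tdt

    def test_runs_without_mii_trios(self):
        cfg = sim.SimConfig(n_families=60, n_background=50, seed=31,
                            stage_probs=(1.0, 0.0, 0.0),
                            parent_pattern_probs=(1.0, 0, 0))
        s = sim.simulate_cohort(cfg)
        res = ph.phenotype_cohort(s.cohort)
        assert len(res.groups["mothers_mii"]) == 0
        assert len(res.groups["mothers_mi"]) > 0
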