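"""Unit and property tests for ratios and the five indices.

Numeric expectations are hand arithmetic on the reference study's printed
group means, frozen here before implementation.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import needlestoich as ns

conc = st.floats(min_value=0.01, max_value=999.0, allow_nan=False)


@pytest.mark.parametrize(
    "c,n,p,exp_cn,exp_cp,exp_np",
    [
        # basal-chlorotic printed means
        (472.4, 7.2, 1.6, 65.61111111, 295.25, 4.5),
        (100.0, 100.0, 100.0, 1.0, 1.0, 1.0),
        # apical-chlorotic printed means
        (461.4, 24.7, 7.9, 18.68016194, 58.40506329, 3.12658228),
    ],
)
def test_ratio_arithmetic(c, n, p, exp_cn, exp_cp, exp_np):
    r = ns.ratios_from_concentrations(c, n, p)
    assert r.c_n == pytest.approx(exp_cn, rel=1e-8)
    assert r.c_p == pytest.approx(exp_cp, rel=1e-8)
    assert r.n_p == pytest.approx(exp_np, rel=1e-8)


@settings(max_examples=100, derandomize=True, database=None)
@given(c=conc, n=conc, p=conc)
def test_ratio_internal_consistency(c, n, p):
    r = ns.ratios_from_concentrations(c, n, p)
    assert r.n_p * r.c_n == pytest.approx(r.c_p, rel=1e-9)


class TestHomeostaticIndex:
    def test_hand_computed_example(self):
        s = ns.homeostatic_index([2, 4, 6])
        assert (s.mean, s.sd, s.cv, s.hi) == (4.0, 2.0, 0.5, 2.0)

    def test_zero_variance_group_is_flagged_not_a_crash(self):
        s = ns.homeostatic_index([5, 5, 5])
        assert s.degenerate and math.isinf(s.hi) and s.cv == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            ns.homeostatic_index([3.0])

    @settings(max_examples=50, derandomize=True, database=None)
    @given(values=st.lists(conc, min_size=2, max_size=10), k=st.floats(0.1, 100))
    def test_cv_and_hi_are_scale_invariant(self, values, k):
        a = ns.homeostatic_index(values)
        b = ns.homeostatic_index([k * v for v in values])
        assert b.cv == pytest.approx(a.cv, rel=1e-9, abs=1e-12)
        if not a.degenerate:
            assert b.hi == pytest.approx(a.hi, rel=1e-9)

    @settings(max_examples=50, derandomize=True, database=None)
    @given(values=st.lists(conc, min_size=2, max_size=10))
    def test_hi_times_cv_is_one_when_defined(self, values):
        s = ns.homeostatic_index(values)
        if not s.degenerate:
            assert s.hi * s.cv == pytest.approx(1.0, rel=1e-9)


class TestNutrientStressIndex:
    @staticmethod
    def _pairs(cns, cps):
        return [(f"s{i}", ns.StoichRatios(c_n=cn, c_p=cp, n_p=cp / cn))
                for i, (cn, cp) in enumerate(zip(cns, cps))]

    def test_two_sample_z_scores(self):
        recs = ns.nutrient_stress_index(self._pairs([10, 20], [100, 200]))
        assert recs[0].nsi == pytest.approx(-2 * 0.70710678, rel=1e-6)
        assert recs[1].nsi == pytest.approx(+2 * 0.70710678, rel=1e-6)

    def test_sample_at_reference_means_scores_zero(self):
        recs = ns.nutrient_stress_index(self._pairs([10, 20, 15], [100, 200, 150]))
        assert recs[2].nsi == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_reference_names_the_ratio(self):
        with pytest.raises(ns.indices.DegenerateReferenceError, match="C:N"):
            ns.nutrient_stress_index(self._pairs([10, 10], [100, 200]))

    @settings(max_examples=50, derandomize=True, database=None)
    @given(data=st.lists(st.tuples(conc, conc, conc), min_size=2, max_size=12))
    def test_nsi_sums_to_zero_over_the_reference_set(self, data):
        pairs = [(f"s{i}", ns.ratios_from_concentrations(c, n, p))
                 for i, (c, n, p) in enumerate(data)]
        try:
            recs = ns.nutrient_stress_index(pairs)
        except ns.indices.DegenerateReferenceError:
            return
        total = sum(r.nsi for r in recs)
        scale = max(sum(abs(r.nsi) for r in recs), 1.0)
        assert abs(total) / scale < 1e-9


class TestResorption:
    def test_printed_mean_examples(self):
        assert ns.resorption_efficiency(24.7, 7.2) == pytest.approx(70.85020243, rel=1e-8)
        assert ns.resorption_efficiency(21.9, 12.8) == pytest.approx(41.55251142, rel=1e-8)
        assert ns.resorption_efficiency(447.8, 481.8) == pytest.approx(-7.59267530, rel=1e-8)

    def test_identical_concentrations_give_zero(self):
        assert ns.resorption_efficiency(12.5, 12.5) == 0.0

    def test_nonpositive_apical_is_an_error(self):
        with pytest.raises(ValueError):
            ns.resorption_efficiency(0.0, 5.0)

    @settings(max_examples=100, derandomize=True, database=None)
    @given(a=conc, b1=conc, b2=conc)
    def test_nre_below_100_and_monotone_in_basal(self, a, b1, b2):
        lo, hi = sorted([b1, b2])
        assert ns.resorption_efficiency(a, lo) < 100.0
        assert ns.resorption_efficiency(a, hi) <= ns.resorption_efficiency(a, lo)


class TestResorptionPriority:
    def test_printed_mean_example_is_coupled_p_leaning(self):
        rpi, label = ns.resorption_priority(70.850, 79.747)
        assert rpi == pytest.approx(0.8884, abs=5e-4)
        assert label == "coupled/P-leaning"

    def test_equal_efficiencies_are_coupled(self):
        assert ns.resorption_priority(50, 50) == (1.0, "coupled")

    def test_zero_nre_p_is_flagged_undefined(self):
        assert ns.resorption_priority(40.0, 0.0) == (None, "undefined")

    @settings(max_examples=50, derandomize=True, database=None)
    @given(a=conc, b=conc, k=st.floats(0.1, 50))
    def test_scale_invariance(self, a, b, k):
        assert ns.resorption_priority(k * a, k * b)[0] == pytest.approx(
            ns.resorption_priority(a, b)[0], rel=1e-9)


class TestStoichiometricDeviation:
    def test_equal_ratios_give_zero(self):
        assert ns.stoichiometric_deviation(4.2, 4.2) == 0.0

    def test_basal_chlorotic_vs_poor_topsoil(self):
        # needle C:N from the basal-chlorotic printed means, soil C:N 5.2
        assert ns.stoichiometric_deviation(472.4 / 7.2, 5.2) == pytest.approx(11.6175, abs=2e-3)

    def test_denominator_is_always_the_soil_ratio(self):
        assert ns.stoichiometric_deviation(2.0, 8.0) != ns.stoichiometric_deviation(8.0, 2.0)

    def test_nonpositive_soil_ratio_is_an_error(self):
        with pytest.raises(ValueError):
            ns.stoichiometric_deviation(3.0, 0.0)

    @settings(max_examples=100, derandomize=True, database=None)
    @given(n=conc, s=conc, k=st.floats(0.1, 50))
    def test_nonnegative_and_scale_invariant(self, n, s, k):
        sdi = ns.stoichiometric_deviation(n, s)
        assert sdi >= 0.0
        assert ns.stoichiometric_deviation(k * n, k * s) == pytest.approx(sdi, rel=1e-9, abs=1e-12)


class TestPairResorption:
    @staticmethod
    def _needle(tree, position, n, p, condition="chlorotic"):
        return ns.ElementalSample(
            sample_id=f"{tree}-{position}", tree_id=tree, condition=condition,
            compartment="needle", position=position, c_conc=460.0, n_conc=n, p_conc=p)

    def test_constant_inputs_reproduce_printed_nre(self):
        needles = []
        for t in ("C1", "C2", "C3"):
            needles += [self._needle(t, "apical", 24.7, 7.9), self._needle(t, "basal", 7.2, 1.6)]
        ds = ns.StudyDataset(needles=tuple(needles), soils=())
        recs = ns.pair_resorption(ds)
        assert len(recs) == 3
        assert all(r.nre_n == pytest.approx(70.85020243) for r in recs)
        assert all(r.nre_p == pytest.approx(79.74683544) for r in recs)

    def test_apical_only_tree_is_excluded_with_warning(self):
        needles = (
            self._needle("C1", "apical", 24.7, 7.9), self._needle("C1", "basal", 7.2, 1.6),
            self._needle("C2", "apical", 25.0, 8.0),
        )
        ds = ns.StudyDataset(needles=needles, soils=())
        with pytest.warns(UserWarning, match="C2"):
            recs = ns.pair_resorption(ds)
        assert [r.tree_id for r in recs] == ["C1"]

    def test_identical_positions_give_zero_nre(self, zero_noise_config):
        cfg = zero_noise_config.model_copy(update={"group_means": {
            g: {"c": 450.0, "n": 20.0, "p": 6.0} for g in ("AH", "BH", "AC", "BC")}})
        ds = ns.generate_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            recs = ns.pair_resorption(ds)
        assert all(r.nre_n == 0.0 and r.nre_p == 0.0 for r in recs)


def test_deviation_records_cover_the_full_grid(zero_noise_dataset):
    recs = ns.deviation_records(zero_noise_dataset)
    # 12 needle samples x 5 layers x 3 ratios, same-tree pairing only
    assert len(recs) == 12 * 5 * 3
    assert all(r.sdi >= 0 for r in recs)
    trees = {(r.tree_id, r.position, r.soil_layer, r.ratio_name) for r in recs}
    assert len(trees) == len(recs)
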