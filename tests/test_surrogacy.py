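import numpy as np
import pytest

from surrokit import io, surrogacy as sg
from surrokit.types import ValidationError


class TestWeightedLinearFit:
    def test_equal_weight_hand_example(self):
        fit = sg.weighted_linear_fit([1, 2, 3], [1, 3, 2], [1, 1, 1])
        assert fit.r2 == pytest.approx(0.25, abs=1e-12)

    def test_collinear_points(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        fit = sg.weighted_linear_fit(x, 2 * x + 1, [3, 1, 2, 5])
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        lo, hi = sg.r2_confidence(fit, "wald")
        assert (lo, hi) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_r2_invariances(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        w = rng.uniform(1, 5, 8)
        base = sg.weighted_linear_fit(x, y, w).r2
        assert sg.weighted_linear_fit(3 * x - 1, y, w).r2 == pytest.approx(base)
        assert sg.weighted_linear_fit(x, -2 * y + 7, w).r2 == pytest.approx(base)
        assert sg.weighted_linear_fit(x, y, 10 * w).r2 == pytest.approx(base)
        assert sg.weighted_linear_fit(y, x, w).r2 == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero weighted variance"):
            sg.weighted_linear_fit([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_too_few_arms_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            sg.weighted_linear_fit([1, 2], [1, 2], [1, 1])

    def test_wald_lower_bound_can_go_negative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 0.1 * x + rng.normal(size=10)
        fit = sg.weighted_linear_fit(x, y, np.ones(10))
        if fit.r2 < 0.3:
            assert fit.r2_ci_low < 0

    def test_bootstrap_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = x + 0.5 * rng.normal(size=12)
        fit = sg.weighted_linear_fit(x, y, np.ones(12))
        lo, hi = sg.r2_confidence(fit, "bootstrap", seed=3)
        assert lo <= fit.r2 <= hi


class TestInteraction:
    def test_identical_groups_zero_interaction(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        y = 2 * x + 1
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = sg.interaction_test(x, y, np.ones(6), g)
        assert res.interaction_coef == pytest.approx(0.0, abs=1e-9)

    def test_unit_slope_offset_recovered(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        y = np.where(np.arange(6) < 3, 2 * x, 3 * x)  # group b slope +1
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = sg.interaction_test(x, y, np.ones(6), g)
        assert res.interaction_coef == pytest.approx(1.0, abs=1e-9)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=14)
            y = 1.5 * x + rng.normal(size=14)
            g = np.repeat(["a", "b"], 7)
            res = sg.interaction_test(x, y, np.ones(14), g)
            rejections += res.interaction_p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            sg.interaction_test([1, 2, 3, 4], [1, 2, 3, 4], np.ones(4),
                                ["a", "a", "a", "a"])


@pytest.fixture(scope="module")
def fits():
    arms = io.load_ici_arm_table()
    return sg.surrogacy_suite(arms, rmst=io.load_rmst_table())


class TestSuiteOnPackagedTables:

    def test_ici_rmst_pairs_reproduce_published_r2(self, fits):
        assert round(fits[("rmst6", "ICI")].r2, 2) == 0.80
        assert round(fits[("rmst12", "ICI")].r2, 2) == 0.80

    def test_ici_rmst_wald_cis_reproduce_published(self, fits):
        f6 = fits[("rmst6", "ICI")]
        assert (round(f6.r2_ci_low, 2), round(f6.r2_ci_high, 2)) == (0.64, 0.96)
        f12 = fits[("rmst12", "ICI")]
        assert (round(f12.r2_ci_low, 2), round(f12.r2_ci_high, 2)) == (0.63, 0.96)

    def test_ici_q1_close_to_published(self, fits):
        # input quartiles are themselves rounded, so match within 0.01
        assert fits[("q1", "ICI")].r2 == pytest.approx(0.89, abs=0.01)
        assert fits[("q1", "ICI")].n_arms == 7

    def test_pairs_without_enough_arms_are_skipped(self, fits):
        assert ("q3", "MKI") not in fits  # only 2 MKI comparator arms packaged

    def test_weights_are_sample_sizes(self, fits):
        f = fits[("rmst6", "ICI")]
        assert sorted(f.weights) == [35, 36, 104, 217, 278, 336, 371]


class TestSubgroupInteractions:
    def test_fixture_tables_yield_valid_p_values(self):
        arms = io.load_ici_arm_table()
        inter = sg.subgroup_interactions(arms, rmst=io.load_rmst_table())
        assert inter  # at least one pair/subgroup combination is testable
        for res in inter.values():
            assert 0.0 <= res.interaction_p <= 1.0
            assert len(res.groups) == 2

    def test_mixed_line_arms_excluded_from_line_split(self):
        arms = io.load_ici_arm_table()
        inter = sg.subgroup_interactions(arms, pairs=("q1",),
                                         subgroups=("line",),
                                         rmst=io.load_rmst_table())
        # only 1 first-line and few second-line Q1 arms remain once the
        # mixed-line CheckMate-040 arms are dropped -> combination skipped
        for (pair, var), res in inter.items():
            assert set(res.groups) <= {"first", "second"}


class TestORRSurrogacy:
    def _arms(self, orr, os_rate, n=None):
        from surrokit.types import ArmRecord, DrugClass, Phase, TreatmentLine

        n = n or [100] * len(orr)
        return [
            ArmRecord(trial_id=f"t{i}", arm_id=f"a{i}", drug_class=DrugClass.ICI,
                      line=TreatmentLine.FIRST, n=ni, phase=Phase.III,
                      controlled=True, orr_pct=o, os_rate_end_fu_pct=r)
            for i, (o, r, ni) in enumerate(zip(orr, os_rate, n))
        ]

    def test_perfectly_linear_arms(self):
        orr = [10.0, 20.0, 30.0, 40.0]
        rate = [15.0, 25.0, 35.0, 45.0]
        fit = sg.orr_surrogacy(self._arms(orr, rate))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation_shows_small_sample_bias(self):
        # E[R^2] under independence is ~1/(k-1) for k arms
        rng = np.random.default_rng(5)
        k, reps = 12, 400
        r2s = []
        for _ in range(reps):
            orr = rng.uniform(5, 40, k)
            rate = rng.uniform(20, 80, k)
            r2s.append(sg.orr_surrogacy(self._arms(orr, rate)).r2)
        assert np.mean(r2s) == pytest.approx(1 / (k - 1), abs=0.04)

    def test_slope_sign_matches_weighted_covariance(self):
        rng = np.random.default_rng(6)
        orr = rng.uniform(5, 40, 8)
        rate = 100 - orr + rng.normal(0, 2, 8)  # negative association
        fit = sg.orr_surrogacy(self._arms(list(orr), list(rate)))
        assert fit.slope < 0

    def test_too_few_usable_arms_rejected(self):
        with pytest.raises(ValidationError, match="3 arms"):
            sg.orr_surrogacy(self._arms([10.0, 20.0], [30.0, 40.0]))
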