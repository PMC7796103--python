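import numpy as np
import pytest
from lifelines import CoxPHFitter
import pandas as pd

from surrokit import ph
from surrokit.types import Endpoint, PHDiagnostics, PseudoIPD, TimeFunction, ValidationError


def _ipd(times, events, arm="arm", endpoint=Endpoint.OS):
    return PseudoIPD(arm, endpoint, np.asarray(times, float),
                     np.asarray(events, bool))


def _pair(rng, n, rate_os=0.08, rate_pfs=0.16, arm="arm"):
    return (
        _ipd(rng.exponential(1 / rate_os, n), np.ones(n), arm, Endpoint.OS),
        _ipd(rng.exponential(1 / rate_pfs, n), np.ones(n), arm, Endpoint.PFS),
    )


class TestStacking:
    def test_concatenation_preserves_counts(self):
        rng = np.random.default_rng(0)
        os_ipd, pfs_ipd = _pair(rng, 100)
        s = ph.stack_endpoints(os_ipd, pfs_ipd)
        assert len(s) == 200
        assert s.group.mean() == 0.5

    def test_arm_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        os_ipd, _ = _pair(rng, 10, arm="a")
        _, pfs_ipd = _pair(rng, 10, arm="b")
        with pytest.raises(ValidationError, match="mismatch"):
            ph.stack_endpoints(os_ipd, pfs_ipd)


class TestCoxPHTest:
    def test_identical_groups_give_exactly_zero_loghr(self):
        t = np.arange(1.0, 41.0)
        s = ph.stack_endpoints(_ipd(t, np.ones(40), endpoint=Endpoint.OS),
                               _ipd(t, np.ones(40), endpoint=Endpoint.PFS))
        d = ph.cox_ph_test(s)
        assert d.log_hr == 0.0

    def test_relabeling_negates_loghr_and_keeps_p(self):
        rng = np.random.default_rng(1)
        os_ipd, pfs_ipd = _pair(rng, 300)
        d1 = ph.cox_ph_test(ph.stack_endpoints(os_ipd, pfs_ipd))
        flipped = ph.StackedSample(
            arm_id="arm",
            times=np.concatenate((pfs_ipd.times, os_ipd.times)),
            events=np.concatenate((pfs_ipd.events, os_ipd.events)),
            group=np.concatenate((np.zeros(300), np.ones(300))),
        )
        d2 = ph.cox_ph_test(flipped)
        assert d2.log_hr == pytest.approx(-d1.log_hr, abs=1e-9)
        assert d2.schoenfeld_p == pytest.approx(d1.schoenfeld_p, abs=1e-9)

    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(2)
        os_ipd, pfs_ipd = _pair(rng, 500, rate_os=0.1, rate_pfs=0.2)
        d = ph.cox_ph_test(ph.stack_endpoints(os_ipd, pfs_ipd))
        assert 1.8 <= np.exp(d.log_hr) <= 2.2

    def test_agrees_with_brute_force_partial_likelihood(self):
        # tie-free instance small enough for an exhaustive grid search
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 18)
        events = np.ones(18, bool)
        events[[4, 11]] = False
        group = (np.arange(18) % 2).astype(float)
        s = ph.StackedSample("arm", times, events, group)
        d = ph.cox_ph_test(s)

        def brute_loglik(beta):
            ll = 0.0
            for t, e, g in zip(times, events, group):
                if not e:
                    continue
                at = times >= t
                ll += beta * g - np.log(np.sum(np.exp(beta * group[at])))
            return ll

        grid = np.linspace(d.log_hr - 0.5, d.log_hr + 0.5, 20001)
        best = grid[np.argmax([brute_loglik(b) for b in grid])]
        assert d.log_hr == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        os_ipd, pfs_ipd = _pair(rng, 200)
        s = ph.stack_endpoints(os_ipd, pfs_ipd)
        d = ph.cox_ph_test(s)
        df = pd.DataFrame({"t": s.times, "e": s.events.astype(int),
                           "x": s.group})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert d.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)

    def test_no_events_in_one_group_rejected(self):
        s = ph.StackedSample("arm", np.array([1.0, 2.0, 3.0, 4.0]),
                             np.array([1, 1, 0, 0], bool),
                             np.array([0.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ValidationError, match="at least one event"):
            ph.cox_ph_test(s)


class TestTimeDependentModels:
    def test_ph_data_mostly_selects_parsimonious_model(self):
        chosen = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            s = ph.stack_endpoints(*_pair(rng, 300))
            chosen.append(ph.time_dependent_hr(s).chosen_time_fn)
        frac_none = np.mean([c is TimeFunction.NONE for c in chosen])
        assert frac_none >= 0.6

    def test_log_time_interaction_coefficient_recovered(self):
        # group-1 hazard = rate * exp(0.5 + 0.3 log t): inversion sampling
        rng = np.random.default_rng(5)
        n, rate = 2000, 0.1
        t0 = rng.exponential(1 / rate, n)
        e1 = rng.exponential(1.0, n)
        t1 = (1.3 * e1 / (rate * np.exp(0.5))) ** (1 / 1.3)
        s = ph.StackedSample(
            "arm", np.concatenate((t0, t1)),
            np.ones(2 * n, bool),
            np.concatenate((np.zeros(n), np.ones(n))),
        )
        d = ph.time_dependent_hr(s, candidates=(TimeFunction.LOG,))
        rt_times = np.unique(s.times[s.events])
        # recover b1 from the fitted HR(t) curve when chosen, else refit check
        assert d.aic_by_model["log"] < d.aic_by_model["none"]
        from surrokit.ph import _fit_td, _risk_table
        coef, _ = _fit_td(_risk_table(s), np.log(rt_times))
        assert coef[1] == pytest.approx(0.3, abs=0.1)
        assert coef[0] == pytest.approx(0.5, abs=0.15)

    def test_crossing_weibull_hazards_detected(self):
        rng = np.random.default_rng(6)
        n = 500
        t0 = rng.weibull(0.5, n) * 10
        t1 = rng.weibull(2.0, n) * 10
        s = ph.StackedSample("arm", np.concatenate((t0, t1)),
                             np.ones(2 * n, bool),
                             np.concatenate((np.zeros(n), np.ones(n))))
        d = ph.time_dependent_hr(s)
        assert not d.ph_holds
        assert d.chosen_time_fn is not TimeFunction.NONE
        assert d.hr_t is not None
        assert len(d.hr_t) <= int(s.times.max())

    def test_aic_bookkeeping_consistent(self):
        rng = np.random.default_rng(7)
        s = ph.stack_endpoints(*_pair(rng, 200))
        d = ph.time_dependent_hr(s)
        assert set(d.aic_by_model) == {"none", "linear", "log", "step6mo"}
        assert d.chosen_time_fn.value == min(d.aic_by_model,
                                             key=d.aic_by_model.get)
        # an interaction model can never fit worse than PH by more than
        # the 2-point parameter penalty
        for name in ("linear", "log", "step6mo"):
            assert d.aic_by_model[name] <= d.aic_by_model["none"] + 2 + 1e-6


class TestNonPHFraction:
    @pytest.mark.parametrize("n_nonph,n_total,expected",
                             [(20, 30, 66.7), (5, 7, 71.4), (0, 4, 0.0)])
    def test_percentage_to_one_decimal(self, n_nonph, n_total, expected):
        diags = [PHDiagnostics(log_hr=0.0, schoenfeld_p=0.01, ph_holds=False)
                 for _ in range(n_nonph)]
        diags += [PHDiagnostics(log_hr=0.0, schoenfeld_p=0.5, ph_holds=True)
                  for _ in range(n_total - n_nonph)]
        assert ph.nonph_fraction(diags) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ph.nonph_fraction([])
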