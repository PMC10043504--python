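import numpy as np
import pytest

from progmetrics.cohort import cohort_to_frame
from progmetrics.metrics import builtin_metrics, get_metric
from progmetrics.rules import rule_leaves, builtin_rules
from progmetrics.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_test_retest_set,
    inject_progression,
)
from progmetrics.thresholds import build_pairs
from progmetrics.trend import fit_trend

from conftest import series_from_points


def small_cfg(**kw):
    base = dict(n_hc=4, n_patients=8, n_suspects=3, n_dp=2, seed=42)
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        c1, t1 = generate_cohort(small_cfg())
        c2, t2 = generate_cohort(small_cfg())
        assert cohort_to_frame(c1).equals(cohort_to_frame(c2))
        assert t1.status == t2.status and t1.rates == t2.rates

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(small_cfg(seed=1))
        c2, _ = generate_cohort(small_cfg(seed=2))
        assert not cohort_to_frame(c1).equals(cohort_to_frame(c2))

    def test_group_sizes_default_config(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0))
        groups = [e.group for e in cohort]
        assert groups.count("HC") == 30
        assert groups.count("patient") + groups.count("suspect") == 91
        assert groups.count("suspect") == 37
        assert sum(e.dp_label == "DP" for e in cohort) == 17
        assert sum(s == "dp" for s in truth.status.values()) == 17

    def test_zero_noise_zero_rates_constant_series(self):
        cfg = small_cfg(frac_nondp_progressing=0.0, n_dp=0)
        cfg.noise_sd = {m: 0.0 for m in cfg.metrics}
        cohort, _ = generate_cohort(cfg)
        for eye in cohort:
            for m in cfg.metrics:
                vals = [v for _, v in eye.metric_tests(m)]
                assert np.ptp(vals) == pytest.approx(0.0)

    def test_dp_rates_are_concordant_for_ss_and_hemifield_md(self):
        """A DP eye worsens in a TI/TS cpRNFL sector, the matching GCL
        region(s) and the matching hemifield MDs -- the concordance the
        S-S and hemifield S-F composites look for."""
        _, truth = generate_cohort(small_cfg())
        dp_eyes = [e for e, s in truth.status.items() if s == "dp"]
        assert dp_eyes
        for eye in dp_eyes:
            rates = truth.rates[eye]
            inf = rates.get("TI_small", 0) < 0 and (
                rates.get("TI_GCL", 0) < 0 or rates.get("I_GCL", 0) < 0
            ) and rates.get("infMD_24", 0) < 0
            sup = rates.get("TS_small", 0) < 0 and (
                rates.get("TS_GCL", 0) < 0 or rates.get("S_GCL", 0) < 0
            ) and rates.get("supMD_24", 0) < 0
            assert inf or sup

    def test_dp_ss_rule_components_all_worsen(self):
        _, truth = generate_cohort(small_cfg(seed=7))
        inf_leaves = rule_leaves(builtin_rules()["InferiorSS"])
        sup_leaves = rule_leaves(builtin_rules()["SuperiorSS"])
        for eye, s in truth.status.items():
            if s != "dp":
                continue
            rates = truth.rates[eye]
            ok_inf = all(rates.get(m, 0) < 0 for m in inf_leaves)
            ok_sup = all(rates.get(m, 0) < 0 for m in sup_leaves)
            assert ok_inf or ok_sup

    def test_visit_schedule_structure(self):
        cohort, _ = generate_cohort(small_cfg(seed=9))
        for eye in cohort:
            days = [(v.date - eye.visits[0].date).days for v in eye.visits]
            assert days[0] == 0
            assert days == sorted(days)
            assert 366 <= days[-1] <= 59 * 30.4375 + 40  # spans 1 year to ~59 months
            baseline = [d for d in days if d <= 120]
            assert 2 <= len(baseline) <= 4

    def test_plausibility_floors(self):
        cfg = small_cfg(seed=3)
        cfg.noise_sd = {m: 60.0 for m in cfg.metrics}  # absurd noise exercises clipping
        cohort, _ = generate_cohort(cfg)
        for eye in cohort:
            for m in cfg.metrics:
                for _, v in eye.metric_tests(m):
                    if get_metric(m).units == "µm":
                        assert v > 0
                    if m == "VFI_24":
                        assert 0 <= v <= 100

    def test_adding_eyes_does_not_shift_existing(self):
        c_small, _ = generate_cohort(small_cfg(n_hc=3))
        c_big, _ = generate_cohort(small_cfg(n_hc=6))
        f_small = cohort_to_frame(c_small)
        f_big = cohort_to_frame(c_big)
        hc3 = f_small[f_small.eye_id == "HC_0002"].reset_index(drop=True)
        hc3_big = f_big[f_big.eye_id == "HC_0002"].reset_index(drop=True)
        assert hc3.equals(hc3_big)


class TestRetestSet:
    def test_all_visits_within_window_and_reproducible(self):
        cfg = small_cfg(n_retest_eyes=20, n_retest_hc=5)
        rt1 = generate_test_retest_set(cfg)
        rt2 = generate_test_retest_set(cfg)
        assert cohort_to_frame(rt1).equals(cohort_to_frame(rt2))
        for eye in rt1:
            days = [(v.date - eye.visits[0].date).days for v in eye.visits]
            assert days[-1] <= 120
            assert 2 <= len(days) <= 4

    def test_zero_noise_followups_equal_baseline(self):
        cfg = small_cfg(n_retest_eyes=10, n_retest_hc=3)
        cfg.noise_sd = {m: 0.0 for m in cfg.metrics}
        rt = generate_test_retest_set(cfg)
        for eye in rt:
            for m in cfg.metrics:
                vals = [v for _, v in eye.metric_tests(m)]
                assert np.ptp(vals) == pytest.approx(0.0)

    def test_pair_scale_and_short_interval_clustering(self):
        """176 retest eyes yield >2000 pairs over 30 metrics, most within 60 days."""
        rt = generate_test_retest_set(GeneratorConfig(seed=0))
        total = 0
        short = 0
        for m in builtin_metrics():
            ps = build_pairs(rt, m)
            total += len(ps)
            short += sum(p.dt_days <= 60 for p in ps.pairs)
        assert total > 2000
        assert short / total > 0.5


class TestInjectProgression:
    def test_zero_rate_is_identity(self):
        s = series_from_points([(0, 100.0), (200, 99.0), (420, 95.0)])
        out = inject_progression(s, {"G_small": 0.0})
        assert [v for _, v in out.metric_tests("G_small")] == [100.0, 99.0, 95.0]

    def test_linear_shift_matches_rate_times_time(self):
        s = series_from_points([(0, 100.0), (731, 100.0)])  # 2.0014 years apart
        out = inject_progression(s, {"G_small": -2.0})
        vals = [v for _, v in out.metric_tests("G_small")]
        assert vals[0] == pytest.approx(100.0)
        assert vals[1] == pytest.approx(100.0 - 2.0 * 731 / 365.25)

    def test_ols_recovers_injected_rate(self):
        rng = np.random.default_rng(0)
        pts = [(int(d), 100.0 + rng.normal(0, 0.05)) for d in np.linspace(0, 1095, 8)]
        s = series_from_points(pts)
        out = inject_progression(s, {"G_small": -2.0})
        fit = fit_trend(out, "G_small")
        assert fit.slope == pytest.approx(-2.0, abs=4 * fit.se_slope + 0.05)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_dp=5, n_patients=3).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(followup_months_range=(6, 59)).validate()
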