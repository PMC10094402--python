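"""Parallelism, Fieller relative potency, and interaction classification."""

import numpy as np
import pytest

from nocistat.dose_response import DoseEffectPoint, fit_log_dose_line
from nocistat.errors import InsufficientDataError
from nocistat.interaction import (
    PotencyComparison,
    classify_interaction,
    fixed_dose_analysis,
    relative_potency,
)
from nocistat.interaction import test_parallelism as parallelism_test
from nocistat.synthetic import ScenarioConfig, simulate_dose_response_experiment


def fit_from(doses, effects):
    return fit_log_dose_line([DoseEffectPoint(d, e) for d, e in zip(doses, effects)])


def noisy_arm(rng, doses, slope, intercept, sd, reps=6):
    d = np.repeat(doses, reps)
    e = intercept + slope * np.log10(d) + rng.normal(0, sd, d.size)
    return fit_from(d, np.clip(e, None, 100.0))


DOSES = np.array([1.0, 4.0, 16.0])


class TestParallelism:
    def test_identical_datasets_exactly_parallel(self):
        f = fit_from([1, 2, 4, 8], [10, 25, 35, 55])
        F, p, (dfn, dfd) = parallelism_test(f, fit_from([1, 2, 4, 8], [10, 25, 35, 55]))
        assert F == 0.0 and p == 1.0
        assert (dfn, dfd) == (1, 4)

    def test_gross_slope_violation(self, rng):
        a = noisy_arm(rng, DOSES, +50.0, 20.0, 0.5)
        b = noisy_arm(rng, DOSES, -50.0, 20.0, 0.5)
        _, p, _ = parallelism_test(a, b)
        assert p < 1e-3

    def test_null_rejection_rate(self, rng):
        """Same true line + noise: parallelism rejected rarely."""
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = noisy_arm(rng, DOSES, 40.0, 10.0, 6.0)
            b = noisy_arm(rng, DOSES, 40.0, 5.0, 6.0)
            _, p, _ = parallelism_test(a, b)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.10

    def test_needs_residual_df(self):
        f3 = fit_from([1, 2, 4], [10, 20, 30])
        f2 = fit_log_dose_line([DoseEffectPoint(1, 10), DoseEffectPoint(2, 20), DoseEffectPoint(4, 30)])
        assert f3.df >= 1 and f2.df >= 1  # 3 points -> df 1, allowed
        bad = fit_from([1, 2, 4], [10, 20, 30])
        bad.df = 0
        with pytest.raises(InsufficientDataError):
            parallelism_test(bad, f3)


class TestRelativePotency:
    def test_exact_2x_dose_shift(self):
        """Arm B = arm A with every dose doubled, same effects ->
        ratio exactly 2, CL collapsed to the point."""
        doses = [1.0, 2.0, 4.0, 8.0]
        effects = [10.0, 25.0, 40.0, 55.0]
        comp = relative_potency(fit_from(doses, effects), fit_from([2 * d for d in doses], effects))
        assert comp.ratio == pytest.approx(2.0, rel=1e-9)
        assert comp.cl_low == pytest.approx(2.0, rel=1e-6)
        assert comp.cl_high == pytest.approx(2.0, rel=1e-6)
        assert comp.g == pytest.approx(0.0, abs=1e-12)
        assert comp.shift_direction == "rightward"

    def test_self_comparison_is_additive_identity(self):
        f = fit_from([1, 2, 4, 8], [12, 28, 41, 57])
        comp = relative_potency(f, fit_from([1, 2, 4, 8], [12, 28, 41, 57]))
        assert comp.parallelism_F == 0.0
        assert comp.ratio == pytest.approx(1.0)
        assert comp.verdict == "additive"

    def test_dose_scale_equivariance(self, rng):
        """Multiplying all doses in both arms by c leaves ratio, F, p
        unchanged (log shift cancels)."""
        a_eff = 20 + 30 * np.log10(np.repeat(DOSES, 6)) + rng.normal(0, 5, 18)
        b_eff = 10 + 30 * np.log10(np.repeat(DOSES, 6)) + rng.normal(0, 5, 18)
        c = 3.7
        comp1 = relative_potency(
            fit_from(np.repeat(DOSES, 6), a_eff), fit_from(np.repeat(DOSES, 6), b_eff)
        )
        comp2 = relative_potency(
            fit_from(np.repeat(DOSES * c, 6), a_eff), fit_from(np.repeat(DOSES * c, 6), b_eff)
        )
        assert comp2.ratio == pytest.approx(comp1.ratio, rel=1e-9)
        assert comp2.parallelism_F == pytest.approx(comp1.parallelism_F, rel=1e-9)
        assert comp2.cl_low == pytest.approx(comp1.cl_low, rel=1e-6)

    def test_nonparallel_withholds_ratio(self, rng):
        a = noisy_arm(rng, DOSES, +50.0, 20.0, 0.5)
        b = noisy_arm(rng, DOSES, -50.0, 20.0, 0.5)
        comp = relative_potency(a, b)
        assert comp.verdict == "indeterminate-nonparallel"
        assert np.isnan(comp.ratio)

    def test_cl_unbounded_when_g_exceeds_one(self, rng):
        """Huge residual noise with a shallow slope drives Fieller's
        g >= 1: the CL must be reported unbounded, not exploded."""
        a = noisy_arm(rng, DOSES, 3.0, 40.0, 30.0)
        b = noisy_arm(rng, DOSES, 3.0, 35.0, 30.0)
        comp = relative_potency(a, b, parallelism_alpha=1e-9)
        if comp.g >= 1.0:
            assert comp.cl_unbounded
            assert not comp.significant

    def test_fieller_interval_contains_point_estimate(self, rng):
        for _ in range(20):
            a = noisy_arm(rng, DOSES, 40.0, 10.0, 6.0)
            b = noisy_arm(rng, DOSES, 40.0, 0.0, 6.0)
            comp = relative_potency(a, b, parallelism_alpha=1e-6)
            if np.isfinite(comp.cl_low) and np.isfinite(comp.cl_high):
                assert comp.cl_low <= comp.ratio <= comp.cl_high


class TestClassification:
    def make_comp(self, ratio, cl_low, cl_high, nonparallel=False):
        sig = np.isfinite(cl_low) and np.isfinite(cl_high) and (cl_low > 1 or cl_high < 1)
        comp = PotencyComparison(
            parallelism_F=0.0,
            parallelism_p=0.001 if nonparallel else 0.9,
            common_slope=40.0,
            log_ratio=np.log10(ratio) if np.isfinite(ratio) else np.nan,
            ratio=ratio,
            cl_low=cl_low,
            cl_high=cl_high,
            significant=sig,
            verdict="indeterminate-nonparallel" if nonparallel else "",
            verdict_significant=sig,
            shift_direction="rightward" if ratio > 1 else "leftward" if ratio < 1 else "none",
        )
        return comp

    def test_published_phase1_case(self):
        """Ratio 2.40 with CL 0.50-139.12: a rightward (antagonism-direction)
        shift that is not statistically significant."""
        comp = self.make_comp(2.40, 0.50, 139.12)
        assert comp.shift_direction == "rightward"
        assert not comp.verdict_significant
        assert classify_interaction(comp) == "additive"  # CL spans 1: no demonstrable departure

    def test_tight_unity_ratio_additive(self):
        assert classify_interaction(self.make_comp(1.0, 0.9, 1.1)) == "additive"

    def test_significant_left_shift_synergy(self):
        comp = self.make_comp(1 / 3.0, 0.2, 0.6)
        assert classify_interaction(comp) == "synergy"
        assert comp.verdict_significant

    def test_significant_right_shift_antagonism(self):
        assert classify_interaction(self.make_comp(3.0, 1.5, 6.0)) == "antagonism"

    def test_nonparallel_indeterminate(self):
        assert classify_interaction(self.make_comp(np.nan, np.nan, np.nan, nonparallel=True)) \
            == "indeterminate-nonparallel"


class TestFixedDoseAnalysis:
    def test_parallel_model_ed50_identity(self):
        """Under the fitted parallel model, ED50_combination equals
        ratio x ED50_alone by construction; checked on a simulated run."""
        cfg = ScenarioConfig(seed=0, noise_cv=0.10)
        recs = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
        rep = fixed_dose_analysis(recs, 1, fixed_ms_dose=5.0)
        assert np.isfinite(rep.comparison.ratio)
        assert rep.ed50_combination == pytest.approx(rep.comparison.ratio * rep.alone_fit.ed50)

    def test_submaximal_route_triggered(self):
        cfg = ScenarioConfig(seed=5, noise_cv=0.05)
        recs = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
        rep = fixed_dose_analysis(recs, 1, fixed_ms_dose=5.0)
        # phase-1 cromoglycate tops out below 60% -> double-reciprocal ED50
        assert rep.alone_fit.method_tag == "emax_rescaled"
        assert rep.alone_max_effect_pct < 60.0

    def test_report_contains_per_dose_inhibition(self):
        cfg = ScenarioConfig(seed=7, noise_cv=0.10, interaction_mode="inhibit",
                             interaction_magnitude=1.0)
        recs = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
        rep = fixed_dose_analysis(recs, 1, fixed_ms_dose=5.0)
        assert set(rep.per_dose_inhibition) <= {1.0, 5.0, 10.0}
        assert len(rep.per_dose_inhibition) >= 2

    def test_requires_three_doses(self):
        cfg = ScenarioConfig(seed=5)
        recs = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
        thin = [r for r in recs if r.cg_dose != 5.0]
        with pytest.raises(InsufficientDataError):
            fixed_dose_analysis(thin, 1, fixed_ms_dose=5.0)
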