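"""Log-dose line fitting, double-reciprocal Emax, ED50."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_line
from nocistat.dose_response import (
    DoseEffectPoint,
    DoseResponseFit,
    ed50_from_line,
    ed50_submaximal,
    estimate_emax_double_reciprocal,
    fit_log_dose_line,
)
from nocistat.errors import (
    InsufficientDataError,
    NoAsymptoteError,
    RankDeficiencyError,
    UndefinedED50Error,
    ValidationError,
)


def points(doses, effects, weights=None):
    weights = weights or [1.0] * len(doses)
    return [DoseEffectPoint(d, e, w) for d, e, w in zip(doses, effects, weights)]


class TestFitLogDoseLine:
    def test_exact_line(self):
        doses = [1.0, 3.0, 10.0, 30.0]
        effects = [10 + 20 * np.log10(d) for d in doses]
        fit = fit_log_dose_line(points(doses, effects))
        assert fit.slope == pytest.approx(20.0)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert fit.df == 2

    def test_symmetric_construction(self):
        fit = fit_log_dose_line(points([1, 10, 100], [0, 50, 100]))
        assert fit.slope == pytest.approx(50.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """100 random small instances agree with explicit normal equations."""
        for _ in range(100):
            n = rng.integers(3, 9)
            doses = rng.uniform(0.1, 50, n)
            doses[1] = doses[0] * 2  # guarantee 2 distinct doses
            effects = rng.uniform(-50, 100, n)
            w = rng.uniform(0.5, 6, n)
            fit = fit_log_dose_line(points(doses, effects, list(w)))
            slope, intercept = brute_force_line(np.log10(doses), effects, w)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_log_dose_line(points([1, 2], [10, 20]))

    def test_identical_doses_rank_deficient(self):
        with pytest.raises(RankDeficiencyError):
            fit_log_dose_line(points([5, 5, 5], [10, 20, 30]))

    def test_zero_dose_rejected_at_point(self):
        with pytest.raises(ValidationError):
            DoseEffectPoint(0.0, 10.0)

    @given(st.floats(-30, 30))
    def test_effect_shift_moves_intercept_only(self, c):
        doses = [1.0, 4.0, 16.0]
        base = [5.0, 40.0, 60.0]
        f0 = fit_log_dose_line(points(doses, base))
        f1 = fit_log_dose_line(points(doses, [e + c for e in base]))
        assert f1.slope == pytest.approx(f0.slope, rel=1e-9)
        assert f1.intercept == pytest.approx(f0.intercept + c, rel=1e-9, abs=1e-9)


class TestED50FromLine:
    @pytest.mark.parametrize(
        "slope, intercept, target, expected",
        [(50.0, 0.0, 50.0, 10.0), (20.0, 10.0, 50.0, 100.0), (50.0, 0.0, 0.0, 1.0)],
    )
    def test_closed_form(self, slope, intercept, target, expected):
        fit = DoseResponseFit(slope, intercept, 0.0, 1, np.nan)
        assert ed50_from_line(fit, target) == pytest.approx(expected)

    def test_zero_slope_undefined(self):
        with pytest.raises(UndefinedED50Error):
            ed50_from_line(DoseResponseFit(0.0, 10.0, 0.0, 1, np.nan))

    def test_negative_slope_warns_but_returns(self):
        fit = DoseResponseFit(-20.0, 90.0, 0.0, 1, np.nan)
        with pytest.warns(UserWarning, match="inverted"):
            assert ed50_from_line(fit) == pytest.approx(100.0)

    def test_extrapolation_flagged(self):
        fit = fit_log_dose_line(points([1, 2, 4], [5.0, 10.0, 15.0]))
        with pytest.warns(UserWarning, match="extrapolated"):
            ed50_from_line(fit)
        assert fit.ed50_extrapolated


class TestDoubleReciprocal:
    def test_hyperbola_recovered_exactly(self):
        doses = [1.0, 5.0, 10.0]
        effects = [80.0 * d / (d + 2.0) for d in doses]
        assert estimate_emax_double_reciprocal(points(doses, effects)) == pytest.approx(80.0)

    def test_flat_curve(self):
        assert estimate_emax_double_reciprocal(points([1, 5, 10], [50, 50, 50])) == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 8))
            doses = rng.uniform(0.5, 40, n)
            effects = rng.uniform(5, 95, n)
            _, intercept = brute_force_line(1.0 / doses, 1.0 / effects)
            if intercept <= 0:
                with pytest.raises(NoAsymptoteError):
                    estimate_emax_double_reciprocal(points(doses, effects))
                continue
            emax = estimate_emax_double_reciprocal(points(doses, effects))
            assert emax == pytest.approx(1.0 / intercept, rel=1e-10)

    def test_nonpositive_effect_strict_errors(self):
        with pytest.raises(ValidationError):
            estimate_emax_double_reciprocal(points([1, 5, 10, 20], [-5, 30, 40, 45]), strict=True)

    def test_nonpositive_effects_excluded_with_warning(self):
        pts = points([1, 5, 10, 20], [40.0, -5.0, 60.0, 70.0])
        with pytest.warns(UserWarning, match="non-positive"):
            estimate_emax_double_reciprocal(pts)

    def test_no_asymptote(self):
        # reciprocal line 1/E = -0.01 + 0.1*(1/D): negative intercept,
        # no finite maximal effect
        doses = [1.0, 2.0, 4.0]
        pts = points(doses, [1.0 / (0.1 / d - 0.01) for d in doses])
        with pytest.raises(NoAsymptoteError):
            estimate_emax_double_reciprocal(pts)


class TestED50Submaximal:
    def test_half_saturation_identity(self):
        """E = 80 D/(D+2) -> Emax 80, ED50 = K = 2, both exact."""
        doses = [1.0, 5.0, 10.0]
        fit = ed50_submaximal(points(doses, [80.0 * d / (d + 2.0) for d in doses]))
        assert fit.emax == pytest.approx(80.0)
        assert fit.ed50 == pytest.approx(2.0)
        assert fit.method_tag == "emax_rescaled"

    def test_line_is_on_rescaled_effects(self):
        doses = [1.0, 5.0, 10.0]
        effects = [80.0 * d / (d + 2.0) for d in doses]
        fit = ed50_submaximal(points(doses, effects))
        slope, intercept = brute_force_line(
            np.log10(doses), [100.0 * e / 80.0 for e in effects]
        )
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_phase1_group_means_give_plausible_ed50(self):
        """Published phase-1 group means (1/5/10 mg/kg -> 33.0/66.6/75%)
        give an ED50 of the same order as the per-rat estimate 2.35."""
        fit = ed50_submaximal(points([1.0, 5.0, 10.0], [33.0, 66.6, 75.0]))
        assert 0.5 < fit.ed50 < 10.0
        assert 75.0 < fit.emax <= 100.0


class TestParameterRecovery:
    def test_ed50_recovery_median_error(self, rng):
        """Per-rat AA simulated from a known line; median |relative error|
        of the recovered ED50 shrinks well under 20% at 6 rats x 3 doses."""
        true_slope, true_ed50 = 45.0, 7.0
        doses = np.repeat([1.0, 10.0, 30.0], 6)
        x = np.log10(doses)
        true_int = 50.0 - true_slope * np.log10(true_ed50)
        errs = []
        for _ in range(200):
            eff = np.clip(true_int + true_slope * x + rng.normal(0, 8, x.size), None, 100.0)
            fit = fit_log_dose_line(points(doses, eff))
            errs.append(abs(fit.ed50 - true_ed50) / true_ed50)
        assert np.median(errs) < 0.20
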