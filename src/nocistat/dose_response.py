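"""Log dose-response fitting, double-reciprocal Emax estimation, ED50.

Pharmacological convention: the effect (AA%) is regressed on log10(dose).
Drugs that reach a full effect get their ED50 read off the fitted line at
an absolute 50% effect.  Drugs with a submaximal asymptote (efficacy below
~60%) are handled Tallarida-style: the maximal effect Emax is estimated
from the double-reciprocal regression of 1/E on 1/D, effects are rescaled
to percent-of-Emax for the line comparison, and the ED50 is the
half-saturation dose.  For an ideal hyperbola E = Emax*D/(D+K) the
reciprocal plot is an exact line with intercept 1/Emax and slope K/Emax,
so both Emax and ED50 = K are recovered exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    NoAsymptoteError,
    RankDeficiencyError,
    UndefinedED50Error,
    ValidationError,
)


@dataclass(frozen=True)
class DoseEffectPoint:
    """One (dose, effect) observation; ``weight`` carries the n behind a
    group-mean point (1 for a per-rat point)."""

    dose: float
    effect: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose) and self.dose > 0):
            raise ValidationError(f"dose must be > 0 (log must exist), got {self.dose!r}")
        if not math.isfinite(self.effect) or self.effect > 100.0 + 1e-9:
            raise ValidationError(f"effect must be finite and <= 100, got {self.effect!r}")
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValidationError(f"weight must be > 0, got {self.weight!r}")


@dataclass
class DoseResponseFit:
    """A fitted log10(dose)-effect line with the data kept for pooled tests.

    ``residual_ss`` and ``df`` feed the parallelism and Fieller machinery
    downstream; ``method_tag`` records whether effects were raw AA%
    (``direct``) or percent-of-Emax (``emax_rescaled``).
    """

    slope: float
    intercept: float
    residual_ss: float
    df: int
    ed50: float
    emax: float | None = None
    method_tag: str = "direct"
    ed50_extrapolated: bool = False
    log_doses: np.ndarray = field(default_factory=lambda: np.empty(0))
    effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_points(self) -> int:
        return len(self.log_doses)


def _as_arrays(points: Sequence[DoseEffectPoint]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.array([p.dose for p in points], dtype=float)
    e = np.array([p.effect for p in points], dtype=float)
    w = np.array([p.weight for p in points], dtype=float)
    return d, e, w


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares of y on x; returns (slope, intercept, rss)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, _, _, _ = np.linalg.lstsq(X, y * sw, rcond=None)
    resid = y - (coef[0] + coef[1] * x)
    rss = float(np.sum(w * resid**2))
    return float(coef[1]), float(coef[0]), rss


def fit_log_dose_line(
    points: Sequence[DoseEffectPoint],
    target_effect: float = 50.0,
) -> DoseResponseFit:
    """Ordinary (weight-aware) least squares of effect on log10(dose).

    Requires >= 3 points spanning >= 2 distinct doses.  The ED50 at
    ``target_effect`` is filled in (extrapolation flagged, not refused).
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 dose-effect points, got {len(points)}")
    d, e, w = _as_arrays(points)
    if np.unique(d).size < 2:
        raise RankDeficiencyError("all doses identical: log-dose line is rank deficient")
    x = np.log10(d)
    slope, intercept, rss = _wls_line(x, e, w)
    fit = DoseResponseFit(
        slope=slope,
        intercept=intercept,
        residual_ss=rss,
        df=len(points) - 2,
        ed50=np.nan,
        log_doses=x,
        effects=e,
        weights=w,
    )
    if slope != 0.0:
        fit.ed50 = ed50_from_line(fit, target_effect)
    return fit


def ed50_from_line(fit: DoseResponseFit, target_effect: float = 50.0) -> float:
    """Dose at which the fitted line crosses ``target_effect``:
    ``10**((target - intercept)/slope)``.

    Sets ``fit.ed50_extrapolated`` when the crossing lies outside the
    fitted dose range; a negative slope yields a value but is warned about
    (inverted curve).
    """
    if fit.slope == 0.0:
        raise UndefinedED50Error("slope is zero: no dose attains the target effect")
    if fit.slope < 0:
        warnings.warn("negative dose-response slope: ED50 from an inverted curve", stacklevel=2)
    log_ed = (target_effect - fit.intercept) / fit.slope
    if fit.n_points:
        fit.ed50_extrapolated = bool(
            log_ed < fit.log_doses.min() - 1e-12 or log_ed > fit.log_doses.max() + 1e-12
        )
        if fit.ed50_extrapolated:
            warnings.warn("ED50 extrapolated beyond the fitted dose range", stacklevel=2)
    return float(10.0**log_ed)


def _reciprocal_fit(
    points: Sequence[DoseEffectPoint], strict: bool = False
) -> tuple[float, float]:
    """Double-reciprocal regression 1/E on 1/D -> (emax, half_saturation_dose)."""
    usable = [p for p in points if p.effect > 0]
    dropped = len(points) - len(usable)
    if dropped:
        if strict:
            raise ValidationError(
                f"{dropped} non-positive effect(s): reciprocal undefined in strict mode"
            )
        warnings.warn(
            f"excluded {dropped} non-positive effect(s) from the reciprocal fit",
            stacklevel=3,
        )
    if len(usable) < 3:
        raise InsufficientDataError("need >= 3 points with positive effects for a reciprocal fit")
    d, e, w = _as_arrays(usable)
    slope, intercept, _ = _wls_line(1.0 / d, 1.0 / e, w)
    if intercept <= 0:
        raise NoAsymptoteError(
            f"reciprocal intercept {intercept:.4g} <= 0: no finite maximal effect"
        )
    emax = 1.0 / intercept
    k = slope * emax  # slope = K/Emax for the hyperbola
    return emax, k


def estimate_emax_double_reciprocal(
    points: Sequence[DoseEffectPoint], strict: bool = False
) -> float:
    """Maximal effect Emax = 1/intercept of the 1/E-vs-1/D regression."""
    emax, _ = _reciprocal_fit(points, strict=strict)
    return emax


def ed50_submaximal(
    points: Sequence[DoseEffectPoint], strict: bool = False
) -> DoseResponseFit:
    """ED50 for a submaximal-efficacy drug via the double-reciprocal route.

    Emax and the half-saturation dose K come from the reciprocal
    regression (exact on hyperbolic data); each effect is then rescaled to
    percent-of-Emax and a log-dose line is fitted on the rescaled effects
    for downstream parallel-line comparison.  The returned fit carries
    ``ed50 = K`` (the dose producing 50% of Emax) and
    ``method_tag = "emax_rescaled"``.
    """
    emax, k = _reciprocal_fit(points, strict=strict)
    if k <= 0:
        raise UndefinedED50Error(f"half-saturation dose {k:.4g} <= 0: curve is not increasing")
    rescaled = [
        DoseEffectPoint(p.dose, min(100.0, 100.0 * p.effect / emax), p.weight)
        for p in points
        if p.effect > 0 or not strict
    ]
    fit = fit_log_dose_line(rescaled)
    fit.emax = emax
    fit.ed50 = k
    fit.method_tag = "emax_rescaled"
    return fit
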