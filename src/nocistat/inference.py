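"""Group-comparison machinery: split-plot ANOVA and Tukey HSD.

The study design is one between-subjects factor (treatment group) crossed
with one within-subjects factor (time bin or phase), balanced at n rats
per group — a classical split-plot / mixed two-way repeated-measures
ANOVA.  Sums of squares are computed in closed form for the balanced
case; unbalanced designs are refused outright rather than silently
approximated.  Post hoc pairwise comparisons use Tukey's honestly
significant difference with p-values from the studentized-range
distribution on the pooled within-group variance.

Sphericity corrections (Greenhouse-Geisser) are off by default;
``sphericity_correction=True`` applies the correction to the within and
interaction terms and reports both p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnsupportedDesignError, ValidationError


@dataclass(frozen=True)
class AnovaResult:
    effect_name: str
    F: float
    df_num: int
    df_den: int
    p: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected, when requested


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adj: float


def _check_balanced(df: pd.DataFrame, subject: str, between: str, within: str) -> None:
    per_subject = df.groupby(subject)[within].nunique()
    n_within = df[within].nunique()
    if (per_subject != n_within).any() or len(df) != df[subject].nunique() * n_within:
        raise UnsupportedDesignError(
            "unbalanced or incomplete within-subject design: every subject needs "
            "exactly one observation per within level"
        )
    subj_groups = df.groupby(subject)[between].nunique()
    if (subj_groups != 1).any():
        raise UnsupportedDesignError("each subject must belong to exactly one between group")
    counts = df.drop_duplicates(subject).groupby(between)[subject].count()
    if counts.nunique() != 1:
        raise UnsupportedDesignError(
            f"unbalanced between-groups design: group sizes {dict(counts)}"
        )


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "treatment",
    within: str = "time",
    subject: str = "rat",
    sphericity_correction: bool = False,
) -> list[AnovaResult]:
    """Balanced split-plot ANOVA: between-subjects treatment, within-subjects
    time, subject nested in treatment as the error stratum for the
    between factor.

    Returns results for the between main effect, the within main effect
    and their interaction.  A design with unequal cell counts raises
    :class:`UnsupportedDesignError`.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValidationError("missing values in the response")
    _check_balanced(df, subject, between, within)

    a = df[between].nunique()
    b = df[within].nunique()
    n = df[subject].nunique() // a  # subjects per group
    grand = df[dv].mean()

    ss_total = float(((df[dv] - grand) ** 2).sum())
    subj_means = df.groupby(subject)[dv].mean()
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_a = float(b * n * ((df.groupby(between)[dv].mean() - grand) ** 2).sum())
    ss_subj_within_a = ss_between_subj - ss_a  # error stratum for the between factor
    ss_b = float(a * n * ((df.groupby(within)[dv].mean() - grand) ** 2).sum())
    cell_means = df.groupby([between, within])[dv].mean()
    ss_cells = float(n * ((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_error = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (n - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)

    def f_and_p(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float]:
        if df_den <= 0:
            raise UnsupportedDesignError("no residual df; need n >= 2 subjects per group")
        ms_den = ss_den / df_den
        ms_num = ss_num / df_num
        if ms_den <= 0.0:
            # degenerate: no within-stratum variability at all
            return (0.0, 1.0) if ms_num <= 0.0 else (math.inf, 0.0)
        F = ms_num / ms_den
        return F, float(stats.f.sf(F, df_num, df_den))

    F_a, p_a = f_and_p(ss_a, df_a, ss_subj_within_a, df_subj)
    F_b, p_b = f_and_p(ss_b, df_b, ss_error, df_err)
    F_ab, p_ab = f_and_p(ss_ab, df_ab, ss_error, df_err)

    gg_b = gg_ab = None
    if sphericity_correction and b > 2:
        eps = _greenhouse_geisser_epsilon(df, dv, within, subject)
        gg_b = float(stats.f.sf(F_b, df_b * eps, df_err * eps)) if math.isfinite(F_b) else p_b
        gg_ab = float(stats.f.sf(F_ab, df_ab * eps, df_err * eps)) if math.isfinite(F_ab) else p_ab

    return [
        AnovaResult(between, F_a, df_a, df_subj, p_a),
        AnovaResult(within, F_b, df_b, df_err, p_b, p_gg=gg_b),
        AnovaResult(f"{between}*{within}", F_ab, df_ab, df_err, p_ab, p_gg=gg_ab),
    ]


def _greenhouse_geisser_epsilon(
    df: pd.DataFrame, dv: str, within: str, subject: str
) -> float:
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    S = np.cov(wide.to_numpy(), rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def tukey_hsd(
    groups: dict[str, np.ndarray | list[float]], alpha: float = 0.05
) -> list[TukeyComparison]:
    """All-pairs Tukey HSD on the pooled within-group variance.

    ``q = |mean_diff| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` (Tukey-Kramer for
    unequal n) with adjusted p from the studentized-range distribution at
    k groups and the pooled error df.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has n < 2")
    k = len(arrays)
    df_err = sum(len(a) - 1 for a in arrays.values())
    msw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values()) / df_err

    out = []
    for (na, va), (nb, vb) in itertools.combinations(arrays.items(), 2):
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(msw / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
        out.append(TukeyComparison(na, nb, diff, q, min(max(p, 0.0), 1.0)))
    return out
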