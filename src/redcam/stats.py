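"""Repeatability, agreement and within-subjects factorial ANOVA.

Implements the analysis layer of the study: pooled within-subject standard
deviation for repeatability, Bland–Altman 95% limits of agreement with
confidence intervals for inter-rater agreement, Pearson correlation
between objective metrics and subjective grades, a balanced fully-crossed
within-subjects (repeated-measures) factorial ANOVA with effect×subject
error strata, and Bonferroni-corrected pairwise comparisons.

The ANOVA is the classical univariate decomposition for a balanced design:
for every nonempty subset E of the within factors, SS_E is computed from
marginal means by inclusion–exclusion, the error stratum is the E×subject
interaction, F = MS_E / MS_{E×subject}, and no sphericity correction is
applied by default (a Greenhouse–Geisser flag is available for the
single-factor case where it is well defined).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticError

__all__ = [
    "BlandAltmanResult",
    "AnovaTable",
    "within_subject_sd",
    "bland_altman",
    "pearson",
    "rm_anova",
    "bonferroni_pairwise",
    "clinician_anova",
]

# SS below this relative tolerance is treated as exactly zero (balanced
# noiseless designs produce 1e-30-scale round-off in both strata).
_ZERO_SS_RTOL = 1e-12


def within_subject_sd(groups) -> float:
    """Pooled within-subject standard deviation (repeatability, Sw).

    ``groups`` is an iterable of per-subject replicate sequences.
    Sw = sqrt( Σ_j Σ_k (x_jk − x̄_j)² / Σ_j (k_j − 1) ); subjects with a
    single measurement contribute nothing.
    """
    ss = 0.0
    dof = 0
    for g in groups:
        x = np.asarray(list(g), dtype=float)
        if len(x) >= 2:
            ss += float(((x - x.mean()) ** 2).sum())
            dof += len(x) - 1
    if dof == 0:
        raise StatisticError("no subject has replicate measurements")
    return float(np.sqrt(ss / dof))


@dataclass
class BlandAltmanResult:
    """95% limits of agreement between two raters/methods."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low_pair: tuple[float, float]
    ci_high_pair: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_low_pair": list(self.ci_low_pair),
            "ci_high_pair": list(self.ci_high_pair),
            "n": self.n,
        }


def bland_altman(rater_a, rater_b) -> BlandAltmanResult:
    """Limits of agreement mean(d) ± 1.96·sd(d), with t-based 95% CIs.

    The CI half-width for each limit uses the standard-error approximation
    sd·sqrt(3/n) with t_{0.975, n−1}.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatisticError("raters must be equal-length 1-D sequences")
    n = len(a)
    if n < 3:
        raise StatisticError("need at least 3 paired observations")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = mean - 1.96 * sd, mean + 1.96 * sd
    half = float(sps.t.ppf(0.975, n - 1) * sd * np.sqrt(3.0 / n))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_low_pair=(loa_low - half, loa_low + half),
        ci_high_pair=(loa_high - half, loa_high + half),
        n=n,
    )


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatisticError("need equal-length samples with n >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise StatisticError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# balanced within-subjects factorial ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Per-effect decomposition of a balanced within-subjects design."""

    table: pd.DataFrame  # effect, ss, df, ms, error_ss, error_df, error_ms, F, p
    total_ss: float
    total_df: int
    subject_ss: float
    n_subjects: int
    factor_levels: dict[str, list]

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]


def _subset_ss(arr: np.ndarray, axes: tuple[int, ...]) -> tuple[float, int]:
    """SS and df for one term of a balanced full-factorial decomposition.

    The effect at each cell of the margin over ``axes`` is the
    inclusion–exclusion alternating sum of marginal means over all subsets
    of ``axes``; SS is the squared effect summed over that margin times
    the number of observations per marginal cell.
    """
    shape = arr.shape
    all_axes = tuple(range(arr.ndim))
    effect = np.zeros([shape[a] if a in axes else 1 for a in all_axes])
    for k in range(len(axes) + 1):
        for sub in itertools.combinations(axes, k):
            reduce_over = tuple(a for a in all_axes if a not in sub)
            m = arr.mean(axis=reduce_over, keepdims=True)
            effect = effect + ((-1) ** (len(axes) - len(sub))) * m
    n_per_cell = int(np.prod([shape[a] for a in all_axes if a not in axes]))
    ss = float(n_per_cell * (effect**2).sum())
    df = int(np.prod([shape[a] - 1 for a in axes]))
    return ss, df


def _effect_name(factors: tuple[str, ...]) -> str:
    return "*".join(factors)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    gg_correction: bool = False,
) -> AnovaTable:
    """Balanced within-subjects factorial ANOVA with up to 4 factors.

    Replicated observations within a subject × cell combination are
    averaged before the decomposition.  Every subject must have every
    factor-level combination; missing cells raise a
    :class:`~redcam.errors.StatisticError` naming them.
    """
    if not 1 <= len(within) <= 4:
        raise StatisticError("between 1 and 4 within factors are supported")
    cols = [subject] + list(within)
    cell = data.groupby(cols, sort=True)[dv].mean()

    subjects = sorted(data[subject].unique())
    levels = {f: sorted(data[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) < 2:
            raise StatisticError(f"factor {f!r} has fewer than 2 levels")
    full_index = pd.MultiIndex.from_product(
        [subjects] + [levels[f] for f in within], names=cols
    )
    missing = full_index.difference(cell.index)
    if len(missing):
        raise StatisticError(f"design is unbalanced; missing cells: {list(missing[:10])}")
    arr = cell.reindex(full_index).to_numpy().reshape(
        [len(subjects)] + [len(levels[f]) for f in within]
    )
    if np.isnan(arr).any():
        raise StatisticError("missing responses in the subject × cell grid")

    grand = arr.mean()
    total_ss = float(((arr - grand) ** 2).sum())
    total_df = arr.size - 1
    subject_ss, _ = _subset_ss(arr, (0,))
    zero_tol = _ZERO_SS_RTOL * max(total_ss, 1.0)

    rows = []
    factor_axis = {f: i + 1 for i, f in enumerate(within)}
    effect_sets = [
        combo
        for k in range(1, len(within) + 1)
        for combo in itertools.combinations(within, k)
    ]
    for combo in effect_sets:
        axes = tuple(factor_axis[f] for f in combo)
        ss, df = _subset_ss(arr, axes)
        err_ss, err_df = _subset_ss(arr, (0,) + axes)
        ms = ss / df
        err_ms = err_ss / err_df if err_df else np.nan
        if ss <= zero_tol and err_ss <= zero_tol:
            f_stat, p = 0.0, 1.0
        elif err_ss <= zero_tol:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ms / err_ms
            df1, df2 = df, err_df
            if gg_correction and len(combo) == 1:
                eps = _gg_epsilon(arr, axes[0])
                df1, df2 = df * eps, err_df * eps
            p = float(sps.f.sf(f_stat, df1, df2))
        rows.append(
            {
                "effect": _effect_name(combo),
                "ss": ss,
                "df": df,
                "ms": ms,
                "error_ss": err_ss,
                "error_df": err_df,
                "error_ms": err_ms,
                "F": f_stat,
                "p": p,
            }
        )
    return AnovaTable(
        table=pd.DataFrame(rows),
        total_ss=total_ss,
        total_df=total_df,
        subject_ss=subject_ss,
        n_subjects=len(subjects),
        factor_levels=levels,
    )


def _gg_epsilon(arr: np.ndarray, axis: int) -> float:
    """Greenhouse–Geisser epsilon for a single within factor."""
    other = tuple(a for a in range(arr.ndim) if a not in (0, axis))
    mat = arr.mean(axis=other) if other else arr  # subjects × levels
    k = mat.shape[1]
    s = np.cov(mat, rowvar=False)
    mean_diag = np.trace(s) / k
    num = (k * mean_diag - s.mean()) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (s.mean(axis=0) ** 2).sum() + k**2 * s.mean() ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def bonferroni_pairwise(
    data: pd.DataFrame,
    factor: str,
    dv: str,
    subject: str = "subject",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests between factor levels with Bonferroni correction.

    Responses are averaged per subject × level over all other conditions,
    each level pair is compared with a paired t-test, and p-values are
    multiplied by the number of pairs within this factor (capped at 1).
    """
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise StatisticError(f"factor {factor!r} needs at least 2 levels")
    per = data.groupby([subject, factor], sort=True)[dv].mean().unstack(factor)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        d = (per[a] - per[b]).to_numpy()
        if np.allclose(d, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_rel(per[a], per[b])
        p_adj = min(1.0, float(p) * m)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float(np.mean(d)),
                "t": float(t_stat),
                "p": float(p),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def clinician_anova(
    grades: pd.DataFrame,
    rater: str = "rater",
    dv: str = "grade",
    unit: str = "image",
) -> tuple[float, float, AnovaTable]:
    """One-way repeated-measures ANOVA across raters, blocked by image.

    Returns (F, p, full table).  When the residual (rater×image) stratum
    is exactly zero while the rater effect is not, F is reported as the
    +inf sentinel with p = 0.
    """
    table = rm_anova(grades, dv=dv, within=[rater], subject=unit)
    row = table.effect(rater)
    return float(row["F"]), float(row["p"]), table
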