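"""Group-level statistics and assay normalisations.

Covers the study's statistical toolkit — two-tailed t tests (classical
equal-variance by default, Welch by flag), two-way ANOVA with a
genotype x phase interaction (type II sums of squares), and the two-sided
Grubbs outlier screen — plus the exact arithmetic normalisations used for
the assay tables: urinary analyte / osmolality, specific (total minus
nonspecific) transporter-mediated uptake, and per-10^6-cell content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

__all__ = [
    "GroupComparison", "compare_groups", "grubbs_outliers",
    "normalize_urinary", "specific_uptake", "per_cell_normalize",
    "group_summary",
]


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    group_stats: pd.DataFrame            # group -> n, mean, sem
    effects: pd.DataFrame | None = None  # two-way ANOVA table
    extra: dict = field(default_factory=dict)


def group_summary(values_by_group: dict) -> pd.DataFrame:
    rows = []
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        n = len(v)
        sem = v.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
        rows.append({"group": g, "n": n, "mean": v.mean() if n else math.nan,
                     "sem": sem})
    return pd.DataFrame(rows)


def compare_groups(data, design: str = "one-factor", *,
                   equal_var: bool = True,
                   factors: tuple = ("genotype", "phase"),
                   value_col: str = "value") -> GroupComparison:
    """Two-tailed group comparison.

    ``design="one-factor"``: ``data`` is a mapping group -> values; a
    two-tailed two-sample t test (classical equal-variance by default,
    Welch with ``equal_var=False``).

    ``design="two-factor"``: ``data`` is a tidy DataFrame with ``value_col``
    and the two factor columns; a two-way ANOVA with interaction, type II
    sums of squares.  The reported statistic/p refer to the first factor's
    main effect; the full table is in ``effects``.
    """
    if design == "one-factor":
        if not isinstance(data, dict) or len(data) != 2:
            raise AnalysisError("one-factor design needs a mapping of two groups")
        (ga, va), (gb, vb) = data.items()
        va = np.asarray(va, dtype=float)
        vb = np.asarray(vb, dtype=float)
        for g, v in ((ga, va), (gb, vb)):
            if len(v) < 2:
                raise AnalysisError(f"group {g!r} has n < 2")
            if not np.all(np.isfinite(v)):
                bad = np.where(~np.isfinite(v))[0].tolist()
                raise AnalysisError(f"non-finite values in group {g!r} at rows {bad}")
        res = sps.ttest_ind(va, vb, equal_var=equal_var)
        return GroupComparison(
            test="t (equal var)" if equal_var else "t (Welch)",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            group_stats=group_summary({ga: va, gb: vb}),
            extra={"mean_difference": float(va.mean() - vb.mean()),
                   "df": float(res.df)})
    if design == "two-factor":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        if not isinstance(data, pd.DataFrame):
            raise AnalysisError("two-factor design needs a tidy DataFrame")
        fa, fb = factors
        for col in (value_col, fa, fb):
            if col not in data.columns:
                raise AnalysisError(f"missing column {col!r}")
        vals = data[value_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.where(~np.isfinite(vals))[0].tolist()
            raise AnalysisError(f"non-finite values at rows {bad}")
        for col in (fa, fb):
            for level, sub in data.groupby(col):
                if len(sub) < 2:
                    raise AnalysisError(f"level {level!r} of {col!r} has n < 2")
        d = data.rename(columns={value_col: "_y", fa: "_a", fb: "_b"})
        model = ols("_y ~ C(_a) * C(_b)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(index={"C(_a)": fa, "C(_b)": fb,
                                    "C(_a):C(_b)": f"{fa}:{fb}"})
        stats_by = {g: sub["_y"].to_numpy() for g, sub in d.groupby("_a")}
        return GroupComparison(
            test="two-way ANOVA (type II)",
            statistic=float(table.loc[fa, "F"]),
            p_value=float(table.loc[fa, "PR(>F)"]),
            group_stats=group_summary(stats_by), effects=table)
    raise AnalysisError(f"unknown design {design!r}")


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.05,
                    iterative: bool = False) -> np.ndarray:
    """Two-sided Grubbs outlier flags at level ``alpha``.

    Single-pass by default: the most extreme point is flagged if its Grubbs
    statistic exceeds the critical value.  With ``iterative=True`` the test
    repeats on the remaining points until none is flagged.  Points are only
    flagged, never removed.  With n < 3 (or zero spread) nothing is tested.
    """
    x = np.asarray(values, dtype=float)
    flags = np.zeros(len(x), dtype=bool)
    if len(x) < 3 or not np.all(np.isfinite(x)):
        return flags
    active = np.arange(len(x))
    while True:
        xs = x[active]
        n = len(xs)
        if n < 3:
            break
        sd = xs.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(xs - xs.mean()) / sd
        i = int(np.argmax(g))
        if g[i] > _grubbs_critical(n, alpha):
            flags[active[i]] = True
            active = np.delete(active, i)
            if not iterative:
                break
        else:
            break
    return flags


def normalize_urinary(analyte_nmol_per_l, osmolality_mmol_per_kg):
    """Analyte / osmolality, the volume-independent urinary output
    (nmol x kg / mmol / L)."""
    a = np.asarray(analyte_nmol_per_l, dtype=float)
    o = np.asarray(osmolality_mmol_per_kg, dtype=float)
    if np.any(o <= 0):
        raise AnalysisError("osmolality must be positive")
    out = a / o
    return float(out) if out.ndim == 0 else out


def specific_uptake(total, nonspecific):
    """Transporter-specific uptake and percent inhibition.

    Returns ``(specific, percent_inhibition, flagged_negative)`` where
    ``specific = total - nonspecific`` and percent inhibition is
    ``100 * specific / total`` (the fraction of uptake blocked by the
    inhibitor).  Negative specific uptake is returned but flagged.
    """
    t = np.asarray(total, dtype=float)
    ns = np.asarray(nonspecific, dtype=float)
    spec = t - ns
    with np.errstate(divide="ignore", invalid="ignore"):
        inhib = 100.0 * spec / t
    neg = spec < 0
    if spec.ndim == 0:
        return float(spec), float(inhib), bool(neg)
    return spec, inhib, neg


def per_cell_normalize(content_pmol, viable_cells):
    """Content per 10^6 viable cells."""
    c = np.asarray(content_pmol, dtype=float)
    n = np.asarray(viable_cells, dtype=float)
    if np.any(n <= 0):
        raise AnalysisError("viable cell count must be positive")
    out = c * 1e6 / n
    return float(out) if out.ndim == 0 else out
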