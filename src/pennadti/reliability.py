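"""Two-way absolute-agreement intraclass correlations and ratings aggregation.

The reliability model is the two-way (mixed) ANOVA decomposition of a
complete subjects x measurements matrix into row (subject), column
(rater/session) and residual mean squares.  The absolute-agreement ICC —
ICC(A,1) in McGraw & Wong's taxonomy, "ICC(2,1)"-style in Shrout & Fleiss's —
penalizes systematic offsets between columns:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with the average-measures analog ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n).
Confidence intervals use the standard F-based construction with
Satterthwaite-style degrees of freedom.  Estimates are categorized on the
Koo-Li scale (>0.90 excellent, 0.75-0.90 good, 0.50-0.75 moderate,
<0.50 poor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_ratings

__all__ = [
    "ICCResult",
    "icc_absolute",
    "categorize_icc",
    "aggregate_ratings",
    "AggregateResult",
    "design_slices",
    "icc_report",
]

DESIGNS = ("test-retest", "inter-reader", "intra-reader")


@dataclass(frozen=True)
class ICCResult:
    """Absolute-agreement ICC with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    variant: str          # "single" | "average"
    n_subjects: int
    k: int
    design: str = ""

    @property
    def category(self) -> str:
        return categorize_icc(self.estimate)


def categorize_icc(estimate: float) -> str:
    """Koo-Li reliability category for an ICC estimate."""
    if not np.isfinite(estimate):
        raise ValueError("ICC estimate must be finite")
    if estimate > 0.90:
        return "excellent"
    if estimate >= 0.75:
        return "good"
    if estimate >= 0.50:
        return "moderate"
    return "poor"


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, sst


def icc_absolute(
    matrix: np.ndarray | pd.DataFrame,
    variant: str = "single",
    alpha: float = 0.05,
    design: str = "",
) -> ICCResult:
    """Absolute-agreement ICC of a complete subjects x measurements matrix.

    ``variant="single"`` gives ICC(A,1) (reliability of one measurement),
    ``"average"`` gives ICC(A,k) (reliability of the k-measurement mean).
    Missing cells are a hard error — the ANOVA decomposition assumes a
    complete balanced table and no imputation is attempted.
    """
    if variant not in ("single", "average"):
        raise ValueError("variant must be 'single' or 'average'")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects x measurements matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 measurements, got {n}x{k}")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains missing or non-finite cells")

    msr, msc, mse, sst = _anova_mean_squares(x)
    if sst <= 0:
        raise ValueError("ICC undefined: zero total variance")

    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw-Wong F-based CI for ICC(A,1); the A,k interval is its k-average
    # (Spearman-Brown) transform with the same Satterthwaite df.
    if single >= 1.0 - 1e-12:
        lo1 = hi1 = 1.0
    else:
        a = k * single / (n * (1.0 - single))
        b = 1.0 + k * single * (n - 1) / (n * (1.0 - single))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        denom_common = k * msc + (k * n - k - n) * mse
        lo1 = n * (msr - f_l * mse) / (f_l * denom_common + n * msr)
        hi1 = n * (f_u * msr - mse) / (denom_common + n * f_u * msr)
        lo1, hi1 = min(lo1, single), max(hi1, single)

    if variant == "single":
        est, lo, hi = single, lo1, hi1
    else:
        est = (msr - mse) / (msr + (msc - mse) / n)

        def _sb(r: float) -> float:
            if r >= 1.0 - 1e-15:
                return 1.0
            return k * r / (1.0 + (k - 1) * r)

        lo, hi = _sb(lo1), _sb(hi1)
        lo, hi = min(lo, est), max(hi, est)

    return ICCResult(estimate=float(est), ci_low=float(lo), ci_high=float(hi),
                     variant=variant, n_subjects=n, k=k, design=design)


@dataclass
class AggregateResult:
    """Ratings averaged across the requested axes."""

    subject_means: pd.Series
    grand_mean: float
    sd: float                 # SD of the per-subject means
    cell_means: pd.Series     # mean per remaining (rater, session) cell


def _check_balanced(table: pd.DataFrame, axes: list[str]) -> None:
    counts = table.groupby("subject", sort=False)[axes].apply(
        lambda g: tuple(sorted(map(tuple, g.drop_duplicates().to_numpy())))
    )
    if counts.nunique() > 1:
        ref = counts.mode().iloc[0]
        bad = sorted(counts.index[counts != ref])
        raise ValueError(f"unbalanced ratings design for subjects {bad}")


def aggregate_ratings(
    ratings: pd.DataFrame,
    over: tuple[str, ...] = ("session", "rater"),
) -> AggregateResult:
    """Average ratings per subject over sessions and/or raters.

    Returns per-subject means, their grand mean and across-subject SD, and
    the per-cell means over the averaged axes.  With a balanced design the
    grand mean equals the mean of the per-rater-per-session cell means.
    Unbalanced designs (unequal cells per subject) are a hard error.
    """
    table = validate_ratings(ratings)
    axes = [a for a in ("rater", "session") if a in over]
    if not axes:
        raise ValueError("'over' must include 'session' and/or 'rater'")
    _check_balanced(table, axes)

    subject_means = table.groupby("subject", sort=True)["value"].mean()
    grand = float(subject_means.mean())
    sd = float(subject_means.std(ddof=1)) if len(subject_means) > 1 else 0.0
    cell_means = table.groupby(axes, sort=True)["value"].mean()
    return AggregateResult(subject_means=subject_means, grand_mean=grand,
                           sd=sd, cell_means=cell_means)


def design_slices(ratings: pd.DataFrame, design: str) -> dict[str, pd.DataFrame]:
    """Build the subjects x measurements matrices for one reliability design.

    * ``test-retest``: one subjects x sessions matrix per rater;
    * ``inter-reader``: one subjects x raters matrix per session;
    * ``intra-reader``: one subjects x reading-occasions matrix per session
      (requires an ``occasion`` column with >= 2 occasions for some rater).

    Returns ``{stratum_name: matrix}``; raises if the required axis has
    fewer than two levels.
    """
    table = validate_ratings(ratings)
    if design == "test-retest":
        if table["session"].nunique() < 2:
            raise ValueError("test-retest requires at least 2 sessions")
        occ = _first_occasion(table)
        return {
            f"rater={r}": occ[occ["rater"] == r].pivot(
                index="subject", columns="session", values="value")
            for r in sorted(occ["rater"].unique())
        }
    if design == "inter-reader":
        if table["rater"].nunique() < 2:
            raise ValueError("inter-reader requires at least 2 raters")
        occ = _first_occasion(table)
        return {
            f"session={s}": occ[occ["session"] == s].pivot(
                index="subject", columns="rater", values="value")
            for s in sorted(occ["session"].unique())
        }
    if design == "intra-reader":
        if "occasion" not in table.columns or table["occasion"].nunique() < 2:
            raise ValueError("intra-reader requires repeated reading occasions")
        out: dict[str, pd.DataFrame] = {}
        for r in sorted(table["rater"].unique()):
            sub = table[table["rater"] == r]
            if sub["occasion"].nunique() < 2:
                continue
            for s in sorted(sub["session"].unique()):
                out[f"rater={r},session={s}"] = sub[sub["session"] == s].pivot(
                    index="subject", columns="occasion", values="value")
        if not out:
            raise ValueError("no rater has repeated reading occasions")
        return out
    raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")


def _first_occasion(table: pd.DataFrame) -> pd.DataFrame:
    if "occasion" in table.columns:
        return table[table["occasion"] == table["occasion"].min()]
    return table


def icc_report(ratings: pd.DataFrame, variant: str = "single") -> pd.DataFrame:
    """All computable designs as one tidy table (CLI backend).

    Columns: design, stratum, variant, estimate, ci_low, ci_high, category,
    n_subjects, k.  Designs whose axis is absent are silently omitted.
    """
    rows = []
    for design in DESIGNS:
        try:
            slices = design_slices(ratings, design)
        except ValueError:
            continue
        for stratum, matrix in slices.items():
            res = icc_absolute(matrix, variant=variant, design=design)
            rows.append({
                "design": design,
                "stratum": stratum,
                "variant": res.variant,
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "category": res.category,
                "n_subjects": res.n_subjects,
                "k": res.k,
            })
    return pd.DataFrame(rows)
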