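"""Feature-reproducibility statistics: ICC, classes, rank tests, ranges.

The intraclass correlation coefficient (ICC) is estimated from ANOVA mean
squares of an n x k ratings matrix (rows = subjects/tumors, columns =
raters/observers):

* two-way mixed effects, absolute agreement, single rating (McGraw & Wong
  case 3A) — used for inter-observer sets::

      ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

* one-way random effects, single rating (case 1) — used for intra-observer
  run pairs::

      ICC = (MSR - MSW) / (MSR + (k-1) MSW)

with MSR the between-subjects, MSC the between-raters, MSE the residual
and MSW the within-subjects mean square. Raw estimates can be negative;
they are clamped to 0 for classification into reproducibility classes
(high: ICC >= 0.8, medium: 0.8 > ICC >= 0.5, low: ICC < 0.5) but kept
unclamped in the result. Groups of features are compared with the
two-sided Wilcoxon rank-sum test (significance at p < 0.05).

The module's modelling surface is :class:`ReproducibilityStudy`, built
from a tidy per-segmentation feature table; ``fit()`` returns a
:class:`ReproducibilityResults` carrying the per-feature ICC tables,
family summaries, classification counts, group comparisons and the
Z-score-normalized range analysis, with a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_CATEGORIES, FEATURE_NAMES

__all__ = [
    "ICCResult",
    "icc_twoway_mixed_absolute",
    "icc_twoway_mixed_consistency",
    "icc_oneway",
    "classify",
    "wilcoxon_ranksum",
    "znormalize_and_range",
    "summarize",
    "icc_per_feature",
    "RangeStats",
    "ReproducibilityStudy",
    "ReproducibilityResults",
]

ICC_HIGH = 0.8
ICC_MEDIUM = 0.5


@dataclass
class ICCResult:
    """One ICC estimate with its ANOVA mean squares.

    ``icc`` is clamped to [0, 1]; ``icc_raw`` keeps the unclamped ANOVA
    estimate. ``defined`` is False when the denominator degenerates (all
    ratings identical).
    """

    icc: float
    icc_raw: float
    model: str  # "oneway" | "twoway_mixed_absolute" | "twoway_mixed_consistency"
    n: int
    k: int
    msr: float
    msc: float | None = None
    mse: float | None = None
    msw: float | None = None
    defined: bool = True


def _check_ratings(ratings: np.ndarray) -> np.ndarray:
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D (subjects x raters) matrix")
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings must be finite (drop incomplete subjects first)")
    return ratings


def _twoway_mean_squares(ratings: np.ndarray):
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((ratings - grand) ** 2).sum()
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), max(sse, 0.0) / ((n - 1) * (k - 1))


def icc_twoway_mixed_absolute(ratings: np.ndarray) -> ICCResult:
    """ICC, two-way mixed effects, absolute agreement, single rating."""
    ratings = _check_ratings(ratings)
    n, k = ratings.shape
    msr, msc, mse = _twoway_mean_squares(ratings)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return ICCResult(np.nan, np.nan, "twoway_mixed_absolute", n, k,
                         msr, msc=msc, mse=mse, defined=False)
    raw = (msr - mse) / denom
    return ICCResult(float(np.clip(raw, 0.0, 1.0)), float(raw),
                     "twoway_mixed_absolute", n, k, msr, msc=msc, mse=mse)


def icc_twoway_mixed_consistency(ratings: np.ndarray) -> ICCResult:
    """Consistency form of the two-way ICC (rater offsets not penalized)."""
    ratings = _check_ratings(ratings)
    n, k = ratings.shape
    msr, msc, mse = _twoway_mean_squares(ratings)
    denom = msr + (k - 1) * mse
    if denom <= 0:
        return ICCResult(np.nan, np.nan, "twoway_mixed_consistency", n, k,
                         msr, msc=msc, mse=mse, defined=False)
    raw = (msr - mse) / denom
    return ICCResult(float(np.clip(raw, 0.0, 1.0)), float(raw),
                     "twoway_mixed_consistency", n, k, msr, msc=msc, mse=mse)


def icc_oneway(ratings: np.ndarray) -> ICCResult:
    """ICC, one-way random effects, single rating."""
    ratings = _check_ratings(ratings)
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((ratings - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msr + (k - 1) * msw
    if denom <= 0:
        return ICCResult(np.nan, np.nan, "oneway", n, k, msr, msw=msw, defined=False)
    raw = (msr - msw) / denom
    return ICCResult(float(np.clip(raw, 0.0, 1.0)), float(raw),
                     "oneway", n, k, msr, msw=msw)


def classify(icc: float | ICCResult) -> str:
    """Reproducibility class: high (>= 0.8), medium (>= 0.5), low, or unclassified."""
    if isinstance(icc, ICCResult):
        if not icc.defined:
            return "unclassified"
        icc = icc.icc
    if not np.isfinite(icc):
        return "unclassified"
    icc = max(0.0, float(icc))
    if icc >= ICC_HIGH:
        return "high"
    if icc >= ICC_MEDIUM:
        return "medium"
    return "low"


def wilcoxon_ranksum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration for combined sample size <= 20 without ties,
    tie-corrected normal approximation otherwise. Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired signed-rank alternative, for sensitivity analysis."""
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float),
                         alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def summarize(values) -> tuple[float, float]:
    """Mean and (population) SD of a collection of ICCs or feature values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no defined values to summarize")
    return float(arr.mean()), float(arr.std())


# ---------------------------------------------------------------------------
# feature-table level operations

_META_COLS = ("tumor", "group", "observer", "run")


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def ratings_matrix(table: pd.DataFrame, feature: str) -> tuple[np.ndarray, int]:
    """Tumors x raters matrix for one feature; drops tumors with NaN rows.

    Raters are the distinct (group, observer, run) combinations present in
    ``table``. Returns the matrix and the number of dropped subjects.
    """
    wide = table.pivot_table(
        index="tumor", columns=["group", "observer", "run"], values=feature,
        aggfunc="first", dropna=False,
    )
    complete = wide.dropna(axis=0)
    return complete.to_numpy(dtype=float), int(len(wide) - len(complete))


def icc_per_feature(
    table: pd.DataFrame,
    model: str = "twoway_mixed_absolute",
    features: list[str] | None = None,
) -> pd.Series:
    """One ICC per feature over the raters present in ``table``.

    ``table`` should already be restricted to the observer subset of
    interest (e.g. the five manual observers, or one semi-automatic run
    set). Tumors with an undefined feature value are dropped per feature.
    """
    fit = {"twoway_mixed_absolute": icc_twoway_mixed_absolute,
           "twoway_mixed_consistency": icc_twoway_mixed_consistency,
           "oneway": icc_oneway}[model]
    features = _feature_cols(table) if features is None else features
    out = {}
    for feat in features:
        mat, _dropped = ratings_matrix(table, feat)
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            out[feat] = np.nan
            continue
        out[feat] = fit(mat).icc
    return pd.Series(out, name=f"icc_{model}")


@dataclass
class RangeStats:
    """Z-normalized per-group feature ranges.

    ``per_tumor`` has one row per (tumor, feature, group) with min, max and
    range of the group's z-scores; ``per_feature`` aggregates (mean) over
    tumors. ``n_zero_sd`` counts tumor-features whose 11 values had zero
    spread (z-scores defined as 0 there, flagged).
    """

    per_tumor: pd.DataFrame
    per_feature: pd.DataFrame
    mode: str
    n_zero_sd: int


def znormalize_and_range(table: pd.DataFrame, mode: str = "per_tumor") -> RangeStats:
    """Z-score every feature value and compute per-group ranges.

    ``mode="per_tumor"`` (default) normalizes each tumor-feature over its
    own segmentations (the 11 values under the default design);
    ``mode="pooled"`` normalizes each feature over all tumors and
    segmentations at once.
    """
    if mode not in ("per_tumor", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    feats = _feature_cols(table)
    z = table.copy()
    if mode == "per_tumor":
        grouped = z.groupby("tumor")[feats]
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda s: s.std(ddof=0))
        n_zero = int((z.groupby("tumor")[feats].std(ddof=0) == 0).to_numpy().sum())
        zvals = (z[feats] - mean) / sd.where(sd != 0, 1.0)
        zvals = zvals.where(sd != 0, 0.0)
    else:
        mean = z[feats].mean()
        sd = z[feats].std(ddof=0)
        n_zero = int((sd == 0).sum())
        zvals = (z[feats] - mean) / sd.where(sd != 0, 1.0)
        zvals.loc[:, (sd == 0).to_numpy()] = 0.0
    z[feats] = zvals

    rows = []
    for (tumor, group), sub in z.groupby(["tumor", "group"]):
        for feat in feats:
            vals = sub[feat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append((tumor, group, feat, vals.min(), vals.max(),
                         vals.max() - vals.min()))
    per_tumor = pd.DataFrame(
        rows, columns=["tumor", "group", "feature", "lower", "upper", "range"]
    )
    per_feature = (
        per_tumor.groupby(["feature", "group"])[["lower", "upper", "range"]]
        .mean()
        .reset_index()
    )
    return RangeStats(per_tumor, per_feature, mode, n_zero)


# ---------------------------------------------------------------------------
# statsmodels-style modelling surface


class ReproducibilityStudy:
    """Reproducibility analysis of a (tumor x segmentation) feature table.

    Parameters
    ----------
    table
        Tidy DataFrame with columns ``tumor``, ``group`` ("manual" or
        "semiauto"), ``observer``, ``run`` and one column per feature.
    features
        Feature columns to analyse (default: every non-metadata column).
    range_mode
        Z-normalization mode for the range analysis (see
        :func:`znormalize_and_range`).
    """

    def __init__(self, table: pd.DataFrame, features: list[str] | None = None,
                 range_mode: str = "per_tumor"):
        missing = [c for c in _META_COLS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks metadata columns {missing}")
        self.table = table.reset_index(drop=True)
        self.features = features if features is not None else _feature_cols(self.table)
        if not self.features:
            raise ValueError("no feature columns")
        self.range_mode = range_mode

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "ReproducibilityStudy":
        return cls(table, **kw)

    def fit(self) -> "ReproducibilityResults":
        tab = self.table
        feats = self.features
        manual = tab[tab.group == "manual"]
        semi = tab[tab.group == "semiauto"]
        runs = sorted(semi.run.unique())
        observers = sorted(semi.observer.unique())

        icc = pd.DataFrame(index=feats)
        icc["manual"] = icc_per_feature(manual, "twoway_mixed_absolute", feats)
        for r in runs:
            icc[f"semiauto_set{r + 1}"] = icc_per_feature(
                semi[semi.run == r], "twoway_mixed_absolute", feats)
        set_cols = [f"semiauto_set{r + 1}" for r in runs]
        icc["semiauto"] = icc[set_cols].mean(axis=1)
        for o in observers:
            icc[f"intra_obs{o + 1}"] = icc_per_feature(
                semi[semi.observer == o], "oneway", feats)
        intra_cols = [f"intra_obs{o + 1}" for o in observers]
        icc["intra"] = icc[intra_cols].mean(axis=1)
        icc["family"] = [FEATURE_CATEGORIES.get(f, "other") for f in feats]
        icc["class_manual"] = [classify(v) for v in icc["manual"]]
        icc["class_semiauto"] = [classify(v) for v in icc["semiauto"]]

        ranges = znormalize_and_range(tab[list(_META_COLS) + feats], self.range_mode)
        return ReproducibilityResults(self, icc, ranges)


@dataclass
class ReproducibilityResults:
    """Fitted reproducibility analysis; all tables are per feature."""

    model: ReproducibilityStudy
    icc_table: pd.DataFrame  # per-feature ICCs, classes, family
    range_stats: RangeStats
    _cache: dict = field(default_factory=dict, repr=False)

    # -- summaries ---------------------------------------------------------
    def group_summary(self, column: str, family: str | None = None) -> tuple[float, float]:
        """Mean +/- SD of one ICC column, optionally within a feature family."""
        tab = self.icc_table
        if family is not None:
            tab = tab[tab.family == family]
        return summarize(tab[column])

    def class_counts(self, column: str = "class_semiauto") -> pd.Series:
        return self.icc_table[column].value_counts()

    @property
    def n_features_higher_semiauto(self) -> int:
        t = self.icc_table
        return int((t["semiauto"] > t["manual"]).sum())

    def icc_comparison_test(self, family: str | None = None) -> tuple[float, float]:
        """Rank-sum test: manual vs semi-automatic per-feature ICCs."""
        tab = self.icc_table
        if family is not None:
            tab = tab[tab.family == family]
        ok = tab[["manual", "semiauto"]].dropna()
        return wilcoxon_ranksum(ok["manual"], ok["semiauto"])

    def range_comparison_tests(self) -> dict[str, tuple[float, float]]:
        """Rank-sum tests manual vs semi-automatic for range and bounds."""
        pf = self.range_stats.per_feature
        man = pf[pf.group == "manual"].set_index("feature")
        sem = pf[pf.group == "semiauto"].set_index("feature")
        common = man.index.intersection(sem.index)
        out = {}
        for col in ("range", "lower", "upper"):
            out[col] = wilcoxon_ranksum(man.loc[common, col], sem.loc[common, col])
        return out

    # -- report ------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Reproducibility of radiomic features", "=" * 38]
        for col, label in [("manual", "manual inter-observer ICC"),
                           ("semiauto", "semi-auto inter-observer ICC (avg of sets)"),
                           ("intra", "semi-auto intra-observer ICC (avg of pairs)")]:
            m, s = self.group_summary(col)
            lines.append(f"{label:45s} {m:.2f} +/- {s:.2f}")
        lines.append("")
        for fam in ("intensity", "shape", "texture"):
            mm, ms = self.group_summary("manual", fam)
            sm, ss = self.group_summary("semiauto", fam)
            lines.append(f"{fam:9s}  manual {mm:.2f}+/-{ms:.2f}   semiauto {sm:.2f}+/-{ss:.2f}")
        lines.append("")
        n = len(self.icc_table)
        lines.append(
            f"features with higher semi-auto ICC: {self.n_features_higher_semiauto}/{n}"
        )
        stat, p = self.icc_comparison_test()
        lines.append(f"rank-sum manual vs semi-auto ICC: p = {p:.4g}")
        for col in ("class_manual", "class_semiauto"):
            counts = self.class_counts(col)
            parts = ", ".join(f"{k}: {counts.get(k, 0)}" for k in ("high", "medium", "low"))
            lines.append(f"{col}: {parts}")
        tests = self.range_comparison_tests()
        lines.append("")
        lines.append("z-normalized range comparison (manual vs semi-auto):")
        for col in ("range", "lower", "upper"):
            lines.append(f"  {col:6s} p = {tests[col][1]:.4g}")
        return "\n".join(lines)
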