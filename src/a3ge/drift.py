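"""Young-vs-old transcriptional drift statistics.

The central quantity is the slope m of the ordinary-least-squares
regression of old log-expression on young log-expression across the
panel: m = 1 means the quantitative transcriptome structure is
preserved, m < 1 means expression levels converge toward a common
attractor (lowly expressed genes rise, highly expressed genes fall).
From m the package derives A3GE — the age-associated alteration of gene
expression, by default 1 - m^2, the fraction of young between-gene
variance lost with age.  Alongside the slope the module computes:

* wRMSD, a CV-weighted root-mean-square deviation of the comparison
  group from the reference group, w_i = CV_i / sum(CV), weights from the
  reference replicates;
* per-category drift for the eight epi-driver gene categories;
* median/variance convergence summaries;
* LEG/HEG tier analysis (bottom/top-ranked genes by young expression)
  with paired and two-sample t statistics from the textbook formulas;
* a sample-overview PCA after median-of-ratios size-factor
  normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

A3GE_VARIANTS = ("one_minus_m_squared", "one_minus_m_quantity_squared")


class InsufficientDataError(ValueError):
    """Too few shared features (or replicates) for the statistic."""


class DegenerateWeightsError(ValueError):
    """All CV weights are zero and no fallback is configured."""


@dataclass(frozen=True)
class DriftConfig:
    """Analysis knobs for a young/old contrast.

    ``log_base``: base of the log transform behind the regression
    (default 2).  ``pseudo_level``: added before the log; at the default
    0, nonpositive/missing levels are excluded pairwise instead.
    ``a3ge_variant``: 1 - m^2 (default) or (1 - m)^2.  ``wrmsd_scale``:
    compute wRMSD on the raw level scale (default) or the log scale.
    ``tier_n``: LEG/HEG tier size (50 for the amplicon panel, 500 for
    genome-wide FPKM).
    """

    log_base: float = 2.0
    pseudo_level: float = 0.0
    a3ge_variant: str = "one_minus_m_squared"
    tier_n: int = 50
    min_features: int = 3
    wrmsd_scale: str = "level"
    variance_scale: str = "log"
    equal_weight_fallback: bool = False

    def validate(self) -> None:
        if self.log_base not in (2, 10, 2.0, 10.0):
            raise ValueError("log_base must be 2 or 10")
        if self.pseudo_level < 0:
            raise ValueError("pseudo_level must be >= 0")
        if self.a3ge_variant not in A3GE_VARIANTS:
            raise ValueError(f"a3ge_variant must be one of {A3GE_VARIANTS}")
        if self.wrmsd_scale not in ("level", "log"):
            raise ValueError("wrmsd_scale must be 'level' or 'log'")
        if self.variance_scale not in ("level", "log"):
            raise ValueError("variance_scale must be 'level' or 'log'")


@dataclass(frozen=True)
class DriftComparison:
    """Summary of one reference-vs-comparison contrast."""

    reference_label: str
    comparison_label: str
    slope_m: float
    intercept: float
    r_squared: float
    wrmsd: float
    a3ge: float
    n_features_used: int

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_label,
            "comparison": self.comparison_label,
            "slope_m": self.slope_m,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "wrmsd": self.wrmsd,
            "a3ge": self.a3ge,
            "n_features_used": self.n_features_used,
        }


# ---------------------------------------------------------------------------
# building blocks


def group_means(
    values: pd.DataFrame, meta: pd.DataFrame, group: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-feature mean over a group's replicates (missing-aware).

    Returns the mean vector and the feature x replicate matrix; features
    missing in every replicate stay NaN.
    """
    samples = meta.loc[meta["group"] == group, "sample_id"]
    if samples.empty:
        raise KeyError(f"unknown or empty group: {group!r}")
    reps = values[list(samples)]
    return reps.mean(axis=1), reps


def _log(x, config: DriftConfig):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(x + config.pseudo_level) / np.log(config.log_base)
    return np.where(x + config.pseudo_level > 0, lx, np.nan)


def fit_young_old_regression(
    ref: pd.Series, cmp: pd.Series, config: DriftConfig | None = None
) -> tuple[float, float, float, int]:
    """OLS of log(comparison) on log(reference), pairwise-complete.

    Returns (slope_m, intercept, r_squared, n_features_used); R^2 is the
    squared Pearson correlation.
    """
    config = config or DriftConfig()
    config.validate()
    ref, cmp = ref.align(cmp, join="inner")
    x = _log(ref, config)
    y = _log(cmp, config)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < config.min_features:
        raise InsufficientDataError(
            f"only {n} shared features after log/missing exclusion "
            f"(need >= {config.min_features})"
        )
    fit = stats.linregress(x[ok], y[ok])
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), n


def a3ge_score(slope_m: float, variant: str = "one_minus_m_squared") -> float:
    """A3GE from the regression slope, clipped to [0, 1].

    Default variant 1 - m^2 equals the fraction of young between-gene
    (log) variance lost under pure compression; (1 - m)^2 is available
    as the alternative rendering.
    """
    if variant not in A3GE_VARIANTS:
        raise ValueError(f"variant must be one of {A3GE_VARIANTS}")
    if not math.isfinite(slope_m):
        raise ValueError("slope must be finite")
    raw = (
        1.0 - slope_m**2
        if variant == "one_minus_m_squared"
        else (1.0 - slope_m) ** 2
    )
    return float(min(1.0, max(0.0, raw)))


def wrmsd(
    ref_replicates: pd.DataFrame,
    cmp: pd.Series,
    config: DriftConfig | None = None,
) -> float:
    """CV-weighted RMSD of the comparison values from the reference means.

    CV_i = sd/mean of feature i across the reference replicates (on the
    configured scale); w_i = CV_i / sum(CV); the statistic is
    sqrt(sum w_i (E_mi - E_i)^2) with E_mi the reference mean and E_i the
    comparison value.  Features with undefined CV (fewer than two
    replicate values, zero mean) or a missing comparison value are
    dropped with a warning; all-zero CVs raise unless the equal-weight
    fallback is enabled.
    """
    config = config or DriftConfig()
    config.validate()
    ref_replicates, cmp = ref_replicates.align(cmp, join="inner", axis=0)
    if config.wrmsd_scale == "log":
        ref_replicates = pd.DataFrame(
            _log(ref_replicates, config),
            index=ref_replicates.index,
            columns=ref_replicates.columns,
        )
        cmp = pd.Series(_log(cmp, config), index=cmp.index)

    mean = ref_replicates.mean(axis=1)
    sd = ref_replicates.std(axis=1, ddof=1)
    n_rep = ref_replicates.notna().sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs()
    ok = (n_rep >= 2) & np.isfinite(cv) & np.isfinite(mean) & cmp.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "wrmsd: dropping %d feature(s) with undefined CV or missing "
            "comparison value", n_dropped,
        )
    cv, mean, cmp = cv[ok], mean[ok], cmp[ok]
    if len(cv) == 0:
        raise InsufficientDataError("no features with a defined CV")
    total_cv = float(cv.sum())
    if total_cv == 0.0:
        if not config.equal_weight_fallback:
            raise DegenerateWeightsError(
                "all reference CVs are zero; enable equal_weight_fallback "
                "to use uniform weights"
            )
        w = np.full(len(cv), 1.0 / len(cv))
    else:
        w = (cv / total_cv).to_numpy()
    dev = (mean - cmp).to_numpy()
    return float(np.sqrt(np.sum(w * dev**2)))


class DriftModel(BaseEstimator):
    """Estimator for one young/old contrast.

    ``fit(ref_replicates, cmp_replicates)`` takes feature x replicate
    DataFrames (a Series is treated as a single replicate) and exposes
    ``slope_m_``, ``intercept_``, ``r_squared_``, ``wrmsd_``, ``a3ge_``
    and ``n_features_used_``.  ``predict(ref_means)`` returns the fitted
    old log-levels for given young levels.
    """

    def __init__(
        self,
        log_base: float = 2.0,
        pseudo_level: float = 0.0,
        a3ge_variant: str = "one_minus_m_squared",
        wrmsd_scale: str = "level",
        min_features: int = 3,
        equal_weight_fallback: bool = False,
    ):
        self.log_base = log_base
        self.pseudo_level = pseudo_level
        self.a3ge_variant = a3ge_variant
        self.wrmsd_scale = wrmsd_scale
        self.min_features = min_features
        self.equal_weight_fallback = equal_weight_fallback

    def _config(self) -> DriftConfig:
        return DriftConfig(
            log_base=self.log_base,
            pseudo_level=self.pseudo_level,
            a3ge_variant=self.a3ge_variant,
            wrmsd_scale=self.wrmsd_scale,
            min_features=self.min_features,
            equal_weight_fallback=self.equal_weight_fallback,
        )

    def fit(self, ref_replicates, cmp_replicates, y=None):
        config = self._config()
        config.validate()
        if isinstance(ref_replicates, pd.Series):
            ref_replicates = ref_replicates.to_frame("rep1")
        if isinstance(cmp_replicates, pd.Series):
            cmp_replicates = cmp_replicates.to_frame("rep1")
        ref_mean = ref_replicates.mean(axis=1)
        cmp_mean = cmp_replicates.mean(axis=1)
        slope, intercept, r2, n = fit_young_old_regression(
            ref_mean, cmp_mean, config
        )
        self.slope_m_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.n_features_used_ = n
        self.wrmsd_ = wrmsd(ref_replicates, cmp_mean, config)
        self.a3ge_ = a3ge_score(slope, config.a3ge_variant)
        return self

    def predict(self, ref_means) -> np.ndarray:
        if not hasattr(self, "slope_m_"):
            raise RuntimeError("DriftModel is not fitted")
        x = _log(ref_means, self._config())
        return self.slope_m_ * x + self.intercept_


def compare_groups(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    ref_group: str,
    cmp_group: str,
    config: DriftConfig | None = None,
) -> DriftComparison:
    """Full drift record for one contrast (slope, R^2, wRMSD, A3GE)."""
    config = config or DriftConfig()
    _, ref_reps = group_means(values, meta, ref_group)
    _, cmp_reps = group_means(values, meta, cmp_group)
    model = DriftModel(
        log_base=config.log_base,
        pseudo_level=config.pseudo_level,
        a3ge_variant=config.a3ge_variant,
        wrmsd_scale=config.wrmsd_scale,
        min_features=config.min_features,
        equal_weight_fallback=config.equal_weight_fallback,
    ).fit(ref_reps, cmp_reps)
    return DriftComparison(
        reference_label=ref_group,
        comparison_label=cmp_group,
        slope_m=model.slope_m_,
        intercept=model.intercept_,
        r_squared=model.r_squared_,
        wrmsd=model.wrmsd_,
        a3ge=model.a3ge_,
        n_features_used=model.n_features_used_,
    )


def category_analysis(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    ref_group: str,
    cmp_group: str,
    feature_to_category: pd.Series,
    config: DriftConfig | None = None,
    min_category_features: int = 5,
) -> tuple[list[DriftComparison], dict[str, str]]:
    """Per-category drift: the global contrast restricted to each category.

    Returns the list of per-category records (labels
    ``cmp_group|category``) and a dict of skipped categories with the
    reason.  No multiplicity correction is applied across categories.
    """
    if feature_to_category.empty:
        raise ValueError("empty category map")
    uncat = values.index.difference(feature_to_category.index)
    if len(uncat):
        raise ValueError(f"uncategorized features: {list(uncat[:5])}")
    results, skipped = [], {}
    cats = feature_to_category.loc[values.index]
    for cat in sorted(cats.unique()):
        feats = cats.index[cats == cat]
        if len(feats) < min_category_features:
            skipped[cat] = (
                f"only {len(feats)} features (< {min_category_features})"
            )
            continue
        try:
            rec = compare_groups(
                values.loc[feats], meta, ref_group, cmp_group, config
            )
        except InsufficientDataError as exc:
            skipped[cat] = str(exc)
            continue
        results.append(
            DriftComparison(
                reference_label=rec.reference_label,
                comparison_label=f"{cmp_group}|{cat}",
                slope_m=rec.slope_m,
                intercept=rec.intercept,
                r_squared=rec.r_squared,
                wrmsd=rec.wrmsd,
                a3ge=rec.a3ge,
                n_features_used=rec.n_features_used,
            )
        )
    return results, skipped


def summarize_dispersion(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    groups: list[str],
    reference: str,
    config: DriftConfig | None = None,
) -> pd.DataFrame:
    """Median (level scale) and variance (log scale by default) per group,
    plus ratios relative to the reference group."""
    config = config or DriftConfig()
    config.validate()
    rows = {}
    for g in groups:
        mean, _ = group_means(values, meta, g)
        med = float(mean.median())
        x = mean.to_numpy(float) if config.variance_scale == "level" else _log(
            mean, config
        )
        var = float(np.nanvar(x, ddof=1))
        rows[g] = {"median_level": med, "variance": var}
    out = pd.DataFrame(rows).T
    if reference not in out.index:
        raise KeyError(f"reference group {reference!r} not summarized")
    out["median_ratio"] = out["median_level"] / out.at[reference, "median_level"]
    out["variance_ratio"] = out["variance"] / out.at[reference, "variance"]
    out.index.name = "group"
    return out


# ---------------------------------------------------------------------------
# LEG / HEG tier analysis


@dataclass(frozen=True)
class TierResult:
    """Paired drift of one expression tier (LEG or HEG)."""

    tier: str
    feature_ids: tuple[str, ...] = field(repr=False)
    mean_log2_fold_change: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    df: int = 0

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "n_features": len(self.feature_ids),
            "mean_log2_fold_change": self.mean_log2_fold_change,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "df": self.df,
        }


def select_leg_heg(
    young_means: pd.Series, tier_n: int = 50, min_level: float = 0.0
) -> tuple[list[str], list[str]]:
    """Bottom/top ``tier_n`` features ranked by young expression level.

    Features at or below ``min_level`` (default 0: unexpressed) are
    excluded first; ties at tier boundaries are broken by feature id so
    the selection is deterministic.
    """
    kept = young_means[(young_means > min_level) & young_means.notna()]
    if len(kept) < 2 * tier_n:
        raise InsufficientDataError(
            f"need >= {2 * tier_n} features above min_level, have {len(kept)}"
        )
    # stable sort on an id-ordered series, so boundary ties resolve by id
    ranked = kept.sort_index(kind="mergesort").sort_values(kind="mergesort")
    leg = list(ranked.index[:tier_n])
    heg = list(ranked.index[-tier_n:])
    return leg, heg


def paired_t_one_sample(d: np.ndarray) -> tuple[float, float, int]:
    """One-sample t of the paired differences against 0: t = mean/(sd/sqrt(n)).

    Two-sided p from the Student-t distribution with df = n - 1.  If
    sd = 0 the statistic degenerates: p = 1 when the common difference is
    0, otherwise t = +/-inf and p = 0 (flagged case).
    """
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 2:
        raise InsufficientDataError("need >= 2 paired differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean), 0.0, df
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0), df


def welch_t_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t with Welch–Satterthwaite df; two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 values per tier")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(na + nb - 2)
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, float(
            na + nb - 2
        )
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0), float(df)


def drift_by_tier(
    ref_means: pd.Series,
    cmp_means: pd.Series,
    leg_ids: list[str],
    heg_ids: list[str],
    pseudo: float = 0.0,
) -> tuple[TierResult, TierResult, float]:
    """Paired drift of LEG and HEG tiers plus the between-tier contrast.

    Per feature d_i = log2((cmp + pseudo)/(ref + pseudo)); each tier gets
    the mean d and a one-sample paired t-test of d against 0; the LEG and
    HEG d's are compared with a two-sample (Welch) t-test.
    """
    if set(leg_ids) & set(heg_ids):
        raise ValueError("LEG and HEG tiers must be disjoint")

    def tier_d(ids):
        r = ref_means.loc[ids].to_numpy(float) + pseudo
        c = cmp_means.loc[ids].to_numpy(float) + pseudo
        bad = ~((r > 0) & (c > 0))
        if bad.any():
            name = np.asarray(ids)[bad][0]
            raise ValueError(
                f"feature {name!r} nonpositive after pseudo-count; "
                "cannot take log2 fold change"
            )
        return np.log2(c / r)

    results = []
    tiers = {"LEG": leg_ids, "HEG": heg_ids}
    ds = {}
    for tier, ids in tiers.items():
        d = tier_d(ids)
        ds[tier] = d
        t, p, df = paired_t_one_sample(d)
        results.append(
            TierResult(
                tier=tier,
                feature_ids=tuple(ids),
                mean_log2_fold_change=float(d.mean()),
                t_statistic=t,
                p_value=p,
                df=df,
            )
        )
    _, between_p, _ = welch_t_two_sample(ds["LEG"], ds["HEG"])
    return results[0], results[1], between_p


# ---------------------------------------------------------------------------
# PCA overview


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples input).

    Per sample: median over features of count / geometric-mean-across-
    samples, computed on features with no zero counts.
    """
    x = matrix.to_numpy(float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise InsufficientDataError("no feature is positive in all samples")
    logx = np.log(x[positive])
    log_geo = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - log_geo, axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


class ExpressionPCA(TransformerMixin, BaseEstimator):
    """Sample-overview PCA: size-factor normalize, log2(x+1), restrict to
    the most variable features, center, SVD.

    ``fit_transform(matrix)`` takes a features x samples DataFrame and
    returns sample coordinates on the first ``n_components`` PCs;
    ``explained_variance_ratio_`` holds the variance fractions.
    """

    def __init__(self, n_components: int = 2, top_k_variable: int = 500):
        self.n_components = n_components
        self.top_k_variable = top_k_variable

    def fit_transform(self, matrix: pd.DataFrame, y=None) -> pd.DataFrame:
        if matrix.shape[1] < 2:
            raise InsufficientDataError("PCA needs >= 2 samples")
        matrix = matrix.loc[(matrix > 0).any(axis=1)]
        sf = size_factors(matrix)
        norm = np.log2(matrix.to_numpy(float) / sf.to_numpy() + 1.0)
        var = norm.var(axis=1)
        k = min(self.top_k_variable, norm.shape[0])
        top = np.argsort(var, kind="stable")[::-1][:k]
        x = norm[top]
        x = x - x.mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(x.T, full_matrices=False)
        n_pc = min(self.n_components, s.size)
        coords = u[:, :n_pc] * s[:n_pc]
        total = float((s**2).sum())
        self.explained_variance_ratio_ = (
            s[:n_pc] ** 2 / total if total > 0 else np.zeros(n_pc)
        )
        self.size_factors_ = sf
        self.n_features_used_ = k
        return pd.DataFrame(
            coords,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_pc)],
        )

    def fit(self, matrix, y=None):
        self.fit_transform(matrix)
        return self


def pca_overview(
    matrix: pd.DataFrame, top_k_variable: int = 500, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Thin wrapper over :class:`ExpressionPCA`; returns (coords,
    explained-variance fractions)."""
    pca = ExpressionPCA(n_components=n_components, top_k_variable=top_k_variable)
    coords = pca.fit_transform(matrix)
    return coords, pca.explained_variance_ratio_
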