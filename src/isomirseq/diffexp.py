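"""Negative-binomial differential expression with median-of-ratios normalization.

The procedure follows the standard count-based RNA-seq testing scheme:
per-sample size factors by the median-of-ratios rule, a per-feature
negative-binomial generalized linear model with a log link and size-factor
offsets for a two-group comparison, a two-sided Wald test on the group
coefficient, and Benjamini–Hochberg adjustment across tested features. A
feature is called significant when ``padj <= alpha`` AND ``|log2FC| >=
min_abs_lfc`` AND ``baseMean >= min_base_mean`` (all thresholds inclusive;
defaults 0.05 / 1.0 / 50).

This is deliberately a simplified NB-Wald procedure, not a re-implementation
of DESeq2: per-feature dispersions come from a method-of-moments estimate on
normalized counts (floored at 1e-8) with no shrinkage toward a mean-dispersion
trend, and no fold-change shrinkage, independent filtering or outlier
replacement is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
#: pseudo-count used only for the descriptive fold change fallback when the
#: GLM cannot be fitted (e.g. a group with all-zero counts)
DESCRIPTIVE_PSEUDO = 0.5


@dataclass(frozen=True)
class SignificanceThresholds:
    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    min_base_mean: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.min_abs_lfc < 0 or self.min_base_mean < 0:
            raise ValueError("min_abs_lfc and min_base_mean must be >= 0")


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    factor_j = median over features i, restricted to features with a positive
    geometric mean across samples, of count_ij / geomean_i.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    usable = np.all(np.isfinite(log_mat), axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; size factors are "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geomean = log_mat[usable].mean(axis=1)
    log_factors = np.median(log_mat[usable] - log_geomean[:, None], axis=0)
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values; NaN inputs stay NaN and are not counted."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _fit_nb_wald(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[float, float] | None:
    """Fit the NB GLM and return (log2FC, wald p) or None on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                y, design, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            )
            res = model.fit(maxiter=100, tol=1e-8)
        beta = res.params[1]
        se = res.bse[1]
        if not (np.isfinite(beta) and np.isfinite(se)) or se <= 0 or se > 1e3:
            return None
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return beta / np.log(2.0), float(p)
    except Exception:
        return None


def nb_differential(
    counts: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    reference_level: str | None = None,
) -> pd.DataFrame:
    """Two-group NB-Wald differential expression over a count matrix.

    Parameters
    ----------
    counts
        Features x samples non-negative integer matrix.
    groups
        One label per sample column; exactly two distinct levels.
    reference_level
        The baseline group (log2FC > 0 means higher in the other group).
        Defaults to the alphabetically first level.

    Returns a DataFrame indexed by feature with columns ``baseMean``,
    ``log2FoldChange``, ``pvalue``, ``padj``. All-zero features, and all
    features when either group has fewer than two samples, carry missing
    p-values but keep descriptive columns.
    """
    groups = pd.Series(list(groups), index=counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if reference_level is None:
        reference_level = levels[0]
    elif reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not among {levels}")
    other = next(l for l in levels if l != reference_level)

    sf = estimate_size_factors(counts)
    norm = counts.div(sf, axis=1)
    base_mean = norm.mean(axis=1)

    is_b = (groups == other).to_numpy()
    n_a, n_b = int((~is_b).sum()), int(is_b.sum())
    testable_design = n_a >= 2 and n_b >= 2

    design = np.column_stack([np.ones(counts.shape[1]), is_b.astype(float)])
    offset = np.log(sf.to_numpy())
    y_mat = counts.to_numpy(dtype=float)
    norm_mat = norm.to_numpy()

    lfc = np.full(counts.shape[0], np.nan)
    pval = np.full(counts.shape[0], np.nan)

    for i in range(counts.shape[0]):
        y = y_mat[i]
        if y.sum() == 0:
            continue
        mean_a = norm_mat[i, ~is_b].mean()
        mean_b = norm_mat[i, is_b].mean()
        descriptive = np.log2(
            (mean_b + DESCRIPTIVE_PSEUDO) / (mean_a + DESCRIPTIVE_PSEUDO)
        )
        if not testable_design:
            lfc[i] = descriptive
            continue
        # method-of-moments dispersion, pooled within groups
        var_a = norm_mat[i, ~is_b].var(ddof=1)
        var_b = norm_mat[i, is_b].var(ddof=1)
        pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        mu = norm_mat[i].mean()
        alpha = max((pooled_var - mu) / mu**2, DISPERSION_FLOOR)
        # continuity correction only when one group is entirely zero, where
        # the log-link MLE diverges
        y_fit = y if (mean_a > 0 and mean_b > 0) else y + DESCRIPTIVE_PSEUDO
        fit = _fit_nb_wald(y_fit, design, offset, alpha)
        if fit is None:
            lfc[i] = descriptive
        else:
            lfc[i], pval[i] = fit

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pval,
            "padj": benjamini_hochberg(pval),
        },
        index=counts.index,
    )


def filter_significant(
    records: pd.DataFrame, thresholds: SignificanceThresholds | None = None
) -> pd.DataFrame:
    """Apply the significance filter and annotate direction.

    Adds boolean ``significant`` and ``direction`` ('up'/'down'/'') columns;
    records with missing padj are never significant.
    """
    thresholds = thresholds or SignificanceThresholds()
    out = records.copy()
    padj = out["padj"]
    lfc = out["log2FoldChange"]
    sig = (
        padj.notna()
        & (padj <= thresholds.alpha)
        & (lfc.abs() >= thresholds.min_abs_lfc)
        & (out["baseMean"] >= thresholds.min_base_mean)
    )
    out["significant"] = sig
    out["direction"] = np.where(sig & (lfc > 0), "up", np.where(sig, "down", ""))
    return out


@dataclass(frozen=True)
class Contrast:
    name: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]
    label_a: str
    label_b: str


def build_default_contrasts(
    sample_sheet: pd.DataFrame, reference_time: str | None = None
) -> list[Contrast]:
    """The study's contrast manifest from a (sample_id, group, time_point) sheet.

    Emits every group-vs-group comparison (all time points pooled) and, within
    each group, every later time point against the reference (pre-feeding)
    time point.
    """
    sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet else sample_sheet
    groups = sorted(sheet["group"].unique())
    times = list(dict.fromkeys(sheet["time_point"]))
    if reference_time is None:
        reference_time = times[0]
    contrasts: list[Contrast] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            contrasts.append(
                Contrast(
                    name=f"{gb}_vs_{ga}",
                    samples_a=tuple(sheet.index[sheet["group"] == ga]),
                    samples_b=tuple(sheet.index[sheet["group"] == gb]),
                    label_a=ga,
                    label_b=gb,
                )
            )
    for g in groups:
        in_g = sheet["group"] == g
        ref_samples = tuple(sheet.index[in_g & (sheet["time_point"] == reference_time)])
        if not ref_samples:
            continue
        for t in times:
            if t == reference_time:
                continue
            t_samples = tuple(sheet.index[in_g & (sheet["time_point"] == t)])
            if not t_samples:
                continue
            contrasts.append(
                Contrast(
                    name=f"{g}_{t}_vs_{reference_time}",
                    samples_a=ref_samples,
                    samples_b=t_samples,
                    label_a=f"{g}:{reference_time}",
                    label_b=f"{g}:{t}",
                )
            )
    return contrasts


def run_contrast(counts: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Run nb_differential for one contrast (baseMean over its samples only)."""
    cols = list(contrast.samples_a) + list(contrast.samples_b)
    labels = [contrast.label_a] * len(contrast.samples_a) + [
        contrast.label_b
    ] * len(contrast.samples_b)
    return nb_differential(counts[cols], labels, reference_level=contrast.label_a)
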