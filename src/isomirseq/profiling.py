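"""Descriptive library analytics: RNA-species distribution, clustering, PCA,
and the abundance vs. up-regulation overlap analysis.

Counts are placed on a common scale as ``log2(count / size_factor + 1)`` — a
plain variance-stabilizing approximation of a regularized log transform —
before Euclidean distances, Ward (Ward.D2) linkage and principal components
are computed. PCA is run on the top-``k`` most variable features (default
500), centered but not scaled, with component signs fixed by a deterministic
convention (the largest-magnitude loading of each component is positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .preprocess import ReadClass, TERMINAL_CLASSES


def species_distribution(
    class_counts: Mapping[str, Mapping[ReadClass, int]],
    sample_groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample read-class percentages of total library size.

    Returns (per-sample table, per-group mean table or None). Samples with
    zero reads are kept as all-zero rows flagged ``empty`` and excluded from
    group means. Unknown class labels are a hard error.
    """
    classes = list(TERMINAL_CLASSES)
    rows = {}
    for sample, counts in class_counts.items():
        unknown = set(counts) - set(classes)
        if unknown:
            raise ValueError(f"sample {sample!r}: unknown read classes {unknown}")
        rows[sample] = [counts.get(c, 0) for c in classes]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.value for c in classes]
    )
    table.index.name = "sample_id"
    total = table.sum(axis=1)
    pct = table.div(total.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0)
    pct["total_reads"] = total
    pct["empty"] = total == 0

    group_means = None
    if sample_groups is not None:
        nonempty = pct.loc[~pct["empty"]]
        groups = pd.Series({s: sample_groups[s] for s in nonempty.index})
        group_means = nonempty[[c.value for c in classes]].groupby(groups).mean()
        group_means.index.name = "group"
    return pct, group_means


def transform_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(normalized count + 1), features x samples."""
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def top_variance_features(transformed: pd.DataFrame, k: int) -> pd.DataFrame:
    """Rows with the k largest across-sample variances (ties by feature id)."""
    variances = transformed.var(axis=1, ddof=1)
    order = sorted(transformed.index, key=lambda f: (-variances[f], f))
    return transformed.loc[order[: min(k, len(order))]]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_percent: np.ndarray
    loadings: pd.DataFrame  # features x components


def transform_and_pca(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    k: int = 500,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the log-normalized counts restricted to the top-k variable features."""
    if counts.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    sub = top_variance_features(transform_counts(counts, size_factors), k)
    X = sub.to_numpy().T  # samples x features
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: the largest-|loading| entry of each component is positive
    for j in range(len(s)):
        idx = int(np.argmax(np.abs(vt[j])))
        if vt[j, idx] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float((s**2).sum())
    explained = (s**2) / total_var * 100.0 if total_var > 0 else np.zeros_like(s)
    n_keep = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{j + 1}" for j in range(n_keep)]
    coords = pd.DataFrame(
        (u[:, :n_keep] * s[:n_keep]), index=counts.columns, columns=comp_names
    )
    loadings = pd.DataFrame(vt[:n_keep].T, index=sub.index, columns=comp_names)
    return PCAResult(coords, explained[:n_keep], loadings)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    sample_ids: list[str]
    method: str = "ward.D2"


def hierarchical_cluster(
    counts: pd.DataFrame, size_factors: pd.Series, k: int | None = None
) -> ClusterResult:
    """Ward.D2 hierarchical clustering of samples on Euclidean distances of the
    log-normalized matrix (optionally restricted to the top-k variable features)."""
    if counts.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    transformed = transform_counts(counts, size_factors)
    if k is not None:
        transformed = top_variance_features(transformed, k)
    X = transformed.to_numpy().T
    Z = hierarchy.linkage(X, method="ward", optimal_ordering=False)
    leaves = hierarchy.leaves_list(Z)
    samples = list(counts.columns)
    return ClusterResult(Z, [samples[i] for i in leaves], samples)


@dataclass(frozen=True)
class OverlapResult:
    time_point: str
    n_top: int
    overlap_count: int
    overlap_percent: float
    top_read_fraction_percent: float
    overlap_features: tuple[str, ...]


def rank_by_abundance(
    reference_counts: pd.DataFrame, size_factors: pd.Series
) -> pd.Series:
    """Features ranked by mean normalized count in the reference group,
    descending, ties broken by feature id."""
    mean_norm = reference_counts.div(size_factors, axis=1).mean(axis=1)
    order = sorted(mean_norm.index, key=lambda f: (-mean_norm[f], f))
    return mean_norm.loc[order]


def abundance_overlap(
    reference_counts: pd.DataFrame,
    size_factors: pd.Series,
    up_sets: Mapping[str, set[str] | Sequence[str]],
    n_top: int = 100,
) -> list[OverlapResult]:
    """Overlap of the reference group's top-``n_top`` most abundant features
    with the up-regulated feature set of each time point.

    Also reports the cumulative share of reads (percent of the reference
    group's total normalized counts) carried by the top-``n_top`` set.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    ranked = rank_by_abundance(reference_counts, size_factors)
    if n_top > len(ranked):
        import warnings

        warnings.warn(
            f"n_top={n_top} exceeds feature count {len(ranked)}; using all features"
        )
        n_top = len(ranked)
    top = list(ranked.index[:n_top])
    top_set = set(top)
    total = float(ranked.sum())
    top_fraction = 100.0 * float(ranked.iloc[:n_top].sum()) / total if total > 0 else 0.0

    results = []
    for time_point, up in up_sets.items():
        overlap = sorted(top_set & set(up))
        results.append(
            OverlapResult(
                time_point=time_point,
                n_top=n_top,
                overlap_count=len(overlap),
                overlap_percent=100.0 * len(overlap) / n_top,
                top_read_fraction_percent=top_fraction,
                overlap_features=tuple(overlap),
            )
        )
    return results
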