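"""Gene-level pathway over-representation for significant miRNAs.

A single miRNA can target many genes inside one pathway, so testing at the
(miRNA, target) pair level inflates enrichment. The query set is therefore
the *union* of target genes over all significant miRNAs — a gene targeted by
several miRNAs counts once — and each pathway is scored with an upper-tail
hypergeometric test against a universe of all genes that appear both in the
target map and in at least one pathway, followed by Benjamini–Hochberg
adjustment across pathways.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg


def load_homolog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping miRNA ids to homologous ids (e.g. bta -> hsa)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        src, dst = line.split("\t")[:2]
        mapping[src] = dst
    return mapping


def load_target_map(
    path: str | Path,
    evidence_filter: str | None = None,
    homolog_map: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Load a miRNA -> target-gene map from a 2- or 3-column TSV.

    Columns: miRNA id, gene id, optional evidence label. When
    ``evidence_filter`` is given only rows with that label are kept. miRNA ids
    are translated through ``homolog_map`` when provided (identity otherwise).
    Duplicate (miRNA, gene) pairs collapse to one.
    """
    targets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"target map line {lineno}: expected >= 2 columns")
        mirna, gene = parts[0], parts[1]
        if evidence_filter is not None:
            if len(parts) < 3 or parts[2] != evidence_filter:
                continue
        targets.setdefault(mirna, set()).add(gene)
    if homolog_map:
        targets = {homolog_map.get(m, m): g for m, g in targets.items()}
    return targets


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    pathways: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, genes")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise ValueError(f"GMT line {lineno}: empty gene set {parts[0]!r}")
        pathways[parts[0]] = genes
    return pathways


def pathway_enrichment(
    significant_mirnas: Iterable[str],
    target_map: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in the collapsed target set.

    Returns a DataFrame sorted by ascending p-value (ties by pathway id) with
    columns ``overlap`` (k), ``pathway_size`` (K), ``query_size`` (n),
    ``universe_size`` (N), ``pvalue``, ``padj`` and ``mirnas`` (the
    significant miRNAs contributing at least one overlapping target).
    """
    mirnas = list(dict.fromkeys(significant_mirnas))
    missing = [m for m in mirnas if m not in target_map]
    if missing:
        warnings.warn(f"miRNAs absent from target map, skipped: {missing}")
    present = [m for m in mirnas if m in target_map]

    universe = set().union(*target_map.values()) if target_map else set()
    pathway_genes = set().union(*pathways.values()) if pathways else set()
    universe &= pathway_genes

    query = set()
    for m in present:
        query |= target_map[m]
    query &= universe
    if not query:
        raise ValueError("query gene set is empty after restriction to the universe")

    N, n = len(universe), len(query)
    rows = []
    for pid in sorted(pathways):
        pset = pathways[pid] & universe
        K = len(pset)
        overlap = query & pset
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        contributing = sorted(m for m in present if target_map[m] & pset & query)
        rows.append(
            {
                "pathway": pid,
                "overlap": k,
                "pathway_size": K,
                "query_size": n,
                "universe_size": N,
                "pvalue": p,
                "mirnas": ";".join(contributing) if k else "",
            }
        )
    df = pd.DataFrame(rows).set_index("pathway")
    df["padj"] = benjamini_hochberg(df["pvalue"])
    # rows were built in sorted pathway order; stable sort keeps id as tie-break
    return df.sort_values("pvalue", kind="mergesort")


def top_pathways(enrichment: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The n most enriched pathways (ascending p)."""
    return enrichment.head(n)
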