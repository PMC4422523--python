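"""Overrepresentation analysis with BH FDR, GMT I/O, and cross-tables.

Per namespace (e.g. biological-process-like, pathway-like), each term is
tested with the one-sided hypergeometric tail

    p = P(X >= Significant),  X ~ Hypergeom(|universe|, Annotated, |query|)

with Expected = Annotated * |query ∩ universe| / |universe|, and q-values
from Benjamini–Hochberg step-up across the namespace's terms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "overrepresentation",
    "bh_fdr",
    "expected_count",
    "cross_table",
]

# catalog type: {namespace: {term_id: (term_name, frozenset(genes))}}
Catalog = Mapping[str, Mapping[str, tuple[str, frozenset]]]


def read_gmt(path, namespace: str = "default") -> dict[str, dict[str, tuple[str, frozenset]]]:
    """Read one GMT file into a single-namespace catalog."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, genes = parts[0], parts[1], parts[2:]
            if not term_id:
                raise ValueError("empty term id in GMT")
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"term {term_id} has no genes")
            terms[term_id] = (name, frozenset(genes))
    return {namespace: terms}


def write_gmt(terms: Mapping[str, tuple[str, frozenset]], path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            name, genes = terms[term_id]
            if not term_id:
                raise ValueError("empty term id")
            if not genes:
                raise ValueError(f"term {term_id} has empty gene set")
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def namespace_universe(catalog: Catalog, namespace: str) -> frozenset:
    """Default universe: all genes annotated in the namespace."""
    if namespace not in catalog:
        raise KeyError(f"unknown namespace {namespace!r}")
    out: set = set()
    for _, genes in catalog[namespace].values():
        out |= genes
    return frozenset(out)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def expected_count(annotated: float, sampling_fraction: float) -> float:
    """Expected annotations in the query set: Annotated x sampling fraction.

    The sampling fraction is |query ∩ universe| / |universe|; given any
    reported (Annotated, Expected) pair of the same namespace it can be
    recovered as Expected / Annotated and reused for other terms.
    """
    return annotated * sampling_fraction


def overrepresentation(
    query: Iterable[str],
    catalog: Catalog,
    namespace: str,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation for every term.

    Returns rows (term_id, name, annotated, significant, expected, p, q)
    sorted by q then p.  ``universe`` defaults to all genes annotated in
    the namespace; pass the expression universe to use it instead.
    """
    if namespace not in catalog:
        raise KeyError(f"unknown namespace {namespace!r}")
    uni = frozenset(universe) if universe is not None else namespace_universe(catalog, namespace)
    if not uni:
        raise ValueError("empty universe")
    q_set = frozenset(query) & uni
    if not q_set:
        raise ValueError("query does not intersect the universe")
    M, N = len(uni), len(q_set)
    rows = []
    for term_id, (name, genes) in catalog[namespace].items():
        ann = genes & uni
        n = len(ann)
        k = len(ann & q_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "annotated": n,
                "significant": k,
                "expected": n * N / M,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def cross_table(
    pairs: pd.DataFrame,
    enriched_terms: Iterable[str],
    catalog: Catalog,
    namespace: str,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Seed-gene x term counts of annotated predicted targets.

    Cell (seed e, term t) counts e's predicted target genes annotated
    with t (targets shared by several seeds are counted once per seed).
    Returns the count table plus hierarchical-clustering leaf orders for
    rows and columns (identity order for degenerate shapes).
    """
    terms = list(enriched_terms)
    unknown = [t for t in terms if t not in catalog[namespace]]
    if unknown:
        raise KeyError(f"terms not in catalog: {unknown[:5]}")
    seeds = sorted(pairs["seed"].unique()) if not pairs.empty else []
    table = pd.DataFrame(0, index=seeds, columns=terms, dtype=int)
    for seed_gene, grp in pairs.groupby("seed"):
        targets = set(grp["gene"])
        for t in terms:
            _, genes = catalog[namespace][t]
            table.loc[seed_gene, t] = len(targets & genes)

    def _leaf_order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3 or np.allclose(pdist(mat), 0):
            return np.arange(mat.shape[0])
        return np.asarray(hierarchy.leaves_list(hierarchy.linkage(mat, method="average")))

    vals = table.to_numpy(dtype=float)
    row_order = _leaf_order(vals) if len(seeds) else np.arange(0)
    col_order = _leaf_order(vals.T) if terms else np.arange(0)
    return table, row_order, col_order


def plot_cross_table(table: pd.DataFrame, row_order=None, col_order=None, ax=None):
    """Optional heat-map rendering of a cross-table (requires matplotlib)."""
    import matplotlib.pyplot as plt  # lazy: plotting is optional

    if row_order is not None:
        table = table.iloc[list(row_order)]
    if col_order is not None:
        table = table.iloc[:, list(col_order)]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, table.shape[1] / 2), max(3, table.shape[0] / 3)))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="annotated targets")
    return ax
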