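"""Correlation and mutual-rank matrices, and foreground/background tests.

Mutual rank (MR) follows the co-expression database convention: for genes
a and b, rank all partners of a by descending Pearson correlation
(excluding a itself, average ranks at ties) and vice versa; then

    MR(a, b) = sqrt(rank_a(b) * rank_b(a)).

MR is >= 1, symmetric, and equals 1 exactly when a and b are reciprocal
top-ranked partners.  Being rank-based, it is invariant under strictly
monotone transforms of each gene's correlation profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ExpressionCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_matrix",
    "mutual_rank",
    "fisher_z",
    "compare_foreground_background",
    "DistributionComparison",
    "pair_values",
    "read_pair_table",
    "write_pair_table",
]


def pearson_matrix(comp: ExpressionCompendium, min_obs: int = 20) -> pd.DataFrame:
    """Pairwise Pearson correlation between gene rows.

    With complete data this is a single BLAS call; with missing values it
    falls back to pairwise-complete correlation requiring at least
    ``min_obs`` shared observations per pair (entries below that are NaN).
    Zero-variance genes yield NaN rows/columns (diagonal kept at 1).
    """
    data = comp.data
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        corr = data.T.corr(min_periods=min_obs)
    else:
        sd = values.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(values)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning("%d zero-variance genes: correlations set to missing",
                           int(degenerate.sum()))
            c[degenerate, :] = np.nan
            c[:, degenerate] = np.nan
        np.fill_diagonal(c, 1.0)
        c = np.clip(c, -1.0, 1.0)
        corr = pd.DataFrame(c, index=data.index, columns=data.index)
    return corr


def mutual_rank(corr: pd.DataFrame) -> pd.DataFrame:
    """Mutual-rank matrix from a symmetric correlation matrix.

    Self-correlations are excluded from the ranking; ties receive average
    ranks; missing correlations propagate to missing MR entries.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    c = corr.to_numpy(dtype=float).copy()
    n = c.shape[0]
    np.fill_diagonal(c, np.nan)
    if np.isnan(c[~np.eye(n, dtype=bool)]).any():
        logger.warning("missing correlations: corresponding MR entries are missing")
    # rank partners by descending rho per row (average ties, NaN -> NaN)
    ranks = pd.DataFrame(-c).rank(axis=1, method="average").to_numpy()
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, np.nan)
    return pd.DataFrame(mr, index=corr.index, columns=corr.columns)


def fisher_z(rho):
    """Fisher z-transform, z = atanh(rho); requires |rho| < 1."""
    arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |rho| < 1")
    return np.arctanh(rho)


def write_pair_table(corr: pd.DataFrame, mr: pd.DataFrame | None, path) -> None:
    """Write matrices as a long-form pair list (gene1, gene2, rho[, mr])."""
    genes = list(corr.index)
    rows = []
    c = corr.to_numpy()
    m = mr.to_numpy() if mr is not None else None
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            rec = {"gene1": genes[i], "gene2": genes[j], "rho": c[i, j]}
            if m is not None:
                rec["mr"] = m[i, j]
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Ingest a precomputed long-form pair table (gene1, gene2, rho[, mr]).

    This is the ingestion path for database exports whose MR values were
    computed upstream; entries absent from the table are missing in the
    returned square matrices (diagonal rho = 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    if not {"gene1", "gene2", "rho"} <= set(df.columns):
        raise ValueError("pair table needs columns gene1, gene2, rho")
    genes = sorted(set(df["gene1"]) | set(df["gene2"]))
    corr = pd.DataFrame(np.nan, index=genes, columns=genes)
    has_mr = "mr" in df.columns
    mr = pd.DataFrame(np.nan, index=genes, columns=genes) if has_mr else None
    for _, r in df.iterrows():
        corr.loc[r["gene1"], r["gene2"]] = corr.loc[r["gene2"], r["gene1"]] = r["rho"]
        if has_mr:
            mr.loc[r["gene1"], r["gene2"]] = mr.loc[r["gene2"], r["gene1"]] = r["mr"]
    for g in genes:
        corr.loc[g, g] = 1.0
    return corr, mr


def pair_values(matrix: pd.DataFrame, pairs) -> np.ndarray:
    """Extract matrix values for an iterable of (gene, gene) pairs."""
    idx = {g: i for i, g in enumerate(matrix.index)}
    vals = matrix.to_numpy()
    out = [vals[idx[a], idx[b]] for a, b in pairs if a in idx and b in idx]
    return np.asarray(out, dtype=float)


@dataclass
class DistributionComparison:
    foreground: str
    background: str
    n_fg: int
    n_bg: int
    t_statistic: float
    p_t: float  # one-sided t-test on Fisher-z values (alt: background smaller)
    p_wilcoxon_mr: float | None  # rank-sum on MR values (alt: foreground smaller)
    fg_z: np.ndarray
    bg_z: np.ndarray
    ecdf_fg: tuple[np.ndarray, np.ndarray] | None = None
    ecdf_bg: tuple[np.ndarray, np.ndarray] | None = None


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, xs.size + 1) / xs.size


def compare_foreground_background(
    fg_pairs,
    bg_pairs,
    corr: pd.DataFrame,
    mr: pd.DataFrame | None = None,
    fg_label: str = "foreground",
    bg_label: str = "background",
) -> DistributionComparison:
    """Test whether foreground pairs are more strongly co-expressed.

    Correlations are Fisher-transformed and compared with a one-sided
    two-sample t-test (alternative: background correlations are smaller);
    mutual ranks, when given, are compared with a one-sided Wilcoxon
    rank-sum test (alternative: foreground MR smaller).  Also emits ECDF
    points for cumulative-distribution plots.
    """
    fg_pairs, bg_pairs = list(fg_pairs), list(bg_pairs)
    if not fg_pairs or not bg_pairs:
        raise ValueError("foreground and background pair sets must be nonempty")
    if {frozenset(p) for p in fg_pairs} & {frozenset(p) for p in bg_pairs}:
        raise ValueError("foreground and background pair sets must be disjoint")
    fg_rho = pair_values(corr, fg_pairs)
    bg_rho = pair_values(corr, bg_pairs)
    fg_rho = fg_rho[np.isfinite(fg_rho)]
    bg_rho = bg_rho[np.isfinite(bg_rho)]
    if fg_rho.size < 2 or bg_rho.size < 2:
        raise ValueError("need >= 2 finite correlation values per set")
    fg_z = fisher_z(np.clip(fg_rho, -0.999999, 0.999999))
    bg_z = fisher_z(np.clip(bg_rho, -0.999999, 0.999999))
    t_res = stats.ttest_ind(fg_z, bg_z, alternative="greater", equal_var=False)
    p_w = None
    if mr is not None:
        fg_mr = pair_values(mr, fg_pairs)
        bg_mr = pair_values(mr, bg_pairs)
        fg_mr = fg_mr[np.isfinite(fg_mr)]
        bg_mr = bg_mr[np.isfinite(bg_mr)]
        p_w = float(stats.ranksums(fg_mr, bg_mr, alternative="less").pvalue)
    return DistributionComparison(
        foreground=fg_label,
        background=bg_label,
        n_fg=fg_z.size,
        n_bg=bg_z.size,
        t_statistic=float(t_res.statistic),
        p_t=float(t_res.pvalue),
        p_wilcoxon_mr=p_w,
        fg_z=fg_z,
        bg_z=bg_z,
        ecdf_fg=_ecdf(fg_rho),
        ecdf_bg=_ecdf(bg_rho),
    )
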