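"""Co-expression target prediction: top-pair selection, tightness, sweep.

A candidate target is any non-seed gene appearing among the K highest
correlating (seed gene, other gene) pairs.  Its *tightness* is the number
of distinct seed genes it pairs with; filtering at tightness >= 2 keeps
only genes associated with multiple seed-network members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeedNetwork",
    "SelectionReport",
    "load_default_seed_network",
    "select_top_pairs",
    "compute_tightness",
    "filter_tightness",
    "tightness_sweep",
]


@dataclass
class SeedNetwork:
    """Curated seed network: nodes with layer (CCN within ECCN) and signed edges."""

    nodes: pd.DataFrame  # columns: gene, layer in {CCN, ECCN}
    edges: pd.DataFrame  # columns: gene1, gene2, sign, refs

    def __post_init__(self) -> None:
        layers = set(self.nodes["layer"])
        if not layers <= {"CCN", "ECCN"}:
            raise ValueError(f"unknown node layers: {layers - {'CCN', 'ECCN'}}")
        if self.nodes["gene"].duplicated().any():
            raise ValueError("duplicate genes in seed network")

    @property
    def genes(self) -> set[str]:
        return set(self.nodes["gene"])

    @property
    def ccn_genes(self) -> set[str]:
        return set(self.nodes.loc[self.nodes["layer"] == "CCN", "gene"])

    @classmethod
    def from_tsv(cls, nodes_path, edges_path) -> "SeedNetwork":
        nodes = pd.read_csv(nodes_path, sep="\t", comment="#")
        edges = pd.read_csv(edges_path, sep="\t", comment="#")
        return cls(nodes=nodes, edges=edges.fillna({"refs": ""}))


def load_default_seed_network() -> SeedNetwork:
    """The shipped 43-gene seed fixture (14 core-clock + 29 interactors)."""
    data = resources.files("circanet") / "data"
    return SeedNetwork.from_tsv(
        data / "seed_network_nodes.tsv", data / "seed_network_edges.tsv"
    )


@dataclass
class SelectionReport:
    """Summary of a top-K pair selection.

    fraction_pct = 100 * K / (n_seed * n_universe); cutoff_in_sd is the
    implied |rho| cutoff in multiples of the background correlation SD.
    """

    K: int
    n_universe_genes: int
    n_seed_genes: int
    implied_cutoff: float = float("nan")
    background_sd: float = float("nan")
    n_returned: int = 0

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.K / (self.n_seed_genes * self.n_universe_genes)

    @property
    def cutoff_in_sd(self) -> float:
        return self.implied_cutoff / self.background_sd


def select_top_pairs(
    corr: pd.DataFrame,
    seed: SeedNetwork | Iterable[str],
    K: int,
    ranking: str = "absolute",
    exclude_seed_seed: bool = True,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Top-K (seed gene, non-seed gene) pairs by correlation strength.

    ``ranking='absolute'`` ranks by |rho| (the default: the published
    cutoff is an absolute-correlation cutoff); ``'signed'`` ranks by rho.
    Boundary ties are all retained, so slightly more than K pairs may be
    returned (logged).  Returns the pair table (seed, gene, rho) sorted
    by descending strength and a SelectionReport.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if ranking not in ("absolute", "signed"):
        raise ValueError("ranking must be 'absolute' or 'signed'")
    seed_genes = sorted(seed.genes if isinstance(seed, SeedNetwork) else set(seed))
    missing = [g for g in seed_genes if g not in corr.index]
    if missing:
        raise ValueError(f"seed genes absent from correlation matrix: {missing[:5]}")
    all_genes = list(corr.index)
    n_universe = len(all_genes)
    seed_set = set(seed_genes)

    sub = corr.loc[seed_genes]  # seeds x all genes
    long = sub.stack(future_stack=True).rename("rho").reset_index()
    long.columns = ["seed", "gene", "rho"]
    long = long[long["seed"] != long["gene"]]
    if exclude_seed_seed:
        long = long[~long["gene"].isin(seed_set)]
    long = long.dropna(subset=["rho"])
    key = long["rho"].abs() if ranking == "absolute" else long["rho"]
    long = long.assign(_key=key).sort_values(
        ["_key", "seed", "gene"], ascending=[False, True, True], kind="mergesort"
    )

    total = len(long)
    if K >= total:
        logger.warning("K=%d >= %d available pairs: returning all", K, total)
        chosen = long
    else:
        cutoff_key = long["_key"].iloc[K - 1]
        chosen = long[long["_key"] >= cutoff_key]
        if len(chosen) > K:
            logger.info("boundary ties: returning %d pairs for K=%d", len(chosen), K)

    bg_sd = float(long["rho"].std())
    report = SelectionReport(
        K=K,
        n_universe_genes=n_universe,
        n_seed_genes=len(seed_genes),
        implied_cutoff=float(chosen["_key"].min()) if len(chosen) else float("nan"),
        background_sd=bg_sd,
        n_returned=len(chosen),
    )
    return chosen.drop(columns="_key").reset_index(drop=True), report


def compute_tightness(pairs: pd.DataFrame, seed_genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Candidate table (gene, tightness, partners, rhos) from selected pairs.

    Tightness counts *distinct* seed partners; duplicated pairs do not
    inflate it.  Pairs whose non-seed side is itself a seed gene are
    excluded (logged).
    """
    if pairs.empty:
        return pd.DataFrame(columns=["gene", "tightness", "partners", "rhos"])
    df = pairs
    if seed_genes is not None:
        seed_set = set(seed_genes)
        bad = df["gene"].isin(seed_set)
        if bad.any():
            logger.warning("%d pairs with two seed genes excluded", int(bad.sum()))
            df = df[~bad]
    dedup = df.drop_duplicates(["seed", "gene"])
    grouped = dedup.groupby("gene", sort=True)
    out = pd.DataFrame(
        {
            "gene": list(grouped.groups),
            "tightness": grouped["seed"].nunique().to_numpy(),
            "partners": grouped["seed"].agg(list).to_numpy(),
            "rhos": grouped["rho"].agg(list).to_numpy(),
        }
    )
    return out.sort_values(["tightness", "gene"], ascending=[False, True]).reset_index(drop=True)


def filter_tightness(candidates: pd.DataFrame, min_t: int = 2) -> pd.DataFrame:
    """Candidates with tightness >= min_t (min_t >= 1)."""
    if min_t < 1:
        raise ValueError("min_t must be >= 1")
    if candidates.empty:
        return candidates
    return candidates[candidates["tightness"] >= min_t].reset_index(drop=True)


def tightness_sweep(
    candidates: pd.DataFrame,
    enrich: Callable[[set[str]], list[tuple[str, float]]],
    t_range: Iterable[int] = range(1, 11),
    tracked_terms: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Candidate counts and tracked-term q trajectories over tightness cuts.

    ``enrich`` maps a gene set to (term, q) pairs; for each minimum
    tightness t the sweep records the candidate count and, per tracked
    term, its q-value and rank (1 = most significant).  Empty candidate
    sets are recorded with count 0 and missing q values.
    """
    rows = []
    tracked = list(tracked_terms) if tracked_terms is not None else None
    for t in t_range:
        kept = filter_tightness(candidates, t) if not candidates.empty else candidates
        genes = set(kept["gene"]) if not kept.empty else set()
        rec: dict = {"min_tightness": t, "n_candidates": len(genes)}
        if genes:
            results = enrich(genes)
            order = sorted(results, key=lambda tq: tq[1])
            rank = {term: i + 1 for i, (term, _) in enumerate(order)}
            qmap = dict(results)
            terms = tracked if tracked is not None else list(qmap)
            for term in terms:
                rec[f"q:{term}"] = qmap.get(term, np.nan)
                rec[f"rank:{term}"] = rank.get(term, np.nan)
        elif tracked is not None:
            for term in tracked:
                rec[f"q:{term}"] = np.nan
                rec[f"rank:{term}"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
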