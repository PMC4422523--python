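"""Literature-evidence ingestion, partner ranking, capping, homology mapping.

The on-disk dialect mirrors text-mining exports: one row per supporting
sentence with columns gene1, gene2, pmid, sentence, confidence.  Rows are
aggregated into unordered gene pairs carrying their sentence count and
maximum classifier confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_interaction_table",
    "aggregate_interactions",
    "top_partners",
    "cap_sentences",
    "HomologyTable",
    "map_homologs",
    "write_interaction_table",
]

MANDATORY_COLUMNS = ("gene1", "gene2", "pmid", "sentence", "confidence")


def aggregate_interactions(rows: pd.DataFrame) -> pd.DataFrame:
    """Group sentence rows into unordered evidence pairs.

    Returns one row per pair: gene1 < gene2 lexically, n_sentences,
    max_confidence, pmids (list) and sentences (list of (confidence,
    sentence, pmid), confidence-descending).  Self-pairs and rows with
    missing fields are skipped and counted.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"interaction table lacks mandatory columns: {missing}")
    df = rows.copy()
    n0 = len(df)
    df = df.dropna(subset=["gene1", "gene2", "confidence"])
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    df = df.dropna(subset=["confidence"])
    df = df[df["gene1"].astype(str) != df["gene2"].astype(str)]
    skipped = n0 - len(df)
    if skipped:
        logger.warning("skipped %d malformed or self-pair rows", skipped)
    if df.empty:
        return pd.DataFrame(
            columns=["gene1", "gene2", "n_sentences", "max_confidence", "pmids", "sentences"]
        )
    g1 = df[["gene1", "gene2"]].astype(str).min(axis=1)
    g2 = df[["gene1", "gene2"]].astype(str).max(axis=1)
    df = df.assign(gene1=g1, gene2=g2)
    records = []
    for (a, b), grp in df.groupby(["gene1", "gene2"], sort=True):
        sentences = sorted(
            zip(grp["confidence"], grp["sentence"], grp["pmid"].astype(str)),
            key=lambda t: (-t[0], t[1]),
        )
        records.append(
            {
                "gene1": a,
                "gene2": b,
                "n_sentences": len(grp),
                "max_confidence": float(grp["confidence"].max()),
                "pmids": sorted(set(grp["pmid"].astype(str))),
                "sentences": sentences,
            }
        )
    return pd.DataFrame.from_records(records)


def load_interaction_table(path) -> pd.DataFrame:
    """Read a sentence-level evidence TSV and aggregate it into pairs."""
    rows = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str, "pmid": str})
    return aggregate_interactions(rows)


def write_interaction_table(pairs: pd.DataFrame, path) -> None:
    """Write aggregated pairs back to the sentence-level dialect."""
    records = []
    for _, r in pairs.iterrows():
        for conf, sentence, pmid in r["sentences"]:
            records.append(
                {"gene1": r["gene1"], "gene2": r["gene2"], "pmid": pmid,
                 "sentence": sentence, "confidence": conf}
            )
    pd.DataFrame.from_records(records, columns=list(MANDATORY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def top_partners(
    pairs: pd.DataFrame, seed_genes: Iterable[str], n_top: int = 50
) -> tuple[set[str], pd.DataFrame]:
    """Per-seed top partners by evidence support; union of non-seed partners.

    Partners of each seed gene are ranked by sentence count (descending),
    with deterministic tie-breaks on max confidence (descending) then
    lexical gene id.  Returns the union of each seed's top ``n_top``
    non-seed partners and the per-seed partner table with ranks.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    seed_set = set(seed_genes)
    records = []
    for _, r in pairs.iterrows():
        for seed, partner in ((r["gene1"], r["gene2"]), (r["gene2"], r["gene1"])):
            if seed in seed_set:
                records.append(
                    {"seed": seed, "partner": partner,
                     "n_sentences": r["n_sentences"], "max_confidence": r["max_confidence"]}
                )
    if not records:
        return set(), pd.DataFrame(columns=["seed", "partner", "n_sentences", "max_confidence", "rank"])
    table = pd.DataFrame.from_records(records)
    table = table.sort_values(
        ["seed", "n_sentences", "max_confidence", "partner"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    table["rank"] = table.groupby("seed").cumcount() + 1
    kept = table[table["rank"] <= n_top]
    union = set(kept["partner"]) - seed_set
    return union, kept.reset_index(drop=True)


def cap_sentences(pairs: pd.DataFrame, max_sentences: int = 5) -> pd.DataFrame:
    """Keep only the ``max_sentences`` highest-confidence sentences per pair.

    The original sentence count is preserved in ``n_sentences``; the
    retained count is added as ``n_sentences_kept``.
    """
    if max_sentences < 1:
        raise ValueError("max_sentences must be >= 1")
    out = pairs.copy()
    out["sentences"] = out["sentences"].map(lambda s: list(s)[:max_sentences])
    out["n_sentences_kept"] = out["sentences"].map(len)
    return out


@dataclass
class HomologyTable:
    """cluster id -> set of (taxon, gene); each gene in at most one cluster."""

    clusters: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for cid, members in self.clusters.items():
            for m in members:
                if m in seen and seen[m] != cid:
                    raise ValueError(f"gene {m} appears in clusters {seen[m]} and {cid}")
                seen[m] = cid
        self._gene_to_cluster = {gene: cid for (taxon, gene), cid in
                                 (((t, g), c) for c, ms in self.clusters.items() for t, g in ms)}

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        need = {"cluster_id", "taxon_id", "gene_id"}
        if not need <= set(df.columns):
            raise ValueError(f"homology TSV needs columns {sorted(need)}")
        clusters: dict[str, set[tuple[str, str]]] = {}
        for _, r in df.iterrows():
            clusters.setdefault(r["cluster_id"], set()).add((r["taxon_id"], r["gene_id"]))
        return cls(clusters=clusters)

    def cluster_of(self, gene: str) -> str | None:
        return self._gene_to_cluster.get(gene)


def map_homologs(
    genes: Iterable[str], table: HomologyTable, target_taxon: str
) -> tuple[set[str], list[str]]:
    """Map genes to all their target-taxon homologs (deduplicated).

    Genes with no cluster, or whose cluster has no target-taxon member,
    are returned in the unmapped list.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        cid = table.cluster_of(g)
        if cid is None:
            unmapped.append(g)
            continue
        members = {gene for taxon, gene in table.clusters[cid] if taxon == target_taxon}
        if members:
            mapped |= members
        else:
            unmapped.append(g)
    return mapped, unmapped
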