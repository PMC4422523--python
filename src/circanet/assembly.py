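"""Layered network assembly with edge provenance and annotation joins.

The assembled graph has three nested layers — the core-clock network
(CCN), the curated extended network (ECCN, which contains the CCN), and
the consensus-predicted extension layer (NCRG) — with every evidence edge
tagged by provenance: known (curated seed edge), coexpression,
textmining, or both.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .targets import SeedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "intersect_evidence",
    "classify_edges",
    "assemble_ncrg",
    "annotate_nodes",
    "load_consensus_annotations",
    "write_graphml",
    "read_graphml",
    "write_sif",
]

REPORT_COLUMNS = [
    "entrezID", "symbol", "reverba", "reverbb", "reverbab", "rora", "rorg",
    "rorag", "circadian", "high_A", "long_T", "short_T", "bmal1",
    "ml_similar", "disease",
]


def intersect_evidence(coexp_genes: Iterable[str], textmine_genes: Iterable[str]) -> set[str]:
    """Consensus gene set: genes predicted by both evidence streams."""
    a, b = set(coexp_genes), set(textmine_genes)
    consensus = a & b
    logger.info("coexpression=%d, textmining=%d, consensus=%d", len(a), len(b), len(consensus))
    if not consensus:
        logger.warning("empty consensus: NCRG layer will be empty")
    return consensus


def _norm(pairs) -> set[frozenset]:
    return {frozenset(p) for p in pairs if len(set(p)) == 2}


def classify_edges(
    coexp_pairs: Iterable[tuple[str, str]],
    textmine_pairs: Iterable[tuple[str, str]],
    consensus: set[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition evidence edges touching consensus genes by provenance.

    Returns the edge table (gene1, gene2, provenance) and the counts of
    both / coexpression-specific / textmining-specific edges.
    """
    co = {e for e in _norm(coexp_pairs) if e & consensus}
    tm = {e for e in _norm(textmine_pairs) if e & consensus}
    rows = []
    for e in sorted(co | tm, key=sorted):
        if e in co and e in tm:
            prov = "both"
        elif e in co:
            prov = "coexpression"
        else:
            prov = "textmining"
        a, b = sorted(e)
        rows.append({"gene1": a, "gene2": b, "provenance": prov})
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "provenance"])
    counts = {
        "both": int((df["provenance"] == "both").sum()),
        "coexpression": int((df["provenance"] == "coexpression").sum()),
        "textmining": int((df["provenance"] == "textmining").sum()),
    }
    logger.info("evidence edges: %s", counts)
    return df, counts


def assemble_ncrg(
    seed: SeedNetwork,
    consensus: Iterable[str],
    edges: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the layered graph: seed nodes plus the consensus layer.

    Consensus genes already present in the seed are dropped from the
    consensus layer (logged) — the extension layer holds new genes only.
    Curated seed edges carry provenance 'known' and keep their sign and
    direction as attributes; evidence edges are undirected.
    """
    consensus = set(consensus)
    overlap = consensus & seed.genes
    if overlap:
        logger.warning("%d consensus genes already in seed network dropped: %s",
                       len(overlap), sorted(overlap)[:5])
        consensus -= overlap
    g = nx.Graph()
    ccn = seed.ccn_genes
    for gene in seed.genes:
        g.add_node(gene, layer="CCN" if gene in ccn else "ECCN")
    for gene in consensus:
        g.add_node(gene, layer="NCRG")
    for _, r in seed.edges.iterrows():
        g.add_edge(r["gene1"], r["gene2"], provenance="known",
                   sign=r.get("sign", "other"), source=r["gene1"], target=r["gene2"])
    if edges is not None:
        for _, r in edges.iterrows():
            if r["gene1"] not in g or r["gene2"] not in g:
                logger.warning("evidence edge endpoint not in node set: %s-%s",
                               r["gene1"], r["gene2"])
                continue
            if g.has_edge(r["gene1"], r["gene2"]) and \
                    g.edges[r["gene1"], r["gene2"]]["provenance"] == "known":
                continue  # curated knowledge wins over re-derived evidence
            g.add_edge(r["gene1"], r["gene2"], provenance=r["provenance"])
    return g


def load_consensus_annotations() -> pd.DataFrame:
    """The shipped consensus-gene annotation table.

    One row per consensus gene showing at least one property: per-TF
    ChIP-seq target flags (REV-ERBα, REV-ERBβ, REV-ERBα/β, RORα, RORγ,
    RORα/γ, BMAL1), circadian expression, RNAi phenotype class (high
    amplitude / long period / short period), clock-gene ML similarity,
    and disease annotation.
    """
    path = resources.files("circanet") / "data" / "consensus_gene_annotations.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def annotate_nodes(
    network: nx.Graph,
    tf_targets: Mapping[str, Iterable[str]] | None = None,
    rhythm_flags: Mapping[str, bool] | None = None,
    rnai_classes: Mapping[str, str] | None = None,
    disease: Mapping[str, str] | None = None,
    ml_similar: Iterable[str] | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Set per-node annotation flags and emit the consensus report table.

    Inputs are keyed by gene id; ids absent from the network are logged
    and ignored.  The report holds one row per consensus (NCRG-layer)
    gene with at least one flag; RNAi classes are high-A / long-T /
    short-T.
    """
    tf_targets = {tf: set(v) for tf, v in (tf_targets or {}).items()}
    rhythm_flags = dict(rhythm_flags or {})
    rnai_classes = dict(rnai_classes or {})
    disease = dict(disease or {})
    ml = set(ml_similar or ())

    known = set(network.nodes)
    for source in (rhythm_flags, rnai_classes, disease):
        unknown = set(source) - known
        if unknown:
            logger.warning("%d annotation ids not in network ignored", len(unknown))
    valid_rnai = {"high-A", "long-T", "short-T"}
    bad = {g: c for g, c in rnai_classes.items() if c not in valid_rnai}
    if bad:
        raise ValueError(f"unknown RNAi phenotype classes: {bad}")

    for gene in network.nodes:
        attrs = network.nodes[gene]
        attrs["tf_targets"] = ",".join(sorted(tf for tf, s in tf_targets.items() if gene in s))
        attrs["circadian"] = bool(rhythm_flags.get(gene, False))
        attrs["rnai_class"] = rnai_classes.get(gene, "")
        attrs["disease"] = disease.get(gene, "")
        attrs["ml_similar"] = gene in ml

    rows = []
    for gene in sorted(n for n, d in network.nodes(data=True) if d["layer"] == "NCRG"):
        attrs = network.nodes[gene]
        tf_cols = {tf: ("x" if gene in s else "") for tf, s in tf_targets.items()}
        row = {
            "gene": gene,
            **tf_cols,
            "circadian": "x" if attrs["circadian"] else "",
            "high_A": "x" if attrs["rnai_class"] == "high-A" else "",
            "long_T": "x" if attrs["rnai_class"] == "long-T" else "",
            "short_T": "x" if attrs["rnai_class"] == "short-T" else "",
            "ml_similar": "x" if attrs["ml_similar"] else "",
            "disease": attrs["disease"],
        }
        if any(v for k, v in row.items() if k != "gene"):
            rows.append(row)
    report = pd.DataFrame(rows)
    return network, report


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(network: nx.Graph, path) -> None:
    """Simple interaction format: gene1 <provenance> gene2 (one edge per line)."""
    with open(path, "w") as fh:
        for a, b, d in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{d.get('provenance', 'interaction')}\t{b}\n")
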