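"""Top-pair selection, tightness computation, filtering and the sweep."""

import numpy as np
import pandas as pd
import pytest

from circanet.enrichment import overrepresentation
from circanet.targets import (
    SeedNetwork,
    SelectionReport,
    compute_tightness,
    filter_tightness,
    load_default_seed_network,
    select_top_pairs,
    tightness_sweep,
)


def _toy_corr():
    """3 seeds x 5 candidates with fixed correlations."""
    seeds = ["E1", "E2", "E3"]
    cands = ["g1", "g2", "g3", "g4", "g5"]
    genes = seeds + cands
    rng = np.random.default_rng(0)
    c = rng.uniform(-0.05, 0.05, (8, 8))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    corr = pd.DataFrame(c, index=genes, columns=genes)
    stated = {("E1", "g1"): 0.9, ("E2", "g1"): -0.85, ("E1", "g2"): 0.7,
              ("E3", "g3"): 0.6, ("E2", "g4"): 0.5, ("E1", "g5"): 0.1}
    for (a, b), v in stated.items():
        corr.loc[a, b] = corr.loc[b, a] = v
    return corr, seeds, stated


def test_select_top_pairs_matches_sort_oracle():
    corr, seeds, stated = _toy_corr()
    pairs, report = select_top_pairs(corr, seeds, K=4)
    got = {(r["seed"], r["gene"]) for _, r in pairs.iterrows()}
    oracle = sorted(stated.items(), key=lambda kv: -abs(kv[1]))[:4]
    assert got == {k for k, _ in oracle}
    assert report.implied_cutoff == pytest.approx(0.6)


def test_select_top_pairs_signed_mode_drops_anticorrelated():
    corr, seeds, _ = _toy_corr()
    pairs, _ = select_top_pairs(corr, seeds, K=4, ranking="signed")
    got = {(r["seed"], r["gene"]) for _, r in pairs.iterrows()}
    assert ("E2", "g1") not in got  # rho = -0.85 ranks low under signed mode
    assert ("E1", "g1") in got


def test_select_top_pairs_k_exceeding_total_returns_all():
    corr, seeds, _ = _toy_corr()
    pairs, report = select_top_pairs(corr, seeds, K=10_000)
    assert len(pairs) == 3 * 5
    assert report.implied_cutoff == pytest.approx(pairs["rho"].abs().min())


def test_select_top_pairs_boundary_ties_all_kept():
    genes = ["S", "a", "b", "c"]
    c = np.full((4, 4), 0.0)
    np.fill_diagonal(c, 1.0)
    corr = pd.DataFrame(c, index=genes, columns=genes)
    corr.loc["S", ["a", "b", "c"]] = [0.5, 0.5, 0.2]
    corr.loc[["a", "b", "c"], "S"] = [0.5, 0.5, 0.2]
    pairs, report = select_top_pairs(corr, ["S"], K=1)
    assert len(pairs) == 2  # tie at the boundary retained
    assert report.n_returned == 2


def test_select_top_pairs_gene_order_invariance(rng):
    corr, seeds, _ = _toy_corr()
    perm = rng.permutation(len(corr))
    shuffled = corr.iloc[perm, perm]
    p1, _ = select_top_pairs(corr, seeds, K=4)
    p2, _ = select_top_pairs(shuffled, seeds, K=4)
    key = lambda df: sorted(map(tuple, df[["seed", "gene"]].to_numpy()))
    assert key(p1) == key(p2)


def test_selection_report_fraction_self_consistent():
    r = SelectionReport(K=10_000, n_universe_genes=19_788, n_seed_genes=43)
    assert r.fraction_pct == pytest.approx(100 * r.K / (r.n_seed_genes * r.n_universe_genes))
    assert round(r.fraction_pct, 2) == 1.18


def _pairs(*items):
    return pd.DataFrame([{"seed": s, "gene": g, "rho": r} for s, g, r in items])


def test_compute_tightness_counts_distinct_partners():
    pairs = _pairs(("E1", "g", 0.5), ("E2", "g", 0.4), ("E1", "h", 0.3))
    out = compute_tightness(pairs).set_index("gene")
    assert out.loc["g", "tightness"] == 2
    assert out.loc["h", "tightness"] == 1


def test_compute_tightness_ignores_duplicates_and_seed_pairs():
    pairs = _pairs(("E1", "g", 0.5), ("E1", "g", 0.5), ("E1", "E2", 0.9))
    out = compute_tightness(pairs, seed_genes={"E1", "E2"}).set_index("gene")
    assert out.loc["g", "tightness"] == 1
    assert "E2" not in out.index


def test_compute_tightness_empty_and_sum_invariant(rng):
    assert compute_tightness(pd.DataFrame(columns=["seed", "gene", "rho"])).empty
    items = [(f"E{rng.integers(3)}", f"g{rng.integers(10)}", 0.5) for _ in range(60)]
    pairs = _pairs(*items)
    out = compute_tightness(pairs)
    n_distinct = len({(s, g) for s, g, _ in items})
    assert out["tightness"].sum() == n_distinct


def test_filter_tightness_nesting():
    pairs = _pairs(*[(f"E{i}", f"g{j}", 0.5) for j in range(6) for i in range(j + 1)])
    cands = compute_tightness(pairs)
    assert set(filter_tightness(cands, 1)["gene"]) == set(cands["gene"])
    prev = set(filter_tightness(cands, 1)["gene"])
    for t in range(2, 8):
        cur = set(filter_tightness(cands, t)["gene"])
        assert cur <= prev
        prev = cur
    with pytest.raises(ValueError):
        filter_tightness(cands, 0)


def test_tightness_sweep_counts_and_q_trajectories():
    pairs = _pairs(*[(f"E{i}", f"g{j}", 0.5) for j in range(8) for i in range(min(j + 1, 4))])
    cands = compute_tightness(pairs)
    universe = [f"g{j}" for j in range(8)] + [f"u{j}" for j in range(20)]
    catalog = {"ns": {"T1": ("term1", frozenset(universe[:6])),
                      "T2": ("term2", frozenset(universe[10:24]))}}

    def enrich(genes):
        df = overrepresentation(genes, catalog, "ns", universe=universe)
        return list(zip(df["term_id"], df["q"]))

    sweep = tightness_sweep(cands, enrich, t_range=range(1, 6), tracked_terms=["T1", "T2"])
    counts = sweep["n_candidates"].tolist()
    assert counts == sorted(counts, reverse=True)
    # trajectory equals direct per-threshold enrichment calls (recomputation oracle)
    for _, row in sweep.iterrows():
        kept = set(filter_tightness(cands, int(row["min_tightness"]))["gene"])
        if kept:
            direct = dict(enrich(kept))
            assert row["q:T1"] == pytest.approx(direct["T1"])


def test_default_seed_network_fixture_shape():
    net = load_default_seed_network()
    assert len(net.genes) == 43
    assert len(net.ccn_genes) == 14
    assert net.ccn_genes <= net.genes
    assert set(net.edges["sign"]) <= {"activation", "inhibition", "other"}


def test_seed_network_rejects_unknown_layer():
    nodes = pd.DataFrame({"gene": ["a"], "layer": ["XXX"]})
    with pytest.raises(ValueError):
        SeedNetwork(nodes=nodes, edges=pd.DataFrame(columns=["gene1", "gene2", "sign", "refs"]))
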