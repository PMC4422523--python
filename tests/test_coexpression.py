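"""Correlation, mutual rank, Fisher transform and distribution tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from circanet.coexpression import (
    compare_foreground_background,
    fisher_z,
    mutual_rank,
    pearson_matrix,
)
from circanet.synthetic import ExpressionCompendium


def _comp(rows: dict) -> ExpressionCompendium:
    return ExpressionCompendium(data=pd.DataFrame(rows).T.astype(float))


def brute_force_mutual_rank(corr: np.ndarray) -> np.ndarray:
    """Independent MR oracle: explicit rank enumeration per gene."""
    n = corr.shape[0]
    ranks = np.full((n, n), np.nan)
    for a in range(n):
        partners = [b for b in range(n) if b != a]
        vals = [corr[a, b] for b in partners]
        order = sorted(vals, reverse=True)
        for b, v in zip(partners, vals):
            positions = [i + 1 for i, x in enumerate(order) if x == v]
            ranks[a, b] = sum(positions) / len(positions)  # average ties
    mr = np.sqrt(ranks * ranks.T)
    return mr


@pytest.mark.parametrize(
    "x,y,expected",
    [((1, 2, 3), (2, 4, 6), 1.0), ((1, 2, 3), (3, 2, 1), -1.0), ((1, 2, 3, 4), (1, 3, 2, 4), 0.8)],
)
def test_pearson_known_values(x, y, expected):
    corr = pearson_matrix(_comp({"x": x, "y": y}))
    assert corr.loc["x", "y"] == pytest.approx(expected)
    assert corr.loc["x", "x"] == 1.0


def test_pearson_zero_variance_gene_yields_missing():
    corr = pearson_matrix(_comp({"x": (1, 2, 3), "flat": (5, 5, 5)}))
    assert np.isnan(corr.loc["x", "flat"])
    assert corr.loc["x", "x"] == 1.0


def test_pearson_sample_order_invariance(small_universe, rng):
    comp, _ = small_universe
    sub = ExpressionCompendium(data=comp.data.iloc[:30])
    perm = rng.permutation(sub.data.shape[1])
    shuffled = ExpressionCompendium(data=sub.data.iloc[:, perm])
    pd.testing.assert_frame_equal(pearson_matrix(sub), pearson_matrix(shuffled))


def test_mutual_rank_toy_matrix():
    genes = ["g1", "g2", "g3", "g4"]
    c = np.ones((4, 4))
    vals = {(0, 1): 0.9, (0, 2): 0.5, (0, 3): 0.1, (1, 2): 0.8, (1, 3): 0.2, (2, 3): 0.7}
    for (i, j), v in vals.items():
        c[i, j] = c[j, i] = v
    corr = pd.DataFrame(c, index=genes, columns=genes)
    mr = mutual_rank(corr)
    assert mr.loc["g3", "g4"] == pytest.approx(np.sqrt(2.0))
    assert mr.loc["g1", "g2"] == pytest.approx(1.0)


def test_mutual_rank_one_iff_reciprocal_top():
    genes = ["a", "b", "c"]
    c = pd.DataFrame([[1, 0.9, 0.1], [0.9, 1, 0.2], [0.1, 0.2, 1]], index=genes, columns=genes)
    mr = mutual_rank(c)
    assert mr.loc["a", "b"] == 1.0
    assert mr.loc["a", "c"] > 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(n=st.integers(3, 20), seed=st.integers(0, 10_000))
def test_mutual_rank_matches_brute_force(n, seed):
    rng = np.random.default_rng(seed)
    c = rng.uniform(-1, 1, (n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    genes = [f"g{i}" for i in range(n)]
    got = mutual_rank(pd.DataFrame(c, index=genes, columns=genes)).to_numpy()
    expected = brute_force_mutual_rank(c)
    mask = ~np.eye(n, dtype=bool)
    np.testing.assert_allclose(got[mask], expected[mask], rtol=1e-10)
    assert np.all(got[mask] >= 1.0 - 1e-12)
    np.testing.assert_allclose(got, got.T, rtol=1e-12)


def test_mutual_rank_invariant_under_monotone_row_transforms(rng):
    n = 12
    c = rng.uniform(-1, 1, (n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    genes = [f"g{i}" for i in range(n)]
    base = mutual_rank(pd.DataFrame(c, index=genes, columns=genes))
    warped = mutual_rank(pd.DataFrame(np.tanh(2.5 * c), index=genes, columns=genes))
    pd.testing.assert_frame_equal(base, warped)


def test_fisher_z_values_and_symmetry():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0))
    assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3))
    with pytest.raises(ValueError):
        fisher_z(1.0)


def _null_universe(seed, n_genes=40, n_samples=60):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                        index=[f"g{i}" for i in range(n_genes)])
    return pearson_matrix(ExpressionCompendium(data=data))


def test_compare_null_pvalues_uniform():
    """fg and bg from one null generator -> p uniform over replicates."""
    pvals = []
    for seed in range(150):
        corr = _null_universe(seed)
        genes = list(corr.index)
        fg = [(genes[i], genes[i + 1]) for i in range(0, 20, 2)]
        bg = [(genes[i], genes[i + 2]) for i in range(20, 38)]
        pvals.append(compare_foreground_background(fg, bg, corr).p_t)
    assert stats.kstest(pvals, "uniform").statistic < 0.12


def test_compare_detects_shifted_foreground():
    """fg shifted by +0.3 in rho at n=50/500 -> p < 0.01 in >= 95% of replicates."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 60
    for _ in range(reps):
        fg_rho = np.clip(rng.normal(0.3, 0.1, 50), -0.99, 0.99)
        bg_rho = np.clip(rng.normal(0.0, 0.1, 500), -0.99, 0.99)
        n = 50 + 500
        genes = [f"g{i}" for i in range(2 * n)]
        corr = pd.DataFrame(np.eye(2 * n), index=genes, columns=genes)
        pairs_fg, pairs_bg = [], []
        for i, r in enumerate(fg_rho):
            a, b = genes[2 * i], genes[2 * i + 1]
            corr.loc[a, b] = corr.loc[b, a] = r
            pairs_fg.append((a, b))
        for i, r in enumerate(bg_rho, start=50):
            a, b = genes[2 * i], genes[2 * i + 1]
            corr.loc[a, b] = corr.loc[b, a] = r
            pairs_bg.append((a, b))
        if compare_foreground_background(pairs_fg, pairs_bg, corr).p_t < 0.01:
            hits += 1
    assert hits / reps >= 0.95


def test_compare_planted_pairs_separate_from_background(small_universe):
    """Planted-edge pairs have larger rho and smaller MR than random pairs."""
    comp, truth = small_universe
    corr = pearson_matrix(comp)
    mr = mutual_rank(corr)
    fg = sorted(truth.true_edges)
    bg_genes = sorted(truth.all_genes - truth.seed_genes - truth.true_targets)[:80]
    seeds = sorted(truth.seed_genes)
    bg = [(seeds[i % len(seeds)], g) for i, g in enumerate(bg_genes)]
    res = compare_foreground_background(fg, bg, corr, mr)
    assert res.p_t < 1e-6
    assert res.p_wilcoxon_mr < 1e-6


def test_compare_rejects_overlapping_or_empty_sets(small_universe):
    comp, truth = small_universe
    corr = pearson_matrix(comp)
    fg = sorted(truth.true_edges)[:5]
    with pytest.raises(ValueError):
        compare_foreground_background(fg, fg[:2], corr)
    with pytest.raises(ValueError):
        compare_foreground_background([], fg, corr)


def test_pair_table_round_trip(tmp_path, small_universe):
    from circanet.coexpression import read_pair_table, write_pair_table

    comp, _ = small_universe
    sub = ExpressionCompendium(data=comp.data.iloc[:12])
    corr = pearson_matrix(sub)
    mr = mutual_rank(corr)
    write_pair_table(corr, mr, tmp_path / "pairs.tsv")
    corr2, mr2 = read_pair_table(tmp_path / "pairs.tsv")
    genes = list(corr.index)
    np.testing.assert_allclose(
        corr2.loc[genes, genes].to_numpy(), corr.to_numpy(), atol=1e-9)
    off = ~np.eye(len(genes), dtype=bool)
    np.testing.assert_allclose(
        mr2.loc[genes, genes].to_numpy()[off], mr.to_numpy()[off], atol=1e-9)
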