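"""Generator behaviour: determinism, planted structure, closed-form checks."""

import io

import numpy as np
import pandas as pd
import pytest

from circanet.config import ClockGene, SyntheticConfig
from circanet import synthetic as syn
from circanet.chipseq import call_targets, closest_gene_scores
from circanet.enrichment import overrepresentation, read_gmt, write_gmt
from circanet.evidence import aggregate_interactions


def _two_gene_config(n, noise_sd, dphi, seed=3):
    return SyntheticConfig(
        n_samples=n,
        n_background_genes=0,
        clock_genes=(ClockGene("A", 1.0, 0.0), ClockGene("B", 1.0, dphi)),
        planted_edges=(),
        noise_sd=noise_sd,
        rng_seed=seed,
    )


def test_fixed_seed_gives_identical_outputs(small_config, tmp_path):
    comp1, truth1 = syn.generate_compendium(small_config)
    comp2, truth2 = syn.generate_compendium(small_config)
    pd.testing.assert_frame_equal(comp1.data, comp2.data)
    assert truth1.true_edges == truth2.true_edges
    for i in (1, 2):
        syn.write_expression_tsv(comp1, tmp_path / f"e{i}.tsv")
        syn.generate_literature_table(truth1, small_config).to_csv(
            tmp_path / f"l{i}.tsv", sep="\t", index=False)
    assert (tmp_path / "e1.tsv").read_bytes() == (tmp_path / "e2.tsv").read_bytes()
    assert (tmp_path / "l1.tsv").read_bytes() == (tmp_path / "l2.tsv").read_bytes()


@pytest.mark.parametrize(
    "noise_sd,dphi,expected,tol",
    [
        (0.0, 0.0, 1.0, 1e-9),          # noiseless identical phase
        (0.5, 12.0, -2.0 / 3.0, 0.05),  # cos(pi)/(1+2*0.25) = -0.6667
    ],
)
def test_clock_pair_correlation_matches_closed_form(noise_sd, dphi, expected, tol):
    comp, _ = syn.generate_compendium(_two_gene_config(2000, noise_sd, dphi))
    rho = np.corrcoef(comp.data.loc["A"], comp.data.loc["B"])[0, 1]
    assert rho == pytest.approx(expected, abs=tol)


def test_clock_correlation_attenuation_monte_carlo_oracle(rng):
    # independent simulation of the same generative model cross-checks the
    # closed form cos(2*pi*dphi/24) / (1 + 2*sigma^2/a^2)
    n, sd, dphi = 200_000 // 40, 0.5, 12.0
    theta = rng.uniform(0, 24, 20_000)
    a = np.cos(2 * np.pi * theta / 24) + rng.normal(0, sd, theta.size)
    b = np.cos(2 * np.pi * (theta - dphi) / 24) + rng.normal(0, sd, theta.size)
    assert np.corrcoef(a, b)[0, 1] == pytest.approx(-2.0 / 3.0, abs=0.02)


def test_default_phases_give_per_bmal_anticorrelation():
    comp, _ = syn.generate_compendium(SyntheticConfig(n_samples=500, n_background_genes=0,
                                                      planted_edges=(), rng_seed=5))
    rho = np.corrcoef(comp.data.loc["ARNTL"], comp.data.loc["PER3"])[0, 1]
    assert rho < 0
    rho_pc = np.corrcoef(comp.data.loc["PER2"], comp.data.loc["CRY2"])[0, 1]
    assert rho_pc > 0


def test_planted_target_correlates_with_its_seeds(small_universe):
    comp, truth = small_universe
    seed, target = sorted(truth.true_edges)[0]
    rho = np.corrcoef(comp.data.loc[seed], comp.data.loc[target])[0, 1]
    assert abs(rho) > 0.3


def test_compendium_validation_errors():
    with pytest.raises(ValueError, match="n_samples"):
        syn.generate_compendium(SyntheticConfig(n_samples=2))
    dup = (ClockGene("A", 1, 0), ClockGene("A", 1, 1))
    with pytest.raises(ValueError, match="duplicate"):
        syn.generate_compendium(SyntheticConfig(clock_genes=dup, planted_edges=()))


def test_literature_zero_fp_emits_only_true_edges(small_universe, small_config):
    _, truth = small_universe
    cfg = SyntheticConfig(**{**small_config.__dict__, "literature_fp_rate": 0.0})
    table = syn.generate_literature_table(truth, cfg)
    true_sets = {frozenset(e) for e in truth.true_edges}
    emitted = {frozenset((a, b)) for a, b in zip(table["gene1"], table["gene2"])}
    assert emitted <= true_sets


def test_literature_fp_fraction_within_binomial_ci(small_universe, small_config):
    _, truth = small_universe
    # pool pairs over replicates so the binomial CI is tight
    true_sets = {frozenset(e) for e in truth.true_edges}
    n_fp = n_pairs = 0
    for seed in range(10):
        cfg = SyntheticConfig(**{**small_config.__dict__, "rng_seed": seed})
        table = syn.generate_literature_table(truth, cfg)
        pairs = {frozenset((a, b)) for a, b in zip(table["gene1"], table["gene2"])}
        n_pairs += len(pairs)
        n_fp += len(pairs - true_sets)
    frac = n_fp / n_pairs
    half_width = 3 * np.sqrt(0.1 * 0.9 / n_pairs)
    assert abs(frac - 0.10) < half_width + 0.02


def test_literature_round_trips_through_aggregation(small_universe, small_config):
    _, truth = small_universe
    table = syn.generate_literature_table(truth, small_config)
    pairs = aggregate_interactions(table)
    emitted = {frozenset((a, b)) for a, b in zip(table["gene1"], table["gene2"])}
    aggregated = {frozenset((a, b)) for a, b in zip(pairs["gene1"], pairs["gene2"])}
    assert emitted == aggregated
    assert pairs["n_sentences"].sum() == len(table)


def test_peaks_without_background_recover_all_targets(small_universe, small_config):
    _, truth = small_universe
    gm = syn.generate_gene_models(truth)
    peak_sets = syn.generate_peaks(truth, gm, small_config, n_background_peaks=0)
    for tf, peaks in peak_sets.items():
        table = closest_gene_scores(peaks, gm, tf=tf)
        assert call_targets(table, 3.0) >= truth.true_tf_targets[tf]


def test_peak_weight_halving_halves_gene_scores(small_universe, small_config):
    _, truth = small_universe
    gm = syn.generate_gene_models(truth)
    peaks = next(iter(syn.generate_peaks(truth, gm, small_config).values()))
    s1 = closest_gene_scores(peaks, gm).scores
    halved = peaks.assign(weight=peaks["weight"] / 2)
    s2 = closest_gene_scores(halved, gm).scores
    np.testing.assert_allclose(s2.to_numpy(), s1.to_numpy() / 2, rtol=1e-12)


def test_gene_score_distribution_is_bimodal_on_log2_scale(small_universe, small_config):
    from circanet.chipseq import threshold_suggest

    _, truth = small_universe
    gm = syn.generate_gene_models(truth)
    peaks = next(iter(syn.generate_peaks(truth, gm, small_config,
                                         n_background_peaks=150).values()))
    table = closest_gene_scores(peaks, gm)
    suggestion, diag = threshold_suggest(table, min_scores=30)
    assert suggestion is not None and not diag["fallback"]
    lo, hi = diag["component_means"]
    assert lo < suggestion < hi


def test_timeseries_warns_when_underpowered(small_universe, small_config):
    _, truth = small_universe
    cfg = SyntheticConfig(**{**small_config.__dict__, "timepoints": (0.0, 4, 8, 12, 16, 20)})
    with pytest.warns(UserWarning, match="fewer than 8 timepoints"):
        syn.generate_timeseries(truth, cfg)


def test_annotations_round_trip_and_planted_enrichment(small_universe, small_config, tmp_path):
    _, truth = small_universe
    catalog = syn.generate_annotations(truth, small_config)
    ns = "biological_process"
    write_gmt(catalog[ns], tmp_path / "t.gmt")
    back = read_gmt(tmp_path / "t.gmt", ns)
    assert {t: g for t, (_, g) in back[ns].items()} == {
        t: g for t, (_, g) in catalog[ns].items()}
    result = overrepresentation(truth.true_targets, catalog, ns)
    planted = result.set_index("term_id").loc[f"{ns.upper()}:PLANTED"]
    assert planted["q"] < 0.01
    # a term disjoint from the query has p = P(X >= 0) = 1
    disjoint_universe = sorted(truth.all_genes - truth.true_targets)[:30]
    cat2 = {ns: {"T:DISJOINT": ("disjoint", frozenset(disjoint_universe[:10])),
                 "T:OTHER": ("other", frozenset(disjoint_universe[10:]))}}
    res2 = overrepresentation(set(disjoint_universe[10:]), cat2, ns)
    assert res2.set_index("term_id").loc["T:DISJOINT", "p"] == pytest.approx(1.0)


def test_truth_json_round_trip(small_universe, tmp_path):
    _, truth = small_universe
    truth.to_json(tmp_path / "truth.json")
    back = syn.SyntheticTruth.from_json(tmp_path / "truth.json")
    assert back.true_edges == truth.true_edges
    assert back.true_tf_targets == truth.true_tf_targets
    assert back.true_rhythmic == truth.true_rhythmic


def test_expression_tsv_round_trip(small_universe, tmp_path):
    comp, _ = small_universe
    syn.write_expression_tsv(comp, tmp_path / "x.tsv")
    back = syn.read_expression_tsv(tmp_path / "x.tsv")
    np.testing.assert_allclose(back.data.to_numpy(), comp.data.to_numpy(), rtol=0, atol=1e-9)
    assert back.genes == comp.genes
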