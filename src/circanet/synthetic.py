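"""Synthetic-data generators with known planted truth.

Every pipeline input can be produced here: an unsynchronized expression
compendium with a phase-structured clock module and planted seed→target
edges, a literature-evidence table with a controlled false-positive rate,
ChIP-seq peak sets enriched near planted target TSSs, gene models, cosine
time courses, and GMT annotation catalogs with planted enriched terms.

The compendium model: each sample *s* draws a latent circadian phase
theta_s ~ U[0, 24) (samples are unsynchronized experiments, which is what
attenuates clock-pair correlations well below |cos(dphi)|).  A clock gene
g with amplitude a_g and phase phi_g takes the value

    a_g * cos(2*pi*(theta_s - phi_g)/24) + N(0, noise_sd^2).

For two clock genes with amplitude a and phase difference dphi the
expected Pearson correlation is cos(2*pi*dphi/24) / (1 + 2*noise_sd^2/a^2).
A planted target is sqrt(e) * (standardized mean of its seeds' values)
plus sqrt(1-e) * N(0,1); background genes are independent N(0,1) noise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SyntheticConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCompendium",
    "SyntheticTruth",
    "generate_compendium",
    "generate_literature_table",
    "generate_gene_models",
    "generate_peaks",
    "generate_timeseries",
    "generate_annotations",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gene_models_bed",
    "write_narrowpeak",
]

_SALT_COMPENDIUM = 1
_SALT_LITERATURE = 2
_SALT_PEAKS = 3
_SALT_TIMESERIES = 4
_SALT_ANNOTATIONS = 5


@dataclass
class ExpressionCompendium:
    """Genes x samples numeric matrix with a dataset label."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in compendium")
        if self.data.shape[1] < 3:
            raise ValueError("compendium needs >= 3 samples")
        if self.data.isna().all(axis=1).any():
            raise ValueError("all-missing gene row in compendium")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic universe."""

    true_edges: set[tuple[str, str]] = field(default_factory=set)  # (seed, target)
    true_rhythmic: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_tf_targets: dict[str, set[str]] = field(default_factory=dict)
    true_term_memberships: dict[str, set[str]] = field(default_factory=dict)
    seed_genes: set[str] = field(default_factory=set)
    all_genes: set[str] = field(default_factory=set)

    @property
    def true_targets(self) -> set[str]:
        return {t for _, t in self.true_edges}

    def check(self) -> None:
        referenced = (
            {g for e in self.true_edges for g in e}
            | set(self.true_rhythmic)
            | {g for s in self.true_tf_targets.values() for g in s}
            | {g for s in self.true_term_memberships.values() for g in s}
        )
        missing = referenced - self.all_genes
        if missing:
            raise ValueError(f"truth references unknown genes: {sorted(missing)[:5]}")

    def to_json(self, path) -> None:
        payload = {
            "true_edges": sorted(map(list, self.true_edges)),
            "true_rhythmic": {g: list(v) for g, v in sorted(self.true_rhythmic.items())},
            "true_tf_targets": {tf: sorted(s) for tf, s in sorted(self.true_tf_targets.items())},
            "true_term_memberships": {t: sorted(s) for t, s in sorted(self.true_term_memberships.items())},
            "seed_genes": sorted(self.seed_genes),
            "all_genes": sorted(self.all_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_edges={tuple(e) for e in d["true_edges"]},
            true_rhythmic={g: tuple(v) for g, v in d["true_rhythmic"].items()},
            true_tf_targets={tf: set(s) for tf, s in d["true_tf_targets"].items()},
            true_term_memberships={t: set(s) for t, s in d["true_term_memberships"].items()},
            seed_genes=set(d["seed_genes"]),
            all_genes=set(d["all_genes"]),
        )


def generate_compendium(config: SyntheticConfig) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Simulate the expression compendium and its planted truth."""
    config.validate()
    rng = config.rng(_SALT_COMPENDIUM)
    n = config.n_samples

    theta = rng.uniform(0.0, 24.0, size=n)
    rows: dict[str, np.ndarray] = {}
    for g in config.clock_genes:
        signal = g.amplitude * np.cos(2.0 * np.pi * (theta - g.phase) / 24.0)
        rows[g.gene] = signal + rng.normal(0.0, config.noise_sd, size=n)

    # planted targets: noisy linear mix of their (observed) seed values
    by_target: dict[str, list[tuple[str, float]]] = {}
    for seed, target, eff in config.planted_edges:
        by_target.setdefault(target, []).append((seed, eff))
    for target, parents in by_target.items():
        mix = np.zeros(n)
        for seed, _ in parents:
            v = rows[seed]
            mix += (v - v.mean()) / v.std()
        mix /= max(mix.std(), 1e-12)
        eff = float(np.mean([e for _, e in parents]))
        rows[target] = np.sqrt(eff) * mix + np.sqrt(1.0 - eff) * rng.normal(0.0, 1.0, size=n)

    for i in range(config.n_background_genes):
        rows[f"BG{i + 1:05d}"] = rng.normal(0.0, 1.0, size=n)

    data = pd.DataFrame(rows).T
    data.columns = [f"S{j + 1:04d}" for j in range(n)]
    comp = ExpressionCompendium(data=data, label="synthetic")

    truth = SyntheticTruth(
        true_edges={(s, t) for s, t, _ in config.planted_edges},
        seed_genes={g.gene for g in config.clock_genes},
        all_genes=set(data.index),
    )
    # rhythmic truth: clock genes plus a fraction of the planted targets
    for g in config.clock_genes:
        truth.true_rhythmic[g.gene] = (24.0, g.phase)
    targets = sorted(by_target)
    n_rhythmic = int(round(config.rhythmic_fraction * len(targets)))
    rng_phase = config.rng(_SALT_TIMESERIES)
    for t in targets[:n_rhythmic]:
        truth.true_rhythmic[t] = (24.0, float(np.round(rng_phase.uniform(0, 24) * 2) / 2))
    # per-TF target sets: disjoint-ish slices of the planted targets
    tfs = ["NR1D1", "NR1D2", "RORC", "ARNTL"]
    tfs = [tf for tf in tfs if tf in truth.seed_genes] or sorted(truth.seed_genes)[:4]
    for i, tf in enumerate(tfs):
        truth.true_tf_targets[tf] = set(targets[i::2][: max(1, len(targets) // 2)])
    truth.check()
    return comp, truth


def generate_literature_table(
    truth: SyntheticTruth, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Emit a GeneView-style evidence table (one row per sentence).

    True planted edges are always emitted; their sentence counts follow a
    shifted geometric distribution (heavy-tailed: the mean sits well above
    the median, as in real text-mining support counts).  A fraction
    ``literature_fp_rate`` of the emitted *pairs* are random non-edges.
    """
    if not truth.true_edges:
        raise ValueError("truth has no edges")
    fp = config.literature_fp_rate
    if not (0.0 <= fp <= 1.0):
        raise ValueError("fp_rate must be in [0, 1]")
    rng = rng if rng is not None else config.rng(_SALT_LITERATURE)

    pairs: list[tuple[str, str, bool]] = [(s, t, True) for s, t in sorted(truth.true_edges)]
    n_true = len(pairs)
    n_fp = int(rng.binomial(n_true, fp / (1.0 - fp))) if fp < 1.0 else 0
    genes = sorted(truth.all_genes)
    true_set = {frozenset(e) for e in truth.true_edges}
    added = 0
    while added < n_fp:
        a, b = rng.choice(genes, size=2, replace=False)
        if frozenset((a, b)) in true_set:
            continue
        pairs.append((str(a), str(b), False))
        added += 1

    records = []
    for g1, g2, is_true in pairs:
        # shifted geometric: 1 + Geom(p); p chosen so true-edge support is
        # heavy-tailed with mean ~10; false pairs get thin support
        p = 0.1 if is_true else 0.6
        n_sent = 1 + int(rng.geometric(p)) - 1 + (1 if is_true else 0)
        n_sent = max(1, n_sent)
        for k in range(n_sent):
            conf = rng.uniform(0.5, 1.0) if is_true else rng.uniform(0.3, 0.9)
            records.append(
                {
                    "gene1": g1,
                    "gene2": g2,
                    "pmid": f"PM{rng.integers(10_000_000, 30_000_000)}",
                    "sentence": f"{g1} interacts with {g2} (statement {k + 1}).",
                    "confidence": round(float(conf), 4),
                }
            )
    return pd.DataFrame.from_records(records, columns=["gene1", "gene2", "pmid", "sentence", "confidence"])


def generate_gene_models(
    truth: SyntheticTruth, spacing: int = 10_000, n_chroms: int = 4
) -> pd.DataFrame:
    """Deterministic gene models (gene, chrom, tss, strand) for the universe.

    Genes are laid out on ``n_chroms`` chromosomes with TSSs ``spacing``
    bp apart, alternating strand.
    """
    genes = sorted(truth.all_genes)
    records = []
    per_chrom = -(-len(genes) // n_chroms)
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        pos = (i % per_chrom + 1) * spacing
        strand = "+" if i % 2 == 0 else "-"
        records.append({"gene": g, "chrom": chrom, "tss": pos, "strand": strand})
    df = pd.DataFrame.from_records(records)
    if df.duplicated(["chrom", "tss"]).any():
        raise ValueError("overlapping identical gene TSS coordinates")
    return df


def generate_peaks(
    truth: SyntheticTruth,
    gene_models: pd.DataFrame,
    config: SyntheticConfig,
    tf: str | None = None,
    n_background_peaks: int = 300,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-TF peak sets (chrom, start, end, weight) with planted targets.

    Each true target of a TF receives 1–3 peaks whose midpoints are nearer
    its own TSS than any other TSS, with weights drawn so the summed gene
    score clears the default log2 threshold of 3.  Background peaks are
    placed uniformly along the chromosomes with low weights, producing a
    bimodal log2 gene-score distribution.
    """
    rng = rng if rng is not None else config.rng(_SALT_PEAKS)
    gm = gene_models.set_index("gene")
    missing = {g for s in truth.true_tf_targets.values() for g in s} - set(gm.index)
    if missing:
        raise ValueError(f"true TF targets without gene models: {sorted(missing)[:5]}")
    spacing = int(np.median(np.diff(np.sort(gene_models["tss"].unique())))) or 10_000
    tfs = [tf] if tf is not None else sorted(truth.true_tf_targets)
    out: dict[str, pd.DataFrame] = {}
    chrom_span = gene_models.groupby("chrom")["tss"].max()
    for tf_name in tfs:
        records = []
        for target in sorted(truth.true_tf_targets.get(tf_name, ())):
            row = gm.loc[target]
            n_peaks = int(rng.integers(1, 4))
            # total weight >= 2**3.5 so log2(sum) clears threshold 3
            total = float(2.0 ** rng.uniform(3.5, 6.0))
            parts = rng.dirichlet(np.ones(n_peaks)) * total
            for w in parts:
                offset = int(rng.integers(-spacing // 4, spacing // 4))
                mid = int(row["tss"]) + offset
                half = int(rng.integers(50, 200))
                records.append(
                    {"chrom": row["chrom"], "start": max(0, mid - half), "end": mid + half,
                     "weight": round(float(max(w, 0.01)), 4)}
                )
        for _ in range(n_background_peaks):
            chrom = str(rng.choice(chrom_span.index))
            mid = int(rng.integers(0, int(chrom_span[chrom]) + spacing))
            half = int(rng.integers(50, 200))
            records.append(
                {"chrom": chrom, "start": max(0, mid - half), "end": mid + half,
                 "weight": round(float(2.0 ** rng.uniform(-1.0, 1.5)), 4)}
            )
        out[tf_name] = pd.DataFrame.from_records(
            records, columns=["chrom", "start", "end", "weight"]
        )
    return out


def generate_timeseries(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Time-course table (genes x numeric-hour columns).

    Genes in ``truth.true_rhythmic`` follow cos(2*pi*(t - phase)/period)
    plus Gaussian noise; all others are pure noise.
    """
    tp = np.asarray(config.timepoints, dtype=float)
    if np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if tp.size < 8:
        warnings.warn("fewer than 8 timepoints: rhythm scan will be underpowered", stacklevel=2)
    rng = rng if rng is not None else config.rng(_SALT_TIMESERIES)
    if genes is None:
        genes = sorted(truth.all_genes)
    sd = config.timecourse_noise_sd
    rows = {}
    for g in genes:
        if g in truth.true_rhythmic:
            period, phase = truth.true_rhythmic[g]
            rows[g] = np.cos(2.0 * np.pi * (tp - phase) / period) + rng.normal(0, sd, tp.size)
        else:
            rows[g] = rng.normal(0, 1.0, tp.size)
    df = pd.DataFrame(rows).T
    df.columns = tp
    return df


def generate_annotations(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    n_terms_per_namespace: int = 20,
    enriched_fraction: float = 0.6,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, tuple[str, frozenset]]]:
    """Annotation catalog with planted enrichment, over two namespaces.

    In each namespace one term is enriched in the planted target set by
    construction (it contains ``enriched_fraction`` of the targets plus a
    small random background); the remaining terms are random gene sets.
    Records the planted memberships in ``truth.true_term_memberships``.
    """
    rng = rng if rng is not None else config.rng(_SALT_ANNOTATIONS)
    genes = sorted(truth.all_genes)
    targets = sorted(truth.true_targets)
    catalog: dict[str, dict[str, tuple[str, frozenset]]] = {}
    for ns in ("biological_process", "pathway"):
        terms: dict[str, tuple[str, frozenset]] = {}
        n_in = max(2, int(round(enriched_fraction * len(targets))))
        members = set(rng.choice(targets, size=n_in, replace=False))
        members |= set(rng.choice(genes, size=max(2, len(genes) // 100), replace=False))
        term_id = f"{ns.upper()}:PLANTED"
        terms[term_id] = (f"planted {ns} term", frozenset(members))
        truth.true_term_memberships[term_id] = set(members)
        for i in range(n_terms_per_namespace - 1):
            size = int(rng.integers(5, max(6, len(genes) // 20)))
            rand_members = frozenset(rng.choice(genes, size=size, replace=False))
            terms[f"{ns.upper()}:{i + 1:04d}"] = (f"random {ns} term {i + 1}", rand_members)
        catalog[ns] = terms
    return catalog


# ---------------------------------------------------------------------------
# writers / readers for the on-disk dialects


def write_expression_tsv(comp: ExpressionCompendium, path) -> None:
    df = comp.data.copy()
    df.insert(0, "entrez", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, label: str = "") -> ExpressionCompendium:
    df = pd.read_csv(path, sep="\t", dtype={"entrez": str})
    if "entrez" not in df.columns:
        raise ValueError("expression TSV lacks 'entrez' gene id column")
    df = df.set_index("entrez")
    df.index.name = None
    return ExpressionCompendium(data=df.astype(float), label=label or "file")


def write_gene_models_bed(gene_models: pd.DataFrame, path) -> None:
    """BED6: TSS is start for '+' genes and end-1 for '-' genes."""
    with open(path, "w") as fh:
        for _, r in gene_models.iterrows():
            tss = int(r["tss"])
            if r["strand"] == "+":
                start, end = tss, tss + 1000
            else:
                start, end = max(0, tss - 999), tss + 1
            fh.write(f"{r['chrom']}\t{start}\t{end}\t{r['gene']}\t0\t{r['strand']}\n")


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """narrowPeak (BED6+4): weight in signalValue, summit = midpoint offset."""
    with open(path, "w") as fh:
        for i, r in peaks.reset_index(drop=True).iterrows():
            start, end = int(r["start"]), int(r["end"])
            summit = (end - start) // 2
            fh.write(
                f"{r['chrom']}\t{start}\t{end}\tpeak{i + 1}\t0\t.\t{r['weight']}\t-1\t-1\t{summit}\n"
            )
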