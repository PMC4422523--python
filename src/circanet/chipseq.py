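"""ChIP-seq peak-to-gene association scoring and target calling.

Each peak is assigned to the gene whose TSS is nearest the peak's
anchor point (the summit when the source provides one, otherwise the
interval midpoint), restricted to the peak's chromosome.  A gene's
association score S_g is the sum of the signal weights of its assigned
peaks (1 per peak when the source has no score column), so total signal
is conserved:  sum_g S_g = sum of assigned peak weights.  Targets are
called at log2(S_g) >= threshold (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "read_peaks",
    "read_gene_models_bed",
    "read_gene_models_gtf",
    "read_target_list",
    "closest_gene_scores",
    "call_targets",
    "threshold_suggest",
    "TargetScoreTable",
]


def read_peaks(path, default_weight: float = 1.0) -> pd.DataFrame:
    """Read BED4+/narrowPeak peaks (0-based half-open).

    narrowPeak columns are honored: signalValue (col 7) becomes the peak
    weight and the summit offset (col 10) an absolute ``summit`` column.
    Plain BED without a score yields ``default_weight`` per peak.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            weight = default_weight
            summit = np.nan
            if len(parts) >= 7:  # narrowPeak signalValue
                try:
                    weight = float(parts[6])
                except ValueError:
                    pass
            if len(parts) >= 10:
                off = int(parts[9])
                if off >= 0:
                    summit = start + off
            if weight <= 0:
                weight = default_weight
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "weight": weight, "summit": summit})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "weight", "summit"])


def read_gene_models_bed(path) -> pd.DataFrame:
    """Gene models from BED6: TSS = start on '+', end-1 on '-'."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = pd.DataFrame({"gene": df["gene"], "chrom": df["chrom"], "tss": tss,
                        "strand": df["strand"]})
    _check_gene_models(out)
    return out


def read_gene_models_gtf(path) -> pd.DataFrame:
    """Minimal GTF reader: one TSS per gene from 'gene' or 'transcript' rows."""
    records: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "transcript"):
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene = item.split(" ", 1)[1].strip().strip('"')
            if gene is None:
                continue
            tss = start - 1 if strand == "+" else end - 1  # GTF is 1-based closed
            if gene not in records or f[2] == "gene":
                records[gene] = (chrom, tss, strand)
    out = pd.DataFrame(
        [{"gene": g, "chrom": c, "tss": t, "strand": s} for g, (c, t, s) in records.items()]
    )
    _check_gene_models(out)
    return out


def _check_gene_models(gm: pd.DataFrame) -> None:
    if gm["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in gene models (apply one-TSS-per-gene upstream)")
    if not set(gm["strand"]) <= {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")


def read_target_list(path) -> set[str]:
    """Provided-target-list reader (one gene id per line or first TSV column).

    Covers TFs whose peak coordinates are unavailable and only an
    author-provided target list exists.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0])
    return genes


@dataclass
class TargetScoreTable:
    """Per-gene association scores for one TF."""

    scores: pd.Series  # index: gene id, value: S_g >= 0
    tf: str = ""
    n_unassigned_peaks: int = 0
    log2_threshold: float = 3.0

    @property
    def n_gene(self) -> int:
        return int((self.scores > 0).sum())

    def n_target(self, log2_threshold: float | None = None) -> int:
        thr = self.log2_threshold if log2_threshold is None else log2_threshold
        return len(call_targets(self, thr))


def closest_gene_scores(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    tf: str = "",
    use_summit: bool = True,
) -> TargetScoreTable:
    """Assign each peak to the gene with the nearest TSS; sum weights.

    Peaks on chromosomes absent from the gene models are left unassigned
    (counted, logged).  Distance ties between two TSSs go to the lexically
    smaller gene id, keeping the conservation invariant exact.
    """
    _check_gene_models(gene_models)
    scores = pd.Series(0.0, index=gene_models["gene"].tolist())
    if peaks.empty:
        return TargetScoreTable(scores=scores, tf=tf)
    unassigned = 0
    anchors = peaks["start"].to_numpy() + (peaks["end"] - peaks["start"]).to_numpy() // 2
    if use_summit and "summit" in peaks.columns:
        s = peaks["summit"].to_numpy(dtype=float)
        anchors = np.where(np.isfinite(s), s, anchors).astype(np.int64)
    by_chrom_genes = {c: g.sort_values("tss") for c, g in gene_models.groupby("chrom")}
    for chrom, grp in peaks.assign(_anchor=anchors).groupby("chrom"):
        gm = by_chrom_genes.get(chrom)
        if gm is None:
            unassigned += len(grp)
            continue
        tss = gm["tss"].to_numpy(dtype=np.int64)
        names = gm["gene"].to_numpy()
        pos = grp["_anchor"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(tss, pos)
        for p, w, i in zip(pos, grp["weight"].to_numpy(dtype=float), idx):
            cands = []
            if i > 0:
                cands.append((abs(p - tss[i - 1]), names[i - 1]))
            if i < len(tss):
                cands.append((abs(p - tss[i]), names[i]))
            d, g = min(cands)  # ties resolve to lexically smaller gene id
            scores[g] += w
    if unassigned:
        logger.warning("%d peaks on chromosomes absent from gene models", unassigned)
    return TargetScoreTable(scores=scores, tf=tf, n_unassigned_peaks=unassigned)


def call_targets(scores: TargetScoreTable, log2_threshold: float = 3.0) -> set[str]:
    """Genes with S > 0 and log2(S) >= threshold."""
    s = scores.scores
    positive = s[s > 0]
    return set(positive.index[np.log2(positive.to_numpy()) >= log2_threshold])


def threshold_suggest(
    scores: TargetScoreTable,
    min_scores: int = 50,
    random_state: int = 0,
) -> tuple[float | None, dict]:
    """Data-driven log2 threshold from the gene-score distribution.

    Fits a two-component Gaussian mixture to log2(S) over genes with
    S > 0.  For a genuinely bimodal distribution the suggestion is the
    mixture-density valley between the component means; when the
    components merge (unimodal / right-shoulder case) the fallback
    mean + 1 SD is returned and flagged.  Histogram data for a
    score-distribution plot is included in the diagnostics.
    """
    s = scores.scores
    log2s = np.log2(s[s > 0].to_numpy(dtype=float))
    counts, edges = np.histogram(log2s, bins=min(50, max(10, log2s.size // 20 or 10)))
    diagnostics: dict = {
        "n_gene": int(log2s.size),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
        "fallback": False,
    }
    if log2s.size < min_scores:
        logger.warning("only %d positive scores: no threshold suggestion", log2s.size)
        return None, diagnostics
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(log2s.reshape(-1, 1))
    mu = np.sort(gm.means_.ravel())
    sd = np.sqrt(gm.covariances_.ravel())
    diagnostics["component_means"] = mu.tolist()
    diagnostics["component_sds"] = np.sort(sd).tolist()
    merged = (mu[1] - mu[0]) < max(np.mean(sd), 0.5)
    if merged:
        suggestion = float(log2s.mean() + log2s.std())
        diagnostics["fallback"] = True
        return suggestion, diagnostics
    grid = np.linspace(mu[0], mu[1], 512)
    dens = np.exp(gm.score_samples(grid.reshape(-1, 1)))
    valley = float(grid[np.argmin(dens)])
    if valley <= mu[0] or valley >= mu[1]:  # no interior valley -> shoulder
        suggestion = float(log2s.mean() + log2s.std())
        diagnostics["fallback"] = True
        return suggestion, diagnostics
    return valley, diagnostics
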