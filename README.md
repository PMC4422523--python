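# circanet

Multi-evidence expansion of the mammalian core circadian clock network.

The circadian clock — a ~24 h transcriptional oscillator built around the
PER/CRY and ROR/BMAL/REV-ERB feedback loops — regulates a much larger set
of clock-controlled genes than the core oscillator itself.  `circanet`
implements a reproducible pipeline for predicting those clock-regulated
genes by requiring agreement between two independent evidence streams,
and for validating the predictions with ChIP-seq binding data and
rhythmicity analysis of time-course expression:

1. **Co-expression target prediction.**  From a genes × samples
   expression compendium, pairwise Pearson correlations ρ and mutual
   ranks MR(a,b) = √(rank_a(b)·rank_b(a)) are computed against a curated
   seed network (14 core-clock genes inside a 43-gene extended clock
   network).  The K highest-|ρ| (seed, non-seed) pairs are selected and
   each candidate gene's *tightness* — the number of distinct seed genes
   it pairs with — is computed; candidates with tightness ≥ 2 are kept.
2. **Literature-evidence integration.**  A text-mining-style interaction
   table (gene1, gene2, pmid, sentence, confidence) is aggregated into
   evidence pairs; each seed gene's 50 most-supported partners (ranked by
   sentence count, ties by confidence then gene id) form the second
   candidate set, with supporting sentences capped at the 5 most
   confident per pair.
3. **Consensus and assembly.**  The intersection of the two candidate
   sets defines the consensus extension layer; a layered graph
   (core clock ⊂ extended clock ⊂ extension) is assembled with per-edge
   provenance (known / coexpression / textmining / both).
4. **Validation.**  ChIP-seq peaks are assigned to the gene with the
   nearest TSS; a gene's score S_g is the summed peak signal and targets
   are called at log2(S_g) ≥ 3.  Time courses are scanned for rhythmicity
   with a rank-based (Kendall-tau vs. cosine reference) scan over a
   20–28 h period grid, with Monte-Carlo-calibrated p-values and BH
   q-values.  Candidate gene sets are profiled with one-sided
   hypergeometric term overrepresentation (Expected = Annotated·|query|/|universe|)
   and BH FDR.

A synthetic-data generator with planted ground truth (clock-phased
expression, seed→target edges, literature tables with a controlled
false-positive rate, peaks near planted target TSSs, cosine time courses,
GMT catalogs) makes the entire pipeline runnable and testable offline.

## Worked example

Run the full pipeline on the default synthetic universe (200 unsynchronized
samples, 14 clock genes, 40 planted targets, 1000 background genes):

```python
from circanet import synthetic_pipeline_config
from circanet.pipeline import run_pipeline

result = run_pipeline(synthetic_pipeline_config(seed=1), outdir="run1")
print(result.manifest["selection"])
print(result.manifest["counts"])
print(result.manifest["recovery"]["consensus"])
```

prints

```
{'K': 200, 'n_returned': 200, 'n_seed_genes': 14, 'n_universe_genes': 1054,
 'implied_cutoff': 0.2773..., 'fraction_pct': 1.3554..., 'cutoff_in_sd': 3.1232...}
{'coexpression_genes': 40, 'textmining_genes': 40, 'consensus_genes': 40,
 'network_nodes': 54, 'edge_provenance': {'both': 94, 'coexpression': 105, 'textmining': 6}}
{'precision': 1.0, 'recall': 1.0, 'n_predicted': 40, 'n_true': 40, 'n_correct': 40}
```

Reading: selecting the top 200 of 14×1040 seed/non-seed pairs (1.36% of
pairs, an implied |ρ| cutoff of 0.28 ≈ 3.1 background SDs) and keeping
genes tied to ≥ 2 seed genes yields 40 co-expression candidates; the
literature stream contributes 40 partner genes; their intersection — the
consensus extension layer — recovers all 40 planted targets with no false
positives, giving a 54-node layered network (14 seed + 40 extension).
The rhythm scan on the accompanying time course calls, e.g., gene
`PER1` with p = 0.0005, period 24 h, phase 8 h (tau = 0.76).

The same run is available from the shell:

```bash
circanet run --seed 1 --out run1          # full pipeline + manifest.json
circanet simulate --seed 1 --out inputs   # synthetic inputs only
circanet coexpress --expression inputs/expression.tsv --out co
circanet chip --peaks inputs/peaks_NR1D1.narrowPeak \
              --gene-models inputs/gene_models.bed --tf NR1D1 --out chip
circanet rhythm --timecourse inputs/timecourse.tsv --out calls.tsv
```

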