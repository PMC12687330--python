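# stagedev

Comparative developmental transcriptomics for **replicate-free, stage-matched
single-embryo RNA-seq**, plus rank-based collinear-block synteny detection.

The motivating design is a pair of fly species profiled with *one* single-embryo
library per embryonic stage (stages 1, 5, 8, 9, 10, 12, 13, 15, 17) and a few
post-embryonic samples. With no biological replicates, a per-gene variance
cannot be estimated, so the pipeline:

1. **Normalizes** counts by library size with TMM scaling factors, and computes
   CPM and TPM (gene length = CDS of the longest isoform, extractable from
   GFF3).
2. **Ordinates** samples by the leading log-fold-change distance (RMS of the
   top-N largest |log2 differences|) and classical MDS, then k-means-clusters
   the leading axes (k chosen by silhouette over a WSS/silhouette scan) to form
   **pseudo-replicate groups** of developmentally adjacent stages.
3. **Estimates one global NB dispersion** φ (variance = μ + φμ²) from those
   groups by conditional maximum likelihood on counts quantile-adjusted to a
   common library size.
4. Calls **differentially expressed genes** between each pair of *sequential
   stages* with the NB **exact test** (conditional on the two-sample total,
   double-tail rule) at the fixed global φ, flagging genes with |fold| ≥ 3 and
   p < 0.001.
5. Soft-clusters temporal profiles with **fuzzy c-means** on per-gene z-scores;
   genes join a cluster's reporting list at membership ≥ 0.7.
6. Scores cluster gene lists for **GO Biological Process over-representation**
   (hypergeometric upper tail, Benjamini–Hochberg FDR, strength =
   log₁₀(obs/exp), signal = weighted harmonic mean of obs/exp and −log₁₀FDR).
7. Classifies **orphan genes** (no ortholog, no sequence hit — consumed as a
   precomputed flag table) and filters for **embryo-specific expression**:
   CPM > 1 in ≥ 1 embryonic stage and CPM < 1 in every larval/pupal/adult
   sample, then profiles each gene's peak stage.
8. Detects **collinear blocks** between two genomes from homolog anchor pairs
   by dynamic programming over gene ranks (match_score = 50, match_size = 5,
   gap_penalty = 0, max_gaps = 100).

A first-class **synthetic-data generator** reproduces this design with planted,
truth-tracked effects (fold jumps, temporal archetypes, embryo-specific
orphans, collinear anchor chains), so every stage is testable without any
external download.

## Worked example

```python
from stagedev import AnalysisConfig, run_pipeline

cfg = AnalysisConfig(outdir="demo_run", seed=7, simulate=True,
                     simulate_spec={"n_genes": 1000}, n_clusters=8)
manifest = run_pipeline(cfg)
print({k: v for k, v in manifest["stages"].items()})
```

prints (abridged):

```
'normalize': {'status': 'ok', 'n_genes': 1000, 'n_kept': 1000}
'dge':       {'status': 'ok', 'k': 4, 'phi': 0.46646, 'n_deg_total': 40}
'cluster':   {'status': 'ok', 'n_genes': 29, 'converged': True}
'orphans':   {'status': 'ok', 'n_orphans': 20, 'n_embryo_specific': 20}
'synteny':   {'status': 'ok', 'n_blocks': 3, 'n_anchor_genes': 42}
```

Reading the numbers: the sample ordination found `k = 4` pseudo-replicate
groups among the nine embryonic stages and estimated a global dispersion
`phi ≈ 0.47` — *larger* than the generator's φ = 0.36 because pseudo-groups of
adjacent (non-identical) stages absorb real developmental signal into the
variance, which is exactly what makes the downstream exact tests conservative.
40 sequential-stage DEG calls survive |fold| ≥ 3 and p < 0.001; all 20 planted
embryo-specific orphan genes are recovered with no false positives; and the
three planted collinear chains (5, 7 and 9 anchors, one inverted) are found
among 50 noise anchors. Every output lands in `demo_run/` as TSV, with a
`manifest.json` recording parameters; rerunning the same config reproduces the
tables byte for byte.

The same stages are available as shell subcommands:

```bash
stagedev simulate --outdir sim --n-genes 2000 --seed 1
stagedev dge --counts sim/counts.tsv --samples sim/samples.tsv
stagedev synteny --anchors sim/anchors.tsv \
    --positions-a sim/positions_a.tsv --positions-b sim/positions_b.tsv
stagedev run --config config.yaml
```

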