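# regmeth

Differential-methylation analysis for Illumina-style methylation arrays
(450K/EPIC-class beta matrices), built for studies of **regional
epigenetic identity in epithelium** — e.g. how DNA methylation
distinguishes gastric antrum, corpus and fundus, and how those patterns
shift in pre-neoplastic lesions such as intestinal metaplasia — and for
anyone who wants that analysis reproducible end to end on plain-text
inputs.

## What it computes

* **Per-CpG differential methylation.** Testing on M-values
  M = log2(β/(1−β)) with an empirical-Bayes moderated t-statistic: the
  per-CpG residual variance s²_g is shrunk toward a
  scaled-inverse-chi-square prior (d0, s0²) estimated by closed-form
  moment matching on log s²_g, giving t̃_g = β̂_g /(u·s̃_g) with
  s̃²_g = (d0 s0² + d s²_g)/(d0 + d) on d0 + d df. Effects are reported
  as **delta beta** (difference of group-mean β); calls use
  Δβ ≥ 0.2 and BH-FDR q < 0.05 by default. Paired designs are tested
  on per-patient differences.
* **Gene/promoter aggregation.** A gene is DM at ≥ 2 same-direction DM
  CpGs (1 for exception-listed genes); a promoter
  (TSS1500/TSS200/5'UTR/1stExon) at ≥ 1. Plus gene-set DM fractions,
  promoter-methylation × expression Pearson correlation, set overlaps,
  and fold-threshold gene-set builders.
* **Enrichment.** Locus-overlap enrichment of DM CpGs in BED region
  sets (two-sided Fisher exact, log-odds-ratio threshold 0.6,
  BH-FDR), Pearson-residual analysis of DM CpGs over genomic
  feature × CpG-island classes, direction-specific CpG-set
  construction (|Δβ| > 0.2, capped below 3000), and preranked GSEA
  (weighted KS running sum, membership-permutation null, NES).
* **ExE-hyper-CGI scoring.** Per-sample two-stage mean methylation
  over signature CpG islands, a normal-derived classification
  threshold (mean + 1.96 sd), and Wilcoxon rank-sum group tests.
* **Sample structure.** Classical MDS on the most variable CpGs and
  hierarchical clustering with high-methylation cluster selection.
* **Synthetic methylome generator.** Bimodal array-like betas, planted
  group effects, planted region-set enrichment, methylation-coupled
  expression, paired designs and an epithelial/contaminant admixture
  model — with recorded ground truth, so the whole pipeline is
  testable without any download.

Inputs are plain text: beta/expression matrices (TSV), manifest-style
CpG annotation (TSV), sample sheets (CSV), region sets (BED3+), gene
sets (GMT). See `docs/methods.md` for the statistical details and
design decisions.

## Worked example

```python
from regmeth import SimulationConfig, generate_methylome, differential_methylation
from regmeth.aggregate import call_dm_genes

cfg = SimulationConfig(seed=42, n_cpgs=5000, n_genes=300,
                       groups=(("antrum", 6), ("corpus", 6)))
beta, annotation, sheet, truth = generate_methylome(cfg)

dm = differential_methylation(beta, sheet, ("antrum", "corpus"))
print(dm["call"].value_counts().to_dict())
called = set(dm.index[dm["call"] != "ns"])
planted = set(truth.dm_cpg_ids)
print(f"sensitivity = {len(called & planted) / len(planted):.3f}, "
      f"false discoveries = {len(called - planted)}")

genes = call_dm_genes(dm["call"], annotation)
print(genes.head(3).to_string(index=False))
```

Output:

```
{'ns': 4752, 'hypo': 129, 'hyper': 119}
sensitivity = 0.992, false discoveries = 0
 gene direction  n_dm_cpgs  n_total_cpgs    pct_dm
G0058      hypo          3            12 25.000000
G0040      hypo          3            13 23.076923
G0171     hyper          2            10 20.000000
```

Of 5000 CpGs, 248 are called DM between the synthetic "antrum" and
"corpus" (the generator planted 5% at Δβ = 0.3); 99.2% of the planted
CpGs are recovered with zero false positives, and the gene table ranks
genes by the fraction of their interrogated CpGs that are DM.

The same analysis is available from the shell:

```sh
regmeth simulate --seed 42 --outdir data/
regmeth dm --beta data/beta.tsv --annotation data/annotation.tsv \
  --sheet data/samples.csv --contrast antrum,corpus --out dm.tsv
regmeth run-all --config config.yaml        # full pipeline, one YAML
```

`run-all` executes simulate → dm → aggregate → enrich → gsea →
exe-score → cluster, writes every stage table plus a `manifest.json` of
file hashes, and is byte-identical across runs at a fixed seed.

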