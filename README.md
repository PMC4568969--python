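# coexmotif

Co-expression-guided transcription-factor motif enrichment.

## The problem

When a gene of interest (the motivating case is *SIRT3*, the mitochondrial
deacetylase induced by dietary restriction) is transcriptionally regulated
by an unknown factor, one productive strategy is to ask which binding
motifs are over-represented in the regulatory regions of the genes whose
expression most closely tracks it: co-expressed genes plausibly share
regulators, and a group of 25–100 genes gives far more statistical power
than one promoter alone. `coexmotif` packages that strategy as a tested
pipeline:

1. **Induction screen** — per-probe two-tailed pooled-variance Student
   *t*-test of the seed gene between conditions (e.g. dietary restriction
   vs. control), at P < 0.05.
2. **Co-expression sets** — Pearson *r* of every array probe against the
   seed probe; promiscuous `_s_`/`_x_` probes dropped unless a gene would
   be orphaned; per-gene probe averaging; top-N sets (N = 25, 50, 100,
   seed included) on an "all genes" and a "mitochondrial" (MitoCarta-style
   annotated) track, plus hypergeometric/BH GO over-representation.
3. **Motif scoring** — JASPAR-format PFMs converted to log-odds (bits)
   with a proportional pseudocount; both-strand scanning of −10 kb..+10 kb
   TSS windows; per-gene score = best site log-odds × mean cross-species
   conservation weight over the site.
4. **Enrichment** — per (motif, gene set), the AUC statistic
   AUC = P(score_fg > score_bg) + ½·P(tie), a permutation p-value from
   random matched-size gene sets, Benjamini–Hochberg q-values across the
   motif family, significance tiers q < 0.05 / q < 0.01, and overlap
   reports across set sizes and tracks.
5. **Promoter dissection** — IUPAC consensus-site finding (e.g. the
   NRF-2/GABP core CCGGAA) on a bidirectional promoter, tandem-pair
   detection, a cross-species conservation profile, and reporter-mutant
   design: the CCGGAA→CCTTAA double transversion and the tandem-pair
   deletion (two 6-bp sites + 14-bp spacer = 26 bases).
6. **Assay reductions** — ΔΔCt relative expression against a reference
   gene and background-normalized ChIP percent input, with replicate SE
   and Student *t*-tests.

A first-class synthetic-data module generates expression matrices with a
seed-correlated gene block (target ρ = 0.9), promoters with a planted
NRF-2-like consensus preferentially in the block (planting probability
0.8 foreground vs 0.1 background), and diverged ortholog sequences — so
the whole pipeline is testable end to end with planted ground truth and no
external downloads.

## Worked example

```python
from coexmotif.simulate import SyntheticConfig, run_planted_pipeline

res = run_planted_pipeline(SyntheticConfig(rng_seed=1))
print(res.heatmap)
print(res.result_for("NRF2"))
```

prints

```
analysis  SIRT3_top25_all
motif
NRF2             0.782514
OCT4             0.619657
SP1              0.550629
NFKB             0.545371
GATA1            0.527429
MEF2             0.513486
AP1              0.474286
CEBPA            0.472114
MYC              0.451429
CREB             0.415657
EnrichmentResult(motif_id='NRF2', set_name='SIRT3_top25_all',
                 auc=0.7825142857142857, p_value=0.000999000999000999,
                 q_value=0.00999000999000999, tier='q<0.01')
```

The planted NRF-2-like motif tops the summary table: a random gene from
the 25-gene co-expression set out-scores a random background gene 78% of
the time (AUC 0.78), no random matched-size gene set among 1,000
permutations did as well (p = 1/1001), and after BH adjustment across the
10-motif family the call survives at the strict q < 0.01 tier. The decoy
motifs hover near the null AUC of 0.5.

Command-line entry points wrap the same library calls:

```bash
coexmotif simulate --seed 3 --out dataset/
coexmotif scan --fasta genome.fa --tss tss.bed --motifs motifs.jaspar \
               --upstream 10000 --downstream 10000 --threshold 8
coexmotif enrich --scores scores.tsv --sets set.tsv --seed-gene SIRT3 \
                 --n-perm 1000 --seed 17
coexmotif promoter --fasta promoter.fa --pattern CCGGAA --max-spacer 50
```

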