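# Methods

## Induction screen and co-expression sets

The screen applies the classic pooled-variance two-sample Student *t*-test
(not Welch) to each probe of the seed gene individually, two-tailed, with
the conventional resolutions for degenerate inputs: zero pooled variance
with equal means gives p = 1, with unequal means p = 0 (warned), since the
separation is then infinitely many standard errors.

Probe filtering follows the Affymetrix suffix convention: any probe whose
identifier contains `_s_` or `_x_` (anywhere, configurable) is treated as
promiscuous/cross-hybridizing and removed — unless all of a gene's probes
carry such suffixes, in which case the gene keeps them all. The rule is
therefore guaranteed never to orphan a gene, and unmapped probes pass
through untouched.

Pearson correlations against the seed probe are computed across **all**
samples, not within condition groups. With only a handful of samples per
condition, within-group correlations are too noisy to rank on, and the
induction itself is part of the co-expression signal being sought; this is
the package's default and is not stratified. Zero-variance probes are
excluded (Pearson undefined) with a warning; genes average the r of their
surviving probes.

A gene set of size N is the seed gene plus the (N−1) top-ranked eligible
genes — the seed counts toward N, so the "top-25" set holds 24 correlates.
Boundary ties in mean r are broken by lexicographic gene symbol purely for
reproducibility. The mitochondrial track restricts eligibility to a
user-supplied inventory of nuclear-encoded mitochondrial genes; no gene is
otherwise special-cased. GO over-representation is an upper-tail
hypergeometric test per term with Benjamini–Hochberg adjustment across the
tested terms.

## Motif model and gene scores

A motif is a 4×L position frequency matrix. Log-odds are in bits against
a background composition b (uniform by default, configurable):

    logodds[i,j] = log2( ((counts[i,j] + c·b[i]) / (colsum_j + c)) / b[i] )

with total pseudocount c = 0.8 distributed proportionally to the
background, a common JASPAR-tooling convention. Increasing c shrinks all
scores toward 0 (this monotonicity is property-tested).

Promoter windows are 0-based half-open intervals around the TSS, by
default −10 kb..+10 kb; minus-strand genes take the mirrored interval
reverse-complemented so the returned sequence always reads 5'→3' along the
gene. Windows are clipped at contig edges with a warning.

Scanning scores every offset on both strands; the minus strand is scored
by the reverse-complemented PWM, which is exactly the score of the
reverse-complemented L-mer. Offsets overlapping N score −∞ and are never
reported.

Conservation is consumed from pre-aligned ortholog sequences: the weight
at a position is the fraction of orthologs whose base matches the window
base (gap and N count as mismatch), and with no orthologs the profile is
all ones, so the pipeline runs unweighted out of the box. The per-gene
score is the **maximum over sites of (site log-odds × mean conservation
weight over the site span)**, with 0 for windows lacking any
positive-scoring site. The maximum was chosen as the simplest
site-aggregation statistic consistent with ranking genes by their best
candidate site; a sum-of-top-k option (`top_k`) is exposed for sensitivity
analysis. This aggregate is a documented analogue of phylogenetic
cis-regulatory scoring tools, not a bit-compatible reimplementation of
any of them: it uses a flat identity fraction rather than a species tree.

## Enrichment statistic

For a gene set F inside a scored universe U, the statistic is the area
under the ROC curve,

    AUC = P(s_F > s_B) + ½·P(s_F = s_B),  B = U \ F,

computed by the midrank (Mann–Whitney) formula. The null model is random
gene sets of identical size drawn uniformly without replacement from U —
the natural exchangeability null when no per-gene covariates are modelled
— with the add-one estimate p = (1 + #{AUC_null ≥ AUC_obs}) / (n_perm + 1),
so p ≥ 1/(n_perm+1) and unbiased coverage is property-tested by a
Kolmogorov–Smirnov check of p-uniformity under the null. n_perm defaults
to 1,000 and a seed is mandatory; results are bit-reproducible. For tiny
universes an `exhaustive` mode enumerates all C(|U|,|F|) subsets instead.

q-values are Benjamini–Hochberg across the motif family **within each
analysis** (set size × track); pooling across analyses would mix null
distributions of different set sizes. Tiers are q < 0.05 and q < 0.01.
The summary heat-map table orders motifs by their maximum AUC across
however many analyses were run, ties broken by motif id, top 10 retained.
Overlap reports list, per motif, the analyses where it is significant,
the motifs common to every combination of analyses, and optionally the
intersection with a promoter-scan motif list.

## Promoter dissection and mutant design

Consensus matching is exact IUPAC matching (overlap-aware), with
minus-strand sites found via the reverse-complemented pattern and reported
at forward offsets; a bidirectional promoter is scanned once — which gene
"direction" a site serves is reporting orientation, not a separate scan.
For mutation design the site is the 6-bp core (CCGGAA for NRF-2/GABP);
full-length PWMs are used only in scanning. Tandem pairs are co-oriented,
non-overlapping site pairs with spacer ≤ 50 bp by default — generous
around the 14-bp spacing at which tandem NRF-2 sites occur, where two 6-bp
cores span 26 bp. The double-transversion design substitutes each site
core in place (CCGGAA→CCTTAA changes exactly the two central G's),
preserving length; the deletion design removes the half-open span from
the first site's start to the second site's end. Both record every edit
and re-scan to count surviving sites. The conservation report is a
per-column identity fraction against a designated reference with a
sliding-window mean; ties go to the leftmost window.

## Assay reductions

Relative expression uses ΔΔCt with amplification efficiency fixed at 2
(fold = 2^−ΔΔCt), the field default when no standard curve is modelled:
ΔCt = Ct(gene) − Ct(reference) per sample, ΔΔCt contrasts condition means,
and the p-value is a two-tailed Student *t* on per-sample ΔCt values.
ChIP percent input is divided by a background locus (e.g. β-actin) within
each precipitation — making the statistic invariant to per-precipitation
scale — then averaged across precipitations with SE = sd/√n.

## Synthetic data

The generator emulates a two-condition (control/DR) array experiment:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | desk-scale universe standing in for a whole array |
| `n_samples_per_condition` | 10 | samples per group |
| `induction_effect` | 1.0 | log-units DR shift of the seed gene |
| `correlated_block_size` | 24 | genes tracking the seed (24 + seed = 25-gene set) |
| `target_correlation` | 0.9 | block-to-seed Pearson ρ |
| `noise_sd` | 1.0 | log-scale intensity noise |
| `duplicate_probe_fraction` | 0.2 | genes given a second probe (half clean, half `_s_`/`_x_` cross-hybridizing noise) |
| `promoter_length` | 2,000 bp | per-gene promoter (desk-scale stand-in for 20-kb windows; configurable) |
| `planted_consensus` | ACCGGAAGT | NRF-2/GABP-like planted site |
| `p_site_fg` / `p_site_bg` | 0.8 / 0.1 | planting probability, block ∪ seed vs rest |
| `n_species`, `substitution_rate` | 3, 0.2 | ortholog divergence; planted sites substitute at `site_substitution_rate` (default 0) |

Block genes are built directly on the standardized realized seed profile,
`ρ·z + √(1−ρ²)·ε`, so their model correlation with the seed is exactly ρ —
the moment checked by the generator's oracle test. One site at most is
planted per promoter (simplifying truth accounting). The planted
consensus is 9 bp rather than the 6-bp mutagenesis core: a specific 6-mer
occurs by chance in nearly every 2-kb random promoter (expected ≈1 exact
hit per promoter), which would erase the foreground/background contrast at
this scale, while a 9-mer keeps chance hits rare (≈0.015 per promoter)
and still contains the CCGGAA core.

The default scanning family is 10 strong-consensus PFMs of well-known
mammalian motifs (NRF-2/GABP plus AP-1, MYC, SP1, CEBPA, NF-κB, CREB,
MEF2, GATA, OCT decoys). Decoys were chosen dissimilar to the GGAA core
so that planted-motif recovery is not confounded by ETS-family
cross-recognition — a real phenomenon in this family, but a separate
question from pipeline correctness. The family size also interacts with
the permutation resolution: with n_perm = 1,000 the smallest attainable
p is 1/1001, so a BH rank-1 q-value across a family of ~130 motifs could
never clear 0.05 regardless of effect size; at 10 motifs the floor is
q ≈ 0.01. Analyses of large motif collections should scale n_perm with
family size.

What the generator does **not** model: array-specific noise (GC/probe
affinity structure), correlated background genes, multiple or clustered
binding sites, indels or tree-structured evolution in orthologs, and
composition-biased promoters. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated
generative model — not that real arrays or genomes meet its assumptions.

## Problem sizes and numerical choices

The end-to-end benchmark uses the default configuration above (200 genes,
2-kb promoters, 10-motif family, n_perm = 1,000, 20 replicates); null
calibration uses 100 motifs × 50 replicates at n_perm = 200. These sizes
give stable statistics while keeping a full run to tens of seconds.
Tie-breaks are lexicographic everywhere a total order is needed (gene
symbols at set boundaries, motif ids in report ordering). All
acceptance-level comparisons against independent oracles (pair-counting
AUC, hand BH recursion, naive window extraction and site enumeration) are
exact to ~1e-12; simulation-based checks state their tolerance in the
test (3 binomial SE for calibration, ±0.05 for the correlation moment).

## Known limitations

- Conservation weighting is alignment-free identity, not a phylogenetic
  likelihood; it underweights deep-branch conservation.
- The permutation null ignores gene-level covariates (promoter GC, length);
  on real data a stratified null may be preferable.
- Exact-consensus site finding does not quantify affinity; near-consensus
  sites are only visible to the PWM scan.
- ΔΔCt assumes perfect doubling per cycle; primer efficiencies are not
  calibrated.
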