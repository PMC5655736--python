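# Methods

`epivasc` re-implements, as a tested pipeline over synthetic data, the
count-level analysis of a tissue-comparative study design in a C4 grass:
whole-genome bisulfite methylomes and RNA-seq transcriptomes of four sample
classes (whole root, whole shoot, root vascular and root nonvascular
tissue), three biological replicates each. This note records the models,
the parameter choices, and what the synthetic world does and does not
establish.

## Methylation calling

Replicate methcounts tables are pooled per cytosine (read counts summed).
The bisulfite non-conversion ("error") rate is estimated from an
unmethylated spike-in sequence as pooled methylated reads over pooled
reads; typical values sit in the 0.01–0.33% range, and a floor of 1e-4 is
applied when the spike-in yields zero methylated reads (a rate of exactly 0
would make every non-zero count infinitely significant). Each cytosine with
pooled depth n ≥ 4 is tested with the exact upper-tail binomial probability
B(x ≥ k; n, p) against the error rate p. Benjamini–Hochberg correction is
applied per sample across all tested cytosines of all three contexts
jointly (one test family per sample); a site is methylated iff q ≤ 0.01.
Sites below 4× are "uncallable" and excluded from testing and from all
downstream status-based statistics.

Two deliberate readings where the procedure is underdetermined:

* symmetric CG positions are **not** pooled across strands — each strand's
  cytosine is its own test unit (the conservative reading);
* BH runs jointly across contexts, not per context.

**Weighted methylation level** of any site selection is Σk/Σn
(read-weighted), never the mean of per-site fractions. **Replicate
correlation** is the Pearson r of the 0/1 status vectors over sites
callable in both replicates. **Methylation-state PCA** operates on the
binary (0/1) status matrix over sites callable in *every* sample
(tissue × replicate); columns are centred, components come from SVD, and
the sign convention makes each component's largest-magnitude loading
positive so coordinates are reproducible.

## Metagene profiles

Each gene contributes 300 ordered bins in transcriptional orientation:
100 × 20-bp windows tiling the 2-kb upstream flank, 100 bins partitioning
the exon-concatenated body into contiguous pieces whose lengths differ by
at most 1 bp, and 100 × 20-bp windows downstream. Genes with under 100 bp
of exonic sequence are skipped (a 100-way partition cannot cover them).
Per gene per bin the fraction is methylated *calls* over cytosines covered
≥ 4× (status counts, not read-weighted levels — the literal reading of the
"methylated marks / total cytosines" construction); the profile value of a
bin is the unweighted mean over genes with a defined fraction
(gene-weighted averaging; the cytosine-weighted alternative is retained in
the `marks`/`covered` fields).

Group differences (expression quartiles or tissues) over a genic region are
tested with Kruskal–Wallis followed by Tukey HSD on the per-bin averages,
treating bins as observations. The source methods mention both 100 20-bp
flank windows and a 50-bin upstream view; the native resolution here is
100 bins, with an aggregated 50 × 40-bp view available in
`compare_groups(..., aggregate_50=True)`. Caveat: neighbouring bins are
autocorrelated, so these p-values are descriptive rather than strictly
calibrated.

Expression quartiles (1 = lowest) are assigned from RPKM among expressed
genes with breakpoints at the 25/50/75th percentiles; values tied with a
breakpoint fall to the lower group (so an all-tied sample is all group 1).

## DMR detection

Windows of 100 bp stepped by 50 bp tile each chromosome from 0; only
windows fully inside the chromosome are kept. A cytosine contributes only
when covered ≥ 4× in **both** samples; all three contexts are pooled (a
per-context mode exists). Windows holding ≥ 15 such cytosines are tested
with a two-sided Fisher exact test on the read-level 2×2 table
(methylated/unmethylated reads × sample) — read counts rather than binary
site statuses, preserving depth. Touching or overlapping windows with
p < 0.001 (strict) merge into maximal regions; a region is a DMR iff its
weighted level is < 30% in one sample and > 70% in the other (strict
inequalities). A DMR associates with every gene whose span extended by
1000 bp on each side it intersects, with the relation (overlap / 5′ / 3′)
recorded strand-aware.

Per-gene hypermethylation: for one context, N = cytosines covered ≥ 4× in
the gene span, K = those called methylated, P = the genome-wide fraction of
callable cytosines of that context called methylated in the same sample;
one-tailed binomial upper tail, genes with N < 20 excluded, BH over tested
genes, significant at q ≤ 0.05. DMRs are clustered by k-means (k is a user
parameter, default 4; the source fixes no k) on their per-sample weighted
levels, with a fixed seed and the silhouette reported when defined
(k ≥ 2 and fewer clusters than points).

## Expression analysis

CPM = count·1e6/library; RPKM = count·1e9/(library·length). A gene is
*expressed* in a tissue iff CPM ≥ 3 in every replicate. Differential
expression is a deliberately simple negative-binomial exact test:
median-of-ratios size factors, one common dispersion by method of moments
on normalized within-group means/variances (floored at 1e-8), and a
conditional two-sided exact test on the per-condition normalized count
sums — the sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n), and conditioning on
the total, the p-value sums all splits no likelier than the observed one.
BH FDR; DE iff FDR ≤ 0.05, with direction labelled from the sign of the
log fold-change (both directions are reported; "positive log fold-change"
is a direction label, not a one-sided test). This honours the operation
contract without reproducing any empirical-Bayes machinery; tagwise
dispersion shrinkage is out of scope.

The vascular-enrichment filter keeps a gene iff its abundance in some focal
class is strictly > 1.2-fold every contrast class's abundance and its
q-value is ≤ 0.001.

**Coexpression.** A gene's tissue profile (per-tissue mean RPKM across
replicates) is converted to the vector of differences over all ordered
tissue pairs i ≠ j ("slopes of the lines connecting tissue values"); the
coexpression score is the Pearson correlation of two slope vectors, and
r ≥ 0.9 calls a pair coexpressed. Because the full ordered-pair slope
vector has mean zero, this score equals the plain Pearson correlation of
the tissue profiles exactly — the half-set of pairs i < j does not have
this property, which is why the both-directions construction is used. A
constant profile has no defined score (signalled as NaN with a warning).

## Enrichment

GO over-representation: per term with ≥ 1 study hit, the upper-tail
hypergeometric probability of the observed overlap; population = all
annotated genes (intersected with any user universe); Bonferroni over the
tested terms; enriched iff corrected p < 0.05 (strict). No DAG
up-propagation is performed beyond what the association file encodes.
TF-family enrichment is the analogous one-sided test of a family's members
against the focal (e.g. vascular-expressed) fraction of the genome.

## Synthetic data

The generator emulates the study's data structure, not its sequences.

* **Genome**: i.i.d. bases at a GC fraction of 0.44 (grass-like), plus a
  dedicated fully unmethylated `spikein` chromosome (default 20 kb) whose
  observed methylated fraction estimates the error rate.
* **Methylome**: site-level, not read-level. Every cytosine carries a true
  binary state drawn from its regional rate; per replicate, coverage is
  Poisson (default mean 8, within the study's 5–12× merged range), and
  methylated/unmethylated sites emit methylated reads at 1−e / e
  respectively, with a single error rate e (default 0.002, inside the
  printed 0.01–0.33% spike-in range; e = 0 is allowed only as a degenerate
  no-error world). Baseline rates default to mCG 0.85, mCHG 0.65,
  mCHH 0.05 — the level of a heavily methylated C4 grass methylome — and
  only these relative magnitudes (CG > CHG > CHH) are load-bearing.
  Planted DMRs override the regional rate (≥ 0.7 high side, ≤ 0.3 low
  side, so truth is recoverable under the 30/70 rule); replicates share
  true states and differ only by sampling, matching the near-unity
  replicate correlations the study reports. An optional per-tissue state
  re-draw (`state_divergence`) models tissue-of-origin divergence for PCA
  tests.
* **Expression**: NB counts (default dispersion 0.05) around per-gene
  baselines (log-normal, median ≈ 100) scaled to a target library size,
  with planted fold-changes per tissue. Coexpression-module members get
  tissue-mean profiles constructed to have an *exact* planted Pearson
  correlation with a strongly tissue-specific reference profile
  (geometric 50→3200 across tissues), by rotating in the orthogonal
  complement of the centred reference with rejection of draws that would
  drive a mean non-positive; count noise then attenuates the realized
  correlation slightly. A module needs ≥ 3 tissue classes.

What a green test does **not** establish: the generator has no repeat or
transposon landscape, no chromosomal methylation gradients, no
GC-landscape autocorrelation, no replicate-level random effects, no
library-composition artefacts beyond what per-tissue scaling induces, and
reads are never simulated — alignment, PCR-duplicate and conversion-bias
effects are entirely out of frame. Results demonstrate the correctness and
calibration of the statistics on data satisfying their assumptions, not
robustness to real-data pathologies.

## Numerical choices and degenerate inputs

* Exact tests use scipy's binomial survival function, Fisher exact and
  hypergeometric distributions; the test suite pins each against
  brute-force enumeration oracles (exact rational arithmetic for the
  hypergeometric ones) to ≤ 1e-10.
* BH is statsmodels' `fdr_bh`, pinned against the textbook
  sort-and-threshold definition.
* Empty selections (weighted level of an uncovered region, spike-in with
  zero reads, constant vectors for correlation) raise or signal NaN with a
  warning rather than returning silent zeros.
* All internal coordinates are 0-based half-open; methcounts positions are
  1-based on disk only.
* With only 4–5 tissue classes, chance coexpression correlations ≥ 0.9
  among unrelated genes are common; the r ≥ 0.9 rule is a recall filter,
  not a specificity guarantee, and tests assert module recall only.
* Replicate r² of raw FPKM has an upper bound of roughly (1+φ)⁻² at NB
  dispersion φ; the study's printed 0.94–0.98 corresponds to φ ≈ 0.02,
  which is what the replicate-QC calibration test uses, while DE power
  simulations use the more conservative φ = 0.05.

## Known limitations

* The Fisher window test on read-level counts treats reads within a
  cytosine as independent; overdispersion across cytosines within a window
  is not modelled (the merged-region 30/70 rule is the practical guard).
* Tukey on bins treats autocorrelated bins as independent observations
  (inherited from the procedure being reproduced).
* The DE test's common dispersion underfits genes with atypical
  variability; it is a contract implementation, not a replacement for a
  dedicated DE package.
* k-means on DMR levels is seed-deterministic but not globally optimal;
  the silhouette is reported so degenerate clusterings are visible.
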