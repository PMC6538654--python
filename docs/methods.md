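# Methods

`censcape` re-implements, as a tested library, the sequence-analysis
computations used to compare fission-yeast centromeres: composition-normalised
k-mer enrichment of sliding genome windows, chromatin-group classification and
PCA, a permutation test for recurrent tRNA-gene clusters, and minichromosome
assay arithmetic. This note records the models, the defaults and why, the
numerical choices, and what the synthetic data do and do not establish.

## Windowing

Genomes are tiled with fixed-length sliding windows (default 12 kb, 4.5 kb
overlap, so a 7.5 kb step — the window length matches the ~12 kb scale of
CENP-A domains in fission yeasts). Windows are anchored at coordinate 0 of
each chromosome; the anchor is a convention, not a published choice. Partial
terminal windows are dropped so every window shares one denominator: the
group-coverage rules below assume a fixed window length. All coordinates are
0-based half-open internally; GFF3 is converted on read.

## K-mer enrichment z-scores

For each window the observed counts of all 4^k k-mers (default k = 5, counted
on the forward strand as written, overlapping, k-mers containing ambiguity
codes skipped) are compared against a null built by permuting the letters of
that same window: each of `n_shuffles` (default 1000) artificial sequences is
a uniformly random permutation, so mononucleotide composition — and therefore
GC content — is preserved exactly. With null mean m and sample standard
deviation s (denominator n−1) per k-mer,

    z = (obs − m) / s,   with z = 0 whenever s = 0.

The s = 0 convention is exact, not a fudge: a vanishing permutation variance
means the composition pins the count (e.g. homopolymers), in which case the
observed count necessarily equals the null mean. The resulting vector of 4^k
z-scores is the window's composition-normalised k-mer usage; AT-rich and
GC-rich windows become directly comparable.

Counting strand: k-mers are counted strand-specifically without canonical
collapsing. This is self-consistent — the null shuffles the same strand — and
is the conservative reading where the original strand handling is not
recorded.

Randomisation is a permutation, not i.i.d. resampling: resampling with
replacement would only preserve GC in expectation, while the stated purpose of
the null is to hold composition fixed exactly.

Implementation: windows are encoded as int8 arrays; a compiled kernel performs
Fisher–Yates shuffles (swap indices pre-drawn from a `numpy.random.Generator`,
so all determinism reduces to numpy seeding) fused with rolling-code k-mer
counting. Each window's stream is derived from (master seed, chromosome,
per-chromosome window index), so chunked, reordered and serial runs agree
row-for-row. A pure-Python re-implementation reproduces the z-vectors to
1e-9 in the test suite.

Calibration: on i.i.d. random 2-kb windows the z-scores are centred (grand
mean within ±0.05) with ~5% of |z| > 1.96. The tail is close to nominal
despite the counts being small and discrete (mean count ≈ 2 per 5-mer in a
2-kb window) because the lower tail's deficit and the upper tail's excess
roughly cancel; per-k-mer tails are asymmetric and should not be treated as
Gaussian individually.

## Chromatin groups

Windows are assigned exactly one of six labels by the first matching rule:
CENPA (CENP-A peak coverage > 6 kb, strict), NEOCEN (any overlap with a
neocentromere-forming region), MAT (more than half the window in the
mating-type locus), CEN_HET (more than half covered by H3K9me2 peaks and
abutting — gap ≤ 1 bp, configurable — a CENP-A peak or CENPA window), SUBTEL
(more than half H3K9me2 and within 100 kb of a chromosome end, configurable),
else OTHER. CENP-A first because its rule is the most specific; the 6 kb,
half-coverage and strictness conventions follow the published definitions,
while the adjacency gap and telomere distance are declared defaults, since no
canonical values exist.

For genomes whose centromeres cannot be delimited, a limited mode selects the
top-n windows by an enrichment score (ties to the genomically earlier window)
and compares them with uniformly sampled non-centromeric control windows.

## PCA and group statistics

The window × 4^k z-score matrix is centred per column but not rescaled —
entries are already z-scores on one scale, and rescaling would up-weight
k-mers whose null variance is tiny. Components come from a full SVD; signs are
fixed so each component's largest-magnitude loading is positive, making scores
reproducible across runs and row orders. Group clouds in (PC1, PC2) are
summarised by normal-theory 95% data ellipses (sample mean and covariance,
axes scaled by sqrt of the chi-square(2) 0.95 quantile ≈ 2.448); a data
ellipse was chosen over convex-hull peeling as the standard reading of "an
oval enclosing 95% of the points".

Between-group location differences on a component use the two-sided Wilcoxon
rank-sum test — exact when both groups have ≤ 25 tie-free observations,
normal approximation with continuity correction otherwise — annotated with
the conventional stars (ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥
****). The rank-sum test is the default "mean comparison" of the plotting
convention this mirrors; the exact test identity behind the original
annotations is not recorded anywhere, so a distribution-free test is the safe
choice. A logistic regression of group membership on the component scores
(statsmodels, maximum likelihood) reports the likelihood-ratio p against the
intercept-only model; perfect separation — the expected outcome when a
planted signal is strong — is detected and flagged instead of reporting
divergent coefficients, and the capped-iteration likelihood still gives a
valid (understated) likelihood-ratio statistic.

## tRNA-gene clusters and the location-shuffle test

Genes with end-to-start gaps strictly below 1000 bp are chained greedily per
chromosome. A cluster's signature is its sequence of (amino acid, strand)
pairs in genomic order, canonicalised against orientation flip (reverse the
order, invert the strands, take the lexicographic minimum), so a cluster and
its mirror are one signature. Anticodon identity is not part of the match —
amino-acid letter plus relative strand is the coarsest criterion consistent
with the published cluster descriptions.

Significance: gene locations are shuffled (default 1000 permutations), each
gene re-placed uniformly across the genome — chromosome chosen proportional
to length, placements non-overlapping, lengths/strands/identities preserved —
and each observed signature's p-value is the raw proportion of permutations
containing it at least as often as observed. p = 0 only means "below the
resolution of n_perm" and carries a `below_resolution` flag; n_perm is
exposed precisely because a raw proportion cannot resolve below 1/n_perm.
Benjamini–Hochberg q-values account for the many signatures tested.

Selection effect and calibration: signatures are tested *because they were
observed*, so with a large signature space (20 amino acids × 2 strands) even
a chance pair is individually rare under the null and its raw p is small —
the raw proportion is anti-conservative under selection, which is exactly why
q-values are attached. The type-I calibration study therefore scatters genes
from a reduced 2-letter amino-acid alphabet on a single strand (four
equal-mass pair-signature classes; mixed strands would add palindromic
classes at half mass whose chance doubles sit just under p = 0.05) at a
density of 500 genes on a 62.5 Mb genome, so each class has an expected
cluster count near 1 and chance triples are rare. Under those conditions
~4% of chance signatures reach p < 0.05 (the discreteness of the raw
proportion makes the test conservative). Conclusions about rare-signature
p-values on real genomes should rest on the q-values, not the raw
proportions.

## Minichromosome assay arithmetic

Establishment frequency is the percentage of transformant colonies scoring
white/pale-pink on replica plating, corrected for integration events
estimated from a re-streaked subsample: n_white × (1 − integrants/checked).
The per-division loss rate is the percentage of half-sectored (≥ 50% red)
colonies among all non-pure-red colonies. Percentages are rounded half-up to
one decimal, matching the published table formatting; rates across
transformants are pooled count-weighted (the published pooling is not
specified). The package ships the published reference table; reconstructing
integer counts as round(rate/100 × n) reproduces every printed rate at one
decimal except one establishment entry (28.1% of 208 — no integer count over
208 yields 28.1, presumably a fractional integration adjustment or a
different pooling), which the checks flag honestly.

## Synthetic data

The generator plants the minimal effect the pipeline is designed to detect.
Background sequence is i.i.d. from a configurable composition (default
A/C/G/T = 0.32/0.18/0.18/0.32, the AT-rich fission-yeast regime). Each
chromosome's centromere-like domain is drawn from the sticky Markov kernel
T = (1 − ε)·1p′ + ε·I: with probability ε the chain repeats the previous
base, otherwise it draws fresh. Its stationary distribution is the base
composition for every ε ∈ [0, 1) (verified numerically at 1e-9), so GC is
matched by construction while dinucleotide — hence 5-mer — usage is biased:
precisely the signal a mononucleotide-preserving shuffle null exposes, and
the minimal faithful effect model. Default ε = 0.15.

Default geometry (3 chromosomes × 4 Mb): a 30-kb CENP-A core per chromosome
(the scale of a full central domain; wide enough that each planted centromere
spans several complete 12-kb windows), 9-kb H3K9 flanks, 30-kb subtelomeric
H3K9 blocks, one 15-kb mating-type locus, one 12-kb neocentromere region,
all aligned to the window grid so the intended label of every window is
unambiguous. tRNA annotations combine one planted cluster (default D+V+A+)
per centromere with 150 scattered decoy singletons kept ≥ 1 kb apart. Colony
counts are binomial draws at the positive-control rates (establishment 0.94
of 217 transformants; loss 0.058 of 3284 colonies). All randomness flows
from one master seed through named substreams.

What passing on synthetic data shows — and does not: recovery of planted
labels demonstrates the interval plumbing and rule logic, not peak-calling
robustness (real peak boundaries are noisy; the generator's are exact).
PC1 separation demonstrates sensitivity to higher-order compositional bias
at matched GC, but real centromeres differ from euchromatin in many
correlated ways (repeats, transposon remnants, transcription) that a
first-order chain does not emulate. The cluster test's power case (a 3-gene
signature recurring on all 3 centromeres reaches p ≤ 0.01 at 1000
permutations) mirrors the published setting, but real tRNA-gene placement is
not uniform, so the null is idealised.

## Problem sizes used by the checks

The acceptance script and test suite run the full pipeline on the default
3 × 4 Mb genome at k = 5 with 1000 shuffles per window (~1600 windows), the
null-calibration study on 200 × 2-kb windows, the permutation-theory sweep
over all 494 base compositions of lengths ≤ 8 at 50 000 shuffles each, and
the cluster-test calibration over 200 scattered-gene replicates (500 genes on
62.5 Mb each) at 1000 permutations each.

## Known limitations

* The limited-PCA mode (top-enriched windows vs random controls) is provided
  but the synthetic generator does not emit a read-level enrichment track to
  drive it; scores must come from the caller.
* The shuffle null conditions on mononucleotide composition only; a
  dinucleotide-preserving null would answer a different question and is not
  implemented.
* `profile_matrix` is single-threaded; a 12-Mb genome at default settings
  takes minutes, not seconds.
* Coordinates are validated but no liftover or assembly handling is included;
  inputs must share one coordinate system.
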