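# Methods

## The model

The package reconstructs the regulon of a DNA-binding repressor from three
ingredients: a positional weight matrix (PWM) describing its operator, a
panel of annotated genomes with an orthology map, and differential-expression
measurements.

### PWM and Z-score

Training sites are aligned W-mers (W = 21 by default, odd because the
operator is a palindrome with a one-base non-palindromic centre).  Counts
`N(b,k)` accumulate per column; for palindromic motifs each training site
also contributes its reverse complement, which enforces
`w(b,k) = w(comp(b), W−1−k)` and makes every score exactly strand-symmetric
— the property that lets one physical operator in a short divergent
intergenic gap serve two oppositely transcribed genes.  Weights are centred
log counts

    w(b,k) = ln(N(b,k) + c) − ¼ Σ_b' ln(N(b',k) + c),

with pseudocount `c = 0.5` (configurable).  This form was chosen because it
depends only on the counts and gives the column-sum-zero invariant that the
test suite asserts; any per-column constant would shift all scores equally
and leave rankings unchanged.  Scores are natural-log units; the choice of
base is arbitrary and fixed for comparability across runs.  A site's
Z-score is the plain sum of its positional weights; a window containing an
ambiguity code scores −∞ (draft-genome-safe).  The scan threshold is the
minimum training-site score, recomputed from whatever training set is
supplied rather than hard-coded, because a published threshold is only
meaningful relative to its own training set.  During scanning an absolute
tolerance of 1e−9·max(1,|Z_min|) guards the threshold comparison so that
summation-order rounding cannot reject the training-minimum site itself.

### Motif discovery

Discovery is a one-occurrence-per-sequence EM/Gibbs-family search.  Each
restart picks a seed region and tries *every* window of that region as a
single-site seed model, keeping the seed whose best-window assignment across
all regions maximizes the summed score; plain random initialization was
found to strand the search in local optima (AT-rich pseudo-palindromes),
while enumerated seeding recovers planted sites reliably.  Refinement then
revisits regions in turn, proposing the held-out region's best window under
the leave-one-out model and accepting the move only if the total information
content of the rebuilt model strictly increases — this makes the objective
non-decreasing within a restart and guarantees termination.  After
convergence a region is reported siteless when its window scores below half
the leave-one-out training minimum (a heuristic margin; the unqualified
"below the training minimum" rule is vacuous for the window that defines
the minimum), subject to a minimum fraction of regions keeping their site
(default 0.5).  Ties break to the leftmost window, forward strand first,
for determinism.

### Regulon assembly

Scanning scores every window on both strands; for palindromic models the
two strands give identical scores and each locus is reported once.  A site
is assigned to every gene whose upstream window — default −300..+50 nt
around the translation start, in gene orientation — covers the site's
centre (`position + W//2`).  The window default is wide enough to span all
observed operator placements, including a distal site 167 nt upstream of
its TSS.  Transcription units are maximal runs of co-directional genes with
intergenic gaps ≤ 100 bp (configurable); this reproduces the observed
groupings where a 29-bp divergent gap shares one site and a 118-bp
divergent gap holds two.  The consistency check retains a site-bearing TU
only when orthologues of at least one of its genes carry candidate sites in
at least K *other* genomes (default K = 2); counting the candidate's own
genome would make the filter circular.  Finally, every gene of a surviving
TU becomes a member — genes whose own window covers a site as
`direct_site`, the rest as `operon_inherited`.

### Expression analysis

Per spot, `m = log2(test/ref)` with dye orientation resolved so positive m
always means higher in the test condition, and `a = ½·log2(test·ref)`.
LOWESS (span 0.4, per array; statsmodels implementation) of m on a is
subtracted to remove intensity-dependent dye bias.  The replicate filter
follows the ≥ 6-significant-of-8-replicates rule: each spot's m is referred
to the gene's replicate scatter (t = m_i/s, df = n−1, two-sided) and spots
with p < α = 0.05 count as significant.  The published analysis software's
exact per-spot test is not documented, so this reading — replicate m values
per gene — is one of two defensible interpretations and is configurable.
Calls use inclusive cut-offs (mean m ≥ +1.0 up, ≤ −1.0 down; 1.0 in log2 is
exactly two-fold); inclusivity matters because a boundary gene with m = 1.0
belongs in the up set.  No multiple-testing correction is applied by
default, matching the per-test 5% rule; Benjamini–Hochberg is available but
off.  qPCR fold changes are `2^−ΔCP` with ΔCP the difference of mean
crossing points (test − control), so ΔCP = −3 is exactly 8-fold.

### Regulatory geometry

A site overlapping the −35 element alone or together with the −10 element
is repression-compatible (bound repressor occludes RNA polymerase); any
non-overlapping placement is distal with the strand-aware distance from the
site's downstream edge to the TSS (negative = downstream of the TSS,
flagged).  There is deliberately no intermediate class.  Leaderless
transcripts are detected as TSS coinciding with the first base of the start
codon.  Band-shift probes are 40-mers with the 21-bp site centred in native
genomic flanks (left flank 10 nt, right 9 nt — the uneven split is fixed
for determinism).  Mutant probes apply transitions (A↔G, C↔T), which are
involutions, to either the motif or the flanks; motif transitions drive the
PWM score below threshold while flank transitions leave it untouched,
mirroring the loss/retention of binding seen in vitro.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
real genomes.  Background sequence is an order-1 Markov chain whose
stationary composition is set by GC content (default 54%, typical of
high-GC actinobacteria) with a mild same-base persistence (ρ = 0.1).  Genes
are fixed-length (600 bp) with 400-bp intergenic spacing so upstream
windows never collide.  Regulon architecture follows three templates drawn
from the observed geometry: a three-gene operon with one upstream site, a
three-gene operon sharing one site with a divergent partner across a 29-bp
gap, and a divergent pair with two sites in a 118-bp gap.  Each designated
genome (default 8 of 10) receives sites sampled column-wise from the PWM's
maximum-likelihood frequencies — the raw count proportions, since the
pseudocount is a scoring regularizer, not part of the site distribution —
and, by default, rejection-sampled until they meet the model's own site
definition (z ≥ Z_min).  Without that conditioning roughly a third of
draws from a five-site training model fall below its training minimum, and
end-to-end benchmarks would measure sampling luck instead of the
scan/consistency machinery; `functional=False` restores unconditioned
draws.  Orthology links the template gene slots across genomes.

Microarray simulation places 4 spots per gene on each of 2 dye-swapped
arrays (8 replicates); per spot, m is the true log2 fold plus Gaussian
noise (σ = 0.25) plus an optional intensity-dependent dye bias whose sign
follows the orientation, and the two channel intensities are reconstructed
from (m, a).  qPCR simulation sets `CP_test = CP_control − log2(fold) +
N(0, σ)` with σ = 0.2 and two technical replicates by default.

What the generator does **not** emulate: gene-content evolution, upstream
genes truncating windows, spot-level spatial artefacts, background
subtraction, probe cross-hybridization, or amplification-efficiency
differences in qPCR.  Passing benchmarks therefore demonstrate the
correctness of the algorithms under their stated assumptions, not
performance on raw experimental data.

## Problem sizes and numerical choices

The bundled benchmarks use a 10-genome panel (~27 kb per genome, 29 genes),
100 microarray simulations of 200 genes × 8 spots, and 1,000 qPCR
simulations — sizes chosen so the full suite runs in about a minute while
keeping Monte-Carlo error on the reported fractions below ~1%.  All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give byte-identical outputs.  Consensus ties break alphabetically and are
flagged.  Degenerate inputs are defined, not fatal: empty annotations warn,
fully off-contig windows return empty flagged regions, arrays with < 20
spots skip normalization, and genes with fewer spots than the significance
quota are 'filtered'.

## Known limitations

The discovery search assumes one strong shared motif; multi-motif or
variable-width search is out of scope.  Z-scores are not calibrated to
p-values and the background model is mononucleotide-stationary.  Promoter
coordinates are user inputs — there is no −10/−35 prediction.  The
consistency check treats orthology as given and ignores paralogy within a
genome beyond the one-family-per-gene constraint.
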