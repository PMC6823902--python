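# Methods

This note documents the models implemented in `forestbind`, the tunable
parameters that matter, what the synthetic benchmark generator does and
does not emulate, and the numerical and design choices made where the
design was genuinely open.

## Biophysical affinity model

A motif of width *W* is given as a position frequency matrix (counts or
probabilities, A/C/G/T). Conversion to a position-specific energy matrix
regularizes counts with a pseudocount (default 1) distributed by the
background base frequencies (uniform by default, configurable GC), then
sets per-position mismatch energies

    E_j(b) = (1/λ) · ln( p_j(b_max) / p_j(b) ),   λ = 0.7.

Probability matrices skip count regularization but are floored at 1e-4 to
avoid infinite energies. The scaled binding constant follows the width law
`ln R0 = 0.584·W − 5.66`. These are the published defaults of the TRAP
occupancy model and are exposed as parameters on `pwm_to_psem`.

The affinity of a sequence is the sum over all length-*W* windows on both
strands of the occupancy `p = R0 e^{-E} / (1 + R0 e^{-E})`; windows
containing `N` contribute 0, and sequences shorter than *W* score 0. The
reverse strand is scored by applying the position- and base-reversed
energy matrix to the forward sequence, which makes the both-strand sum
exactly reverse-complement invariant. Summation is the default because it
preserves low-affinity contributions; a `max` aggregate (best single
window) is available. For many intervals on one chromosome the
implementation scores the chromosome once per motif and reads interval
sums from a cumulative array; this is bit-identical to scoring each
subsequence separately because a window contributes to an interval exactly
when it lies fully inside it.

Mismatch energies are steep at λ = 0.7: one non-consensus base in a
sharply peaked 12-mer costs ≈ 4 energy units and drops the window
occupancy from ≈ 0.8 to ≈ 0.07. This matters both for interpreting
affinities and for generating synthetic sites (below).

## Bins, labels, balanced training sets

Prediction units are 200 bp bins every 50 bp (both configurable;
`bin_size` must be a multiple of `step`); trailing windows that would
overrun a chromosome are dropped so all bins have equal width. Coordinates
are 0-based half-open throughout; label files use a `chrom/start/stop`
header. Labels are B/U/A per bin and tissue; ambiguous bins are excluded
from training and evaluation everywhere. Chromosomes chr1, chr8 and chr21
are reserved for testing by default.

Training sets are exactly balanced: positives are capped at 30,000 and
negatives matched 1:1, both sampled without replacement with a mandatory
seed. The cap is applied to positives first, then negatives are matched;
if a (synthetic) tissue has fewer unbound than bound bins, positives are
downsampled so the balance stays exact.

## Feature matrices

*Peak setup.* Replicate peak files are merged with bedtools-`merge`
semantics (overlapping and book-ended intervals join). Affinities and the
median per-base DNase signal are computed once per merged peak; every bin
inherits the row of the peak it overlaps most (ties go to the leftmost
peak), and bins overlapping no peak get all-zero rows. Because merged
peaks vary in length and summed occupancies grow linearly with the number
of windows, peak-level affinities are divided by the per-motif window
count by default (`normalize_affinity=True`): without this, every motif
column — including motifs absent from the region — partly encodes peak
width, which both confounds importance analysis and leaks accessibility
strength into sequence features. The raw sums remain available.

*Bin setup.* Affinities are computed on each bin's own sequence; the
accessibility features are the mean per-base coverage of the bin and of
its non-overlapping neighbours at ±bin_size (the replicate median is
taken). Neighbours falling off the chromosome read 0. The ±bin_size
offset was chosen over ±step because step-shifted neighbours would share
75 % of the bin's own signal and add no information; the offset is a
parameter. The peak setup yields `n_motifs + 1` columns, the bin setup
`n_motifs + 3`.

## The two-step ensemble

Forests are scikit-learn `RandomForestClassifier`s with bootstrap
sampling, √p feature subsampling and out-of-bag scoring; Gini importance
is scikit-learn's mean-decrease-impurity. Defaults: 4,500 trees (the
reference configuration; the test suite and the acceptance runs use 200
to keep runtimes in minutes — results at the fixture scale are insensitive
to the difference), top-*t* reduction with t = 20 (t = 10 supported), and
a 30,000-per-class cap which is re-applied to the concatenated ensemble
rows.

The ensemble matrix `T'_E` contains, for every training bin of every
tissue, the bound-probability of every reduced tissue forest. A tissue's
own rows enter in-sample by default, per the method's defining equations;
`use_oob_inputs=True` substitutes out-of-bag probabilities for the own
tissue column, which is the statistically cleaner stacking construction
and is recommended when the tissue forests are far from saturation. No
tissue-identity column is included.

The ensemble forest `RF_E` over the *m* probability columns uses
`min_samples_leaf=5` while all tissue-level forests grow full trees. This
is a probability-resolution choice: with near-binary input columns, fully
grown trees agree on a handful of split points and the forest's vote
fractions collapse onto few tied values, which degrades rank metrics
(PR-/ROC-AUC) on test data even when the decision boundary is right. A
small leaf size keeps leaf class-fractions mixed and the output scores
usable for ranking.

OOB error is reported as misclassification at probability threshold 0.5.
Baselines: *pooled* (one forest on the row-concatenated reduced matrices)
and *averaging* (arithmetic mean of the tissue forests' probabilities).
The tissue-subset experiment fits the full two-step model on every
non-empty subset of tissues (guarded above 8 tissues) and reports OOB
error per subset.

## Evaluation

ROC-AUC is the rank (Mann–Whitney) statistic via scikit-learn. PR-AUC uses
the continuous Davis–Goadrich interpolation: between operating points the
false positives are linear in the true positives, giving per-segment
closed-form integrals `(Δ TP)/c − d/c² · ln((TP_b+FP_b)/(TP_a+FP_a))`.
This matches the PRROC-style convention rather than step-wise average
precision; the two agree closely unless score ties are heavy. There is no
universal random baseline for PR-AUC, so it is always compared between
alternatives evaluated on the same data. Confusion counts use threshold
0.5; FNR = FN/(TP+FN), FPR = FP/(TN+FP). Large test sets can be
downsampled to 100,000 bins preserving the bound:unbound ratio
(largest-remainder rounding, at least one sample per present class,
seeded).

## Interaction score

For a target *t* with selected predictors *P* and Gini weights GI(p),

    S(t, P) = −ln( Σ_{p∈P} (R[p,t] + R[t,p]) · GI(p) / (2|P|) ),

with the interaction matrix R asymmetric by construction and a 1e-12 floor
before the log. Natural log is used (the base only shifts the scale; all
comparisons are within one base). Weights are used raw; scaling all
weights by k shifts S by exactly −ln k, so observed-vs-random comparisons
are scale-free. The random baseline redraws predictor sets of the same
size uniformly from the matrix symbols (excluding the target) and reuses
the observed weights in rank order, keeping the comparison about set
membership. Motif names are case-folded and stripped of version suffixes
before matrix lookup; unresolvable symbols are dropped and reported.

## The synthetic benchmark generator

The generator produces the statistical structure the method assumes, fully
determined by one seed:

* a shared genome of i.i.d. nucleotides at a configurable GC fraction
  (default 0.41) — tissues share sequence and differ only in accessibility,
  as in reality;
* per tissue, planted bound sites: a near-consensus target-motif instance
  (consensus with at most one PWM-sampled mismatch — instances sampled
  fully from the PWM would average ~2 mismatches and carry almost no
  occupancy under the steep energy model) plus an instance of one of the
  tissue's co-factor motifs within ±100 bp. The default study gives each
  tissue its own co-factor and, cyclically, the next tissue's, so
  repertoires are tissue-specific yet partially shared — the property that
  makes cross-tissue prediction informative at all: a held-out tissue's
  co-factors must be known, positively, to some training tissue;
* per tissue, decoy accessible regions placed clear of every tissue's
  bound sites. Half of them (configurable) carry a target-motif instance
  plus a *degraded* (3-mismatch) co-factor instance: the realistic
  "motif in open chromatin, not bound" false-positive class that forces
  the classifier to read co-factor context, and whose intermediate
  affinities produce intermediate forest votes;
* smooth accessibility: Gaussian bumps (sd = peak width/4, default width
  150 bp) at bound sites (amplitude U(0.8, 1.6)) and decoys (U(0.5, 1.3) —
  weaker on average, reflecting the empirical link between occupancy and
  accessibility strength), sampled on a 10 bp grid, two replicates with
  independent Gaussian noise clipped at zero. Peaks are threshold (0.25)
  runs of each replicate's signal with runs under 50 bp discarded,
  emulating a peak caller's minimum width. A configurable fraction of
  sites can be "weak" (amplitude 0.15, below threshold): bound, visible in
  the raw signal, invisible to peak calling — the mechanism behind the
  peak-vs-bin design trade-off;
* labels: a bin overlapping a bound site by ≥ 1 bp is B, a near miss
  within one bin width is A, everything else U.

Default sizes (two 200 kb chromosomes, 500 sites and 300 decoys per
tissue, 36 never-planted decoy motifs, zero noise) were chosen so a full
three-tissue study trains in seconds at 200 trees while the genome is
dense enough for non-trivial co-factor competition; they are the
conditions used by the test suite and the acceptance script, with fixed
seeds throughout.

What the generator does **not** emulate: read-level noise, fragment-size
or cut-bias effects, real motif redundancy and family structure, copy
number, mappability, chromatin-state heterogeneity beyond a single
accessibility track, and — importantly — heterogeneous data quality across
tissues. Synthetic tissue models are therefore near-perfect and mutually
symmetric on the noiseless defaults, a regime in which averaging tissue
predictions is already close to the best achievable combination; the
ensemble's practical advantage over naive averaging on real data comes
precisely from the miscalibration and quality differences that these
clean fixtures lack. Passing fixture tests shows the machinery recovers
planted structure and respects the method's contracts, not that any
particular margin will transfer to experimental data.

## Degenerate inputs and tie-breaks

Affinity of sequences shorter than the motif is 0; windows containing N
score 0. Top-feature ranking breaks importance ties lexicographically so
reductions are reproducible. Bins overlapping several peaks take the
largest overlap, then the leftmost peak. Balanced sampling, downsampling,
random PPI draws and every forest fit take explicit seeds; one
`random_state` on the ensemble estimator derives all internal seeds
through a `SeedSequence`.

## Known limitations

Peak-setup features are constant across all bins inheriting one peak, so
within-peak resolution is limited to peak boundaries. The OOB error of an
ensemble trained on in-sample prediction columns is optimistic; prefer
`use_oob_inputs=True` when comparing OOB numbers across architectures.
The PR-AUC interpolation assumes scores are comparable across thresholds;
heavily quantized scores (few trees) lower it through tied blocks. The
generator's placement is rejection sampling and will raise a
`PlacementError` rather than silently degrade when asked for more sites
than the genome can hold.
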