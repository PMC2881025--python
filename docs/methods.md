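# Methods

## The mosaic-class model

DNA is modelled as a mosaic of short classes: a hidden Markov model in which
each class is a single state, so class lengths are geometric with mean
1/(1 − a_ss) where a_ss is the self-transition probability.  Emissions are
first-order in the observed sequence: the probability of a base depends on
the state and on the immediately previous *emitted* base, giving each state
a 4×4 conditional table E[s][y][x] = P(x | s, previous = y) — classes are
characterised by dinucleotide, not just mononucleotide, composition.  The
previous base is conditioned on even across state changes (states describe
composition, not insulated segments).

Because the two DNA strands are chemically equivalent and the measurement
strand is arbitrary, states come in strand-symmetric pairs: the partner of
state s emits the A↔T / C↔G complement, E[pair(s)][c(y)][c(x)] = E[s][y][x],
and transition probabilities satisfy A[pair(i)][pair(j)] = A[i][j].  The
tying is literal complementation (no sequence reversal); the alternative
full reverse-complement constraint, which would relate A[i][j] to
A[pair(j)][pair(i)], is noted but not implemented.  Tying is imposed at
initialisation and re-imposed after every EM M-step by averaging tied
parameters and renormalising rows; the operator is idempotent and the
post-symmetrisation likelihood drop on strand-balanced data is below 1e-8
per iteration in practice (asserted in tests).

Model start: the first base of a sequence is emitted from a per-state
initial-base distribution e0[s] (initialised to the stationary composition
of E[s], re-estimated by EM).  This keeps the model properly generative; a
conditional-only parameterisation would leave the first base undefined.

Masked positions (N) contribute an emission factor of 1 (missing data) and
reset the conditioning: the next observed base is scored by e0 of its
state.  Masked runs therefore carry transition information but never bias
emission estimates.

## Inference and training

Forward–backward and Viterbi use per-position scaling (log-space for
Viterbi); log-likelihoods remain finite at 10^6 bases.  Training is batch
Baum–Welch over all sequences, with sequences of equal length stacked and
the recursions vectorised across the batch.  Convergence is declared when
the largest absolute change in per-pair steady-state proportions *and* in
per-pair stationary base compositions falls below `tol` (default 1e-4,
`max_iter` 500 for the library, 60 in the replication harness).

Random initialisation draws each emission row from a Dirichlet centred on
the training batch's global conditional dinucleotide composition
(concentration 50), sets self-transitions to 0.97 (mean dwell ≈ 33 bases),
and symmetrises.  Degenerate M-step rows (a state–context never visited)
fall back to the previous parameters.

## Replicate training and class matching

Independently trained runs label classes arbitrarily and can differ in
which classes they find, so replicate runs are reconciled geometrically.
Each class pair is represented by one canonical member — the one with
T+C ≥ 0.5 in stationary composition (ties by T+G, then state index) — at
the coordinates (T+A, T+C, T+G).  These three pair-sums give an undistorted
view of the composition tetrahedron, and strand partners mirror through 0.5
in the second and third coordinates; matching canonical members only (the
partner's assignment mirrors it) prevents a pair matching one strand image
in one run and the other image in another.

Two point sets are matched by an exact assignment that first maximises the
number of pairs within a Euclidean cap D = 0.12 and then minimises the
total distance (rectangular assignment with a prohibitive cost on capped
edges).  Runs are merged sequentially; consensus positions are running
weighted means so every run contributes equally; singletons stay in the
pool and may match later runs.  Because the sequential result depends on
run order, all orders differing in the first four places are enumerated
(n(n−1)(n−2)(n−3); all permutations when there are fewer than four runs)
and the result with the most matched sets kept, ties broken by smaller
average within-set distance, then lexicographically — fully deterministic.

Matched sets covering at least a majority of runs (5 of 8 by default,
configurable) are averaged into a consensus model: emissions, initial
probabilities and e0 averaged with equal run weighting, partner states
rebuilt by complementation, transitions averaged over runs covering both
endpoints and renormalised, symmetry re-imposed.  Positional uncertainty of
a consensus class is the RMS member distance over √(set size), analogous to
a standard error of the mean.  The consensus initialises a final training
round on the pooled sequences of all replicates.

At desk scale the replication harness adds one element: best-of-3 random
restarts within each replicate, keeping the highest final log-likelihood.
With few classes a single EM start loses a small class roughly half the
time; a lost class is a genuinely worse likelihood optimum (unlike state
splitting, which is likelihood-neutral), so likelihood selection is sound
and inexpensive.

## Motif scanning and class-conditional abundance

The scanner is a log-odds PWM scanner with exact p-values: motif
probabilities are pseudocounted (1e-4), scores discretised at 1e-3 bits,
and the null score distribution computed by dynamic programming over an
i.i.d. background, so the p-value of a score is exactly the probability
that a random background word of the motif's width scores at least as high
(verified against exhaustive 4^w enumeration).  Both strands are scanned;
same-position opposite-strand duplicates collapse to the better p-value;
windows containing N are skipped.  The default reporting threshold is
p ≤ 1e-4.  This is deliberately *not* a re-implementation of MAST's
product-of-p-values statistic; published numbers that depend on MAST
internals are matched only at the aggregate level of the packaged tables.

Class-conditional motif abundance clamps the chain to one state, simulates
pure-class sequence (default 10 × 10^6 bases; tests and the acceptance
script use 4 × 2.5×10^5), scans with the class's stationary composition as
background (empirical composition when the emission chain is degenerate),
and reports c = hits per 10^7 bases.  Motif occurrences are then
apportioned across classes in proportion to b·c (b = the class's share of
genome bases); the genome size cancels in the normalisation.

## The binding-site pipeline

Subsequence preprocessing applies, in order: even deterministic subsampling
to ~5000 records (fixed stride over coordinate-sorted input) when a dataset
is larger; exclusion of subsequences longer than 700 bases; extension of
subsequences shorter than 30 bases by 15 bases each side; exclusion of
records with more than a quarter of bases masked.

Each site is assigned a class vector by posterior decoding of a window of
~4000 unmasked bases with the motif at the centre (truncated and flagged at
sequence ends), averaging the forward–backward state posterior over the
motif's positions.  Averaging over the span is the symmetric choice where a
single representative base would be arbitrary; a Viterbi mode (indicator
average of the decoded path) is provided as the contrast case and agrees
within 0.05 — running slightly higher on the preferred classes — on
strong-contrast synthetic data.  Factor summaries are means of site vectors
aggregated to pairs, pairs numbered by descending genome proportion; the
preferred total sums a designated subset of pairs (a configuration
parameter; on synthetic data it is whatever the experiment designates).

TSS splits partition sites at an unsigned motif-midpoint distance of 1500
bases and report the far/near fraction alongside each summary.  The
low-tag analysis takes M = the median control-tag density at 10,000 seeded
random positions of a designated reference sequence and keeps sites whose
density is zero or strictly below M.  The within-subsequence position
statistic is p = (bases to the nearer subsequence end)/length ∈ [0, 0.5],
histogrammed per dataset and averaged with equal dataset weight.  Region
class composition is posterior-weighted, computed per region and averaged
with equal region weight regardless of region length.

## The synthetic-data generator

The generator produces every input with known ground truth: a genome from
a known symmetric mosaic model, planted motif occurrences biased toward
designated preferred classes, TSS annotations, and an integer Poisson
control-tag track.

Default conditions (chosen once, as the study conditions the pipeline
emulates at desk scale):

* Four class pairs with strongly separated compositions — AT-rich
  (0.45, 0.05, 0.05, 0.45), GC-rich (0.05, 0.45, 0.45, 0.05), C-skewed
  (0.30, 0.45, 0.05, 0.20), A-skewed (0.45, 0.20, 0.05, 0.30) — every
  inter-class distance ≥ 0.16 nats/base, so posterior class identification
  of an interior site is near-certain.  One pair is CpG-rich (CG doublet
  frequency 0.10); the others are CpG-suppressed to ~20 % of their i.i.d.
  expectation, as in real genomes.  Emission tables are built by pinning
  E[C][G] and running a short fixed point that restores the target
  stationary composition (achieved within 0.01).
* Mean lengths 200/500/200/500 bases; with uniform off-diagonal
  transitions the stationary share of a pair is proportional to its mean
  length, putting ~28.6 % of bases in the preferred pairs {1, 3} —
  mirroring the ~26 % genome share of the preferred classes in the real
  analysis.
* Planted consensus TGACTCAG (AP-1-like): base-balanced (two of each
  nucleotide) and CpG-free, so its occurrence probability is nearly the
  same within each composition tier and class-conditional occurrence rates
  track base content — the property that makes the site/motif dissociation
  a *finding* rather than an artefact of motif composition.
* 2000 sites, preferred-placement probability 0.75.  A site is eligible if
  the motif plus 12 same-class bases on each side lies within one class
  run: a site's true class is the class of its local context, and a motif
  straddling a run boundary has no well-defined class.  Subsequences of
  200–500 bases are drawn with the site near the middle (Gaussian jitter),
  and TSS distances are drawn so ~85 % of sites are farther than 1500
  bases.

What the generator does *not* emulate: transposon/repeat structure,
chromosome-scale composition gradients, alignment gaps, experimental
subsequence-boundary noise, or motif degeneracy (sites are planted as the
consensus; a PWM-sampled mode is the obvious extension).  Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted structure under the model's own assumptions, not performance on
real genomes.

## Numerical choices and scales

* All probability rows validated to 1 ± 1e-6 on file load, 1e-9
  internally; stationary distributions via the eigenvector at eigenvalue 1
  with strong-connectivity checked first (reducible chains raise, naming
  the blocks).
* Score discretisation 1e-3 bits; assignment-cap penalty 1e9 (exact
  lexicographic optimum since any real match costs ≤ D).
* Tie-breaks: canonical pair member by (T+C, T+G, state index); order
  search by (set count, average distance, order tuple); all deterministic.
* Problem sizes: the replication harness trains 8 replicates of 200
  sequences × 2000 bases (the full-scale protocol used 6000 × 2000 and 25
  initial pairs; both are accepted as parameters), and the end-to-end
  analysis uses a 4 × 10^6-base genome with 2000 planted sites.  These
  sizes give recovery errors (emissions ≤ 0.01 absolute, dwell lengths
  ≤ a few %, coordinates ≤ 0.002) an order of magnitude inside the
  acceptance bands.
* Seeds: every stochastic routine takes an explicit seed; derived seeds
  are drawn below 2^31.

## Known limitations

* Geometric length distributions only; no explicit-duration states.
* Complement-only symmetry tying (see above); whether published class
  lengths are dwell times or posterior-segment lengths is resolved in
  favour of the closed-form dwell time 1/(1 − a_ss).
* The scanner's p-values assume an i.i.d. background even when scanning
  Markov-generated class sequence; for the abundance estimator this is a
  scoring convention, not a model claim.
* `preprocess_subsequences` subsamples before applying exclusions, so the
  output can fall somewhat short of the 5000 target on heavily filtered
  inputs.
* Matching assumes runs share a coordinate scale; it is not a general
  clustering method and deliberately implements only the sequential
  protocol with order search.
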