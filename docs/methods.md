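# Methods

## The model

Multichannel source activity `x(n) ∈ R^M` (sampled at 256 Hz) is modelled
as a nonlinear multivariate autoregressive (nMVAR) process of order `p`:

    x(n) = f(x_p) + σ(n),
    x_p  = [x_1(n−1), …, x_M(n−1), x_1(n−2), …, x_M(n−p)]ᵀ,

with `σ(n)` the innovation noise.  `f` is realized by a single-hidden-layer
perceptron (`H` tanh units) trained to predict `x(n)` from `x_p`.  The
fitted predictor is split as `f = f_Lin + f_NonLin`, where `f_Lin` is the
first-order Taylor expansion of the network at the standardized input mean
(the zero vector — the canonical operating point, at which `tanh′` is
closed-form in the hidden biases):

    A[τ](j, i) = Σ_k W2[j, k] · act′(b1[k]) · W1[k, (τ−1)M + i].

From this decomposition come the two unitless directed connectivity
measures:

- **Linear connectivity** `lC_{i→j}` = mean over lags τ of `|A[τ](j, i)|`.
- **Non-linear connectivity** `NC_{i→j}` = mean over samples n and lags τ
  of `|J_n(j, (i, τ)) − A[τ](j, i)|`, where `J_n` is the network's
  input–output Jacobian evaluated at the n-th lag vector.

These aggregations satisfy the two properties that anchor the
decomposition and are isolated in one function for easy substitution:
a network with identity activation has `NC ≡ 0` exactly, and in the same
linear limit `lC` equals the absolute least-squares VAR coefficients.
Because both measures live on standardized (per-channel z-scored) data,
an edge's lC scales with `sd(source)/sd(target)`; synthetic scenarios are
therefore designed with comparable channel variances (see below).

## Training protocol

Incremental (per-sample) gradient-descent error back-propagation with
momentum `α` (default 0.9), weights initialized uniformly in [−0.5, 0.5].
The learning rate `η` (initial 0.01) adapts per epoch on the full-set
training error: an epoch that does not increase the error is accepted and
`η ← min(1.05 η, η_max)`; an epoch that increases it is rejected — weights
*and* momentum state restored — and `η ← 0.7 η`.  Two consequences:

- the accepted-epoch training-error sequence is non-increasing by
  construction (the classic heuristic that tolerates ≤4% increases does
  not guarantee this, so we reject on any increase);
- `η_max` (default 0.05) caps the growth of the step size.  Without the
  cap, per-sample updates at a momentum-amplified effective step jitter
  around the optimum and the identity-activation fit stops short of the
  least-squares solution.

Early stopping monitors a validation block: training stops after
`patience` (default 20) epochs without improvement, and the
best-validation weights are restored (restore-best rather than
keep-last).

**Cross-validation.**  One seeded permutation of the regression rows is
split into `n_folds` blocks; the test block rotates across folds, the
next block validates, and the rest trains (80/10/10 at the default 10
folds).  Test blocks are therefore disjoint and exhaustive — every row is
tested exactly once.  Channel standardization is fitted on each fold's
training rows only and applied to validation/test (leakage control).
Connectivity is reported as the mean over the fold models, which
measurably reduces initialization variance relative to a single fold.

**Model order.**  Least-squares VAR fits for `p = 1..p_max` on a common
sample (rows valid at `p_max`), scored by Akaike
(`ln det Σ + 2k/T`) and Schwartz (`ln det Σ + k ln T / T`, `k = pM²`)
criteria.  Both selections are reported; the pipeline defaults to the more
parsimonious Schwartz choice when they disagree.

## Surrogate significance testing

The null for each directed edge comes from time-shifted surrogates: every
channel is independently circularly shifted by an offset drawn uniformly
from `[L/8, 7L/8]`, preserving each channel's marginal distribution exactly
and its autocorrelation up to wraparound, while destroying cross-channel
alignment — both driver and response are resampled.  For each surrogate
the lag rows are rebuilt and the network retrained with identical
hyperparameters but fresh weight initialization under a derived seed
("identical network parameters" is read as identical hyperparameters).
An edge is significant when its observed strength exceeds the 95th
percentile of its per-edge null (one-sided, matching the α = 0.05 used
elsewhere); non-significant edges are reported as missing.  Surrogates
whose training diverges are dropped and logged; more than 20% dropped
aborts the test.

A practical caveat established on synthetic data: NC retains its nominal
specificity on linear data only when the network is well converged.  With
short series and few epochs the observed fit of a truly *linearly* coupled
edge carries slightly more curvature than its decoupled surrogates,
inflating the NC false-positive rate above nominal.  The specificity
checks therefore use series long enough (and training budgets large
enough) for convergence — which is also what the analysis protocol
prescribes by concatenating all trials of a condition.

## Signal preparation

Band-pass filtering uses an odd-length windowed-sinc (Hamming) FIR applied
forward-backward (zero phase — lag distortion would corrupt directed
estimates).  Band edges: theta 4–7 Hz, alpha 8–12 Hz, beta 15–30 Hz.  The
transition width is `min(0.75·f_lo, f_hi − f_lo)` with cutoffs half a
transition outside the band edges; the taps are re-centred for an exact
null at DC.  This meets the design contract — passband gain within
[0.9, 1.1], stopband gain ≤ 0.1 one octave outside the edges — with the
shortest impulse response that does so.  Deliberately sharper filters
narrow the signal's effective bandwidth further, making lag vectors nearly
collinear and widening the surrogate null of every cross-channel edge;
filter length here is a connectivity-power issue, not only a spectral one.

Epochs cover the half-open window [0, 1000) ms after stimulus onset
(256 samples at 256 Hz); trials of a condition are concatenated with the
start of every trial recorded.  Lag rows whose window would span two
concatenated trials are excluded, so concatenation cannot fabricate
cross-trial "causality".

## Source-cluster extraction

The Neural Activity Index is the voxelwise ratio of source power to the
local noise estimate (invariant to common rescaling).  Suprathreshold
voxels are those at or above the (100−1)th linear-interpolation percentile
of the (atlas-)masked NAI values — ties at the threshold are all included,
which keeps the rule deterministic.  Clustering groups *adjacent* voxels:
eps-connected components of the voxel-centre graph at `eps = 1.5 ×` grid
spacing (face and edge neighbours connect; corner neighbours at
`√3 ×` spacing do not), keeping components of at least `min_pts = 5`
voxels and labelling the rest noise.  `min_pts` is a minimum *cluster
size*, not a core-point neighbourhood count: a straight line of five
adjacent voxels is a cluster, which a core-based rule could never produce
at this eps.  This semantics also removes the classic border-point
ambiguity, making cluster membership independent of voxel input order.
The atlas mask is an input, never a bundled atlas copy.  Bands or
conditions with fewer than two clusters are skipped by the connectivity
stage (a connectivity analysis needs at least two regions), with the skip
recorded in the run manifest.

## Group statistics

Behavioral hit rate is correct probe responses over all events of a design
cell (misses and false responses stay in the denominator); mean RT is
computed over correct-probe trials only.  The 2×2 within-subject ANOVA
(response relation × feature overlap) is computed from explicit sums of
squares; each 1-df effect is tested against its own effect-by-subject
interaction, so its F equals the squared paired t on the per-subject
contrast — an identity the tests verify, alongside an independent
cross-check against pingouin.  Partial eta squared is
`SS_effect/(SS_effect + SS_error)`.

Paired comparisons screen the differences for normality (default:
Lilliefors-corrected Kolmogorov–Smirnov, since means and variances are
estimated; the uncorrected KS variant is a config switch) and route to a
two-tailed paired t-test or a Wilcoxon signed-rank test (Pratt handling of
zeros).  Spearman correlations use the subjects complete on each variable
pair (pairwise-complete), midranks for ties, a t-approximation p-value for
n ≥ 10 and exact pairing permutation below; pairs with fewer than 5
complete subjects are reported missing.  The Benjamini–Hochberg step-up
procedure controls FDR at q = 0.05 and reports the data-dependent critical
p-value (0 when nothing is rejected).

## Synthetic ground truth

The generator produces everything the pipeline consumes:

- **Coupled nMVAR series.**  Direct recursion of the model above: linear
  lag matrices plus optional non-linear terms (quadratic, tanh, or
  cross-product of lagged samples — smooth forms an MLP can represent),
  i.i.d. Gaussian innovations per channel (the standard MVAR assumption),
  500 burn-in samples discarded (transient decay for poles ≤ 0.98).
  Specs whose linear companion matrix has spectral radius ≥ 1 are
  rejected.  Band-resonant dynamics come from an AR(2) pole pair at the
  band centre: `a1 = 2r·cos(2πf₀/fs)`, `a2 = −r²`.
- **NAI-like volumes.**  Baseline + Gaussian blobs + voxel noise on a
  5-mm grid.
- **Behavioral tables.**  Per-trial Bernoulli probe correctness around
  subject-and-cell accuracy (between-subject spread on the probability
  scale) and Gaussian RTs drawn for correct trials only.  The bundled
  crossover spec (accuracy ≈ .94/.79/.96/.78 across the four cells, 43
  subjects × 24 trials per cell) produces the response × overlap
  interaction with high power; a flat spec calibrates the type-I error.

The bundled end-to-end scenario ("two-region alpha") couples a strongly
alpha-resonant driver (pole radius 0.9) into a weakly resonant receiver
(0.3, smaller innovation noise) with one directed edge at lag 1, in 30
one-second trials.  The receiver is deliberately *not* strongly resonant:
feeding a resonant signal through a second strong resonance amplifies the
received component so much that, after standardization, the forward
coefficient shrinks toward the surrogate noise floor.  Balanced channel
variances mirror real source analyses, where region time courses have
comparable scale.

What the generator does **not** emulate: volume conduction and field
spread, non-Gaussian or non-stationary innovations, measurement noise at
the sensors, inter-subject anatomical variability, and any particular
form of the nonlinearity in real source dynamics (the chosen term forms
are stand-ins, not claims about data).  Passing tests therefore establish
the estimator's correctness and calibration under the model's own
assumptions, not its behaviour under beamformer leakage or artifacts.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage, per-condition and per-surrogate children from one master seed
via `numpy.random.SeedSequence` spawning in a fixed documented order, so a
full run is byte-reproducible and any stage can be re-run in isolation.
Stage results are written as plain text (TSV/CSV/JSON) with 12-significant-
digit floats; the manifest records config, seeds, stage status and output
files.  No stage caching is performed — at these problem sizes retraining
is cheaper than guaranteeing byte-stable cache round trips.

Test and acceptance problem sizes (e.g. 2-channel systems, series of
1 500–8 000 samples, 30–50 surrogates, 20-seed batteries) are chosen so
the full battery runs in minutes on one core while leaving comfortable
statistical margins; all are set in one place per test and scale up
directly.

## Known limitations

- The lC/NC aggregation formulas are this package's own (contract-anchored)
  choices; the original method's source publication may weight lags or
  samples differently.  They are isolated in `connectivity.compute_lc_nc`
  for substitution.
- lC/NC inherit the standardized scale: edges between channels of very
  different variance are asymmetric by construction.
- Incremental EBP with momentum is sequential; runtime scales linearly in
  samples × epochs × surrogates (the numba kernel keeps this practical).
- The surrogate test assumes exchangeability of observed and shifted data
  under the null; under-trained networks break this mildly for NC on
  linearly coupled edges (see above).
- Narrowband analysis fundamentally limits directed inference: zero-phase
  filtering is non-causal and strong resonance makes lag vectors nearly
  collinear.  The estimator remains calibrated, but power drops as bands
  narrow.
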