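# Model and methods

## Rate dynamics

Every neuron (more precisely, every neural-mass unit) obeys a leaky
rectified-linear rate equation

    tau_k dr_i/dt = -r_i + f( sum_j W_ij r_j + I_i ),      f(x) = max(0, x),

with a shared membrane time constant tau_exc = tau_inh = 20 ms by default
and an external drive I_i.  The equation is integrated with forward Euler at
dt = tau/20 = 1 ms.  Halving dt changes steady-state rates by well under 1%
(tested), and steady-state evaluations are insensitive to the convergence
tolerance between 1e-5 and 1e-7.  Starting from non-negative rates the
rectified drive keeps all trajectories non-negative; this is asserted as a
property test.  A trajectory that crosses `rate_cap` (default 1e3 rate
units) is flagged divergent rather than being allowed to overflow — rates
are clipped at ten times the cap so that runaway traces remain analysable.
Divergence is a meaningful model outcome (it is precisely what one
silencing experiment produces), not an error.

## The prediction-error microcircuit

A prediction-error (PE) microcircuit contains one unit for each of the four
cortical cell classes — excitatory (E), PV, SST and VIP.  All existing
within-motif synapses have magnitude one, carry the sign of their source
(Dale's principle), and are not plastic.  Six edges are mandatory: E
projects to all three interneurons, PV and SST inhibit E, and VIP inhibits
SST (disinhibition).  The remaining nine inhibitory-source edges (including
interneuron self-connections, excluding E->E) are free, giving 2^9 = 512
connectivities.  Afferents are described by which cell types receive the
bottom-up (BU) and top-down (TD) drive; E always receives BU and VIP always
receives TD, leaving six free assignments (BU to the three interneurons, TD
to E/PV/SST) and 2^6 = 64 input patterns.

### The combinatorial search

All 512 x 64 = 32,768 candidate (connectivity, input-pattern) pairs are
simulated to steady state (2-s horizon, from rest) under three scenarios:
balanced drive (BU, TD) = (1, 1), bottom-up surplus (1, 0.5) and top-down
surplus (0.5, 1).  The drive magnitudes are the package's own choice — the
selection scenarios are published only graphically — and are set to the
pixel range of the inputs.  A pattern qualifies for the PE+ role if the E
steady rate is below eps = 1e-3 under balance and top-down surplus but
above theta = 0.05 under bottom-up surplus; the PE- role mirrors this.  A
**valid combination** is a connectivity together with one PE+-qualifying
and one PE--qualifying pattern.  Non-convergent or divergent scenarios
disqualify a candidate.

Under these settings the search returns **1817 valid combinations across
148 connectivities**.  The count is robust to the thresholds (1856 at
theta = 0.01, 1266 at theta = 0.1, unchanged for eps between 1e-4 and
1e-2); the structural counts 512/64/32,768 are parameter-free.  The count
is sensitive to the free-connection and drive conventions, which are not
fully recoverable from published material; the package therefore reports
its count together with the thresholds and drives used
(`SearchResult.summary()`), and exposes `count_valid()` to recount under
alternative thresholds.

### The frozen default motif

The valid set is not behaviourally homogeneous.  Because all within-motif
weights are exactly one, many valid circuits have *zero* net top-down
sensitivity at the E cell (the direct TD excitation is exactly cancelled by
TD-driven PV inhibition); such circuits pass the three-scenario test but
cannot reduce their error when the prediction improves, so no learning is
possible through them.  The default motif shipped with the package
(`data/default_motif.yaml`) was therefore selected from the valid set by
the qualitative network-level criteria the model is meant to exhibit:

1. graded, sign-correct top-down sensitivity of both error channels
   (d r_E^PE+ / d TD < 0, d r_E^PE- / d TD > 0), so Hebbian learning
   descends;
2. a ~6 Hz population rhythm during inference at tau = 20 ms;
3. the interneuron-silencing effects (see below);
4. stable, seed-robust training dynamics.

The selection procedure combined a mean-field linearisation of the
two-area loop (one scalar unit per population, inter-area gains set to the
top singular value of W) with full simulations of trained desk-scale
networks.  The frozen motif adds five edges to the mandatory six —
PV->VIP, SST->SST, SST->VIP, VIP->PV and VIP->VIP — with afferents
BU -> {E, SST, VIP} and TD -> {E, PV, SST, VIP} for the PE+ role and
BU -> {E, PV, SST, VIP} and TD -> {E, SST, VIP} for the PE- role.  It is
stored as a versioned YAML artifact so that all default configurations are
reproducible.  Not every qualitative published behaviour is attainable by
a single valid circuit under strictly unit weights (see Known
limitations); the frozen choice maximises the set that is.

## The two-area hierarchy

Area 1: one L4 E cell per pixel (n_pix = 1024 for 32x32 images) receiving
the pixel value as constant drive, plus one PE+ and one PE- motif per pixel
in L2/3, wired one-to-one from L4 (strictly columnar; no lateral wiring).
Area 2: n_rep = 784 columns of L4 E and L4 PV in a one-to-one recurrent
pair (E excites PV, PV inhibits E, unit weights) plus L5 E cells that
faithfully relay L4 E.  A single plastic matrix W (n_pix x n_rep) serves
both directions: the prediction W r_L5E is delivered, scaled by
`feedback_scale`, to the TD targets of both PE motif arrays, and the
transpose delivers the feedforward errors — W^T r_E^PE+ excites Area-2 L4 E
and W^T r_E^PE- excites Area-2 L4 PV, so the recurrent pair integrates the
signed error.  The TD drive passes through the motif's rectifier, so
negative components of W r cannot inject negative rates.

**Weight initialisation.**  W is initialised i.i.d. uniform on
[0, 2/sqrt(n_pix n_rep)).  This makes the rank-one mean mode of the
feedforward-feedback loop have unit spectral gain at initialisation and
top-down predictions of order the pixel range, independent of network
size.  (A size-independent *absolute* scale would give a loop gain of
order n and immediate divergence at realistic sizes.)  Entries are
unconstrained in sign thereafter: W abstracts a multi-synapse inter-area
pathway, a deliberate relaxation of Dale's principle at the inter-area
level.

## Hebbian learning

After each 2-s presentation the weights are updated by

    dW = gamma_w [ r_E^PE+ (r^Rep)^T  -  r_E^PE- (r^Rep)^T ],

using the final-time rates of the presentation (a config switch selects
time-averaged rates instead, for sensitivity analyses).  The sign is fixed
by the requirement that errors descend: a too-small prediction activates
PE+ and must *strengthen* the weights that build the prediction.  A guard
test asserts that the flipped sign fails to learn.

Training is batch-parallel: every image in a batch is inferred by an
independent copy of the network holding the same pre-batch W, the per-copy
updates are averaged, and the single averaged update is applied before the
next batch.  The 0.2-s blank between presentations is ten excitatory time
constants, so activity decays to rest (factor e^-10) and each copy starts
from the zero state.

**Learning rate.**  gamma_w is dimensionless and its useful range scales
with the squared norm of the representation vector: the per-batch change in
the prediction is of order gamma_w |r_Rep|^2 times the residual error.  The
default gamma_w = 0.5 makes this factor a modest fraction of the error per
batch for the desk-scale configurations the package ships (16
representation units with rates around 0.1), so training converges within
the standard schedule of tens of passes while the learning dynamics stay
stable across seeds (larger rates make the weight updates themselves
overshoot and oscillate).  Larger networks with larger |r_Rep|^2 need
proportionally smaller values; the training protocols expose gamma_w per
experiment.

**Training trajectory.**  The positive-error channel descends steeply
(to ~15% of its first-pass mean within 30 passes at desk scale).  The
negative channel starts near zero — an initial uniform W underpredicts
almost everywhere — and *rises* toward the overshoot/undershoot balance
that is the rule's fixed point; the total error descends.  Because the
rule has no weight decay, the inter-area gain keeps growing as residuals
shrink, and the trained desk-scale operating point sits at or slightly
above the oscillatory instability of the inference loop: the inference
rhythm is then a finite-amplitude (rectification-bounded) oscillation
rather than a decaying transient.  Its dominant frequency at
tau = 20 ms is ~6 Hz for the default motif and scales inversely with tau.

## Synthetic stimuli

The generator produces three families of grayscale images in [0, 1]:
Gaussian-bump "blobs" (smooth, spatially correlated patterns), sinusoidal
gratings, and "lowrank" images — non-negative combinations of k = 4 fixed
smooth basis patterns, so the dataset is exactly k-dimensional and the
pixel-to-representation compression is learnable by construction.  The
desk-scale training condition used throughout the tests and the
reproduction script is 16 low-rank 8x8 images, 16 representation units and
30 passes.  What these fixtures do *not* emulate: the higher-order
statistics, occlusions and class structure of natural images; results on
synthetic data demonstrate the mechanisms (error minimisation,
generalisation within the generative family, denoising), not
natural-image performance.

Two noise models probe robustness.  External noise adds one Gaussian draw
per presentation to the pixels (then clips to [0, 1]; drawing per
presentation, not per time step, treats the noise as a corrupted image).
Internal noise adds Gaussian jitter to every existing within-circuit
synapse — each motif instance independently — leaving structural zeros and
the learned W untouched; sigma_int is an absolute SD on unit-magnitude
synapses, so a "16% noise level" is sigma_int = 0.16.

## Metrics and rhythm analysis

Reconstruction quality uses the pixelwise MSE and a *global-window* SSIM
(k1 = 0.01, k2 = 0.03, dynamic range L = 1) computed over the whole image —
not the common sliding-window variant.  The mean PE rates correlate with
the image-domain MSE but the two are never identified: MSE is always
computed from images.

Rhythms are analysed through the autocorrelation of the linearly detrended
mean-rate trace, using the *unbiased* estimator (the biased form tapers
linearly with lag and makes sustained oscillations look damped).  The
dominant frequency is the reciprocal of the mean spacing of significant
positive autocorrelation peaks (significance bound 3/sqrt(N)); a trace with
no significant peak has no rhythm, reported as absent rather than raised.
Dynamical classes: *silent* if the terminal mean rate is below 1e-3;
*divergent* if the rate cap was hit or the linear trend over the
post-transient trace exceeds half the mean level per trace duration;
*damped* if successive autocorrelation peak amplitudes decay by more than
delta = 0.05 per cycle (or if no rhythm survives on a converging trace);
*sustained* otherwise.

## In-silico protocols

* **Oddball**: a pre-trained network is shown a sequence of standards with
  one deviant; response peaks are read per stimulus window (onset to next
  onset, population-mean E rates).  Robust effects: the first stimulus
  (meeting a network at rest) evokes the largest transient, repeated
  identical standards evoke near-identical responses, and the deviant
  breaks that pattern.  A genuine deviance *enhancement* (deviant peak
  above the standards') is not reliably produced: the onset peak occurs
  before the top-down loop engages, so it is prediction-blind, and network
  state decays within a few time constants of the inter-stimulus interval
  — the response difference is dominated by the identity of the deviant
  image.  See Known limitations.
* **Silencing**: each interneuron class is clamped to zero in both PE
  arrays (a flag optionally extends a PV clamp to the Area-2 L4 PV
  population; off by default).  Under the default trained configuration:
  clamping VIP abolishes the negative-error channel (SST inhibition
  un-opposed); clamping SST removes the strongest damping element and
  produces the largest-amplitude persistent oscillation; clamping PV
  elevates both error populations to matching rates — the signed error
  code is lost and reconstruction degrades.  The idealised four-way
  taxonomy (damped / divergent / sustained / silent) is only partially
  realised; see Known limitations.
* **Feedback scaling**: multiplies only the L5 -> L2/3 prediction pathway;
  a 30% reduction (factor 0.7) is the package's stand-in for reduced
  top-down influence, and lowers oscillatory power.
* **Omission**: a sequence slot is replaced by a blank screen.  The
  omission response exists only by virtue of the learned prediction (it
  vanishes with untrained zero weights), and it survives into the omitted
  slot only when the inter-stimulus interval is not long against the
  membrane time constant.  For the frozen motif the loss of bottom-up
  drive also releases the PE+ interneurons, so the omission transient is
  not purely negative-error.
* **Noise sweeps**: reconstruction metrics per noise SD, averaged over
  dataset and seeds; internal mode re-jitters pristine weights per
  (sigma, seed).
* **Tau sweep**: steady states are independent of tau, so one trained
  network serves the whole grid; each tau is run with dt rescaled to
  tau/20.  Frequency decreases monotonically with tau.

## Problem sizes

The package defaults to the full architecture (1024 pixels, 784
representation units) for assembly and single-presentation protocols, and
to the desk scale (64 pixels, 16 representation units, 16 training images,
30 passes) for everything involving training — the test suite and the
reproduction script use these sizes.  All stochastic components (weight
initialisation, dataset generation, noise draws, presentation order) are
pure functions of their seed.

**Reconstruction readout.**  The reconstructed image is
W applied to the L5 rates *time-averaged over the final quarter of the
presentation* (clipped to [0, 1]).  With a residual rhythm a single-step
snapshot depends on the oscillation phase and is markedly worse than the
integrated readout; averaging is the natural model of a perceptual readout
that integrates over a few hundred milliseconds.

## Known limitations

* Unit within-motif weights make several valid circuits functionally
  degenerate (zero top-down sensitivity); heterogeneity in those weights
  would lift the degeneracy but is out of scope.
* The representation circuit is leaky, so prediction errors settle at a
  small non-zero residual within a presentation; training, not inference,
  drives them toward zero across passes.
* No single valid circuit reproduces the full idealised silencing taxonomy
  together with learnability: with unit weights, a learnable PE+ channel
  (net negative top-down sensitivity) excludes the unmasked positive
  top-down loop that would make a PV clamp divergent, and the trained
  desk-scale operating point is at the oscillatory instability, so the
  control run classifies as sustained rather than damped.  The directional
  silencing effects (listed above) are robust.
* The negative-error channel does not descend monotonically from the first
  pass: it starts near zero and rises toward the PE+/PE- balance.
* Oddball deviance enhancement and omission responses require state or
  predictions that persist across the inter-stimulus interval; with a
  20 ms time constant and no slow variables, this implementation has no
  such memory, so those two mismatch phenomena are limited to the
  transient-carryover effects described under the protocols.
* The oscillation frequency depends on the composition of the inter-area
  loop and on the trained weight gain; it is reported, not imposed, and
  its exact value varies with the frozen motif and training conditions.
* No spiking, conduction delays, topographic receptive fields, colour, or
  inhibitory plasticity; two cortical areas only.
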