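# Methods

## Model

The dentate gyrus is modeled as the hidden layer of a single restricted
Boltzmann machine: 200 binary visible units (entorhinal input) reciprocally
connected to 1000 binary hidden units (granule cells), no within-layer
connections. Conditional activation probabilities are logistic:
p(h_j = 1 | v) = σ(b_j + Σ_i v_i W_ij) and p(v_i = 1 | h) = σ(a_i + Σ_j h_j W_ij).

Learning is one-shot contrastive divergence (CD-1). For each mini-batch a
single brief Gibbs pass is taken: hidden states are sampled from the data,
visible states are sampled from those hidden states, and the hidden layer is
driven once more by that reconstruction. The chain is always driven by binary
Bernoulli samples. The learning *statistics*, however, use the hidden
activation probabilities rather than the samples (the lower-variance
estimator commonly recommended for CD); a `stats="sample"` switch restores
fully sampled statistics. The update, applied per hidden unit j with its own
learning rate ε_j, weight decay λ_j, and sparsity cost:

    ΔW_ij = ε_j (⟨v_i h_j⟩_data − ⟨v_i h_j⟩_recon) − λ_j W_ij − cost_j (q_j − p)
    Δb_j  = ε_j (⟨h_j⟩_data − ⟨h_j⟩_recon) − cost_j (q_j − p)
    Δa_i  = mean(ε) (⟨v_i⟩_data − ⟨v_i⟩_recon)

q_j is the batch-mean data-driven hidden activation and p = 0.05 the target
activation probability. The sparsity penalty is the subtractive form applied
to every incoming weight and the hidden bias of unit j; visible biases carry
no sparsity term. After every update the weight matrix is multiplied
elementwise by the binary connectivity mask, so absent synapses stay exactly
zero. Weights initialize i.i.d. N(0, 0.01²); biases start at zero. Weight
decay defaults to 2e-4 for the neurogenesis variants and 0 for the base and
sparse variants, whose update rules carry no decay term.

## Maturation

Each hidden unit has an age t ∈ [−1, 1] (newborn → mature) mapped through the
Gompertz curve g(t) = exp(−exp(−s t)), s = 5, to its parameters:
ε(t) = 0.1 + 0.2(1 − g(t)), cost(t) = 0.9 g(t), and target connectivity
0.3 + 0.7 g(t). In the neurogenesis variants initial ages are uniform on
[−1, 1]; in the sparsely connected variant each unit's mask column is drawn
Bernoulli at its age's target connectivity.

Between sessions, ages advance by dt and parameters are recomputed.
**dt = 0.05 by default**: adult-born granule cells take roughly five weeks to
traverse the modeled maturation window, so with sessions about a day apart a
newborn matures over ~40 sessions; the protocol's 10 between-group gaps then
advance a unit through about a quarter of its trajectory, leaving the
population heterogeneous throughout. (Larger steps such as dt = 0.2 fully
mature the whole population by the final session, which turns the retroactive
curve's recency effect into a primacy effect and lowers multi-session
accuracy.)

Connectivity growth is probabilistic and monotone: a unit at connected
fraction c with age target f > c switches each disconnected entry on
independently with probability (f − c)/(1 − c), so the expected fraction
lands on the target; new connections get fresh N(0, 0.01²) weights.

Turnover replaces exactly floor(0.05 · n_hidden) units per inter-session
step. Units are scored Z = (0.2 S + 0.65 D + 0.15 A)/1.0 with S the mean
absolute incoming weight over connected synapses, D their standard deviation
(0 with fewer than two connections), A the age rescaled to [0, 1]; each
component is min-max normalized across the population first, because the raw
scales differ by orders of magnitude and the age term would otherwise swamp
the weight terms. The lowest-Z units (ties broken by index) are reset to
newborn age, fresh random weights, zero hidden bias, and — in the sparsely
connected variant — a newborn-fraction mask column. Population size is
conserved (replacement, not additive neurogenesis).

## Synthetic data

Patterns emulate entorhinal input at 10% activation density. Five class
seeds are drawn with each of 200 elements independently active with
probability 0.1. Ten subclass prototypes per class are made by re-drawing
("resetting") a uniformly chosen 20% of the seed's elements at base density —
resetting rather than flipping keeps expected density at 0.1. The seed counts
as subclass 0, giving 55 prototypes. Each prototype yields 18 training and 4
candidate test instances by resetting 5% of elements. Training patterns form
11 groups of 90 (group k = subclass k of every class); 200 test patterns are
drawn without replacement from the 220 candidates, stratified so every group
keeps 18 (two randomly chosen groups keep 19).

What the generator does *not* emulate: real grid/place-cell statistics,
temporal autocorrelation, or any within-pattern spatial structure — patterns
are exchangeable Bernoulli vectors with a two-level similarity hierarchy.
Passing tests therefore demonstrate interference behavior for abstract
overlapping sparse codes, not for realistic entorhinal drive.

## Protocol and evaluation

Groups are learned sequentially, each in 18 class-balanced mini-batches of 5
(class order fixed, within-class order shuffled), one CD-1 update per batch,
one pass per pattern. In the same-session regime nothing happens between
groups; in the multi-session regime each of the 10 gaps applies age advance,
connectivity growth (sparsely connected variant only), and turnover, in that
order.

Reconstruction accuracy is the percent match M = 1 − D/l between a test
pattern and its one-pass reconstruction, where D is the Hamming distance.
The experiment protocol reconstructs **stochastically** (Bernoulli samples at
both layers, exactly matching the training-time brief Gibbs pass); a
deterministic mean-field mode (probabilities at both layers, visible
probabilities thresholded at 0.5, ties reconstructing as 1) is available and
is the default of the standalone `evaluate` function. Sampled evaluation is
the protocol default because the percent match is meant to approximate the
model's reconstruction log-likelihood, which the thresholded mean-field pass
systematically overstates — it hides all posterior uncertainty and saturates
near ceiling for every variant, erasing the differences between models the
experiment is designed to measure.

Pattern separation: hidden mean-field activations are binarized at 0.5 and
overlap between two active sets A, B is |A∩B| / ((|A|+|B|)/2), averaged over
all test-pattern pairs; empty-vs-empty pairs contribute 0.

Model comparison: within each repetition all variants train on the same
freshly generated dataset, so the bootstrap operates on paired differences.
The 95% interval is the 2.5–97.5 percentile range of 10,000 resampled means
of the paired differences; a comparison is significant when the interval
excludes zero.

## Problem sizes and numerics

Headline runs use the full configuration — 200×1000 machines, 990/200
splits, 20 repetitions — for the same-session (four variants) and
multi-session (neurogenesis variants) regimes; the two sweeps take a few
minutes on one CPU. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (one child per repetition, one
grandchild per dataset and per variant), making every run bit-reproducible.
Degenerate cases are fixed deterministically: mean-field ties reconstruct as
1; units with fewer than two connected synapses have differentiation 0;
turnover replaces at least one unit (with a warning) when 5% of the
population rounds to zero; Z ties break by unit index.

## Known limitations

* The base (non-sparse) RBM reconstructs these patterns at ~0.93 under this
  protocol; differences between the base and sparse models are driven mostly
  by the sparsity penalty's under-training of the sparse model early on.
* Neurogenesis is replacement-only; additive growth and regulation of the
  turnover rate are out of scope.
* A single RBM cannot express the full EC→DG→CA3 circuit; reciprocal
  visible–hidden connectivity is an architectural simplification of the
  perforant path.
* Evaluation reconstructs from a single Gibbs pass; longer chains (CD-k,
  k > 1) are available in configuration, but the standard protocol fixes
  k = 1 and all reported quantities use it.
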