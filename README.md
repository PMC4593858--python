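# dgrbm — a dentate-gyrus RBM with adult neurogenesis

`dgrbm` is a computational model of the hippocampal dentate gyrus (DG) built
on a single-layer restricted Boltzmann machine (RBM), for studying how the
developmental trajectory of adult-born granule cells affects memory
interference. The visible layer plays the role of entorhinal-cortex (EC)
input; the hidden layer plays the role of the DG granule cells (DGCs). The
package generates hierarchical binary input patterns, trains four model
variants with one-shot contrastive divergence, and measures proactive and
retroactive interference and pattern separation, with paired bootstrap
comparisons between models.

## The model

Training uses CD-1: a single brief Gibbs pass yields the data-driven pair
(v, h) and the reconstruction-driven pair (v′, h′), and the weight update is

```
ΔW_ij = ε_j ( ⟨v_i h_j⟩_data − ⟨v_i h_j⟩_recon ) − λ_j W_ij − cost_j (q_j − p)
```

with three per-hidden-unit constraints that encode DGC biology:

* **plasticity** — the learning rate ε_j of young cells is high (0.3) and
  falls to 0.1 at maturity;
* **lateral inhibition (sparse coding)** — the penalty `cost_j (q_j − p)`
  pushes each unit's mean activation q_j toward a small target p = 0.05;
  it is negligible for young cells and reaches 0.9 at maturity;
* **sparse connectivity** — a binary mask zeroes absent perforant-path
  synapses; newborn units connect to ~30% of the visible layer and densify
  with age. The mask multiplies W after every update.

Each hidden unit carries an age t ∈ [−1, 1] mapped through the Gompertz
growth curve g(t) = exp(−exp(−s·t)), s = 5:

```
ε(t)    = 0.1 + 0.2 · (1 − g(t))
cost(t) = 0.9 · g(t)
conn(t) = 0.3 + 0.7 · g(t)
```

Between sessions (multi-session regime) all ages advance, connectivity grows
probabilistically toward its age target, and the least useful 5% of units
undergo simulated apoptosis and are replaced by newborns. Units are ranked by

```
Z_i = (α·Strength_i + β·Differentiation_i + γ·Age_i) / (α + β + γ)
```

with α, β, γ = 0.2, 0.65, 0.15, where Strength is the mean |w| of a unit's
incoming weights, Differentiation their standard deviation, and each
component is min-max normalized across the population.

**Model variants.** `base` (no sparsity), `sparse` (sparse coding only),
`neuro` (heterogeneous ages, full connectivity), `neuro_sparse_conn`
(heterogeneous ages plus age-dependent sparse connectivity).

**The task.** 200-dimensional binary patterns at 10% density: 5 class seeds,
11 subclass prototypes per class (20% of elements re-drawn), 18 training and
~4 test instances per prototype (5% re-drawn). The 990 training patterns form
11 session groups of 90 (one prototype per class per group), learned
sequentially in mini-batches of 5 (one pattern per class), one pass per
pattern. Accuracy on a group's test patterns right after that group probes
proactive interference; accuracy on all groups after training probes
retroactive interference. Reconstruction accuracy is the percent match
`M = 1 − D/l` where D is the Hamming distance between a test pattern and its
one-pass reconstruction. Pattern separation is the mean pairwise overlap
|A∩B| / ((|A|+|B|)/2) of hidden codes binarized at 0.5.

## Worked example

```python
from dgrbm import ExperimentConfig, InterferenceExperiment

cfg = ExperimentConfig(variants=["sparse", "neuro"], regime="same",
                       n_repetitions=5, seed=7)
res = InterferenceExperiment(cfg).fit()
print(res.post_means().round(3))
print(res.summary().round(3).to_string(index=False))
```

prints

```
variant
sparse    0.851
neuro     0.933
Name: post_mean, dtype: float64

regime model_a model_b  mean_a  mean_b  mean_diff  ci_low  ci_high  significant
  same  sparse   neuro   0.851   0.933      0.082   0.077    0.087         True
```

The grand-mean post-training reconstruction accuracy of the sparse-coding
RBM is 0.851; adding neurogenesis (a mixture of young, plastic, weakly
inhibited units among mature ones) lifts it to 0.933, and the paired
bootstrap 95% interval of the difference, (0.077, 0.087), excludes zero —
the improvement is significant across the 5 paired repetitions.

The same experiment is available from the shell:

```bash
dgrbm generate --out data --seed 1                 # pattern files + labels
dgrbm run --out results --seed 1 --variants sparse,neuro --regime same --reps 5
dgrbm report results                               # four figures + summary
```

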