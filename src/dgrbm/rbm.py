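"""Single-layer restricted Boltzmann machine with per-unit plasticity.

The visible layer models binary entorhinal-cortex input; the hidden layer
models dentate granule cells. Training is one-shot contrastive divergence
(CD-1, a single brief Gibbs pass), extended with three biologically motivated
constraints, each carried per hidden unit so that young and mature cells
learn differently:

* a per-unit learning rate (young cells are more plastic),
* a per-unit sparse-coding penalty pushing the unit's mean activation toward
  a small target probability (lateral inhibition of mature cells),
* a binary connectivity mask zeroing absent perforant-path synapses (young
  cells are sparsely connected); the mask is re-applied after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .maturation import MaturationSchedule, unit_params

__all__ = [
    "VARIANTS",
    "RBMState",
    "init_rbm",
    "sample_hidden",
    "sample_visible",
    "cd1_update",
    "reconstruct",
]

#: Model variants: plain RBM, sparse-coding RBM, neurogenesis (heterogeneous
#: ages, full connectivity), and neurogenesis with age-dependent sparse
#: connectivity.
VARIANTS = ("base", "sparse", "neuro", "neuro_sparse_conn")

_NEURO = ("neuro", "neuro_sparse_conn")


@dataclass
class RBMState:
    """Complete state of the model.

    ``W`` is visible-by-hidden; ``mask`` has the same shape and every masked
    (0) entry of ``W`` is exactly 0. ``age``, ``epsilon``, ``decay`` and
    ``cost`` are per-hidden-unit vectors; for the non-neurogenesis variants
    ``age`` is pinned at maturity and never used.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mask: np.ndarray
    age: np.ndarray
    epsilon: np.ndarray
    decay: np.ndarray
    cost: np.ndarray
    p_target: float = 0.05
    sigma_init: float = 0.01
    sparse_connectivity: bool = False
    variant: str = "base"
    t_min: float = -1.0
    t_max: float = 1.0

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMState":
        return RBMState(
            W=self.W.copy(), a=self.a.copy(), b=self.b.copy(), mask=self.mask.copy(),
            age=self.age.copy(), epsilon=self.epsilon.copy(), decay=self.decay.copy(),
            cost=self.cost.copy(), p_target=self.p_target, sigma_init=self.sigma_init,
            sparse_connectivity=self.sparse_connectivity, variant=self.variant,
            t_min=self.t_min, t_max=self.t_max,
        )

    def save(self, path) -> None:
        """Checkpoint every array and scalar hyper-parameter to a ``.npz``."""
        np.savez(
            path,
            W=self.W, a=self.a, b=self.b, mask=self.mask, age=self.age,
            epsilon=self.epsilon, decay=self.decay, cost=self.cost,
            p_target=self.p_target, sigma_init=self.sigma_init,
            sparse_connectivity=self.sparse_connectivity,
            variant=np.asarray(self.variant), t_min=self.t_min, t_max=self.t_max,
        )

    @classmethod
    def load(cls, path) -> "RBMState":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                W=f["W"], a=f["a"], b=f["b"], mask=f["mask"], age=f["age"],
                epsilon=f["epsilon"], decay=f["decay"], cost=f["cost"],
                p_target=float(f["p_target"]), sigma_init=float(f["sigma_init"]),
                sparse_connectivity=bool(f["sparse_connectivity"]),
                variant=str(f["variant"]), t_min=float(f["t_min"]), t_max=float(f["t_max"]),
            )


def init_rbm(
    n_visible: int,
    n_hidden: int,
    variant: str = "base",
    rng: Optional[np.random.Generator] = None,
    *,
    schedule: Optional[MaturationSchedule] = None,
    p_target: float = 0.05,
    learning_rate: float = 0.1,
    sparse_cost: float = 0.9,
    weight_decay: float = 2e-4,
    sigma_init: float = 0.01,
) -> RBMState:
    """Create a fresh model for one of the four variants.

    Weights are i.i.d. zero-mean Gaussian with spread ``sigma_init``; biases
    start at zero. ``base``: constant learning rate, no sparsity cost.
    ``sparse``: constant learning rate, sparsity cost ``sparse_cost``.
    ``neuro`` / ``neuro_sparse_conn``: hidden-unit ages drawn uniformly on
    the maturation interval with learning rate and sparsity cost from the
    Gompertz mapping; the sparse-connectivity variant additionally draws a
    per-unit connectivity mask at the age-determined fraction. Weight decay
    applies to the neurogenesis variants only (the plain CD-1 and
    sparse-coding rules carry no decay term).
    """
    if n_visible < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be positive")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = np.random.default_rng() if rng is None else rng
    sched = schedule if schedule is not None else MaturationSchedule()

    W = rng.normal(0.0, sigma_init, (n_visible, n_hidden))
    a = np.zeros(n_visible)
    b = np.zeros(n_hidden)
    mask = np.ones((n_visible, n_hidden), dtype=np.int8)

    if variant in _NEURO:
        age = rng.uniform(sched.t_min, sched.t_max, n_hidden)
        epsilon, cost, conn = unit_params(age, sched)
        decay = np.full(n_hidden, weight_decay)
        if variant == "neuro_sparse_conn":
            mask = (rng.random((n_visible, n_hidden)) < conn[None, :]).astype(np.int8)
            W *= mask
    else:
        age = np.full(n_hidden, sched.t_max)
        epsilon = np.full(n_hidden, learning_rate)
        cost = np.zeros(n_hidden) if variant == "base" else np.full(n_hidden, sparse_cost)
        decay = np.zeros(n_hidden)

    return RBMState(
        W=W, a=a, b=b, mask=mask, age=age, epsilon=epsilon, decay=decay, cost=cost,
        p_target=p_target, sigma_init=sigma_init,
        sparse_connectivity=(variant == "neuro_sparse_conn"), variant=variant,
        t_min=sched.t_min, t_max=sched.t_max,
    )


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return x


def sample_hidden(state: RBMState, v: np.ndarray, rng: np.random.Generator):
    """Hidden activation probabilities and Bernoulli samples given visibles.

    ``p(h_j = 1 | v) = sigma(b_j + sum_i v_i W_ij)``. ``v`` may be a single
    pattern or a batch (rows). Masked weights are exactly zero and contribute
    nothing.
    """
    v = np.atleast_2d(_check_binary(v, "v"))
    if v.shape[1] != state.n_visible:
        raise ValueError(f"expected {state.n_visible} visible units, got {v.shape[1]}")
    probs = expit(state.b + v @ state.W)
    samples = (rng.random(probs.shape) < probs).astype(float)
    return probs, samples


def sample_visible(state: RBMState, h: np.ndarray, rng: np.random.Generator):
    """Visible probabilities and samples given hiddens:
    ``p(v_i = 1 | h) = sigma(a_i + sum_j h_j W_ij)``."""
    h = np.atleast_2d(_check_binary(h, "h"))
    if h.shape[1] != state.n_hidden:
        raise ValueError(f"expected {state.n_hidden} hidden units, got {h.shape[1]}")
    probs = expit(state.a + h @ state.W.T)
    samples = (rng.random(probs.shape) < probs).astype(float)
    return probs, samples


def cd1_update(
    state: RBMState,
    v_batch: np.ndarray,
    rng: np.random.Generator,
    stats: str = "prob",
    k: int = 1,
) -> RBMState:
    """One constrained CD-1 update on a mini-batch, in place.

    A single brief Gibbs pass produces the data-driven and reconstructed
    states: hiddens sampled from the data, visibles sampled from those
    hiddens, hiddens driven once more by the reconstruction. The chain is
    always driven by binary Bernoulli samples; ``stats`` selects what enters
    the learning statistics. With ``stats="prob"`` (default) the Hebbian
    terms, bias updates and the sparsity activation ``q`` use the hidden
    activation *probabilities* — the lower-variance estimator usually
    recommended for CD — while ``stats="sample"`` uses the binary samples
    themselves. With ``q_j`` the batch-mean data-driven hidden activation and
    ``p`` the target activation probability, the update is

        dW_ij = eps_j (<v_i h_j>_data - <v_i h_j>_recon)
                - lambda_j W_ij - cost_j (q_j - p)
        db_j  = eps_j (<h_j>_data - <h_j>_recon) - cost_j (q_j - p)
        da_i  = mean(eps) (<v_i>_data - <v_i>_recon)

    after which W is multiplied elementwise by the connectivity mask, so
    disconnected synapses stay exactly zero. ``k`` extends the chain to CD-k;
    the default single step is used throughout the standard protocol.
    """
    if stats not in ("prob", "sample"):
        raise ValueError(f"unknown stats {stats!r}; expected 'prob' or 'sample'")
    if k < 1:
        raise ValueError("k must be a positive number of Gibbs steps")
    v_data = np.atleast_2d(_check_binary(v_batch, "v_batch"))
    if v_data.shape[1] != state.n_visible:
        raise ValueError(f"expected {state.n_visible} visible units, got {v_data.shape[1]}")
    n = v_data.shape[0]

    hp_data, h_data = sample_hidden(state, v_data, rng)
    h_chain = h_data
    for _ in range(k):
        _, v_recon = sample_visible(state, h_chain, rng)
        hp_recon, h_recon = sample_hidden(state, v_recon, rng)
        h_chain = h_recon

    hd = hp_data if stats == "prob" else h_data
    hr = hp_recon if stats == "prob" else h_recon

    q = hd.mean(axis=0)
    sparsity = state.cost * (q - state.p_target)

    hebb = (v_data.T @ hd - v_recon.T @ hr) / n
    state.W += state.epsilon * hebb - state.decay * state.W - sparsity
    state.b += state.epsilon * (hd.mean(axis=0) - hr.mean(axis=0)) - sparsity
    state.a += state.epsilon.mean() * (v_data.mean(axis=0) - v_recon.mean(axis=0))
    state.W *= state.mask
    return state


def reconstruct(
    state: RBMState,
    v: np.ndarray,
    mode: str = "mean_field",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One up-down pass returning a binary reconstruction of ``v``.

    ``mean_field`` propagates probabilities through both layers and
    thresholds the visible probabilities at 0.5 (ties reconstruct as 1),
    which is deterministic; ``stochastic`` uses Bernoulli samples at both
    layers, matching the training-time sampling.
    """
    v_arr = np.atleast_2d(_check_binary(v, "v"))
    if mode == "mean_field":
        h_prob = expit(state.b + v_arr @ state.W)
        v_prob = expit(state.a + h_prob @ state.W.T)
        out = (v_prob >= 0.5).astype(float)
    elif mode == "stochastic":
        if rng is None:
            rng = np.random.default_rng()
        _, h = sample_hidden(state, v_arr, rng)
        _, out = sample_visible(state, h, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'mean_field' or 'stochastic'")
    return out[0] if np.asarray(v).ndim == 1 else out
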