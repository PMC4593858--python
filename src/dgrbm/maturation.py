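"""Age-dependent properties of dentate granule cells.

Adult-born granule cells follow a developmental trajectory: young cells are
highly plastic, weakly regulated by lateral inhibition, and sparsely connected
to their perforant-path inputs; over several weeks they mature into sparsely
firing, densely connected cells. This module maps a per-unit age parameter
``t`` on [-1, 1] through a Gompertz growth curve to the per-unit learning
rate, sparsity cost, and target connectivity, advances ages between learning
sessions, grows connectivity probabilistically, and implements the
replacement-style turnover rule that recycles the least useful 5% of units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .rbm import RBMState

__all__ = [
    "MaturationSchedule",
    "TurnoverPolicy",
    "gompertz",
    "unit_params",
    "advance_age",
    "grow_connectivity",
    "rank_units",
    "apply_turnover",
]


@dataclass
class MaturationSchedule:
    """Maps unit age to plasticity, inhibition, and connectivity.

    Parameters
    ----------
    s : float
        Gompertz shape/steepness. The growth curve is ``g(t) = exp(-exp(-s*t))``.
    t_min, t_max : float
        Age bounds. A newborn unit has ``t = t_min``; a fully mature unit
        ``t = t_max``.
    eps_min, eps_max : float
        Learning-rate bounds. Plasticity is ``eps_min + (eps_max - eps_min)
        * (1 - g(t))``: newborn units learn at ``eps_max``, mature units at
        ``eps_min``.
    cost_max : float
        Sparsity cost of a fully mature unit; the cost is ``cost_max * g(t)``,
        so newborn units are essentially free of the sparse-coding penalty.
    conn_min, conn_max : float
        Newborn and mature fractions of visible units each hidden unit is
        connected to (sparse-connectivity variants only).
    dt : float
        Age increment applied between sessions. The default 0.05 lets a
        newborn unit traverse the full maturation interval in ~40 sessions,
        matching the several-week developmental trajectory of adult-born
        granule cells when sessions are about a day apart.
    """

    s: float = 5.0
    t_min: float = -1.0
    t_max: float = 1.0
    eps_min: float = 0.1
    eps_max: float = 0.3
    cost_max: float = 0.9
    conn_min: float = 0.3
    conn_max: float = 1.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be strictly below t_max")
        if not self.eps_min < self.eps_max:
            raise ValueError("eps_min must be strictly below eps_max")
        if not (0.0 < self.conn_min <= self.conn_max <= 1.0):
            raise ValueError("connectivity fractions must satisfy 0 < conn_min <= conn_max <= 1")


@dataclass
class TurnoverPolicy:
    """Weights of the survival ranking and the replaced fraction.

    Each hidden unit is scored ``Z = (alpha*Strength + beta*Differentiation
    + gamma*Age) / (alpha + beta + gamma)`` where Strength is the mean
    absolute incoming weight, Differentiation the standard deviation of the
    incoming weights, and Age the unit age normalized to [0, 1]; each
    component is min-max normalized across the population before weighting.
    The lowest-scoring ``fraction`` of units undergo simulated apoptosis and
    are replaced by newborn units.
    """

    alpha: float = 0.2
    beta: float = 0.65
    gamma: float = 0.15
    fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("ranking weights must be positive")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("replacement fraction must lie in (0, 1)")


def gompertz(t, s: float = 5.0):
    """Gompertz growth curve ``g(t) = exp(-exp(-s*t))``.

    Strictly increasing in ``t`` and bounded in (0, 1) for ``s > 0``.
    Accepts scalars or arrays.
    """
    return np.exp(-np.exp(-s * np.asarray(t, dtype=float)))


def unit_params(age_t, sched: MaturationSchedule):
    """Per-unit (learning rate, sparsity cost, target connectivity) at age ``t``.

    Ages are clipped to ``[t_min, t_max]``. Plasticity decreases and the
    sparse-coding cost and connectivity increase monotonically with age.
    """
    t = np.clip(np.asarray(age_t, dtype=float), sched.t_min, sched.t_max)
    g = gompertz(t, sched.s)
    eps = sched.eps_min + (sched.eps_max - sched.eps_min) * (1.0 - g)
    cost = sched.cost_max * g
    conn = sched.conn_min + (sched.conn_max - sched.conn_min) * g
    return eps, cost, conn


def advance_age(state: "RBMState", sched: MaturationSchedule) -> "RBMState":
    """Increment every hidden unit's age by ``sched.dt`` (clipped at ``t_max``)
    and recompute the per-unit learning rates and sparsity costs in place."""
    state.age = np.clip(state.age + sched.dt, sched.t_min, sched.t_max)
    eps, cost, _ = unit_params(state.age, sched)
    state.epsilon = eps
    state.cost = cost
    return state


def grow_connectivity(state: "RBMState", sched: MaturationSchedule, rng: np.random.Generator) -> "RBMState":
    """Probabilistically densify each unit's perforant-path connectivity.

    For each hidden unit with current connected fraction ``c`` below its
    age-determined target ``f``, every disconnected entry switches on
    independently with probability ``(f - c) / (1 - c)`` so the expected
    fraction after the call equals the target. Connections never switch off;
    newly connected entries receive fresh small random weights.
    """
    _, _, targets = unit_params(state.age, sched)
    n_visible = state.mask.shape[0]
    current = state.mask.mean(axis=0)
    deficit = targets - current
    grow = np.flatnonzero((deficit > 0) & (current < 1.0))
    for j in grow:
        p_on = deficit[j] / (1.0 - current[j])
        off = np.flatnonzero(state.mask[:, j] == 0)
        switch = off[rng.random(off.size) < p_on]
        if switch.size:
            state.mask[switch, j] = 1
            state.W[switch, j] = rng.normal(0.0, state.sigma_init, switch.size)
    return state


def rank_units(state: "RBMState", policy: TurnoverPolicy) -> np.ndarray:
    """Survival score Z for every hidden unit (higher = more likely to survive).

    Strength is the mean |w| over a unit's connected incoming weights,
    Differentiation their standard deviation (0 when fewer than two
    connections), and Age the unit age rescaled to [0, 1]. Each component is
    min-max normalized across units before the weighted average so that the
    three terms are scale-comparable.
    """
    mask = state.mask.astype(bool)
    n_conn = mask.sum(axis=0)
    safe = np.maximum(n_conn, 1)

    absW = np.abs(state.W) * mask
    strength = absW.sum(axis=0) / safe

    mean_w = (state.W * mask).sum(axis=0) / safe
    var = ((state.W - mean_w) ** 2 * mask).sum(axis=0) / safe
    differentiation = np.where(n_conn >= 2, np.sqrt(var), 0.0)

    age = (state.age - state.t_min) / (state.t_max - state.t_min)

    def _minmax(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi - lo == 0:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    total = policy.alpha + policy.beta + policy.gamma
    z = (
        policy.alpha * _minmax(strength)
        + policy.beta * _minmax(differentiation)
        + policy.gamma * _minmax(age)
    ) / total
    return z


def apply_turnover(
    state: "RBMState",
    policy: TurnoverPolicy,
    sched: MaturationSchedule,
    rng: np.random.Generator,
) -> "RBMState":
    """Replace the lowest-ranked fraction of hidden units with newborn units.

    Exactly ``floor(fraction * n_hidden)`` units (at least one) with the
    lowest Z scores are reset: age back to newborn (``t_min``), incoming
    weights redrawn at the initialization scale, hidden bias set to 0, and —
    for sparsely connected variants — the connectivity column redrawn at the
    newborn fraction. Ties in Z are broken by unit index (lower index first).
    Population size is conserved: this is a replacement model, not additive
    neurogenesis.
    """
    n_hidden = state.W.shape[1]
    k = int(np.floor(policy.fraction * n_hidden))
    if k < 1:
        warnings.warn(
            "fraction * n_hidden < 1; replacing a single unit", stacklevel=2
        )
        k = 1
    z = rank_units(state, policy)
    idx = np.argsort(z, kind="stable")[:k]

    n_visible = state.W.shape[0]
    eps_new, cost_new, conn_new = unit_params(sched.t_min, sched)
    state.age[idx] = sched.t_min
    state.epsilon[idx] = eps_new
    state.cost[idx] = cost_new
    state.b[idx] = 0.0
    if state.sparse_connectivity:
        state.mask[:, idx] = (rng.random((n_visible, k)) < conn_new).astype(state.mask.dtype)
    else:
        state.mask[:, idx] = 1
    state.W[:, idx] = rng.normal(0.0, state.sigma_init, (n_visible, k)) * state.mask[:, idx]
    return state
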