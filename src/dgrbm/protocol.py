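"""The interference experiment: group-wise one-shot training and evaluation.

Models learn 11 successive groups of 90 overlapping patterns (one prototype
per class per group) in mini-batches of 5, a single pass per pattern.
Accuracy on a group's noisy test patterns immediately after that group probes
proactive interference; accuracy on every group after all training probes
retroactive interference. In the multi-session regime, simulated time passes
between groups: hidden-unit ages advance, sparse connectivity grows, and the
least useful 5% of units turn over. Reconstruction accuracy is the percent
match (one minus the normalized Hamming distance) between a test pattern and
its one-pass reconstruction (sampled, matching the training-time brief Gibbs
pass, by default; mean-field optionally); pattern separation is measured as
the mean pairwise overlap of binarized hidden codes. Models are compared with a paired
percentile bootstrap over repetitions, each repetition using a freshly
generated dataset shared by all models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ExperimentConfig
from .maturation import advance_age, apply_turnover, grow_connectivity
from .patterns import PatternSet, build_dataset
from .rbm import RBMState, cd1_update, init_rbm, reconstruct

__all__ = [
    "hamming",
    "percent_match",
    "evaluate",
    "hidden_overlap",
    "train_group",
    "bootstrap_compare",
    "run_experiment",
    "InterferenceExperiment",
    "InterferenceResults",
]


def hamming(v1: np.ndarray, v2: np.ndarray) -> float:
    """Number of positions at which two equal-length binary vectors differ."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    return float(np.abs(v1 - v2).sum())


def percent_match(v1: np.ndarray, v2: np.ndarray) -> float:
    """1 - hamming/length: the fraction of positions on which two vectors agree."""
    v1 = np.asarray(v1)
    if v1.size == 0:
        raise ValueError("vectors must be non-empty")
    return 1.0 - hamming(v1, v2) / v1.size


def evaluate(
    state: RBMState,
    patterns: np.ndarray,
    mode: str = "mean_field",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean percent match between patterns and their reconstructions.

    In ``mean_field`` mode (default) the result is deterministic for a fixed
    state: the pass involves no sampling. ``stochastic`` mode reconstructs
    with Bernoulli samples at both layers, matching the training-time brief
    Gibbs sampling; the experiment protocol evaluates this way.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise ValueError("needs at least one pattern")
    recon = reconstruct(state, patterns, mode=mode, rng=rng)
    return float(1.0 - np.abs(patterns - recon).mean())


def _pairwise_overlap(codes: np.ndarray) -> float:
    """Mean pairwise overlap |A∩B| / ((|A|+|B|)/2) over binary code rows.

    Pairs in which both active sets are empty contribute 0.
    """
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("needs at least two codes")
    inter = codes @ codes.T
    sizes = codes.sum(axis=1)
    denom = (sizes[:, None] + sizes[None, :]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ov = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    iu = np.triu_indices(n, k=1)
    return float(ov[iu].mean())


def hidden_overlap(state: RBMState, patterns: np.ndarray) -> float:
    """Mean pairwise overlap of the hidden codes elicited by the patterns.

    Hidden mean-field activations are binarized at 0.5; overlap between two
    active-unit sets A, B is |A∩B| normalized by their mean size, averaged
    over all pattern pairs. Lower overlap = stronger pattern separation.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    h_prob = expit(state.b + patterns @ state.W)
    return _pairwise_overlap((h_prob >= 0.5).astype(float))


def train_group(
    state: RBMState,
    patterns: np.ndarray,
    classes: np.ndarray,
    rng: np.random.Generator,
    test_patterns: Optional[np.ndarray] = None,
    batch_size: int = 5,
    cd_stats: str = "prob",
    cd_k: int = 1,
    eval_mode: str = "mean_field",
) -> Tuple[RBMState, Optional[float]]:
    """One-shot training on one session group, in class-balanced mini-batches.

    The group must contain an equal number of patterns from each class. Each
    mini-batch holds one pattern per class (class order fixed, within-class
    order shuffled by ``rng``); every batch is passed to the CD-1 update
    exactly once. If ``test_patterns`` is given, returns the during-training
    accuracy on them after the group, measured in ``eval_mode``.
    """
    patterns = np.asarray(patterns, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    if len(labels) != batch_size:
        raise ValueError("batch size must equal the number of classes in the group")
    per_class = len(patterns) // len(labels)
    order = []
    for c in labels:
        idx = np.flatnonzero(classes == c)
        if idx.size != per_class:
            raise ValueError("group must contain equally many patterns per class")
        order.append(rng.permutation(idx))
    order = np.stack(order)  # [class, batch]
    for i in range(per_class):
        cd1_update(state, patterns[order[:, i]], rng, stats=cd_stats, k=cd_k)
    during = (
        evaluate(state, test_patterns, mode=eval_mode, rng=rng)
        if test_patterns is not None
        else None
    )
    return state, during


def bootstrap_compare(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, Tuple[float, float], bool]:
    """Paired percentile bootstrap of the mean accuracy difference (b - a).

    Resamples the paired differences with replacement ``n_boot`` times and
    returns (mean difference, 95% percentile interval, significant), where
    significant means the interval excludes zero.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("samples must be equal-length 1-d with n >= 2")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals", stacklevel=2)
    rng = np.random.default_rng() if rng is None else rng
    diff = b - a
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boots = diff[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    significant = bool(lo > 0 or hi < 0)
    return float(diff.mean()), (float(lo), float(hi)), significant


def _fresh_model(variant: str, config: ExperimentConfig, rng: np.random.Generator) -> RBMState:
    return init_rbm(
        config.n_visible, config.n_hidden, variant, rng,
        schedule=config.schedule, p_target=config.p_target,
        learning_rate=config.learning_rate, sparse_cost=config.sparse_cost,
        weight_decay=config.weight_decay, sigma_init=config.sigma_init,
    )


def _run_single(
    variant: str,
    regime: str,
    dataset: PatternSet,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> dict:
    """Train one model through all groups of one dataset; return its metrics."""
    state = _fresh_model(variant, config, rng)
    neuro = variant in ("neuro", "neuro_sparse_conn")
    n_groups = dataset.n_groups

    during = np.empty(n_groups)
    for g in range(n_groups):
        pats, cls = dataset.train_in_group(g)
        state, acc = train_group(
            state, pats, cls, rng, test_patterns=dataset.test_in_group(g),
            batch_size=config.batch_size, cd_stats=config.cd_stats,
            cd_k=config.cd_k, eval_mode=config.eval_mode,
        )
        during[g] = acc
        if regime == "multi" and neuro and g < n_groups - 1:
            advance_age(state, config.schedule)
            if state.sparse_connectivity:
                grow_connectivity(state, config.schedule, rng)
            apply_turnover(state, config.policy, config.schedule, rng)

    post = np.array([
        evaluate(state, dataset.test_in_group(g), mode=config.eval_mode, rng=rng)
        for g in range(n_groups)
    ])
    overall = evaluate(state, dataset.test, mode=config.eval_mode, rng=rng)
    overlap = hidden_overlap(state, dataset.test)
    return {"during": during, "post": post, "overall": overall, "overlap": overlap}


class InterferenceExperiment:
    """The full multi-model interference experiment.

    Built from an :class:`~dgrbm.config.ExperimentConfig`; ``fit()`` runs
    every configured model variant over ``n_repetitions`` freshly generated
    datasets (shared across variants within a repetition so comparisons are
    paired) and returns an :class:`InterferenceResults`.
    """

    def __init__(self, config: Optional[ExperimentConfig] = None, **overrides):
        if config is None:
            config = ExperimentConfig(**overrides)
        elif overrides:
            config = ExperimentConfig.from_dict({**config.to_dict(), **overrides})
        self.config = config

    def fit(self, progress: Optional[callable] = None) -> "InterferenceResults":
        cfg = self.config
        master = np.random.SeedSequence(cfg.seed)
        rep_seeds = master.spawn(cfg.n_repetitions)

        group_rows, rep_rows = [], []
        for rep, ss in enumerate(rep_seeds):
            data_ss, model_ss = ss.spawn(2)
            dataset = build_dataset(
                np.random.default_rng(data_ss),
                length=cfg.pattern_length, density=cfg.density,
                n_classes=cfg.n_classes, n_subclasses=cfg.n_subclasses,
                proto_reset=cfg.proto_reset, instance_reset=cfg.instance_reset,
                train_per_prototype=cfg.train_per_prototype,
                test_candidates_per_prototype=cfg.test_candidates_per_prototype,
                n_test=cfg.n_test,
            )
            for variant, var_ss in zip(cfg.variants, model_ss.spawn(len(cfg.variants))):
                res = _run_single(variant, cfg.regime, dataset, cfg, np.random.default_rng(var_ss))
                for g in range(dataset.n_groups):
                    group_rows.append({
                        "repetition": rep, "variant": variant, "regime": cfg.regime,
                        "group": g, "during_accuracy": res["during"][g],
                        "post_accuracy": res["post"][g],
                    })
                rep_rows.append({
                    "repetition": rep, "variant": variant, "regime": cfg.regime,
                    "post_mean": res["overall"], "hidden_overlap": res["overlap"],
                })
                if progress is not None:
                    progress(rep, variant)
        return InterferenceResults(
            cfg, pd.DataFrame(group_rows), pd.DataFrame(rep_rows)
        )


@dataclass
class InterferenceResults:
    """Results of a fitted interference experiment.

    ``per_group`` has one row per (repetition, variant, group) with the
    during-training (proactive) and post-training (retroactive) accuracies;
    ``per_rep`` has one row per (repetition, variant) with the grand-mean
    post-training accuracy over all test patterns and the hidden-code
    overlap. ``summary()`` gives Table-style paired bootstrap comparisons.
    """

    config: ExperimentConfig
    per_group: pd.DataFrame
    per_rep: pd.DataFrame

    def post_means(self) -> pd.Series:
        """Grand mean post-training accuracy per variant."""
        return self.per_rep.groupby("variant", sort=False)["post_mean"].mean()

    def overlap_means(self) -> pd.Series:
        """Mean hidden-code overlap per variant."""
        return self.per_rep.groupby("variant", sort=False)["hidden_overlap"].mean()

    def summary(
        self,
        pairs: Optional[Iterable[Tuple[str, str]]] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> pd.DataFrame:
        """Paired bootstrap comparison of post-training accuracy per model pair.

        Defaults to every ordered pair of configured variants (in config
        order). Columns mirror the usual summary table: the two means, the
        95% bootstrap CI of the difference, and a significance flag.
        """
        if pairs is None:
            pairs = list(itertools.combinations(self.config.variants, 2))
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence(self.config.seed).spawn(1)[0])
        wide = self.per_rep.pivot(index="repetition", columns="variant", values="post_mean")
        rows = []
        for a, b in pairs:
            mean_diff, (lo, hi), sig = bootstrap_compare(
                wide[a].to_numpy(), wide[b].to_numpy(), n_boot=self.config.n_boot, rng=rng
            )
            rows.append({
                "regime": self.config.regime, "model_a": a, "model_b": b,
                "mean_a": wide[a].mean(), "mean_b": wide[b].mean(),
                "mean_diff": mean_diff, "ci_low": lo, "ci_high": hi,
                "significant": sig,
            })
        return pd.DataFrame(rows)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"InterferenceExperiment ({self.config.regime}-session, "
                 f"{self.config.n_repetitions} repetitions)"]
        lines.append(self.post_means().rename("post-training accuracy").to_string())
        return "\n".join(lines)


def run_experiment(config: ExperimentConfig, progress: Optional[callable] = None) -> InterferenceResults:
    """Functional wrapper: ``InterferenceExperiment(config).fit()``."""
    return InterferenceExperiment(config).fit(progress=progress)
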