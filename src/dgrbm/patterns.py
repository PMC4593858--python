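"""Synthetic binary input patterns with nested class/subclass structure.

The visible layer receives 200-dimensional binary patterns emulating
entorhinal-cortex activity at 10% density. Five random class seeds are each
perturbed into 10 overlapping subclass prototypes (re-drawing 20% of the
elements), giving 55 prototypes; individual training and test patterns are
noisy instances of a prototype (re-drawing another 5%). Training patterns are
organized into 11 session groups of 90 — group k holds the instances of
subclass k from every class — so successive groups overlap heavily with
earlier ones, the design that elicits proactive and retroactive interference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatternSet",
    "make_class_seeds",
    "mutate",
    "build_dataset",
    "write_patterns",
    "read_patterns",
]


@dataclass
class PatternSet:
    """The generated dataset: prototypes, train/test instances, and labels.

    ``train`` / ``test`` are binary matrices (one pattern per row);
    ``train_class``, ``train_subclass`` and ``train_group`` (and their test
    counterparts) are parallel integer label vectors. Groups are numbered
    0..n_subclasses-1 and coincide with subclasses: group k contains the
    instances of every class's k-th prototype.
    """

    length: int
    density: float
    class_seeds: np.ndarray
    prototypes: np.ndarray
    prototype_class: np.ndarray
    prototype_subclass: np.ndarray
    train: np.ndarray
    train_class: np.ndarray
    train_subclass: np.ndarray
    train_group: np.ndarray
    test: np.ndarray
    test_class: np.ndarray
    test_subclass: np.ndarray
    test_group: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.train_group.max()) + 1

    def train_in_group(self, g: int):
        """(patterns, class labels) of training group ``g``."""
        sel = self.train_group == g
        return self.train[sel], self.train_class[sel]

    def test_in_group(self, g: int) -> np.ndarray:
        return self.test[self.test_group == g]


def make_class_seeds(
    rng: np.random.Generator, n_classes: int = 5, length: int = 200, density: float = 0.1
) -> np.ndarray:
    """Independent class seed patterns: each element active with ``density``."""
    return (rng.random((n_classes, length)) < density).astype(float)


def mutate(pattern: np.ndarray, fraction: float, density: float, rng: np.random.Generator) -> np.ndarray:
    """Re-draw a random ``fraction`` of a pattern's elements at base density.

    ``round(fraction * length)`` positions chosen uniformly without
    replacement are reset — each becomes active independently with
    probability ``density`` — and all other positions are copied unchanged.
    Resetting (rather than flipping) keeps the expected density of the
    offspring at the base density.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = np.asarray(pattern, dtype=float).copy()
    k = int(round(fraction * out.size))
    if k == 0:
        return out
    pos = rng.choice(out.size, size=k, replace=False)
    out[pos] = (rng.random(k) < density).astype(float)
    return out


def build_dataset(
    rng: np.random.Generator,
    *,
    length: int = 200,
    density: float = 0.1,
    n_classes: int = 5,
    n_subclasses: int = 11,
    proto_reset: float = 0.2,
    instance_reset: float = 0.05,
    train_per_prototype: int = 18,
    test_candidates_per_prototype: int = 4,
    n_test: int = 200,
) -> PatternSet:
    """Generate the full hierarchical dataset.

    With the defaults: 5 class seeds, 10 subclass prototypes per class (the
    seed counts as subclass 0) for 55 prototypes total; 18 training instances
    and 4 test candidates per prototype; 990 training patterns in 11 groups
    of 90; 200 test patterns drawn without replacement from the 220
    candidates, stratified so every group is represented (two rng-chosen
    groups contribute one extra pattern).
    """
    seeds = make_class_seeds(rng, n_classes, length, density)

    protos, p_cls, p_sub = [], [], []
    for c in range(n_classes):
        for s in range(n_subclasses):
            proto = seeds[c] if s == 0 else mutate(seeds[c], proto_reset, density, rng)
            protos.append(proto)
            p_cls.append(c)
            p_sub.append(s)
    prototypes = np.array(protos)
    p_cls = np.array(p_cls)
    p_sub = np.array(p_sub)

    train, tr_cls, tr_sub, tr_grp = [], [], [], []
    cand, ca_cls, ca_sub, ca_grp = [], [], [], []
    for i in range(len(prototypes)):
        for _ in range(train_per_prototype):
            train.append(mutate(prototypes[i], instance_reset, density, rng))
            tr_cls.append(p_cls[i])
            tr_sub.append(p_sub[i])
            tr_grp.append(p_sub[i])
        for _ in range(test_candidates_per_prototype):
            cand.append(mutate(prototypes[i], instance_reset, density, rng))
            ca_cls.append(p_cls[i])
            ca_sub.append(p_sub[i])
            ca_grp.append(p_sub[i])
    train = np.array(train)
    tr_cls, tr_sub, tr_grp = map(np.array, (tr_cls, tr_sub, tr_grp))
    cand = np.array(cand)
    ca_cls, ca_sub, ca_grp = map(np.array, (ca_cls, ca_sub, ca_grp))

    # Stratified test draw: as even an allocation across groups as possible.
    per_group = n_test // n_subclasses
    n_extra = n_test - per_group * n_subclasses
    counts = np.full(n_subclasses, per_group)
    if n_extra:
        counts[rng.choice(n_subclasses, size=n_extra, replace=False)] += 1
    picked = []
    for g in range(n_subclasses):
        pool = np.flatnonzero(ca_grp == g)
        if counts[g] > pool.size:
            raise ValueError("not enough test candidates in a group for the requested test size")
        picked.append(rng.choice(pool, size=counts[g], replace=False))
    picked = np.concatenate(picked)

    return PatternSet(
        length=length, density=density, class_seeds=seeds,
        prototypes=prototypes, prototype_class=p_cls, prototype_subclass=p_sub,
        train=train, train_class=tr_cls, train_subclass=tr_sub, train_group=tr_grp,
        test=cand[picked], test_class=ca_cls[picked], test_subclass=ca_sub[picked],
        test_group=ca_grp[picked],
    )


def write_patterns(pset: PatternSet, out_dir) -> None:
    """Write plain-text pattern files plus a CSV label sidecar.

    ``train.txt`` / ``test.txt`` hold one pattern per line as space-separated
    0/1 tokens; ``labels.csv`` lists split, row index, class, subclass and
    session group for every pattern.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in (("train", pset.train), ("test", pset.test)):
        np.savetxt(out / f"{name}.txt", mat, fmt="%d")
    rows = []
    for split, cls, sub, grp in (
        ("train", pset.train_class, pset.train_subclass, pset.train_group),
        ("test", pset.test_class, pset.test_subclass, pset.test_group),
    ):
        for i in range(len(cls)):
            rows.append({"split": split, "row": i, "class": int(cls[i]),
                         "subclass": int(sub[i]), "group": int(grp[i])})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def read_patterns(path) -> np.ndarray:
    """Read a plain-text pattern file (one 0/1 row per pattern)."""
    mat = np.atleast_2d(np.loadtxt(path, dtype=float))
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError(f"{path}: patterns must be binary 0/1")
    return mat
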