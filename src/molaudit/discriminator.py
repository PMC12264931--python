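"""Decision-tree train-vs-generated discriminator.

A tree that can tell a model's generated molecules from its training
molecules is direct evidence of generation bias, and its most important
features localize the bias chemically. Trees use balanced class weights;
the depth is swept over 3..17 and chosen on a validation split (stratified
20% test, then 90:10 train:validation); scores are balanced accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .descriptors import FingerprintConfig, featurize_set
from .synthetic import GeneratorConfig, paired_sets

DEPTH_RANGE = tuple(range(3, 18))


@dataclass
class DataSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def split_data(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> DataSplit:
    """Stratified 20% test; remaining molecules split 90:10 train:validation."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 10:
        raise ValueError("need at least 10 molecules per class")
    idx = np.arange(len(labels))
    rest, test = train_test_split(
        idx, test_size=0.2, random_state=seed, stratify=labels
    )
    train, val = train_test_split(
        rest, test_size=0.1, random_state=seed, stratify=labels[rest]
    )
    return DataSplit(train_idx=train, val_idx=val, test_idx=test, seed=seed)


@dataclass
class DiscriminatorReport:
    chosen_depth: int
    validation_scores: dict[int, float]
    test_balanced_accuracy: float
    top_features: list[tuple[str, float]]
    feature_importances: np.ndarray = field(repr=False)
    seed: int = 0
    class_sizes: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "chosen_depth": self.chosen_depth,
            "validation_scores": {str(k): v for k, v in self.validation_scores.items()},
            "test_balanced_accuracy": self.test_balanced_accuracy,
            "top_features": [[n, float(v)] for n, v in self.top_features],
            "seed": self.seed,
            "class_sizes": self.class_sizes,
            "degenerate": self.degenerate,
        }


def train_discriminator(
    features: np.ndarray,
    labels: Sequence[str],
    feature_names: Optional[Sequence[str]] = None,
    depth_range: Sequence[int] = DEPTH_RANGE,
    seed: int = 0,
    top_k: int = 5,
) -> DiscriminatorReport:
    """Depth-swept balanced-class decision tree; shallowest depth wins ties."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    names = list(feature_names) if feature_names is not None else [
        f"f{k}" for k in range(X.shape[1])
    ]
    split = split_data(X, y, seed=seed)
    degenerate = bool(np.allclose(X.var(axis=0), 0.0))

    val_scores: dict[int, float] = {}
    trees: dict[int, DecisionTreeClassifier] = {}
    for depth in depth_range:
        tree = DecisionTreeClassifier(
            max_depth=depth, class_weight="balanced", random_state=seed
        )
        tree.fit(X[split.train_idx], y[split.train_idx])
        val_scores[depth] = float(
            balanced_accuracy_score(y[split.val_idx], tree.predict(X[split.val_idx]))
        )
        trees[depth] = tree

    best_depth = min(
        val_scores, key=lambda d: (-round(val_scores[d], 12), d)
    )  # max score, shallowest on ties
    best = trees[best_depth]
    test_score = float(
        balanced_accuracy_score(y[split.test_idx], best.predict(X[split.test_idx]))
    )
    importances = best.feature_importances_
    order = np.argsort(importances)[::-1][:top_k]
    top = [(names[i], float(importances[i])) for i in order]
    classes, counts = np.unique(y, return_counts=True)
    return DiscriminatorReport(
        chosen_depth=int(best_depth),
        validation_scores=val_scores,
        test_balanced_accuracy=test_score,
        top_features=top,
        feature_importances=importances,
        seed=seed,
        class_sizes={str(c): int(n) for c, n in zip(classes, counts)},
        degenerate=degenerate,
    )


def discriminate_sets(
    train_mols,
    generated_mols,
    fp_cfg: Optional[FingerprintConfig] = None,
    seed: int = 0,
    depth_range: Sequence[int] = DEPTH_RANGE,
) -> DiscriminatorReport:
    """Featurize two molecule sets with Morgan fingerprints and train the
    discriminator on the combined, labeled population."""
    fp_cfg = fp_cfg or FingerprintConfig()
    mats = featurize_set(list(train_mols) + list(generated_mols), "fingerprint", fp_cfg)
    y = ["train"] * len(train_mols) + ["generated"] * len(generated_mols)
    return train_discriminator(
        mats.X, y, feature_names=mats.feature_names, seed=seed, depth_range=depth_range
    )


def bias_power_curve(
    generator_cfg: GeneratorConfig,
    shift_levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_per_set: int = 1000,
    seeds: Sequence[int] = tuple(range(5)),
    fp_cfg: Optional[FingerprintConfig] = None,
    depth_range: Sequence[int] = DEPTH_RANGE,
) -> pd.DataFrame:
    """Sensitivity instrument: discriminator accuracy vs injected bias shift.

    For each shift level and seed, a (reference, biased) pair is generated,
    featurized, split and classified; the table reports per-level mean and
    standard error of the test balanced accuracy.
    """
    rows = []
    for shift in shift_levels:
        for seed in seeds:
            ref, gen = paired_sets(generator_cfg, shift, n_per_set, seed=10_000 * seed + 17)
            rep = discriminate_sets(ref, gen, fp_cfg=fp_cfg, seed=seed, depth_range=depth_range)
            rows.append(
                {"shift": shift, "seed": seed, "balanced_accuracy": rep.test_balanced_accuracy}
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("shift")["balanced_accuracy"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_accuracy", "sem": "sem_accuracy", "count": "n_seeds"})
    )
    return summary
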