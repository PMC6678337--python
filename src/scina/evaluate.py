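"""Scoring of predicted cell-type labels against ground truth.

ACC is the percentage of cells whose predicted class (including
"unknown") equals the true class.  ARI is the Hubert–Arabie adjusted Rand
index reported on a percentage scale, so 100 means identical partitions
and ~0 a random relabelling.  A PCA + k-means baseline is provided for
ARI comparisons only: an unsupervised clustering names clusters, not cell
types, so its ACC is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from . import em
from .matrix import ExpressionMatrix
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "MetricsReport",
    "acc",
    "ari",
    "score",
    "repeat_stability",
    "StabilityResult",
    "kmeans_baseline",
]

UNKNOWN_LABEL = em.UNKNOWN_LABEL


@dataclass
class MetricsReport:
    acc: float  # percent
    ari: float  # percent
    n_cells: int
    confusion: pd.DataFrame  # true label (rows) x predicted label (cols)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "ari": self.ari,
            "n_cells": self.n_cells,
            "confusion": {t: row.to_dict() for t, row in self.confusion.iterrows()},
        }


def _check_lengths(true_labels, pred_labels):
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(pred_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("empty label vectors")
    return t, p


def acc(true_labels, pred_labels) -> float:
    """Percentage of cells with predicted label equal to the true label."""
    t, p = _check_lengths(true_labels, pred_labels)
    return 100.0 * float(np.mean(t == p))


def ari(true_labels, pred_labels) -> float:
    """Hubert–Arabie adjusted Rand index on the percentage scale."""
    t, p = _check_lengths(true_labels, pred_labels)
    return 100.0 * float(adjusted_rand_score(t, p))


def score(true_labels, pred_labels, removed_labels=()) -> MetricsReport:
    """Full metrics report.

    removed_labels lists cell types whose signatures were withheld from
    the model on purpose; their cells are scored as correct when
    predicted "unknown", implemented by remapping the truth.
    """
    t, p = _check_lengths(true_labels, pred_labels)
    if removed_labels:
        removed = set(removed_labels)
        t = np.asarray([UNKNOWN_LABEL if lab in removed else lab for lab in t], dtype=object)
    confusion = pd.crosstab(pd.Series(t, name="true"), pd.Series(p, name="predicted"))
    return MetricsReport(acc=acc(t, p), ari=ari(t, p), n_cells=len(t), confusion=confusion)


@dataclass
class StabilityResult:
    """Outcome of the repeat-stability experiment."""

    mean_probability: float  # grand mean of correct-assignment indicators, in [0, 1]
    per_repeat_acc: list  # percent, one entry per successful repeat
    indicators: list  # per repeat: 0/1 array over cells
    n_failures: int
    failures: list


def repeat_stability(
    config: SimulationConfig,
    n_repeats: int,
    opts: em.FitOptions = None,
) -> StabilityResult:
    """Re-simulate and re-fit n_repeats times; report per-cell correctness.

    Each repeat draws a fresh dataset from a child seed of config.seed,
    fits with the true signatures, and records an indicator of correct
    assignment for every cell.  The mean probability is the grand mean of
    all indicators.  A repeat whose fit fails is excluded and reported.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    seeds = np.random.SeedSequence(config.seed, spawn_key=(9,)).generate_state(n_repeats)
    indicators, per_acc, failures = [], [], []
    for i in range(n_repeats):
        child = int(seeds[i]) & 0x7FFFFFFF
        try:
            ds = simulate_dataset(dc_replace(config, seed=child))
            result = em.fit(ds.expression, ds.signatures, opts)
            correct = (result.labels == ds.truth.true_labels).astype(float)
        except Exception as exc:  # noqa: BLE001 - a failed repeat is data, not a crash
            failures.append(f"repeat {i}: {exc}")
            continue
        indicators.append(correct)
        per_acc.append(100.0 * float(correct.mean()))
    if not indicators:
        raise RuntimeError("every repeat failed: " + "; ".join(failures))
    grand = float(np.concatenate(indicators).mean())
    return StabilityResult(
        mean_probability=grand,
        per_repeat_acc=per_acc,
        indicators=indicators,
        n_failures=len(failures),
        failures=failures,
    )


def kmeans_baseline(
    expr: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_components: int = 10,
) -> np.ndarray:
    """Generic PCA + k-means clustering; returns integer cluster IDs.

    Intended only as an unsupervised reference for ARI comparisons; the
    IDs carry no cell-type meaning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > expr.n_cells:
        raise ValueError("k cannot exceed the number of cells")
    x = expr.values.T  # cells x genes
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    if n_components >= 1 and n_components < x.shape[1]:
        x = PCA(n_components=n_components, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(x)
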