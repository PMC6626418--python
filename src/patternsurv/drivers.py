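"""Random-forest identification of the transcripts that drive cluster
structure.

A 100-tree bagged forest (all predictors available at every split) predicts
cluster labels from pattern-vector coordinates.  A feature's importance is
the mean increase in out-of-bag error when that feature is permuted, divided
by the standard deviation of the increase across trees; features exceeding
the prominence threshold (> 1 by convention) are flagged.  The bootstrap is
managed here so each tree's out-of-bag rows are known exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .pattern_space import PatternVectors

logger = logging.getLogger(__name__)

PROMINENCE_THRESHOLD = 1.0


@dataclass
class ImportanceTable:
    gene_ids: list[str]
    importance: np.ndarray
    n_trees: int
    seed: int
    prominence_threshold: float = PROMINENCE_THRESHOLD

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.shape != (len(self.gene_ids),):
            raise ValueError("one importance value per gene required")

    @property
    def prominent(self) -> np.ndarray:
        return self.importance > self.prominence_threshold

    def ranked(self) -> list[tuple[str, float]]:
        """Genes by descending importance; ties broken by panel order."""
        order = np.lexsort((np.arange(len(self.gene_ids)), -self.importance))
        return [(self.gene_ids[i], float(self.importance[i])) for i in order]


def rank_drivers(
    vectors: PatternVectors,
    labels: np.ndarray,
    seed: int,
    *,
    n_trees: int = 100,
) -> ImportanceTable:
    """Out-of-bag permutation importance of each panel gene for the labeling."""
    labels = np.asarray(labels)
    x = vectors.vectors
    n, p = x.shape
    if labels.shape != (n,):
        raise ValueError("labels length must match vectors")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two clusters to rank drivers")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with a single member: {small}")

    rng = np.random.default_rng(seed)
    deltas = np.full((n_trees, p), np.nan)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features=None, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(x[boot], labels[boot])
        if len(oob) == 0:
            continue
        base_err = float(np.mean(tree.predict(x[oob]) != labels[oob]))
        x_oob = x[oob]
        for f in range(p):
            permuted = x_oob.copy()
            permuted[:, f] = permuted[rng.permutation(len(oob)), f]
            err = float(np.mean(tree.predict(permuted) != labels[oob]))
            deltas[t, f] = err - base_err

    mean = np.nanmean(deltas, axis=0)
    std = np.nanstd(deltas, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        importance = np.where(std > 0, mean / std, 0.0)
    importance = np.nan_to_num(importance, nan=0.0)
    return ImportanceTable(
        gene_ids=list(vectors.gene_ids),
        importance=importance,
        n_trees=n_trees,
        seed=seed,
    )


def top_k(table: ImportanceTable, k: int) -> list[str]:
    """The k highest-importance genes (ties resolved by panel order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(table.gene_ids)
    if k > n:
        logger.warning("requested top %d of %d genes; clipping", k, n)
        k = n
    return [g for g, _ in table.ranked()[:k]]
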