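"""3-D t-SNE embedding of pattern vectors: parameter sweep, cluster
discernibility, and hold-out confirmation.

The sweep evaluates a perplexity x learning-rate grid, keeps parameter
settings that produce discernible clusters (a density-gap criterion stands in
for visual inspection), validates the winner with repeat runs, and otherwise
returns a rejection — cohorts without obvious cluster structure are not
analyzed further.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import HDBSCAN
from sklearn.metrics import silhouette_score

from . import _tsne
from .pattern_space import PatternVectors
from .utils import derive_seed

logger = logging.getLogger(__name__)

SWEEP_PERPLEXITIES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
SWEEP_LEARNING_RATES = (0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class EmbeddingParams:
    perplexity: float = 30.0
    learning_rate: float = 100.0
    n_iter_min: int = 2500
    dim: int = 3
    seed: int = 0
    stabilization_tol: float = 1e-4
    stabilization_window: int = 50
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if self.perplexity <= 0 or self.learning_rate <= 0:
            raise ValueError("perplexity and learning_rate must be positive")
        if self.dim != 3:
            raise ValueError("embeddings are three-dimensional")


@dataclass
class Embedding:
    sample_ids: list[str]
    coords: np.ndarray  # samples x 3
    params: EmbeddingParams
    kl_divergence: float
    n_iter_run: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), self.params.dim):
            raise ValueError("coords shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class Discernibility:
    """Operationalized 'obvious clusters' decision for one embedding."""

    k: int
    discernible: bool
    labels: np.ndarray  # dense reference partition, values 1..k
    validity: float  # mean silhouette of the partition (0 when k == 1)


@dataclass
class SweepRecord:
    perplexity: float
    learning_rate: float
    k: int
    discernible: bool
    validity: float
    kl_divergence: float


@dataclass
class SweepResult:
    rejected: bool
    embedding: Embedding | None = None
    k: int = 1
    reference_labels: np.ndarray | None = None
    validity: float = 0.0
    params: EmbeddingParams | None = None
    records: list[SweepRecord] = field(default_factory=list)
    validation_ks: list[int] = field(default_factory=list)


def run_tsne(vectors: PatternVectors, params: EmbeddingParams) -> Embedding:
    """Embed pattern vectors in 3-D; deterministic given ``params.seed``."""
    n = vectors.n_samples
    if n <= 3 * params.perplexity:
        raise ValueError(
            f"n_samples={n} must exceed 3 x perplexity={params.perplexity}; "
            "use a smaller perplexity"
        )
    p = _tsne.joint_probabilities(vectors.vectors, params.perplexity)
    coords, kl, n_iter = _tsne.optimize(
        p,
        dim=params.dim,
        learning_rate=params.learning_rate,
        n_iter_min=params.n_iter_min,
        max_iter=params.max_iter,
        stabilization_tol=params.stabilization_tol,
        stabilization_window=params.stabilization_window,
        seed=params.seed,
    )
    return Embedding(
        sample_ids=list(vectors.sample_ids),
        coords=coords,
        params=params,
        kl_divergence=kl,
        n_iter_run=n_iter,
    )


def count_discernible_clusters(
    embedding: Embedding,
    *,
    min_cluster_frac: float = 0.02,
    min_cluster_size: int = 5,
    silhouette_threshold: float = 0.35,
) -> Discernibility:
    """Decide whether the embedding shows dense groups separated by voids.

    Density clustering (HDBSCAN) on the 3-D coordinates provides the
    reference partition; sparse 'noise' points are attached to the cluster of
    their nearest dense point.  The partition counts as discernible when at
    least two groups exist and their mean silhouette clears the threshold.
    """
    coords = embedding.coords
    n = len(coords)
    mcs = max(min_cluster_size, int(round(min_cluster_frac * n)))
    if n <= mcs:
        return Discernibility(k=1, discernible=False, labels=np.ones(n, dtype=int), validity=0.0)
    with warnings.catch_warnings():
        # sklearn's HDBSCAN warns about an upcoming `copy` default change
        warnings.simplefilter("ignore", FutureWarning)
        raw = HDBSCAN(min_cluster_size=mcs, allow_single_cluster=True).fit_predict(coords)

    labels = _attach_noise(coords, raw)
    labels = _relabel_by_size(labels)
    k = int(labels.max())
    if k < 2:
        return Discernibility(k=1, discernible=False, labels=labels, validity=0.0)
    validity = float(silhouette_score(coords, labels))
    return Discernibility(
        k=k,
        discernible=validity >= silhouette_threshold,
        labels=labels,
        validity=validity,
    )


def _attach_noise(coords: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Assign HDBSCAN noise points (-1) to the cluster of the nearest dense point."""
    labels = raw.copy()
    noise = labels == -1
    if noise.all():
        return np.zeros(len(labels), dtype=int)
    if noise.any():
        tree = cKDTree(coords[~noise])
        _, nearest = tree.query(coords[noise])
        labels[noise] = labels[~noise][nearest]
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..k, largest cluster first (stable, deterministic)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[v] for v in labels], dtype=int)


def default_grid() -> list[tuple[float, float]]:
    return [(p, lr) for p in SWEEP_PERPLEXITIES for lr in SWEEP_LEARNING_RATES]


def sweep_and_select(
    vectors: PatternVectors,
    grid: list[tuple[float, float]] | None = None,
    *,
    seed: int = 0,
    base_params: EmbeddingParams | None = None,
    validation_runs: int = 3,
    silhouette_threshold: float = 0.35,
    min_cluster_frac: float = 0.02,
) -> SweepResult:
    """Evaluate the parameter grid and select a validated embedding.

    Grid points whose embeddings show discernible clusters are ranked by
    validity score; the best is confirmed by re-running with fresh seeds and
    requiring the modal cluster count to recur in at least 2/3 of the runs
    (candidates failing validation are dropped and the next tried).  When no
    grid point yields discernible clusters the result is a rejection.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    base = base_params or EmbeddingParams()

    records: list[SweepRecord] = []
    candidates: list[tuple[float, int, Embedding, Discernibility, EmbeddingParams]] = []
    for i, (perp, lr) in enumerate(grid):
        params = replace(base, perplexity=perp, learning_rate=lr, seed=derive_seed(seed, f"grid{i}"))
        if vectors.n_samples <= 3 * perp:
            logger.debug("skipping perplexity %s: too few samples", perp)
            continue
        emb = run_tsne(vectors, params)
        disc = count_discernible_clusters(
            emb,
            silhouette_threshold=silhouette_threshold,
            min_cluster_frac=min_cluster_frac,
        )
        records.append(
            SweepRecord(perp, lr, disc.k, disc.discernible, disc.validity, emb.kl_divergence)
        )
        if disc.discernible:
            candidates.append((disc.validity, i, emb, disc, params))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    for validity, i, emb, disc, params in candidates:
        if validation_runs <= 0:  # validation disabled (diagnostics only)
            return SweepResult(
                rejected=False, embedding=emb, k=disc.k,
                reference_labels=disc.labels, validity=validity,
                params=params, records=records, validation_ks=[],
            )
        ks = []
        for r in range(validation_runs):
            vparams = replace(params, seed=derive_seed(seed, f"grid{i}:val{r}"))
            vemb = run_tsne(vectors, vparams)
            vdisc = count_discernible_clusters(
                vemb,
                silhouette_threshold=silhouette_threshold,
                min_cluster_frac=min_cluster_frac,
            )
            ks.append(vdisc.k)
        modal_k, modal_count = Counter(ks).most_common(1)[0]
        if modal_k == disc.k and modal_count * 3 >= 2 * validation_runs:
            return SweepResult(
                rejected=False,
                embedding=emb,
                k=disc.k,
                reference_labels=disc.labels,
                validity=validity,
                params=params,
                records=records,
                validation_ks=ks,
            )
        logger.info(
            "grid point %d (perp=%s, lr=%s) failed validation: K=%d vs runs %s",
            i, params.perplexity, params.learning_rate, disc.k, ks,
        )
    return SweepResult(rejected=True, records=records)


def holdout_confirm(
    vectors: PatternVectors,
    labels: np.ndarray,
    seed: int,
    *,
    train_frac: float = 0.75,
    params: EmbeddingParams | None = None,
) -> float:
    """Hold-out consistency check for a full-cohort labeling.

    A stratified ``train_frac`` subset is embedded; each held-out sample then
    receives the label of its nearest training sample in the original
    pattern-vector space, and the fraction agreeing with the full-cohort
    labels is returned.  Clusters with fewer than 4 members are excluded.
    """
    labels = np.asarray(labels)
    if labels.shape != (vectors.n_samples,):
        raise ValueError("labels length must match vectors")
    uniq = np.unique(labels)
    if len(uniq) == 1:
        return 1.0

    keep = np.ones(len(labels), dtype=bool)
    for lab in uniq:
        if (labels == lab).sum() < 4:
            logger.warning("cluster %s has < 4 members; excluded from hold-out check", lab)
            keep &= labels != lab
    idx = np.nonzero(keep)[0]

    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels[idx]):
        members = idx[labels[idx] == lab]
        members = members[rng.permutation(len(members))]
        n_train = max(1, int(round(train_frac * len(members))))
        train_mask[members[:n_train]] = True
    test_idx = idx[~train_mask[idx]]
    train_idx = np.nonzero(train_mask)[0]
    if len(test_idx) == 0:
        return 1.0

    # Embed the training subset (mirrors refitting the map on training data);
    # label transfer itself is nearest-neighbor in input space.
    sub = PatternVectors(
        sample_ids=[vectors.sample_ids[i] for i in train_idx],
        vectors=vectors.vectors[train_idx],
        panel_name=vectors.panel_name,
        n=vectors.n,
    )
    p = params or EmbeddingParams()
    max_perp = (len(train_idx) - 1) / 3.0
    if p.perplexity >= max_perp:
        p = replace(p, perplexity=max(2.0, max_perp * 0.9))
    run_tsne(sub, replace(p, seed=derive_seed(seed, "holdout-embed")))

    tree = cKDTree(vectors.vectors[train_idx])
    _, nearest = tree.query(vectors.vectors[test_idx])
    transferred = labels[train_idx][nearest]
    return float(np.mean(transferred == labels[test_idx]))
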