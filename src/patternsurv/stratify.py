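"""Refinement and integration of cluster solutions.

Covers four procedures: sequential re-analysis of one cluster with a second
panel (treating the cluster as a fresh cohort, re-centered within it);
whole-matrix hierarchical partitioning of samples (average linkage on
1 - Pearson correlation); survival cross-stratification of clusters against
an external partition; and enrichment of a focal category within clusters
(per-cluster 2x2 Fisher tests plus an overall 2xK chi-square).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .clustering import ClusterSolution, assign_clusters
from .embedding import sweep_and_select
from .io import ExpressionMatrix, PathwayPanel, PhenotypeTable
from .pattern_space import pattern_vectors_for_panel
from .survival import ClusterSurvivalReport, compare_clusters, logrank_k
from .utils import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    sample_ids: list[str]
    group: np.ndarray  # one categorical label per sample

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        if self.group.shape != (len(self.sample_ids),):
            raise ValueError("one group label per sample required")

    def as_dict(self) -> dict[str, object]:
        return dict(zip(self.sample_ids, self.group))


@dataclass
class EnrichmentResult:
    cluster: int | None  # None for the overall chi-square
    table: np.ndarray
    test: str  # "fisher_2x2" | "chi_square"
    p_value: float
    odds_ratio: float | None = None


@dataclass
class RefineResult:
    status: str  # "refined" | "rejected" | "skipped"
    cluster_id: int
    n_subset: int
    k: int | None = None
    sub_labels: dict[str, int] = field(default_factory=dict)
    survival: ClusterSurvivalReport | None = None
    reason: str = ""

    @property
    def significant(self) -> bool:
        return (
            self.status == "refined"
            and self.survival is not None
            and self.survival.headline_p is not None
            and self.survival.headline_p < 0.05
        )


def sequential_refine(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    panel1_solution: ClusterSolution,
    panel2: PathwayPanel,
    cluster_id: int,
    *,
    seed: int,
    grid: list[tuple[float, float]] | None = None,
    min_subset: int = 20,
    min_group_size: int = 5,
    work_on_log_scale: bool = False,
    allow_missing: bool = False,
) -> RefineResult:
    """Re-run the full pattern->embed->cluster->survive chain on one cluster
    using a second panel.

    The subset is treated as a fresh cohort (pattern vectors re-centered
    within it).  The upstream solution is never modified.  Subsets that are
    too small are skipped; subsets without discernible sub-structure are
    rejected, not split.
    """
    if cluster_id not in set(panel1_solution.labels.tolist()):
        raise ValueError(f"cluster {cluster_id} not present in the panel-1 solution")
    members = panel1_solution.members(cluster_id)
    if len(members) < min_subset:
        logger.warning(
            "cluster %d has %d samples (< %d); refinement skipped",
            cluster_id, len(members), min_subset,
        )
        return RefineResult(
            status="skipped", cluster_id=cluster_id, n_subset=len(members),
            reason=f"subset smaller than {min_subset}",
        )

    keep = set(members)
    rows = [i for i, s in enumerate(expr.sample_ids) if s in keep]
    sub_expr = ExpressionMatrix(
        sample_ids=[expr.sample_ids[i] for i in rows],
        gene_ids=list(expr.gene_ids),
        values=expr.values[rows],
        scale=expr.scale,
    )
    vectors = pattern_vectors_for_panel(
        sub_expr, panel2, work_on_log_scale=work_on_log_scale, allow_missing=allow_missing
    )
    sweep = sweep_and_select(vectors, grid, seed=derive_seed(seed, f"refine{cluster_id}"))
    if sweep.rejected:
        return RefineResult(
            status="rejected", cluster_id=cluster_id, n_subset=len(members),
            reason="no discernible sub-clusters",
        )
    solution, _ = assign_clusters(
        sweep.embedding, sweep.k, sweep.reference_labels,
        derive_seed(seed, f"refine{cluster_id}:gmm"),
    )
    sub_labels = dict(zip(solution.sample_ids, (int(l) for l in solution.labels)))
    report = compare_clusters(sub_labels, pheno, min_group_size=min_group_size)
    return RefineResult(
        status="refined", cluster_id=cluster_id, n_subset=len(members),
        k=sweep.k, sub_labels=sub_labels, survival=report,
    )


def hierarchical_partition(m: ExpressionMatrix, k_groups: int) -> Partition:
    """Cut an average-linkage tree over 1 - Pearson correlation distance."""
    if k_groups < 1:
        raise ValueError("k_groups must be >= 1")
    if m.n_samples < k_groups:
        raise ValueError("more groups requested than samples")
    sd = m.values.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = [m.sample_ids[i] for i in flat[:5]]
        raise ValueError(f"constant-expression samples (undefined correlation): {names}")
    if k_groups == 1:
        group = np.ones(m.n_samples, dtype=int)
    elif k_groups == m.n_samples:
        group = np.arange(1, m.n_samples + 1)
    else:
        dist = pdist(m.values, metric="correlation")
        tree = linkage(dist, method="average")
        group = fcluster(tree, t=k_groups, criterion="maxclust")
    return Partition(sample_ids=list(m.sample_ids), group=np.asarray(group, dtype=int))


@dataclass
class CrossStratifyReport:
    contingency: pd.DataFrame  # clusters x partition groups
    within_cluster: dict[int, dict]  # cluster -> log-rank across partition groups
    within_group: dict[object, dict]  # partition group -> log-rank across clusters


def cross_stratify(
    solution: ClusterSolution,
    partition: Partition,
    pheno: PhenotypeTable,
    *,
    min_group_size: int = 5,
) -> CrossStratifyReport:
    """Compare survival between partition groups within each cluster and
    between clusters within each partition group."""
    part = partition.as_dict()
    shared = [s for s in solution.sample_ids if s in part and s in set(pheno.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between solution, partition and phenotype")
    lab = {s: int(l) for s, l in zip(solution.sample_ids, solution.labels)}
    sub_pheno = pheno.subset(shared)
    times = dict(zip(sub_pheno.sample_ids, sub_pheno.os_time))
    events = dict(zip(sub_pheno.sample_ids, sub_pheno.os_event))

    df = pd.DataFrame(
        {
            "cluster": [lab[s] for s in shared],
            "group": [part[s] for s in shared],
            "time": [times[s] for s in shared],
            "event": [events[s] for s in shared],
        },
        index=shared,
    )
    contingency = pd.crosstab(df["cluster"], df["group"])

    def _stratified(frame: pd.DataFrame, by: str) -> dict:
        keep = frame.groupby(by)[by].transform("size") >= min_group_size
        frame = frame[keep]
        if frame[by].nunique() < 2 or frame["event"].sum() == 0:
            return {"status": "skipped", "reason": "fewer than two usable strata"}
        res = logrank_k(
            frame["time"].to_numpy(), frame["event"].to_numpy(), frame[by].to_numpy()
        )
        return {
            "status": "tested",
            "chi_square": res.chi_square,
            "df": res.df,
            "p_value": res.p_value,
            "group_sizes": res.group_sizes,
        }

    within_cluster = {
        int(c): _stratified(sub, "group") for c, sub in df.groupby("cluster")
    }
    within_group = {g: _stratified(sub, "cluster") for g, sub in df.groupby("group")}
    return CrossStratifyReport(
        contingency=contingency, within_cluster=within_cluster, within_group=within_group
    )


def enrichment(
    solution: ClusterSolution, partition: Partition, focal_group: object
) -> list[EnrichmentResult]:
    """Fisher 2x2 enrichment of ``focal_group`` in each cluster, plus an
    overall 2xK chi-square of focal membership across clusters (expected
    counts from the full cohort's cluster proportions)."""
    part = partition.as_dict()
    shared = [s for s in solution.sample_ids if s in part]
    if not shared:
        raise ValueError("no samples shared between solution and partition")
    lab = {s: int(l) for s, l in zip(solution.sample_ids, solution.labels)}
    in_focal = np.array([part[s] == focal_group for s in shared])
    if not in_focal.any():
        raise ValueError(f"focal group {focal_group!r} absent from the partition")
    clusters = sorted({lab[s] for s in shared})
    cluster_arr = np.array([lab[s] for s in shared])

    results: list[EnrichmentResult] = []
    for c in clusters:
        in_c = cluster_arr == c
        table = np.array(
            [
                [int(np.sum(in_focal & in_c)), int(np.sum(in_focal & ~in_c))],
                [int(np.sum(~in_focal & in_c)), int(np.sum(~in_focal & ~in_c))],
            ]
        )
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(
                cluster=c, table=table, test="fisher_2x2",
                p_value=float(p), odds_ratio=float(odds),
            )
        )

    overall = np.vstack(
        [
            [int(np.sum(in_focal & (cluster_arr == c))) for c in clusters],
            [int(np.sum(~in_focal & (cluster_arr == c))) for c in clusters],
        ]
    )
    chi2 = stats.chi2_contingency(overall, correction=False)
    results.append(
        EnrichmentResult(
            cluster=None, table=overall, test="chi_square", p_value=float(chi2.pvalue)
        )
    )
    return results


def filter_by_covariate(pheno: PhenotypeTable, column: str, value: object) -> list[str]:
    """Sample IDs whose covariate equals ``value``.

    Downstream survival analysis on the subset retains the full-cohort
    cluster labels (the subset is located within the original clusters).
    """
    if column not in pheno.covariates:
        raise KeyError(f"unknown covariate column {column!r}")
    col = pheno.covariates[column]
    mask = col == value
    if not mask.any():
        raise ValueError(f"value {value!r} absent from covariate {column!r}")
    return [s for s, m in zip(pheno.sample_ids, mask) if m]
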