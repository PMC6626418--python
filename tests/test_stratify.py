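import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import fisher_exact_oracle
from patternsurv.clustering import solution_from_labels
from patternsurv.io import ExpressionMatrix, PhenotypeTable
from patternsurv.stratify import (
    Partition,
    cross_stratify,
    enrichment,
    filter_by_covariate,
    hierarchical_partition,
    sequential_refine,
)
from patternsurv.synthetic import (
    CohortSpec,
    PanelSpec,
    nested_refinement_cohort,
    simulate_cohort,
    toy_panel,
)


def block_matrix(rng, n_per_block=40, blocks=3, genes_per_block=25):
    """Samples x genes matrix with correlated sample blocks."""
    n = n_per_block * blocks
    g = genes_per_block * blocks
    gene_block = np.repeat(np.arange(blocks), genes_per_block)
    sample_block = np.repeat(np.arange(blocks), n_per_block)
    values = rng.normal(8.0, 0.5, size=(n, g))
    values += 3.0 * (gene_block[None, :] == sample_block[:, None])
    return (
        ExpressionMatrix(
            sample_ids=[f"S{i}" for i in range(n)],
            gene_ids=[f"G{j}" for j in range(g)],
            values=np.clip(values, 0, None),
        ),
        sample_block + 1,
    )


class TestHierarchicalPartition:
    def test_recovers_planted_blocks(self, rng):
        m, truth = block_matrix(rng)
        part = hierarchical_partition(m, 3)
        assert adjusted_rand_score(truth, part.group) >= 0.9

    def test_k1_everyone_together(self, rng):
        m, _ = block_matrix(rng, n_per_block=5)
        part = hierarchical_partition(m, 1)
        assert set(part.group) == {1}

    def test_k_equals_n_singletons(self, rng):
        m, _ = block_matrix(rng, n_per_block=4)
        part = hierarchical_partition(m, m.n_samples)
        assert len(set(part.group)) == m.n_samples

    def test_constant_sample_rejected(self):
        m = ExpressionMatrix(
            sample_ids=["S0", "S1", "S2"],
            gene_ids=["G0", "G1"],
            values=np.array([[1.0, 2.0], [5.0, 5.0], [2.0, 1.0]]),
        )
        with pytest.raises(ValueError, match="S1"):
            hierarchical_partition(m, 2)


def survival_pheno(rng, scales, ids=None):
    """Exponential survival with per-sample scale, no censoring."""
    n = len(scales)
    ids = ids or [f"S{i}" for i in range(n)]
    return PhenotypeTable(
        sample_ids=ids,
        os_time=rng.exponential(scales) + 1.0,
        os_event=np.ones(n, dtype=int),
    )


class TestCrossStratify:
    def test_partition_hazard_detected_in_one_cluster(self, rng):
        n = 200
        ids = [f"S{i}" for i in range(n)]
        clusters = np.repeat([1, 2], n // 2)
        groups = np.tile(["A", "B"], n // 2)
        # inside cluster 1 group B dies 4x faster; cluster 2 homogeneous
        scales = np.where((clusters == 1) & (groups == "B"), 250.0, 1000.0)
        pheno = survival_pheno(rng, scales, ids)
        solution = solution_from_labels(ids, clusters)
        report = cross_stratify(solution, Partition(sample_ids=ids, group=groups), pheno)
        assert report.within_cluster[1]["p_value"] < 0.01
        assert report.within_cluster[2]["p_value"] > 0.05

    def test_contingency_margins_conserved(self, rng):
        n = 90
        ids = [f"S{i}" for i in range(n)]
        clusters = rng.integers(1, 4, size=n)
        groups = rng.choice(["X", "Y"], size=n)
        pheno = survival_pheno(rng, np.full(n, 500.0), ids)
        report = cross_stratify(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=groups),
            pheno,
        )
        table = report.contingency
        for c in np.unique(clusters):
            assert table.loc[_dense(clusters, c)].sum() == np.sum(clusters == c)
        assert table.to_numpy().sum() == n

    def test_partition_identical_to_clusters_skipped(self, rng):
        n = 60
        ids = [f"S{i}" for i in range(n)]
        clusters = np.repeat([1, 2], n // 2)
        pheno = survival_pheno(rng, np.full(n, 500.0), ids)
        report = cross_stratify(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=clusters.astype(str)),
            pheno,
        )
        assert all(r["status"] == "skipped" for r in report.within_cluster.values())

    def test_empty_intersection_rejected(self, rng):
        pheno = survival_pheno(rng, np.full(4, 500.0), ["S0", "S1", "S2", "S3"])
        solution = solution_from_labels(["S0", "S1"], np.array([1, 2]))
        partition = Partition(sample_ids=["X0", "X1"], group=np.array(["A", "B"]))
        with pytest.raises(ValueError):
            cross_stratify(solution, partition, pheno)


def _dense(clusters, c):
    # solution_from_labels renumbers to 1..K in sorted order
    uniq = sorted(set(clusters.tolist()))
    return uniq.index(c) + 1


class TestEnrichment:
    def test_perfect_association_matches_oracle(self):
        ids = [f"S{i}" for i in range(20)]
        clusters = np.array([1] * 10 + [2] * 10)
        focal = np.array(["T"] * 10 + ["O"] * 10)
        results = enrichment(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=focal),
            "T",
        )
        r1 = next(r for r in results if r.cluster == 1)
        assert r1.p_value == pytest.approx(fisher_exact_oracle([[10, 0], [0, 10]]), abs=1e-15)

    def test_fisher_matches_oracle_random_tables(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(5, 30, size=2)
            ids = [f"S{i}" for i in range(n1 + n2)]
            clusters = np.array([1] * n1 + [2] * n2)
            focal = rng.choice(["T", "O"], size=n1 + n2)
            if not (focal == "T").any():
                continue
            results = enrichment(
                solution_from_labels(ids, clusters),
                Partition(sample_ids=ids, group=focal),
                "T",
            )
            for r in results:
                if r.test != "fisher_2x2":
                    continue
                assert r.p_value == pytest.approx(
                    fisher_exact_oracle(r.table.tolist()), abs=1e-12
                )

    def test_proportional_distribution_null(self):
        # focal group spread exactly proportionally: all odds ratios 1
        ids = [f"S{i}" for i in range(120)]
        clusters = np.repeat([1, 2, 3], 40)
        focal = np.tile(["T", "O", "O", "O"], 30)
        results = enrichment(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=focal),
            "T",
        )
        for r in results:
            if r.test == "fisher_2x2":
                assert r.odds_ratio == pytest.approx(1.0)
        chi = next(r for r in results if r.test == "chi_square")
        assert chi.p_value > 0.9

    def test_empty_focal_cell_boundary(self):
        ids = [f"S{i}" for i in range(30)]
        clusters = np.array([1] * 10 + [2] * 20)
        focal = np.array(["O"] * 10 + ["T"] * 10 + ["O"] * 10)
        results = enrichment(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=focal),
            "T",
        )
        r1 = next(r for r in results if r.cluster == 1)
        assert r1.odds_ratio == 0.0
        assert 0.0 < r1.p_value <= 1.0

    def test_margins_match_input_sizes(self, rng):
        ids = [f"S{i}" for i in range(50)]
        clusters = rng.integers(1, 4, size=50)
        focal = rng.choice(["T", "O"], size=50)
        results = enrichment(
            solution_from_labels(ids, clusters),
            Partition(sample_ids=ids, group=focal),
            "T",
        )
        for r in results:
            assert r.table.sum() == 50

    def test_absent_focal_group_rejected(self):
        ids = ["S0", "S1"]
        with pytest.raises(ValueError):
            enrichment(
                solution_from_labels(ids, np.array([1, 2])),
                Partition(sample_ids=ids, group=np.array(["A", "B"])),
                "Z",
            )


class TestFilterByCovariate:
    def pheno(self):
        return PhenotypeTable(
            sample_ids=[f"S{i}" for i in range(10)],
            os_time=np.arange(10, dtype=float) + 1,
            os_event=np.ones(10, dtype=int),
            covariates={"stage": np.array(["IV"] * 4 + ["II"] * 6)},
        )

    def test_filter_matches_count(self):
        assert len(filter_by_covariate(self.pheno(), "stage", "IV")) == 4

    def test_absent_value_rejected(self):
        with pytest.raises(ValueError):
            filter_by_covariate(self.pheno(), "stage", "0")

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            filter_by_covariate(self.pheno(), "grade", "IV")


@pytest.fixture(scope="module")
def nested():
    spec = CohortSpec(
        n_samples=220,
        panels=(
            PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=2, sigma=0.1),
            PanelSpec(panel=toy_panel("PanelB", 12), k_clusters=3, sigma=0.1),
        ),
        hazards=(math.log(2) / 300, math.log(2) / 1500, math.log(2) / 800),
        censor_horizon=5000.0,
        nesting={1: (1, 2)},
        seed=21,
    )
    expr, pheno, truth = nested_refinement_cohort(spec)
    solution = solution_from_labels(expr.sample_ids, truth.labels_for("PanelA"))
    return spec, expr, pheno, truth, solution


class TestSequentialRefine:
    def test_split_found_in_nested_cluster(self, nested):
        spec, expr, pheno, truth, solution = nested
        result = sequential_refine(
            expr, pheno, solution, spec.panels[1].panel, 1,
            seed=3, grid=[(15.0, 100.0)], work_on_log_scale=True,
        )
        assert result.status == "refined"
        assert result.k == 2
        assert result.survival.headline_p < 0.05

    def test_non_nested_cluster_rejected(self, nested):
        spec, expr, pheno, truth, solution = nested
        result = sequential_refine(
            expr, pheno, solution, spec.panels[1].panel, 2,
            seed=3, grid=[(15.0, 100.0)], work_on_log_scale=True,
        )
        assert result.status == "rejected"

    def test_upstream_labels_immutable(self, nested):
        spec, expr, pheno, truth, solution = nested
        before = solution.labels.copy()
        sequential_refine(
            expr, pheno, solution, spec.panels[1].panel, 1,
            seed=4, grid=[(15.0, 100.0)], work_on_log_scale=True,
        )
        np.testing.assert_array_equal(solution.labels, before)

    def test_small_subset_skipped(self, nested, caplog):
        spec, expr, pheno, truth, solution = nested
        with caplog.at_level("WARNING"):
            result = sequential_refine(
                expr, pheno, solution, spec.panels[1].panel, 1,
                seed=3, min_subset=10_000, work_on_log_scale=True,
            )
        assert result.status == "skipped"

    def test_unknown_cluster_rejected(self, nested):
        spec, expr, pheno, truth, solution = nested
        with pytest.raises(ValueError):
            sequential_refine(
                expr, pheno, solution, spec.panels[1].panel, 99,
                seed=3, work_on_log_scale=True,
            )
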