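import math

import numpy as np
import pytest
from scipy import stats

from patternsurv.survival import logrank
from patternsurv.synthetic import (
    CohortSpec,
    DirectionInfeasibleError,
    NestingError,
    PanelSpec,
    nested_refinement_cohort,
    pattern_directions,
    simulate_cohort,
    toy_panel,
)


def basic_spec(**overrides):
    defaults = dict(
        n_samples=120,
        panels=(PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=3, sigma=0.1),),
        hazards=(0.001, 0.002, 0.0005),
        censor_horizon=4000.0,
        seed=1,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


class TestDirections:
    def test_pairwise_angle_respected(self, rng):
        dirs = pattern_directions(10, 4, math.pi / 2, rng)
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, -1.0)
        assert dots.max() <= math.cos(math.pi / 2) + 1e-9

    def test_antipodal_pair(self, rng):
        dirs = pattern_directions(5, 2, math.pi, rng)
        np.testing.assert_allclose(dirs[0], -dirs[1], atol=1e-9)

    def test_infeasible_raises(self, rng):
        with pytest.raises(DirectionInfeasibleError):
            pattern_directions(3, 4, math.pi * 0.95, rng)

    def test_unit_norm(self, rng):
        dirs = pattern_directions(7, 3, 1.0, rng)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)


class TestSimulateCohort:
    def test_deterministic(self):
        spec = basic_spec()
        e1, p1, t1 = simulate_cohort(spec)
        e2, p2, t2 = simulate_cohort(spec)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(p1.os_time, p2.os_time)
        np.testing.assert_array_equal(
            t1.labels_for("PanelA"), t2.labels_for("PanelA")
        )

    def test_k1_single_cluster(self):
        spec = basic_spec(
            panels=(PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=1),),
            hazards=(0.001,),
        )
        _, _, truth = simulate_cohort(spec)
        assert set(truth.labels_for("PanelA")) == {1}

    def test_exponential_medians(self):
        lam = (math.log(2) / 1000, math.log(2) / 500)
        spec = basic_spec(
            n_samples=4000,
            panels=(PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=2),),
            hazards=lam,
            censor_horizon=1e9,  # effectively uncensored
        )
        _, pheno, truth = simulate_cohort(spec)
        assert pheno.os_event.all()
        labels = truth.labels_for("PanelA")
        med1 = np.median(pheno.os_time[labels == 1])
        med2 = np.median(pheno.os_time[labels == 2])
        assert med1 == pytest.approx(1000, rel=0.12)
        assert med2 == pytest.approx(500, rel=0.12)

    def test_event_times_are_exponential(self):
        lam = (0.002, 0.0008)
        spec = basic_spec(
            n_samples=4000,
            panels=(PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=2),),
            hazards=lam,
            censor_horizon=1e9,
            seed=5,
        )
        _, pheno, truth = simulate_cohort(spec)
        labels = truth.labels_for("PanelA")
        for cluster, rate in zip((1, 2), lam):
            sample = pheno.os_time[labels == cluster][:2000]
            res = stats.kstest(sample, "expon", args=(0, 1.0 / rate))
            assert res.pvalue > 0.01

    def test_censoring_monotone_in_horizon(self):
        fractions = []
        for horizon in (500.0, 2000.0, 8000.0):
            _, pheno, _ = simulate_cohort(basic_spec(censor_horizon=horizon))
            fractions.append(1.0 - pheno.os_event.mean())
        assert fractions[0] > fractions[1] > fractions[2]

    def test_values_valid_log2p1(self):
        expr, _, _ = simulate_cohort(basic_spec())
        assert expr.scale == "log2p1"
        assert expr.values.min() >= 0
        assert np.isfinite(expr.values).all()

    def test_subtype_enrichment(self):
        spec = basic_spec(
            n_samples=900,
            subtype_enrichment={2: ("TNBC", 0.85)},
        )
        _, pheno, truth = simulate_cohort(spec)
        labels = truth.labels_for("PanelA")
        subtype = pheno.covariates["subtype"]
        in2 = np.mean(subtype[labels == 2] == "TNBC")
        out2 = np.mean(subtype[labels != 2] == "TNBC")
        assert in2 > 0.75
        assert out2 < 0.6

    def test_background_blocks_aligned(self):
        spec = basic_spec(
            n_samples=300,
            n_background_genes=60,
            background_blocks=3,
            background_overlap=1.0,
        )
        expr, _, truth = simulate_cohort(spec)
        assert expr.n_genes == 15 + 60
        labels = truth.labels_for("PanelA")
        np.testing.assert_array_equal(truth.background_block, 1 + (labels - 1) % 3)

    def test_panels_must_be_disjoint(self):
        panel = toy_panel("PanelA", 10)
        with pytest.raises(ValueError, match="disjoint"):
            basic_spec(
                panels=(
                    PanelSpec(panel=panel, k_clusters=2),
                    PanelSpec(panel=panel, k_clusters=2),
                ),
                hazards=(0.001, 0.002),
            )


class TestNestedRefinement:
    def nested_spec(self, lam=(0.002, 0.0005, 0.001), seed=1, n=240):
        return CohortSpec(
            n_samples=n,
            panels=(
                PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=2, sigma=0.1),
                PanelSpec(panel=toy_panel("PanelB", 12), k_clusters=3, sigma=0.1),
            ),
            hazards=lam,
            censor_horizon=4000.0,
            nesting={1: (1, 2)},
            seed=seed,
        )

    def test_labels_nest(self):
        _, _, truth = nested_refinement_cohort(self.nested_spec())
        l1 = truth.labels_for("PanelA")
        l2 = truth.labels_for("PanelB")
        assert set(l2[l1 == 1]) == {1, 2}
        assert set(l2[l1 == 2]) == {3}

    def test_empty_nesting_matches_simulate(self):
        spec = CohortSpec(
            n_samples=100,
            panels=(PanelSpec(panel=toy_panel("PanelA", 15), k_clusters=2),),
            hazards=(0.001, 0.002),
            seed=9,
        )
        e1, p1, t1 = nested_refinement_cohort(spec)
        e2, p2, t2 = simulate_cohort(spec)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(p1.os_time, p2.os_time)

    def test_unknown_cluster_rejected(self):
        spec = self.nested_spec()
        bad = CohortSpec(
            **{**{f: getattr(spec, f) for f in spec.__dataclass_fields__}, "nesting": {7: (1, 2)}}
        )
        with pytest.raises(NestingError):
            nested_refinement_cohort(bad)

    def test_subcluster_ids_must_cover_range(self):
        spec = self.nested_spec()
        bad = CohortSpec(
            **{**{f: getattr(spec, f) for f in spec.__dataclass_fields__}, "nesting": {1: (1, 5)}}
        )
        with pytest.raises(NestingError):
            nested_refinement_cohort(bad)

    def test_null_split_not_significant(self):
        """Equal hazards in the two sub-clusters: within-cluster log-rank on
        true labels stays non-significant in >= 90% of replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = self.nested_spec(lam=(0.001, 0.001, 0.002), seed=1000 + rep, n=160)
            _, pheno, truth = nested_refinement_cohort(spec)
            l1 = truth.labels_for("PanelA")
            l2 = truth.labels_for("PanelB")
            inside = l1 == 1
            a = inside & (l2 == 1)
            b = inside & (l2 == 2)
            res = logrank(
                pheno.os_time[a], pheno.os_event[a], pheno.os_time[b], pheno.os_event[b]
            )
            if res.p_value >= 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep
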