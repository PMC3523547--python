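import numpy as np
import pytest
from scipy import stats as sps

from surfscreen import (
    count_hits,
    pooled_t_statistic,
    screen_disease,
    t_tail_probability,
    top_k_surface_targets,
)


class TestPooledTStatistic:
    def test_identical_groups_give_zero(self):
        t, df = pooled_t_statistic([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert df == 4

    def test_hand_computed_value(self):
        # mean diff 4, pooled variance 1, SE = sqrt(2/3)
        t, df = pooled_t_statistic([5, 6, 7], [1, 2, 3])
        assert df == 4
        assert t == pytest.approx(4.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert t == pytest.approx(4.89898, abs=5e-6)

    @pytest.mark.parametrize("c", [0.5, 2.0, 117.3])
    def test_scale_invariance(self, c):
        t0, _ = pooled_t_statistic([5, 6, 7], [1, 2, 3])
        t1, _ = pooled_t_statistic(np.array([5, 6, 7]) * c, np.array([1, 2, 3]) * c)
        assert t1 == pytest.approx(t0, rel=1e-12)

    def test_matches_reference_implementation_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1 = rng.integers(2, 30)
            n2 = rng.integers(2, 30)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n1)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n2)
            t, df = pooled_t_statistic(x, y)
            expected = sps.ttest_ind(x, y, equal_var=True)
            assert df == n1 + n2 - 2
            assert t == pytest.approx(expected.statistic, rel=1e-10)

    def test_zero_pooled_variance_is_error(self):
        with pytest.raises(ValueError, match="pooled variance"):
            pooled_t_statistic([2.0, 2.0, 2.0], [2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            pooled_t_statistic([1.0], [1.0, 2.0])


class TestTailProbability:
    def test_zero_statistic_gives_one(self):
        assert t_tail_probability(0.0, 22) == 1.0

    def test_symmetric_in_sign(self):
        assert t_tail_probability(-3.3, 10) == t_tail_probability(3.3, 10)

    def test_strictly_decreasing_in_magnitude(self):
        ps = [t_tail_probability(t, 22) for t in np.linspace(0, 30, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_tiny_tails_do_not_underflow_to_garbage(self):
        p = t_tail_probability(30.0, 22)
        assert 0.0 < p < 1e-18

    def test_matches_scipy_survival(self):
        assert t_tail_probability(4.9, 7) == pytest.approx(
            2 * sps.t.sf(4.9, 7), rel=1e-12
        )

    def test_invalid_df_is_error(self):
        with pytest.raises(ValueError, match="freedom"):
            t_tail_probability(1.0, 0)


class TestScreenDisease:
    def test_dominant_probe_ranks_first(self, small_dataset):
        matrix, meta = small_dataset.matrix, small_dataset.metadata
        boosted = matrix.data.copy()
        cohort_samples = meta.cohort_samples("EWS")
        boosted.loc["SYN000005_at", cohort_samples] = (
            boosted.loc["SYN000005_at"].max() + 10.0
        )
        from surfscreen import ExpressionMatrix

        stats = screen_disease(ExpressionMatrix(boosted), meta, "EWS")
        assert stats["probe_id"].iloc[0] == "SYN000005_at"

    def test_screen_matches_direct_statistic(self, small_dataset):
        matrix, meta = small_dataset.matrix, small_dataset.metadata
        stats = screen_disease(matrix, meta, "ARMS")
        from surfscreen.io import Role

        tumor = meta.cohort_samples("ARMS")
        normal = meta.samples_with_role(Role.NORMAL)
        for _, row in stats.sample(20, random_state=0).iterrows():
            x = matrix.data.loc[row["probe_id"], tumor]
            y = matrix.data.loc[row["probe_id"], normal]
            t, df = pooled_t_statistic(x, y)
            assert row["T"] == pytest.approx(t, rel=1e-12)
            assert row["df"] == df
            assert row["p"] == pytest.approx(t_tail_probability(t, df), rel=1e-12)

    def test_ranking_is_a_permutation_of_probes(self, small_dataset):
        stats = screen_disease(small_dataset.matrix, small_dataset.metadata, "OS")
        assert sorted(stats["probe_id"]) == sorted(small_dataset.matrix.probe_ids)
        t = stats["T"].to_numpy()
        assert (np.diff(t) <= 1e-12).all()

    def test_sign_follows_mean_difference(self, small_dataset):
        stats = screen_disease(small_dataset.matrix, small_dataset.metadata, "GBM")
        diff = stats["tumor_mean"] - stats["normal_mean"]
        assert (np.sign(stats["T"]) == np.sign(diff)).all()

    def test_unknown_disease_lists_available_cohorts(self, small_dataset):
        with pytest.raises(ValueError, match="unknown disease.*ARMS"):
            screen_disease(small_dataset.matrix, small_dataset.metadata, "WILMS")

    def test_null_rankings_uncorrelated_between_seeds(self):
        from surfscreen import SimulationConfig, generate_dataset

        orders = []
        for seed in (11, 12):
            ds = generate_dataset(
                SimulationConfig(
                    n_probes=2000,
                    cohort_sizes={"EWS": 10},
                    delta=0.0,
                    planted_per_disease=0,
                    surface_fraction=0.2,
                    seed=seed,
                )
            )
            stats = screen_disease(ds.matrix, ds.metadata, "EWS")
            orders.append(stats.set_index("probe_id")["T"])
        rho = sps.spearmanr(orders[0], orders[1].loc[orders[0].index]).statistic
        assert abs(rho) < 0.1

    def test_per_tissue_means_equivalent_with_one_array_per_tissue(self, small_dataset):
        a = screen_disease(small_dataset.matrix, small_dataset.metadata, "HBL")
        b = screen_disease(
            small_dataset.matrix,
            small_dataset.metadata,
            "HBL",
            normal_mode="per_tissue_means",
        )
        assert np.allclose(a["T"], b["T"])


class TestCountHits:
    def test_empty_list(self):
        import pandas as pd

        assert count_hits(pd.DataFrame(columns=["T"])) == 0

    def test_strict_inequality_at_boundary(self):
        import pandas as pd

        stats = pd.DataFrame({"T": [12.0, 10.0, 9.0]})
        assert count_hits(stats, tau=10) == 1

    def test_monotone_non_increasing_in_threshold(self, small_dataset):
        stats = screen_disease(small_dataset.matrix, small_dataset.metadata, "NBL")
        counts = [count_hits(stats, tau) for tau in np.linspace(-5, 15, 30)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestTopKSurfaceTargets:
    def test_pool_exhaustion_returns_short_table(self, small_dataset):
        stats = screen_disease(small_dataset.matrix, small_dataset.metadata, "STS")
        pool = list(stats["probe_id"].iloc[[4, 40, 400]])
        table = top_k_surface_targets(stats, pool, k=25)
        assert len(table) == 3
        assert table.table["rank"].tolist() == [1, 2, 3]

    def test_planted_targets_recovered(self, small_dataset):
        from surfscreen.annotation import classify_all, surface_probe_set

        calls = classify_all(small_dataset.evidence)
        surface = surface_probe_set(small_dataset.matrix.probe_ids, None, calls)
        recovered = []
        for disease in small_dataset.truth.planted:
            stats = screen_disease(
                small_dataset.matrix, small_dataset.metadata, disease
            )
            table = top_k_surface_targets(stats, surface, k=30)
            planted = small_dataset.truth.planted_probes(disease)
            got = planted & set(table.table["probe_id"])
            recovered.append(len(got) / len(planted))
        assert np.mean(recovered) >= 0.9
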