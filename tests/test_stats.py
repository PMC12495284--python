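import numpy as np
import pandas as pd
import pytest

from redoxdmri.combat import BatchDesign, CombatModel
from redoxdmri.io import CohortTable
from redoxdmri.simulate import CohortSimSpec, simulate_cohort
from redoxdmri.stats import (
    ModelSpec,
    VoxelwiseAssociation,
    build_design,
    chi_square_2x2,
    filter_delay,
    huber_irls_multi,
    median_split,
    robust_lm,
    tfce,
    welch_t,
)


def _cohort(delays, groups=None, gpx=None, gr=None):
    n = len(delays)
    groups = groups or ["HC"] * n
    return CohortTable(
        pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(n)],
                group=groups,
                age=np.linspace(20, 40, n),
                sex=["M", "F"] * (n // 2) + ["M"] * (n % 2),
                scanner=["Prisma"] * n,
                plate=["Infinite"] * n,
                gpx=gpx if gpx is not None else np.linspace(10, 20, n),
                gr=gr if gr is not None else np.linspace(2, 3, n),
                delay=delays,
            )
        )
    )


class TestFilterDelay:
    def test_strictly_larger_excluded(self):
        c = _cohort([10, 59, 60, 61, 271])
        out = filter_delay(c, 60)
        assert sorted(out.df.delay) == [10, 59, 60]

    def test_infinite_cutoff_identity(self):
        c = _cohort([10, 500, 3.0])
        assert len(filter_delay(c, np.inf)) == 3

    def test_all_excluded_gives_empty(self):
        c = _cohort([100, 200])
        assert len(filter_delay(c, 60)) == 0


class TestRobustLM:
    def test_exact_linear_data(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones(30), x])
        y = 2.0 + 3.0 * x
        res = robust_lm(y, X)
        np.testing.assert_allclose(res.params, [2.0, 3.0], atol=1e-10)

    def test_huber_limit_equals_ols(self):
        # tuning constant -> infinity: the Huber loss becomes quadratic
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = X @ [1.0, 2.0] + rng.normal(size=100)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        res = robust_lm(y, X, tuning_const=1e8)
        np.testing.assert_allclose(res.params, ols, atol=1e-8)

    def test_outlier_resistance_vs_ols(self):
        # 10% gross outliers: robust beats OLS in >= 95% of replicates
        rng = np.random.default_rng(42)
        wins = 0
        n_rep = 500
        beta_true = np.array([0.0, 1.0])
        for _ in range(n_rep):
            n = 60
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            y = X @ beta_true + rng.normal(size=n)
            idx = rng.choice(n, size=n // 10, replace=False)
            y[idx] += 20.0
            b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            b_rob = robust_lm(y, X).params
            wins += np.linalg.norm(b_rob - beta_true) < np.linalg.norm(b_ols - beta_true)
        assert wins / n_rep >= 0.95

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20), 2 * np.arange(20)])
        with pytest.raises(ValueError, match="rank deficient"):
            robust_lm(np.random.default_rng(1).normal(size=20), X)

    def test_huber_multi_matches_single(self):
        rng = np.random.default_rng(5)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = np.stack([X @ [1, 2] + rng.normal(size=n), X @ [0, -1] + rng.normal(size=n)], axis=1)
        multi = huber_irls_multi(Y, X)
        for v in range(2):
            single = robust_lm(Y[:, v], X).params
            np.testing.assert_allclose(multi[:, v], single, atol=5e-3)


class TestWelch:
    def test_identical_groups_t_zero(self):
        a = np.array([1.0, 2, 3, 4])
        t, df, p = welch_t(a, a.copy())
        assert t == 0.0

    def test_formula_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5])
        t, df, p = welch_t(a, b)
        # independent closed form
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_exp = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert df == pytest.approx(df_exp, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        t1, *_ = welch_t(a, b)
        t2, *_ = welch_t(10 * a, 10 * b)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.ones(5), np.ones(4) * 2)


class TestChiSquare:
    def test_identical_rows_zero(self):
        chi2, df, p = chi_square_2x2([[10, 20], [10, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 5], [0, 7]])


class TestMedianSplit:
    def test_threshold_from_hc_only(self):
        # HC ratios {5,6,7,9}, PT {4,8}: threshold 6.5
        gpx = [5.0, 6, 7, 9, 4, 8]
        c = _cohort([0] * 6, groups=["HC"] * 4 + ["PT"] * 2, gpx=gpx, gr=[1.0] * 6)
        labels = median_split(c)
        assert list(labels) == ["low", "low", "high", "high", "low", "high"]

    def test_partition_property(self):
        c = _cohort(
            [0] * 8, groups=["HC"] * 4 + ["PT"] * 4,
            gpx=np.linspace(5, 25, 8), gr=np.linspace(2, 3, 8),
        )
        labels = median_split(c)
        assert set(labels) <= {"low", "high"}
        assert len(labels) == 8

    def test_ties_go_high(self):
        c = _cohort([0] * 4, groups=["HC"] * 4, gpx=[6.0, 6, 6, 6], gr=[1.0] * 4)
        assert list(median_split(c)) == ["high"] * 4

    def test_no_hc_rejected(self):
        c = _cohort([0, 0], groups=["PT", "PT"])
        with pytest.raises(ValueError):
            median_split(c)


class TestTFCE:
    def test_single_voxel_analytic(self):
        # isolated suprathreshold voxel of height h: integral h^3/3 (E=.5, H=2)
        indptr = np.array([0, 1, 3, 4])
        indices = np.array([1, 0, 2, 1])
        h0 = 2.0
        out = tfce(np.array([0.0, h0, 0.0]), indptr, indices, E=0.5, H=2.0, n_steps=100)
        assert out[1] == pytest.approx(h0**3 / 3, rel=0.02)
        assert out[0] == 0.0 and out[2] == 0.0

    def test_disconnected_equal_voxels_equal_enhancement(self):
        # two isolated voxels, same height, no edge between them
        indptr = np.array([0, 1, 2, 3, 4])
        indices = np.array([1, 0, 3, 2])  # edges (0,1), (2,3)
        out = tfce(np.array([1.5, 0.0, 1.5, 0.0]), indptr, indices)
        assert out[0] == pytest.approx(out[2], rel=1e-12)

    def test_uniform_map_increasing_in_cluster_size(self, tiny_template):
        t = tiny_template
        vals = []
        for size in (5, 25, 100):
            stat = np.zeros(t.n_voxels)
            from redoxdmri.skeleton import contiguous_cluster

            cl = contiguous_cluster(t, size)
            stat[cl] = 1.0
            vals.append(tfce(stat, t.indptr, t.indices)[cl[0]])
        assert vals[0] < vals[1] < vals[2]

    def test_monotone_in_input(self, tiny_template):
        t = tiny_template
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 2, t.n_voxels)
        b = a + rng.uniform(0, 0.5, t.n_voxels)
        # common threshold grid so the integration ranges align
        steps = 200
        ta = tfce(a, t.indptr, t.indices, n_steps=steps)
        tb = tfce(b, t.indptr, t.indices, n_steps=steps)
        assert (tb - ta).min() > -1e-6 * tb.max()

    def test_nonpositive_input_zero(self, tiny_template):
        t = tiny_template
        out = tfce(np.full(t.n_voxels, -1.0), t.indptr, t.indices)
        assert np.all(out == 0)

    def test_empty_adjacency_rejected(self):
        with pytest.raises(ValueError, match="adjacency"):
            tfce(np.array([1.0]), np.array([0, 0]), np.array([], dtype=np.int64))


class TestDesign:
    def test_age_centred_and_squared(self, small_template):
        cohort, _, _ = simulate_cohort(CohortSimSpec(seed=0), small_template)
        X, names, j = build_design(cohort, ModelSpec(predictor="gr"))
        assert names[j] == "gr"
        age_c = X[:, names.index("age_c")]
        assert abs(age_c.mean()) < 1e-9
        np.testing.assert_allclose(X[:, names.index("age_c2")], age_c**2)

    def test_three_way_design_has_all_lower_terms(self, small_template):
        cohort, _, _ = simulate_cohort(CohortSimSpec(seed=0), small_template)
        labels = median_split(cohort)
        X, names, j = build_design(cohort, ModelSpec(predictor="gpx", interaction="ratio_class:group"), labels)
        assert names[j] == "gpx:group:low_ratio"
        for t in ("group", "low_ratio", "group:low_ratio", "gpx", "gpx:group", "gpx:low_ratio"):
            assert t in names

    def test_constant_response_nothing_significant(self, tiny_template):
        cohort, ds, _ = simulate_cohort(CohortSimSpec(seed=1, cluster_size=20), tiny_template)
        ds.metrics["MK"] = np.ones_like(ds.metrics["MK"])
        res = VoxelwiseAssociation(ds, cohort, ModelSpec(response="MK", predictor="gr")).fit(
            n_perm=120, seed=0, compute_beta=False
        )
        assert res.significant.sum() == 0

    def test_three_way_interaction_model_runs(self, tiny_template):
        # marker x ratio-class x clinical-status contrast end to end
        cohort, ds, _ = simulate_cohort(CohortSimSpec(seed=6, cluster_size=20), tiny_template)
        res = VoxelwiseAssociation(
            ds, cohort, ModelSpec(response="MK", predictor="gpx", interaction="ratio_class:group")
        ).fit(n_perm=120, seed=1, compute_beta=True)
        assert res.term == "gpx:group:low_ratio"
        assert np.all(np.isfinite(res.t_map))
        assert np.all((res.p_fdr_map > 0) & (res.p_fdr_map <= 1))
        assert np.all(np.isfinite(res.beta_map))

    def test_subject_mismatch_rejected(self, tiny_template):
        cohort, ds, _ = simulate_cohort(CohortSimSpec(seed=1, cluster_size=20), tiny_template)
        bad = cohort.subset(np.arange(len(cohort)) < len(cohort) - 1)
        with pytest.raises(ValueError, match="match"):
            VoxelwiseAssociation(ds, bad, ModelSpec(response="MK", predictor="gr"))


class TestPipelineDeterminism:
    def test_simulate_harmonize_associate_bit_reproducible(self, tiny_template):
        def run():
            cohort, ds, _ = simulate_cohort(CohortSimSpec(seed=4, cluster_size=30), tiny_template)
            filt = filter_delay(cohort)
            keep = cohort.df.subject_id.isin(filt.df.subject_id).to_numpy()
            ds2 = ds.subset_subjects(keep)
            df = filt.df
            age_c = (df.age - df.age.mean()).to_numpy()
            cov = np.column_stack(
                [(df.group == "PT").astype(float), (df.sex == "F").astype(float), age_c, age_c**2]
            )
            d = BatchDesign(feature_matrix=ds2.metrics["MK"].T, batch=df.scanner.to_numpy(), covariates=cov)
            ds2.metrics["MK"] = CombatModel(d).fit().adjusted.T
            return VoxelwiseAssociation(ds2, filt, ModelSpec(response="MK", predictor="gr", groups="HC")).fit(
                n_perm=150, seed=11, compute_beta=False
            )

        r1, r2 = run(), run()
        np.testing.assert_array_equal(r1.t_map, r2.t_map)
        np.testing.assert_array_equal(r1.p_fdr_map, r2.p_fdr_map)
        np.testing.assert_array_equal(r1.p_fwe_map, r2.p_fwe_map)
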