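import numpy as np
import pytest

from redoxdmri.io import GradientScheme
from redoxdmri.simulate import (
    CohortSimSpec,
    PhantomSpec,
    SMWatsonParams,
    add_noise,
    build_phantom,
    default_scheme,
    simulate_cohort,
    sphere_directions,
    watson_signal,
)
from redoxdmri.skeleton import contiguous_cluster


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestWatsonSignal:
    def test_b0_returns_s0_exactly(self):
        p = SMWatsonParams(f=0.4, Da=2.1, De_par=1.6, De_perp=0.5, kappa=9.0, S0=123.0)
        sch = GradientScheme(bvals=np.array([0.0]), bvecs=np.zeros((1, 3)))
        assert watson_signal(p, sch)[0] == pytest.approx(123.0, rel=1e-14)

    def test_perpendicular_coherent_stick(self):
        # f=1 coherent stick: no attenuation perpendicular to the axis
        p = SMWatsonParams(f=1.0, Da=2.5, De_par=2.5, De_perp=0.0, kappa=1e6)
        sch = GradientScheme(bvals=np.array([0.0, 3000.0]), bvecs=np.array([[0, 0, 0], [1.0, 0, 0]]))
        sig = watson_signal(p, sch)
        assert sig[1] == pytest.approx(p.S0, rel=1e-3)

    def test_monte_carlo_oracle_parallel(self):
        # importance-weighted MC over uniformly sampled orientations
        p = SMWatsonParams(f=0.5, Da=2.0, De_par=1.5, De_perp=0.5, kappa=16.0)
        sch = GradientScheme(bvals=np.array([1000.0]), bvecs=np.array([[0, 0, 1.0]]))
        rng = np.random.default_rng(0)
        n = rng.normal(size=(1_000_000, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        w = np.exp(p.kappa * (n @ p.mu) ** 2)
        w /= w.sum()
        x2 = (n @ p.mu) ** 2
        b = 1.0  # ms/um^2
        mc = np.sum(
            w * (p.f * np.exp(-b * p.Da * x2) + (1 - p.f) * np.exp(-b * p.De_perp - b * (p.De_par - p.De_perp) * x2))
        )
        assert watson_signal(p, sch)[0] == pytest.approx(mc, rel=1e-3)

    def test_monotone_nonincreasing_in_b(self):
        p = SMWatsonParams(f=0.5, Da=2.2, De_par=1.7, De_perp=0.6, kappa=6.0)
        g = np.array([0.2, -0.4, 0.89])
        g /= np.linalg.norm(g)
        bvals = np.array([0.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0])
        sch = GradientScheme(bvals=bvals, bvecs=np.tile(g, (len(bvals), 1)) * (bvals > 0)[:, None])
        sig = watson_signal(p, sch)
        assert np.all(np.diff(sig) < 0)

    def test_isotropic_odf_direction_independent(self):
        p = SMWatsonParams(f=0.5, Da=2.0, De_par=1.5, De_perp=0.5, kappa=0.0)
        g = sphere_directions(30)
        sch = GradientScheme(bvals=np.full(30, 1500.0), bvecs=g)
        sig = watson_signal(p, sch)
        assert np.ptp(sig) < 1e-6

    def test_rotation_equivariance(self):
        R = _rotation([1, 2, 3], 1.1)
        g = sphere_directions(20)
        sch = GradientScheme(bvals=np.full(20, 2000.0), bvecs=g)
        sch_rot = GradientScheme(bvals=sch.bvals, bvecs=g @ R.T)
        mu = np.array([0.0, 0.0, 1.0])
        p = SMWatsonParams(f=0.45, Da=2.3, De_par=1.8, De_perp=0.4, kappa=12.0, mu=mu)
        p_rot = SMWatsonParams(f=0.45, Da=2.3, De_par=1.8, De_perp=0.4, kappa=12.0, mu=R @ mu)
        np.testing.assert_allclose(watson_signal(p, sch), watson_signal(p_rot, sch_rot), atol=1e-8)


class TestAddNoise:
    def test_sigma_zero_identity(self):
        s = np.linspace(0.1, 1, 10)
        np.testing.assert_array_equal(add_noise(s, 0.0, "rician", rng=0), s)

    def test_rician_zero_signal_rayleigh_mean(self):
        # magnitude of pure noise is Rayleigh: mean sigma*sqrt(pi/2)
        sigma = 0.7
        out = add_noise(np.zeros(1_000_000), sigma, "rician", rng=1)
        assert out.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_gaussian_unbiased(self):
        sig = np.full(200_000, 3.0)
        out = add_noise(sig, 0.5, "gaussian", rng=2)
        se = 0.5 / np.sqrt(len(sig))
        assert abs(out.mean() - 3.0) < 3 * se

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(3), -1.0, "rician")


class TestBuildPhantom:
    def _two_region_spec(self, noise="none"):
        shape = (4, 4, 2)
        m1 = np.zeros(shape, bool)
        m1[:2] = True
        m2 = np.zeros(shape, bool)
        m2[2:3] = True
        p1 = SMWatsonParams(f=0.5, Da=2.2, De_par=1.8, De_perp=0.6, kappa=8.0)
        p2 = SMWatsonParams(f=0.3, Da=2.0, De_par=1.5, De_perp=0.8, kappa=4.0)
        return PhantomSpec(shape=shape, regions=[(m1, p1), (m2, p2)], noise_model=noise)

    def test_noise_free_regions_identical_signals(self):
        sch = default_scheme()
        vol = build_phantom(self._two_region_spec(), sch, seed=0)
        region = vol.data[:2].reshape(-1, len(sch))
        assert np.ptp(region, axis=0).max() == 0.0
        # voxels outside regions are masked out
        assert not vol.mask[3].any()

    def test_seed_determinism(self):
        sch = default_scheme()
        spec = self._two_region_spec(noise="rician")
        v1 = build_phantom(spec, sch, seed=7)
        v2 = build_phantom(spec, sch, seed=7)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_isotropic_gaussian_region_monoexponential(self):
        shape = (2, 2, 1)
        m = np.ones(shape, bool)
        d = 1.1
        p = SMWatsonParams(f=0.0, Da=0.0, De_par=d, De_perp=d, kappa=0.0, S0=2.0)
        sch = default_scheme()
        vol = build_phantom(PhantomSpec(shape=shape, regions=[(m, p)], noise_model="none"), sch, seed=0)
        expected = 2.0 * np.exp(-sch.bvals * 1e-3 * d)
        np.testing.assert_allclose(vol.data[0, 0, 0], expected, rtol=1e-6)

    def test_overlapping_regions_rejected(self):
        shape = (2, 2, 1)
        m = np.ones(shape, bool)
        p = SMWatsonParams(f=0.5, Da=2.0, De_par=1.5, De_perp=0.5, kappa=4.0)
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(shape=shape, regions=[(m, p), (m, p)], noise_model="none")


class TestSimulateCohort:
    def test_marginal_moments_match_targets(self, small_template):
        spec = CohortSimSpec(seed=11)
        cohort, _, _ = simulate_cohort(spec, small_template)
        df = cohort.df
        for group, n in (("HC", 86), ("PT", 82)):
            sub = df[df.group == group]
            assert len(sub) == n
            tg, tr = spec.gpx[group], spec.gr[group]
            assert sub.gpx.mean() == pytest.approx(tg.mean, abs=2 * tg.sd / np.sqrt(n))
            assert sub.gr.mean() == pytest.approx(tr.mean, abs=2 * tr.sd / np.sqrt(n))

    def test_gpx_gr_correlation_near_target(self, small_template):
        # Fisher-z 95% sampling interval around rho = 0.38 at n = 168
        rs = []
        for seed in range(4):
            cohort, _, _ = simulate_cohort(CohortSimSpec(seed=seed), small_template)
            rs.append(np.corrcoef(cohort.df.gpx, cohort.df.gr)[0, 1])
        z = np.arctanh(np.mean(rs))
        lo, hi = np.tanh(np.arctanh(0.38) + np.array([-1, 1]) * 1.96 / np.sqrt(165))
        assert lo < np.tanh(z) < hi

    def test_female_hc_gpx_excess_and_age_decline(self, small_template):
        cohort, _, _ = simulate_cohort(CohortSimSpec(seed=5), small_template)
        hc = cohort.df[cohort.df.group == "HC"]
        assert hc[hc.sex == "F"].gpx.mean() > hc[hc.sex == "M"].gpx.mean()
        slope = np.polyfit(cohort.df.age, cohort.df.gpx, 1)[0]
        assert slope < 0

    def test_planted_cluster_contiguous_and_in_skeleton(self, small_template):
        spec = CohortSimSpec(seed=2)
        _, ds, cluster = simulate_cohort(spec, small_template)
        assert len(cluster) == spec.cluster_size
        assert cluster.max() < small_template.n_voxels
        # contiguity: BFS from first voxel within cluster reaches all of it
        cl = set(cluster.tolist())
        seen = {cluster[0]}
        stack = [cluster[0]]
        while stack:
            v = stack.pop()
            for w in small_template.neighbors(v):
                if w in cl and w not in seen:
                    seen.add(w)
                    stack.append(w)
        assert seen == cl

    def test_seed_bit_reproducibility(self, tiny_template):
        a = simulate_cohort(CohortSimSpec(seed=9, cluster_size=50), tiny_template)
        b = simulate_cohort(CohortSimSpec(seed=9, cluster_size=50), tiny_template)
        assert a[0].df.equals(b[0].df)
        for k in a[1].metrics:
            np.testing.assert_array_equal(a[1].metrics[k], b[1].metrics[k])

    def test_cluster_larger_than_skeleton_rejected(self, tiny_template):
        with pytest.raises(ValueError, match="cluster"):
            simulate_cohort(CohortSimSpec(seed=0, cluster_size=10**6), tiny_template)

    def test_contiguous_cluster_size(self, tiny_template):
        c = contiguous_cluster(tiny_template, 40)
        assert len(np.unique(c)) == 40
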