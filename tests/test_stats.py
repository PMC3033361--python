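"""Shape statistics: sphere geometry, Karcher mean, covariance, sampling."""

import numpy as np
import pytest

from esa import (
    SRVF,
    ShapeDistribution,
    ShapeMean,
    exp_map,
    geodesic_path,
    karcher_mean,
    l2_inner,
    log_map,
    principal_sweep,
    residue_variance,
    sample_shapes,
    shape_covariance,
    srvf_to_curve,
    tangent_density,
)
from esa.stats import _tangent_inner, _tangent_norm

from .conftest import smooth_srvf


def _tangent_at(mu: SRVF, seed: int, scale: float = 0.3) -> np.ndarray:
    """A random tangent vector at mu with the given L2 norm."""
    m = mu.grid_size
    raw = smooth_srvf(m=m, seed=seed).values
    v = raw - _tangent_inner(m, raw, mu.values) * mu.values
    return scale * v / _tangent_norm(m, v)


class TestSphereGeometry:
    def test_log_of_mu_is_zero(self):
        mu = smooth_srvf(seed=0)
        np.testing.assert_allclose(log_map(mu, mu), 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_log_norm_equals_arc_distance(self, seed):
        mu, q = smooth_srvf(seed=0), smooth_srvf(seed=seed)
        theta = np.arccos(np.clip(l2_inner(mu, q), -1, 1))
        v = log_map(mu, q)
        assert _tangent_norm(mu.grid_size, v) == pytest.approx(theta, abs=1e-8)
        assert _tangent_inner(mu.grid_size, v, mu.values) == pytest.approx(
            0.0, abs=1e-8
        )

    @pytest.mark.parametrize("seed", [4, 5])
    def test_exp_log_inversion(self, seed):
        mu, q = smooth_srvf(seed=0), smooth_srvf(seed=seed)
        back = exp_map(mu, log_map(mu, q))
        np.testing.assert_allclose(back.values, q.values, atol=1e-8)

    def test_exp_zero_is_mu_and_output_unit_norm(self):
        mu = smooth_srvf(seed=6)
        np.testing.assert_allclose(exp_map(mu, np.zeros_like(mu.values)).values,
                                   mu.values)
        v = _tangent_at(mu, seed=9, scale=0.7)
        q = exp_map(mu, v)
        assert l2_inner(q, q) == pytest.approx(1.0, abs=1e-8)
        # geodesic length equals the tangent norm
        theta = np.arccos(np.clip(l2_inner(mu, q), -1, 1))
        assert theta == pytest.approx(0.7, abs=1e-8)

    def test_antipodal_log_raises(self):
        mu = smooth_srvf(seed=0)
        with pytest.raises(ValueError):
            log_map(mu, SRVF(values=-mu.values))


class TestKarcherMean:
    def test_single_shape_is_its_own_mean(self):
        q = smooth_srvf(seed=1)
        res = karcher_mean([q])
        np.testing.assert_allclose(res.mu.values, q.values)
        assert res.sum_sq_dist == 0.0
        assert res.converged

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            karcher_mean([])

    def test_two_shapes_mean_is_geodesic_midpoint(self):
        # two small horizontal perturbations of a common shape need no
        # registration, so the Karcher mean must sit at the tau=0.5 point
        # of the connecting great circle
        from esa.fixtures import horizontal_directions

        mu = smooth_srvf(seed=0)
        dirs = horizontal_directions(mu, 2, seed=13)
        q1 = exp_map(mu, 0.15 * dirs[0])
        q2 = exp_map(mu, 0.12 * dirs[1])
        res = karcher_mean([q1, q2])
        mid = geodesic_path(res.aligned[0], res.aligned[1], steps=3)[1]
        gap = np.arccos(np.clip(l2_inner(res.mu, mid), -1, 1))
        assert gap <= 1e-3

    def test_recovers_generating_mean_of_gaussian_ensemble(self):
        from esa.fixtures import horizontal_directions

        rng = np.random.default_rng(7)
        mu = smooth_srvf(seed=0)
        dirs = horizontal_directions(mu, 2, seed=11)
        shapes = []
        for _ in range(50):
            v = 0.1 * rng.standard_normal() * dirs[0] + 0.05 * rng.standard_normal() * dirs[1]
            shapes.append(exp_map(mu, v))
        res = karcher_mean(shapes)
        from esa import align

        assert align(mu, res.mu).theta <= 0.05

    def test_objective_non_increasing(self):
        from esa.fixtures import horizontal_directions

        rng = np.random.default_rng(3)
        mu = smooth_srvf(seed=2)
        dirs = horizontal_directions(mu, 3, seed=4)
        shapes = [
            exp_map(mu, np.tensordot(0.1 * rng.standard_normal(3), dirs, axes=(0, 0)))
            for _ in range(8)
        ]
        res = karcher_mean(shapes)
        assert np.all(np.diff(res.objective_history) <= 1e-6)


def _toy_distribution(m=60, sigmas=(0.04, 0.01), seed=0):
    mu = smooth_srvf(m=m, seed=seed)
    u1 = _tangent_at(mu, seed=21, scale=1.0)
    u2 = _tangent_at(mu, seed=22, scale=1.0)
    # Gram-Schmidt in L2
    u2 = u2 - _tangent_inner(m, u2, u1) * u1
    u2 /= _tangent_norm(m, u2)
    mean = ShapeMean(mu=mu, aligned=(), sum_sq_dist=0.0, iterations=0, converged=True)
    return ShapeDistribution(
        mean=mean,
        directions=np.stack([u1, u2]),
        sigma=np.array(sigmas),
        sample_size=50,
    )


class TestCovariance:
    def test_identical_shapes_give_zero_components(self):
        q = smooth_srvf(seed=5)
        mean = ShapeMean(mu=q, aligned=(q, q, q), sum_sq_dist=0.0,
                         iterations=0, converged=True)
        dist = shape_covariance(mean)
        assert dist.k == 0

    def test_fewer_than_two_shapes_raises(self):
        q = smooth_srvf(seed=5)
        mean = ShapeMean(mu=q, aligned=(q,), sum_sq_dist=0.0,
                         iterations=0, converged=True)
        with pytest.raises(ValueError):
            shape_covariance(mean)

    def test_rank_one_ensemble_recovers_direction(self):
        mu = smooth_srvf(seed=0)
        u = _tangent_at(mu, seed=31, scale=1.0)
        rng = np.random.default_rng(4)
        shapes = [exp_map(mu, 0.1 * z * u) for z in rng.standard_normal(30)]
        mean = ShapeMean(mu=mu, aligned=tuple(shapes), sum_sq_dist=0.0,
                         iterations=0, converged=True)
        dist = shape_covariance(mean)
        cos = _tangent_inner(mu.grid_size, dist.directions[0], u)
        assert abs(cos) > 0.99
        if dist.k > 1:
            assert dist.sigma[1] < 1e-4 * dist.sigma[0]

    def test_trace_equals_mean_squared_tangent_norm(self):
        mu = smooth_srvf(seed=0)
        rng = np.random.default_rng(9)
        shapes = [
            exp_map(mu, _tangent_at(mu, seed=int(s), scale=0.1 * rng.uniform()))
            for s in rng.integers(0, 999, size=12)
        ]
        mean = ShapeMean(mu=mu, aligned=tuple(shapes), sum_sq_dist=0.0,
                         iterations=0, converged=True)
        dist = shape_covariance(mean)
        vs = np.stack([log_map(mu, q) for q in shapes])
        vbar = vs.mean(axis=0)
        m = mu.grid_size
        expected = sum(
            _tangent_norm(m, v - vbar) ** 2 for v in vs
        ) / (len(shapes) - 1)
        assert np.sum(dist.sigma) == pytest.approx(expected, abs=1e-8)

    def test_directions_orthonormal_and_tangent(self):
        dist = _toy_distribution()
        m = dist.mean.mu.grid_size
        for j in range(dist.k):
            assert _tangent_norm(m, dist.directions[j]) == pytest.approx(1.0, abs=1e-6)
            assert _tangent_inner(m, dist.directions[j], dist.mean.mu.values) == (
                pytest.approx(0.0, abs=1e-6)
            )
        assert _tangent_inner(m, dist.directions[0], dist.directions[1]) == (
            pytest.approx(0.0, abs=1e-6)
        )


class TestSampling:
    def test_same_seed_reproduces_samples(self):
        dist = _toy_distribution()
        a = sample_shapes(dist, 5, seed=42)
        b = sample_shapes(dist, 5, seed=42)
        for qa, qb in zip(a, b):
            np.testing.assert_array_equal(qa.values, qb.values)

    def test_zero_variance_returns_mean_copies(self):
        mu = smooth_srvf(seed=8)
        mean = ShapeMean(mu=mu, aligned=(), sum_sq_dist=0.0, iterations=0,
                         converged=True)
        dist = ShapeDistribution(mean=mean, directions=np.zeros((0, mu.grid_size, 3)),
                                 sigma=np.zeros(0), sample_size=3)
        for q in sample_shapes(dist, 4, seed=0):
            np.testing.assert_array_equal(q.values, mu.values)

    def test_empirical_covariance_matches_model(self):
        dist = _toy_distribution(sigmas=(0.04, 0.01))
        m = dist.mean.mu.grid_size
        samples = sample_shapes(dist, 3000, seed=5)
        coords = np.array(
            [
                [
                    _tangent_inner(m, log_map(dist.mean.mu, q), dist.directions[j])
                    for j in range(dist.k)
                ]
                for q in samples
            ]
        )
        emp = np.cov(coords.T)
        np.testing.assert_allclose(emp, np.diag(dist.sigma), atol=0.1 * 0.04)


class TestSweepAndVariance:
    def test_sweep_zero_reproduces_mean_curve(self):
        dist = _toy_distribution()
        sweep = principal_sweep(dist, 0, [0.0])
        np.testing.assert_allclose(
            sweep[0].points, srvf_to_curve(dist.mean.mu).points, atol=1e-12
        )

    def test_sweep_distance_scales_with_t(self):
        dist = _toy_distribution()
        mu = dist.mean.mu
        for t in (-2.0, -1.0, 1.0, 2.0):
            q = exp_map(mu, t * np.sqrt(dist.sigma[0]) * dist.directions[0])
            theta = np.arccos(np.clip(l2_inner(mu, q), -1, 1))
            assert theta == pytest.approx(abs(t) * np.sqrt(dist.sigma[0]), abs=1e-6)

    def test_sweep_component_out_of_range_raises(self):
        dist = _toy_distribution()
        with pytest.raises(ValueError):
            principal_sweep(dist, 5, [0.0])

    def test_zero_variance_distribution_has_zero_residue_variance(self):
        mu = smooth_srvf(seed=8)
        mean = ShapeMean(mu=mu, aligned=(), sum_sq_dist=0.0, iterations=0,
                         converged=True)
        dist = ShapeDistribution(mean=mean, directions=np.zeros((0, mu.grid_size, 3)),
                                 sigma=np.zeros(0), sample_size=3, n_residues=20)
        var = residue_variance(dist, n_samples=5, seed=0)
        assert var.shape == (20,)
        np.testing.assert_allclose(var, 0.0, atol=1e-16)

    def test_tail_localized_noise_gives_tail_localized_variance(self):
        # noise confined to the last 20% of the chain: a flexible C-terminus
        from esa.fixtures import FixtureSpec, make_ensemble
        from esa.matching import curve_to_preshape
        from esa import fit_shape_distribution

        spec = FixtureSpec(kind="helix", n_residues=30)
        curves, _ = make_ensemble(
            spec, n=20, noise_sd=0.08, noise_support=(0.8, 1.0), seed=5,
            grid_size=80,
        )
        # ensemble members share one residue-level parameterization, so
        # they are encoded without arc-length re-canonicalization
        qs = [curve_to_preshape(c, 80, arclength=False) for c in curves]
        dist = fit_shape_distribution(qs, n_residues=30)
        var = residue_variance(dist, n_samples=10, seed=2)
        assert var.shape == (30,)
        tail = var[24:].mean()
        body = var[:24].mean()
        assert tail >= 5.0 * body

    def test_too_few_samples_raises(self):
        dist = _toy_distribution()
        with pytest.raises(ValueError):
            residue_variance(dist, n_samples=1, seed=0)


class TestTangentDensity:
    def test_standard_normal_at_mean(self):
        mu = smooth_srvf(seed=0)
        u = _tangent_at(mu, seed=21, scale=1.0)
        mean = ShapeMean(mu=mu, aligned=(), sum_sq_dist=0.0, iterations=0,
                         converged=True)
        dist = ShapeDistribution(mean=mean, directions=u[None], sigma=np.array([1.0]),
                                 sample_size=10)
        assert tangent_density(dist, mu) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_high_variance_direction_has_higher_density(self):
        # two shapes at the same geodesic distance from the mean: the one
        # along the dominant direction is the more probable one
        dist = _toy_distribution(sigmas=(0.04, 0.005))
        mu = dist.mean.mu
        r = 0.1
        q_major = exp_map(mu, r * dist.directions[0])
        q_minor = exp_map(mu, r * dist.directions[1])
        assert tangent_density(dist, q_major) > tangent_density(dist, q_minor)

    def test_density_monotone_in_displacement(self):
        dist = _toy_distribution()
        mu = dist.mean.mu
        ts = [0.0, 0.05, 0.1, 0.2]
        dens = [
            tangent_density(dist, exp_map(mu, t * dist.directions[0])) for t in ts
        ]
        assert all(a > b for a, b in zip(dens, dens[1:]))
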