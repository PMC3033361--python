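"""Second-order statistics on the shape space.

The preshape space is the unit sphere in L2([0,1], R^3), so statistics are
done in the tangent space at a mean shape: shapes are pulled back with the
spherical log map, averaged / decomposed there, and pushed forward with the
exp map.  This module provides the Karcher (intrinsic) mean, tangent-space
PCA of the sample covariance, Gaussian-type sampling of random shapes,
principal-direction sweeps, per-residue positional variance and a tangent
Gaussian density — the machinery needed to treat an ensemble of protein
structures (e.g. NMR models) as a probability distribution on shapes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .curves import BackboneCurve
from .matching import align, optimal_rotation, rotate_srvf
from .srvf import SRVF, l2_inner, project_to_preshape, srvf_to_curve, trapezoid_weights

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sphere geometry
# ---------------------------------------------------------------------------

def log_map(mu: SRVF, q: SRVF) -> np.ndarray:
    """Inverse exponential map on the preshape sphere.

    Returns the tangent vector v at mu pointing along the geodesic to q,
    with ``||v|| = theta = arccos <mu, q>``:

        v = (theta / sin theta) (q - cos(theta) mu)

    Antipodal pairs (theta = pi) have no unique direction and raise.
    """
    ip = np.clip(l2_inner(mu, q), -1.0, 1.0)
    theta = float(np.arccos(ip))
    if theta > np.pi - 1e-8:
        raise ValueError("antipodal shapes: log map undefined")
    if theta < 1e-12:
        return np.zeros_like(mu.values)
    return (theta / np.sin(theta)) * (q.values - ip * mu.values)


def exp_map(mu: SRVF, v: np.ndarray) -> SRVF:
    """Exponential map on the preshape sphere.

    ``exp_mu(v) = cos(||v||) mu + sin(||v||) v / ||v||``; returns mu itself
    for the zero vector.  Output is unit-norm by construction.
    """
    v = np.asarray(v, dtype=float)
    nv = _tangent_norm(mu.grid_size, v)
    if nv < 1e-14:
        return SRVF(values=mu.values.copy())
    return SRVF(values=np.cos(nv) * mu.values + np.sin(nv) * (v / nv))


def _tangent_norm(m: int, v: np.ndarray) -> float:
    w = trapezoid_weights(m)
    return float(np.sqrt(max(np.sum(w * np.sum(v * v, axis=1)), 0.0)))


def _tangent_inner(m: int, u: np.ndarray, v: np.ndarray) -> float:
    w = trapezoid_weights(m)
    return float(np.sum(w * np.sum(u * v, axis=1)))


# ---------------------------------------------------------------------------
# Karcher mean
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ShapeMean:
    """Karcher mean of a shape sample.

    ``mu`` minimizes (locally) the sum of squared geodesic distances to the
    sample; ``aligned`` holds each input registered (rotation + matching
    function) to mu.
    """

    mu: SRVF
    aligned: tuple[SRVF, ...]
    sum_sq_dist: float
    iterations: int
    converged: bool
    objective_history: tuple[float, ...] = ()


def karcher_mean(
    shapes: Sequence[SRVF],
    tol: float = 1e-5,
    max_iter: int = 50,
    step: float = 0.5,
    align_kwargs: dict | None = None,
) -> ShapeMean:
    """Iterated tangent-averaging estimate of the Karcher mean.

    Each sweep registers every shape to the current mean, averages the log
    maps and moves the mean along the average with step size ``step``
    (halved whenever the objective increases).  Stops when the mean tangent
    ``||v_bar||`` drops below ``tol`` or after ``max_iter`` sweeps.  The
    initial mean is the preshape-projected extrinsic average of the shapes
    registered to the first one.
    """
    shapes = list(shapes)
    if not shapes:
        raise ValueError("karcher_mean needs at least one shape")
    # Register at DP lattice resolution and single-start: registration to
    # the mean is a near-identity problem, and the continuous gamma polish
    # used for pairwise distances would over-register ensemble members to
    # the mean, absorbing transverse shape variation into the nuisance
    # warp and biasing the covariance downward.
    akw = {"refine": False, "multistart": False, **(align_kwargs or {})}
    m = shapes[0].grid_size
    if any(q.grid_size != m for q in shapes):
        raise ValueError("all shapes must share one grid")
    if len(shapes) == 1:
        q = shapes[0]
        return ShapeMean(mu=q, aligned=(q,), sum_sq_dist=0.0, iterations=0,
                         converged=True, objective_history=(0.0,))

    first_aligned = [shapes[0]] + [
        align(shapes[0], q, **akw).q2_star for q in shapes[1:]
    ]
    mu = project_to_preshape(
        SRVF(values=np.mean([q.values for q in first_aligned], axis=0))
    )

    eps = step
    history: list[float] = []
    aligned = first_aligned
    converged = False
    iterations = 0
    mu_prev = mu
    for iterations in range(1, max_iter + 1):
        results = [align(mu, q, **akw) for q in shapes]
        objective = float(sum(r.theta**2 for r in results))
        if history and objective > history[-1] + 1e-9:
            # overshoot: revert the last step and retry with half the step
            mu = mu_prev
            eps = max(eps / 2.0, 1e-3)
            continue
        aligned = [r.q2_star for r in results]
        history.append(objective)
        v_bar = np.mean([log_map(mu, q) for q in aligned], axis=0)
        if _tangent_norm(m, v_bar) < tol:
            converged = True
            break
        mu_prev = mu
        mu = exp_map(mu, eps * v_bar)
    if not converged:
        logger.warning("Karcher mean: no convergence in %d iterations", max_iter)
    return ShapeMean(
        mu=mu,
        aligned=tuple(aligned),
        sum_sq_dist=history[-1] if history else 0.0,
        iterations=iterations,
        converged=converged,
        objective_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# Covariance and the Gaussian shape model
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ShapeDistribution:
    """Gaussian-type shape model: Karcher mean + principal tangent directions.

    ``directions`` is a (k, m, 3) stack of L2-orthonormal tangent vectors at
    the mean (principal components of the sample covariance); ``sigma`` the
    corresponding variances (singular values of the covariance), decreasing.
    ``n_residues`` optionally records how many residues the mean curve
    represents, for per-residue summaries.
    """

    mean: ShapeMean
    directions: np.ndarray
    sigma: np.ndarray
    sample_size: int
    n_residues: int | None = None

    @property
    def k(self) -> int:
        return int(self.sigma.size)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_size": self.mean.mu.grid_size,
            "mean": self.mean.mu.values.tolist(),
            "sigma": self.sigma.tolist(),
            "directions": self.directions.reshape(self.k, -1).tolist(),
            "sample_size": self.sample_size,
            "n_residues": self.n_residues,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapeDistribution":
        payload = json.loads(Path(path).read_text())
        m = payload["grid_size"]
        mu = SRVF(values=np.asarray(payload["mean"]))
        sigma = np.asarray(payload["sigma"], dtype=float)
        directions = np.asarray(payload["directions"], dtype=float).reshape(-1, m, 3)
        mean = ShapeMean(mu=mu, aligned=(), sum_sq_dist=float("nan"),
                         iterations=0, converged=True)
        return cls(mean=mean, directions=directions, sigma=sigma,
                   sample_size=int(payload["sample_size"]),
                   n_residues=payload.get("n_residues"))


def shape_covariance(
    mean: ShapeMean,
    shapes: Sequence[SRVF] | None = None,
    n_residues: int | None = None,
) -> ShapeDistribution:
    """Tangent-space sample covariance and its SVD.

    Each shape (already registered to the mean — by default the aligned
    shapes stored on ``mean``) is pulled back to the tangent space at mu.
    Tangent vectors are flattened with square-root quadrature weights so
    that the Euclidean SVD is exactly the L2 PCA: the retained directions
    are L2-orthonormal and the sigma are tangent-space variances.  Retains
    ``k = min(n-1, 3m)`` components with sigma > 1e-12.
    """
    if shapes is None:
        shapes = mean.aligned
    shapes = list(shapes)
    n = len(shapes)
    if n < 2:
        raise ValueError("covariance needs at least 2 shapes")
    mu = mean.mu
    m = mu.grid_size
    w = trapezoid_weights(m)
    sw = np.sqrt(w)[:, None]
    vs = np.stack([log_map(mu, q) * sw for q in shapes])  # (n, m, 3), weighted
    flat = vs.reshape(n, -1)
    centered = flat - flat.mean(axis=0)
    # SVD of the centered data matrix: right singular vectors are the
    # principal directions, singular values squared / (n-1) the variances.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    sigma = svals**2 / (n - 1)
    k_max = min(n - 1, 3 * m)
    keep = np.where(sigma[:k_max] > 1e-12)[0]
    sigma = sigma[keep]
    directions = (vt[keep].reshape(-1, m, 3)) / sw  # undo weighting
    return ShapeDistribution(
        mean=mean,
        directions=directions,
        sigma=sigma,
        sample_size=n,
        n_residues=n_residues,
    )


def fit_shape_distribution(
    shapes: Sequence[SRVF],
    n_residues: int | None = None,
    **karcher_kwargs,
) -> ShapeDistribution:
    """Convenience: Karcher mean followed by tangent covariance."""
    mean = karcher_mean(shapes, **karcher_kwargs)
    return shape_covariance(mean, n_residues=n_residues)


def sample_shapes(dist: ShapeDistribution, count: int, seed: int) -> list[SRVF]:
    """Draw random shapes from the Gaussian-type model.

    v = sum_j z_j sqrt(sigma_j) U_j with z ~ N(0, I_k), pushed through the
    exp map at the mean.  Reproducible for a fixed seed; with no retained
    components every sample is the mean itself.
    """
    rng = np.random.default_rng(seed)
    mu = dist.mean.mu
    if dist.k == 0:
        return [SRVF(values=mu.values.copy()) for _ in range(count)]
    z = rng.standard_normal((count, dist.k))
    amps = z * np.sqrt(dist.sigma)[None, :]
    out = []
    for i in range(count):
        v = np.tensordot(amps[i], dist.directions, axes=(0, 0))
        out.append(exp_map(mu, v))
    return out


def principal_sweep(
    dist: ShapeDistribution,
    component: int,
    t_values: Sequence[float],
    origin: tuple = (0.0, 0.0, 0.0),
) -> list[BackboneCurve]:
    """Shapes along one principal direction, ``v = t sqrt(sigma_i) U_i``.

    Sweeping t over [-2, 2] visualizes the variability captured by that
    component; t = 0 reproduces the mean shape.
    """
    if not 0 <= component < dist.k:
        raise ValueError(f"component {component} out of range (k={dist.k})")
    mu = dist.mean.mu
    u = dist.directions[component]
    amp = np.sqrt(dist.sigma[component])
    return [srvf_to_curve(exp_map(mu, t * amp * u), origin) for t in t_values]


def residue_variance(
    dist: ShapeDistribution,
    n_samples: int = 10,
    seed: int = 0,
    n_residues: int | None = None,
) -> np.ndarray:
    """Per-residue positional variance of the shape distribution.

    Samples random shapes, reconstructs their curves, rigidly superposes
    each onto the mean curve (rotation from SRVF registration to the mean,
    translation to a common centroid) and returns the mean squared
    deviation of each residue's samples from the mean curve.  Curve grid
    points are assigned to residues by nearest parameter.
    """
    if n_samples < 2:
        raise ValueError("residue variance needs at least 2 samples")
    mu = dist.mean.mu
    m = mu.grid_size
    if n_residues is None:
        n_residues = dist.n_residues or m
    mean_curve = srvf_to_curve(mu).points
    mean_curve = mean_curve - mean_curve.mean(axis=0)
    sq_dev = np.zeros(m)
    for q in sample_shapes(dist, n_samples, seed):
        rot = optimal_rotation(mu, q)
        pts = srvf_to_curve(rotate_srvf(q, rot)).points
        pts = pts - pts.mean(axis=0)
        sq_dev += np.sum((pts - mean_curve) ** 2, axis=1)
    sq_dev /= n_samples
    # average grid-sample deviations within each residue's parameter bin
    owner = np.minimum((np.arange(m) * n_residues) // m, n_residues - 1)
    out = np.zeros(n_residues)
    for r in range(n_residues):
        out[r] = sq_dev[owner == r].mean()
    return out


def tangent_density(dist: ShapeDistribution, q: SRVF) -> float:
    """Gaussian density of a shape under the fitted tangent model.

    The log map of q at the mean is projected onto the k retained principal
    directions and the product of the k univariate normal densities (with
    variances sigma_j) is returned.  Any tangent component orthogonal to
    the retained span is ignored (logged at debug level).  This is a
    density on the k-dimensional tangent coordinates, not a normalized
    probability on shape space.
    """
    mu = dist.mean.mu
    m = mu.grid_size
    v = log_map(mu, q)
    coords = np.array(
        [_tangent_inner(m, v, dist.directions[j]) for j in range(dist.k)]
    )
    residual = v - np.tensordot(coords, dist.directions, axes=(0, 0))
    res_norm = _tangent_norm(m, residual)
    if res_norm > 1e-8:
        logger.debug("tangent component outside model span ignored: %.3g", res_norm)
    dens = 1.0
    for c, s in zip(coords, dist.sigma):
        if s < 1e-15:
            if abs(c) > 1e-10:
                logger.warning("nonzero coordinate along zero-variance direction")
                return 0.0
            continue
        dens *= np.exp(-(c**2) / (2.0 * s)) / np.sqrt(2.0 * np.pi * s)
    return float(dens)
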