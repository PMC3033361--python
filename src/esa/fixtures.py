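"""Synthetic backbone-like curves and shape ensembles with known truth.

Geometric stand-ins for protein backbones — ideal alpha-helix CA traces,
bent helices, helix-turn-helix folds, beta hairpins and smooth random
curves — plus ensembles generated as tangent-space Gaussian perturbations
of a known mean shape, mimicking an NMR model ensemble.  Everything is
deterministic given (spec, seed), so every other module can be tested
without downloading structures.  Fixtures are geometric, not energetic: no
force field is involved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation as R

from .curves import BackboneCurve, polyline_length, rescale_to_unit_length, resample_curve
from .srvf import SRVF, curve_to_srvf, project_to_preshape
from .stats import _tangent_inner, _tangent_norm, exp_map

#: Ideal alpha-helix CA-trace constants (Angstrom / degrees).  Generators
#: and geometry oracles must both read these so they cannot drift apart.
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

KINDS = ("helix", "bent_helix", "helix_turn_helix", "hairpin", "random_smooth")


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic backbone curve."""

    kind: str
    n_residues: int
    radius: float = HELIX_RADIUS
    rise: float = HELIX_RISE
    twist_deg: float = HELIX_TWIST_DEG
    bend_angle_deg: float = 0.0
    turn_length: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; use one of {KINDS}")
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")


def _helix_points(n: int, radius: float, rise: float, twist_deg: float) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])


def make_curve(spec: FixtureSpec) -> BackboneCurve:
    """Generate a CA-trace curve from a fixture recipe (deterministic)."""
    n = spec.n_residues
    if spec.kind == "helix":
        pts = _helix_points(n, spec.radius, spec.rise, spec.twist_deg)
    elif spec.kind == "bent_helix":
        pts = _helix_points(n, spec.radius, spec.rise, spec.twist_deg)
        half = n // 2
        pivot = pts[half]
        rot = R.from_rotvec(np.deg2rad(spec.bend_angle_deg) * np.array([1.0, 0.0, 0.0]))
        pts[half:] = pivot + rot.apply(pts[half:] - pivot)
    elif spec.kind == "helix_turn_helix":
        n1 = (n - spec.turn_length) // 2
        n2 = n - spec.turn_length - n1
        h1 = _helix_points(n1, spec.radius, spec.rise, spec.twist_deg)
        # second helix: axis rotated by the bend angle (default ~150 deg)
        angle = spec.bend_angle_deg if spec.bend_angle_deg else 150.0
        rot = R.from_rotvec(np.deg2rad(angle) * np.array([1.0, 0.0, 0.0]))
        h2 = rot.apply(_helix_points(n2, spec.radius, spec.rise, spec.twist_deg))
        ca_step = 3.8
        # second helix continues from the first across a short CA-spaced gap
        h2 = h2 + h1[-1] - h2[0] + np.array([0.0, ca_step, ca_step])
        turn_pts = np.linspace(h1[-1], h2[0], spec.turn_length + 2)[1:-1]
        pts = np.vstack([h1, turn_pts, h2])
    elif spec.kind == "hairpin":
        n1 = (n - spec.turn_length) // 2
        n2 = n - spec.turn_length - n1
        step = 3.8
        up = np.column_stack([np.zeros(n1), np.zeros(n1), step * np.arange(n1)])
        down_z = step * (n1 - 1) - step * np.arange(n2)
        down = np.column_stack([np.full(n2, 5.0), np.zeros(n2), down_z])
        turn_pts = np.linspace(up[-1], down[0], spec.turn_length + 2)[1:-1]
        pts = np.vstack([up, turn_pts, down])
    else:  # random_smooth
        rng = np.random.default_rng(spec.seed)
        t = np.linspace(0.0, 1.0, n)
        pts = np.zeros((n, 3))
        for k in range(1, 5):
            amp = rng.standard_normal(3) / k**2
            phase = rng.uniform(0, 2 * np.pi, 3)
            pts += amp[None, :] * np.sin(2 * np.pi * k * t[:, None] + phase[None, :])
        pts += np.column_stack([t, np.zeros(n), np.zeros(n)])  # guarantee progress
        pts *= 3.8 * n / max(polyline_length(pts), 1e-9)
    label = f"{spec.kind}-{spec.n_residues}-s{spec.seed}"
    return BackboneCurve(points=pts, params=np.linspace(0.0, 1.0, len(pts)), label=label)


def curve_points_from_srvf(q: SRVF) -> np.ndarray:
    """Curve points whose finite-difference SRVF is exactly ``q``.

    ``srvf_to_curve`` integrates with the cumulative trapezoid, which is not
    the exact inverse of the finite-difference encoder in ``curve_to_srvf``;
    for marginally-resolved oscillatory curves (helices near the grid scale)
    the round trip perturbs the shape.  The generator instead solves the
    small linear system ``G P = q |q|`` (G being the finite-difference
    operator itself, anchored at the origin), so generated members re-encode
    to their target SRVFs to machine precision and ensemble ground truth is
    exact by construction.
    """
    m = q.grid_size
    h = 1.0 / (m - 1)
    g_op = np.gradient(np.eye(m), h, axis=0, edge_order=2)
    speed = np.linalg.norm(q.values, axis=1)
    velocity = q.values * speed[:, None]
    system = np.vstack([g_op, np.eye(m)[:1]])  # anchor P[0] = 0
    pts = np.zeros((m, 3))
    for k in range(3):
        rhs = np.append(velocity[:, k], 0.0)
        pts[:, k] = np.linalg.lstsq(system, rhs, rcond=None)[0]
    return pts


def horizontal_directions(
    mu: SRVF,
    n_modes: int,
    support: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
) -> np.ndarray:
    """Public wrapper: orthonormal horizontal tangent directions at mu.

    Horizontal means orthogonal to the rotation and reparameterization
    nuisance subspace, i.e. directions carrying genuine shape variation.
    """
    rng = np.random.default_rng(seed)
    return _smooth_tangent_directions(mu, n_modes, support, rng)


@dataclasses.dataclass(frozen=True)
class EnsembleTruth:
    """Ground truth behind a generated ensemble."""

    mu0: SRVF
    directions: np.ndarray  # (k, m, 3), L2-orthonormal tangent vectors at mu0
    scales: np.ndarray      # (k,) standard deviations along each direction


def _vertical_basis(mu: SRVF, n_fields: int = 25) -> np.ndarray:
    """Orthonormal basis of the nuisance (vertical) subspace at mu.

    Registration quotients out rotations and reparameterizations, so noise
    placed along their tangent directions is not shape variation and would
    be absorbed by alignment.  Rotations contribute the three fields
    ``e_k x mu(t)``; an infinitesimal warp gamma_eps(t) = t + eps w(t),
    w(0) = w(1) = 0, contributes ``V_w = mu' w + (1/2) w' mu``, spanned
    here by smooth sine fields w_j = sin(j pi t) up to the frequency an
    elastic registration can exploit at finite resolution.
    """
    m = mu.grid_size
    dt = 1.0 / (m - 1)
    t = np.linspace(0.0, 1.0, m)
    dmu = np.gradient(mu.values, dt, axis=0, edge_order=2)
    raw: list[np.ndarray] = []
    # infinitesimal rotations: e_k x mu(t) for the three so(3) generators
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        raw.append(np.cross(np.broadcast_to(e, (m, 3)), mu.values))
    # infinitesimal reparameterizations
    for j in range(1, n_fields + 1):
        w = np.sin(j * np.pi * t)
        wdot = j * np.pi * np.cos(j * np.pi * t)
        raw.append(dmu * w[:, None] + 0.5 * wdot[:, None] * mu.values)
    basis: list[np.ndarray] = []
    for v in raw:
        v = v - _tangent_inner(m, v, mu.values) * mu.values
        for u in basis:
            v = v - _tangent_inner(m, v, u) * u
        nv = _tangent_norm(m, v)
        if nv > 1e-8:
            basis.append(v / nv)
    return np.stack(basis)


def _smooth_tangent_directions(
    mu: SRVF,
    n_modes: int,
    support: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Orthonormal horizontal tangent fields at mu, concentrated on a t-interval.

    Each field starts as a smooth bump on the support window times a unit
    vector field pointwise orthogonal to mu(t) (a normalized cross product
    with a seeded random axis), making it exactly tangent at mu.  The
    component lying in the reparameterization (vertical) subspace is then
    projected out, so the generated variation is genuine shape variation
    that an elastic registration cannot absorb; finally the fields are
    Gram-Schmidt orthonormalized in L2.  The vertical projection spreads a
    small fraction of each field outside the window, so support
    confinement is approximate rather than exact.
    """
    lo, hi = support
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid noise support interval {support}")
    m = mu.grid_size
    t = np.linspace(0.0, 1.0, m)
    window = np.zeros(m)
    inside = (t >= lo) & (t <= hi)
    window[inside] = np.sin(np.pi * (t[inside] - lo) / (hi - lo))
    verticals = _vertical_basis(mu)
    dirs: list[np.ndarray] = []
    for j in range(n_modes):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        field = np.cross(np.broadcast_to(axis, (m, 3)), mu.values)
        norms = np.linalg.norm(field, axis=1)
        ok = norms > 1e-10
        field[ok] /= norms[ok, None]
        field[~ok] = 0.0
        # start at two lobes: single-lobe bumps are the most rigid-motion
        # -like deformations and mostly vanish under the nuisance projection
        bump = np.sin(np.pi * (j + 2) * (t - lo) / (hi - lo)) * window
        v = bump[:, None] * field
        v = v - _tangent_inner(m, v, mu.values) * mu.values
        for u in verticals:
            v = v - _tangent_inner(m, v, u) * u
        for u in dirs:
            v = v - _tangent_inner(m, v, u) * u
        nv = _tangent_norm(m, v)
        if nv < 1e-10:
            continue
        dirs.append(v / nv)
    return np.stack(dirs)


def make_ensemble(
    mean_spec: FixtureSpec,
    n: int,
    noise_sd: float,
    noise_support: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    grid_size: int = 100,
    n_modes: int = 3,
) -> tuple[list[BackboneCurve], EnsembleTruth]:
    """Tangent-Gaussian ensemble around a known mean shape.

    The mean curve's preshape SRVF mu0 is perturbed along ``n_modes``
    smooth orthonormal tangent directions (restricted to the
    ``noise_support`` parameter interval, e.g. the last 20% for a flexible
    C-terminus) with standard deviations ``noise_sd * (1, 0.4, 0.2, ...)``,
    mapped through the exp map and integrated back to curves at the
    original length scale.  Returns the curves together with the generating
    (mu0, directions, scales) ground truth.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    mean_curve = make_curve(mean_spec)
    scale = mean_curve.length
    unit = rescale_to_unit_length(resample_curve(mean_curve, grid_size))
    mu0 = project_to_preshape(curve_to_srvf(unit))
    rng = np.random.default_rng(seed)
    dirs = _smooth_tangent_directions(mu0, n_modes, noise_support, rng)
    scales = noise_sd * (0.4 ** np.arange(len(dirs)))
    params = np.linspace(0.0, 1.0, grid_size)
    curves = []
    for i in range(n):
        z = rng.standard_normal(len(dirs))
        v = np.tensordot(z * scales, dirs, axes=(0, 0))
        pts = curve_points_from_srvf(exp_map(mu0, v)) * scale
        curves.append(
            BackboneCurve(points=pts, params=params,
                          label=f"{mean_curve.label}-member{i}")
        )
    return curves, EnsembleTruth(mu0=mu0, directions=dirs, scales=scales)
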