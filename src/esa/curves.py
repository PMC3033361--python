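"""Protein backbones as parameterized 3D curves.

A protein backbone is reduced to an ordered polyline through its backbone
atoms (N, CA, C per residue, or CA only) and treated as a discretely sampled
curve ``beta(t)`` on the unit interval.  All downstream shape analysis works
on these curves; this module owns PDB input/output, resampling and length
normalization.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Backbone atom names taken from each residue, in chain order.
BACKBONE_ATOMS = ("N", "CA", "C")

#: altLoc codes accepted when a residue has alternate conformations.
_ALTLOCS = ("\x00", "A")


@dataclasses.dataclass(frozen=True)
class BackboneCurve:
    """An ordered polyline sampling of a 3D curve.

    Parameters
    ----------
    points : (n, 3) array
        Sample coordinates, in Angstrom or dimensionless after rescaling.
    params : (n,) array
        Strictly increasing parameter values in [0, 1]; the last value is 1.
        Curves read from PDB files use the ``t_i = i/n`` convention
        (``i = 1..n``); resampled curves are uniform on [0, 1] including 0.
    label : str
        Free-text identifier (e.g. ``"1mp6:A:0"``).
    """

    points: np.ndarray
    params: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        par = np.asarray(self.params, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a curve needs at least 2 points")
        if pts.shape[0] != par.shape[0]:
            raise ValueError("points and params length mismatch")
        if not np.all(np.isfinite(pts)) or not np.all(np.isfinite(par)):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(par) <= 0):
            raise ValueError("params must be strictly increasing")
        if polyline_length(pts) <= 0.0:
            raise ValueError("curve has zero length (all points identical)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "params", par)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Polyline length: sum of consecutive-point distances."""
        return polyline_length(self.points)


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Collapse exactly-repeated consecutive points (zero-speed samples)."""
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > tol
    return points[keep]


def read_backbone(
    path: str | Path,
    chain: str | None = None,
    model: int = 0,
    residue_range: tuple[int, int] | None = None,
    ca_only: bool = False,
) -> BackboneCurve:
    """Read one chain of a PDB/mmCIF file as a backbone curve.

    Parameters
    ----------
    path : str or Path
        PDB (or mmCIF) file.
    chain : str, optional
        Chain identifier; defaults to the first chain of the model.
    model : int
        Model index, 0-based (NMR files carry several MODEL records);
        default is the first model.
    residue_range : (first, last), optional
        Inclusive residue-number interval to keep.
    ca_only : bool
        Keep only CA atoms instead of the full N, CA, C backbone.

    Returns
    -------
    BackboneCurve
        One point per backbone atom in residue order, ``params`` set to
        ``i/n``.  Residues with a missing backbone atom contribute their
        remaining atoms, with a logged warning.
    """
    structure = gemmi.read_structure(str(path))
    if not 0 <= model < len(structure):
        raise ValueError(
            f"model index {model} out of range: file has {len(structure)} model(s)"
        )
    mod = structure[model]
    if len(mod) == 0:
        raise ValueError(f"model {model} of {path} has no chains")
    if chain is None:
        ch = mod[0]
    else:
        ch = mod.find_chain(chain)
        if ch is None:
            names = [c.name for c in mod]
            raise ValueError(f"chain {chain!r} not found; file has chains {names}")

    wanted = ("CA",) if ca_only else BACKBONE_ATOMS
    coords: list[np.ndarray] = []
    for res in ch:
        if residue_range is not None:
            num = res.seqid.num
            if num < residue_range[0] or num > residue_range[1]:
                continue
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue  # waters, ligands, nucleotides
        for name in wanted:
            atom = None
            for alt in _ALTLOCS:
                atom = res.find_atom(name, alt)
                if atom is not None:
                    break
            if atom is None:
                logger.warning(
                    "residue %s %s of %s: missing backbone atom %s, skipped",
                    res.name, res.seqid.num, path, name,
                )
                continue
            coords.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    if not coords:
        raise ValueError(f"no usable backbone atoms in {path} (chain={chain})")
    pts = _dedupe(np.asarray(coords))
    if len(pts) < 2:
        raise ValueError(f"fewer than 2 distinct backbone points in {path}")
    n = len(pts)
    params = np.arange(1, n + 1) / n
    label = f"{Path(path).stem}:{ch.name}:{model}"
    return BackboneCurve(points=pts, params=params, label=label)


def resample_curve(curve: BackboneCurve, m: int) -> BackboneCurve:
    """Resample a curve at ``m`` uniformly spaced parameters.

    Piecewise-linear interpolation of each coordinate against the curve's
    own parameter values; the first and last points are preserved exactly.
    The output parameter grid is uniform on [0, 1] including both endpoints.
    """
    if m < 2:
        raise ValueError("resample requires m >= 2")
    u = curve.params
    t_new = np.linspace(u[0], u[-1], m)
    pts = np.column_stack([np.interp(t_new, u, curve.points[:, k]) for k in range(3)])
    pts[0] = curve.points[0]
    pts[-1] = curve.points[-1]
    return BackboneCurve(points=pts, params=np.linspace(0.0, 1.0, m), label=curve.label)


def resample_by_arclength(curve: BackboneCurve, m: int) -> BackboneCurve:
    """Resample a curve at ``m`` equally spaced arc-length positions.

    Constant-speed (arc-length) parameterization is the canonical neutral
    starting point for elastic matching: the method optimizes over
    reparameterizations, so the initial parameterization is arbitrary, and
    equal-speed sampling removes spurious speed differences between inputs
    before the optimization starts.
    """
    if m < 2:
        raise ValueError("resample requires m >= 2")
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    arclen /= arclen[-1]
    # chord-length values may repeat only for coincident points, which
    # _dedupe removes at construction time
    s = np.linspace(0.0, 1.0, m)
    new = np.column_stack([np.interp(s, arclen, pts[:, k]) for k in range(3)])
    new[0] = pts[0]
    new[-1] = pts[-1]
    return BackboneCurve(points=new, params=s, label=curve.label)


def rescale_to_unit_length(curve: BackboneCurve) -> BackboneCurve:
    """Uniformly scale the curve so its polyline length is 1."""
    length = curve.length
    if length <= 0:
        raise ValueError("cannot rescale a zero-length curve")
    return BackboneCurve(
        points=curve.points / length, params=curve.params, label=curve.label
    )


def write_curve_pdb(
    curves: Sequence[BackboneCurve], path: str | Path, scale: float = 1.0
) -> None:
    """Write curves as a multi-model PDB of CA pseudo-atoms.

    Each curve becomes one MODEL/ENDMDL block of ALA CA records on chain A,
    so geodesic paths and sampled shapes render as trajectories in standard
    molecular viewers.  ``scale`` multiplies coordinates on output (useful
    for unit-length curves, which would otherwise vanish at the 1e-3 PDB
    column precision).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to write")
    lines: list[str] = []
    for k, curve in enumerate(curves, start=1):
        lines.append(f"MODEL     {k:4d}")
        for i, (x, y, z) in enumerate(np.asarray(curve.points) * scale, start=1):
            lines.append(
                f"ATOM  {i % 100000:5d}  CA  ALA A{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
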