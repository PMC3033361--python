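"""Shared fixtures: tiny in-repo PDB text and synthetic shape builders."""

from __future__ import annotations

import numpy as np
import pytest

from esa import SRVF, BackboneCurve, project_to_preshape
from esa.fixtures import FixtureSpec, make_curve

# A minimal 3-residue, single-chain PDB with a complete N, CA, C backbone
# (coordinates loosely follow an extended strand).
TINY_PDB = """\
HEADER    SYNTHETIC TEST PEPTIDE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.988   2.839   0.100  1.00  0.00           C
ATOM      6  C   GLY A   2       5.504   2.693   0.200  1.00  0.00           C
ATOM      7  N   SER A   3       6.191   3.839   0.300  1.00  0.00           N
ATOM      8  CA  SER A   3       7.650   3.851   0.400  1.00  0.00           C
ATOM      9  C   SER A   3       8.221   5.263   0.500  1.00  0.00           C
TER      10      SER A   3
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def tiny_pdb_missing_ca(tmp_path):
    lines = [l for l in TINY_PDB.splitlines() if not l.startswith("ATOM      5")]
    path = tmp_path / "tiny_gap.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def helix():
    return make_curve(FixtureSpec(kind="helix", n_residues=30))


@pytest.fixture
def bent_helix():
    return make_curve(FixtureSpec(kind="bent_helix", n_residues=30, bend_angle_deg=60))


@pytest.fixture
def hth():
    return make_curve(FixtureSpec(kind="helix_turn_helix", n_residues=40))


def smooth_srvf(m: int = 100, seed: int = 0, n_modes: int = 3) -> SRVF:
    """A smooth random preshape SRVF (unit L2 norm)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, m)
    vals = np.ones((m, 3)) * np.array([1.0, 0.3, -0.2])
    for k in range(1, n_modes + 1):
        amp = rng.standard_normal(3) / k
        phase = rng.uniform(0, 2 * np.pi, 3)
        vals += amp[None, :] * np.sin(2 * np.pi * k * t[:, None] + phase[None, :])
    return project_to_preshape(SRVF(values=vals))


def smooth_curve(m: int = 200, seed: int = 0) -> BackboneCurve:
    """A smooth, well-resolved random 3D curve."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, m)
    pts = np.column_stack([t, np.zeros(m), np.zeros(m)])
    for k in range(1, 4):
        amp = rng.standard_normal(3) / (3 * k**2)
        phase = rng.uniform(0, 2 * np.pi, 3)
        pts += amp[None, :] * np.sin(2 * np.pi * k * t[:, None] + phase[None, :])
    return BackboneCurve(points=pts, params=t)
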