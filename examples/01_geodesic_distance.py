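"""Geodesic shape distance between two backbone structures.

Builds a straight ideal helix and a 60-degree bent helix, writes them as
PDB files, reads them back through the standard ingestion path, and
computes the elastic geodesic distance theta (arc length on the preshape
sphere after optimizing rotation and residue correspondence).  theta = 0
means identical shapes; values near pi/2 already indicate very different
folds.
"""

import tempfile
from pathlib import Path

from esa import geodesic_distance, read_backbone, write_curve_pdb
from esa.fixtures import FixtureSpec, make_curve

tmp = Path(tempfile.mkdtemp())
helix = make_curve(FixtureSpec(kind="helix", n_residues=30))
bent = make_curve(FixtureSpec(kind="bent_helix", n_residues=30, bend_angle_deg=60))
write_curve_pdb([helix], tmp / "helix.pdb")
write_curve_pdb([bent], tmp / "bent.pdb")

a = read_backbone(tmp / "helix.pdb", ca_only=True)
b = read_backbone(tmp / "bent.pdb", ca_only=True)

theta_ab = geodesic_distance(a, b)
theta_aa = geodesic_distance(a, a)
print(f"theta(helix, helix)      = {theta_aa:.4f}   # same shape: zero")
print(f"theta(helix, bent helix) = {theta_ab:.4f}   # moderate bend: a fraction of a radian")
print("Larger theta = more deformation (bending + stretching) needed to morph one into the other.")
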