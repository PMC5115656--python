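"""Geometry descriptors of an antioxidant-radical complex.

Builds coordinates with planted values typical of a hydroxykynurenine
transition structure (short O...O bridge, near-linear O-H-O), applies a
random rigid motion, and recovers the descriptors; then demonstrates the
superposed RMSD used to compare endpoint structures.
"""

import numpy as np

from kynox import (AtomRecord, generate_geometry_fixture, geometry_report,
                   kabsch_rmsd)

targets = dict(oho_length=2.41, oho_angle=177.8, plane_angle=58.3,
               torsion=350.7)
atoms, roles, _ = generate_geometry_fixture(seed=1, targets=targets)
report = geometry_report(atoms, roles)
for key, value in report.items():
    unit = "A" if key == "oho_length" else "deg"
    print(f"{key:<12} {value:10.4f} {unit}  (planted {targets[key]})")

# RMSD of a structure against a slightly perturbed copy of itself
rng = np.random.default_rng(1)
perturbed = [AtomRecord(a.element,
                        *(np.array(a.position) + rng.normal(scale=0.02, size=3)))
             for a in atoms]
print(f"\nkabsch_rmsd to a 0.02-A-jittered copy: "
      f"{kabsch_rmsd(atoms, perturbed):.4f} A")
print("The ~2.4 A O...O distance and near-linear O-H-O angle are the "
      "signature of the H-transfer saddle point; RMSD ~0.02-0.03 A is the "
      "level of agreement expected between optimized endpoints and "
      "reaction-path termini.")
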