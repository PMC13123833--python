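"""Dimer-interface classification.

Builds the side-by-side parallel dimer of the knotted solenoid with the
conserved Phe/Cys coil decoration, and applies the composite
knotted-solenoid-dimer rule: both chains trefoil-knotted, parallel N-to-C
chains, a predominantly hydrophobic and central interface, beta-solenoid
axial rise.  An antiparallel assembly fails exactly one clause.
"""

import numpy as np

from knotsol.geometry import axial_rise, coordinate_profile, segment_coils
from knotsol.interface import classify_knotted_solenoid_dimer
from knotsol.knots import classify_open_chain
from knotsol.synthetic import (
    SolenoidSpec,
    decorate_sequence,
    make_dimer_assembly,
    make_ideal_solenoid,
)

axis = np.array([0.0, 0.0, 1.0])
spec = SolenoidSpec(skip_and_backtrack=True, seed=0)
chain = decorate_sequence(make_ideal_solenoid(spec), "PHE,GLY,ILE,CYS,LEU,GLY")

for orientation in ("parallel", "antiparallel"):
    a, b = make_dimer_assembly(chain, separation=6.0, orientation=orientation)
    knots = tuple(classify_open_chain(c, 100, seed=2).dominant.name for c in (a, b))
    segs = tuple(segment_coils(coordinate_profile(c, axis)) for c in (a, b))
    rises = tuple(axial_rise(c, axis, (4, 9), 18)[0] for c in (a, b))
    report = classify_knotted_solenoid_dimer((a, b), knots, segs, axis, rises)
    print(f"{orientation} assembly:")
    print(f"  contacts {report.n_contacts}, hydrophobic fraction "
          f"{report.hydrophobic_fraction:.2f}, orientation {report.orientation}")
    print(f"  features {report.features}")
    print(f"  knotted-solenoid dimer: {report.is_knotted_solenoid_dimer}")
# Only the parallel hydrophobic assembly satisfies the full conjunction.
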