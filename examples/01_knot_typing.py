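"""Probabilistic knot typing of open chains.

Builds an open trefoil curve with protein-like C-alpha spacing, closes it
stochastically 200 times through a sphere far outside the structure, and
types every closure by its Alexander invariants.  The dominant type, its
closure frequency and its handedness (from the mean projected writhe) are
what one would report for a real protein backbone.
"""

from knotsol.knots import classify_open_chain, knot_core
from knotsol.synthetic import make_torus_knot

chain = make_torus_knot(2, 3, n_points=120, open_gap=6, seed=0)
spectrum = classify_open_chain(chain, n_closures=200, seed=1)

print(f"chain of {len(chain)} residues")
print(f"closure spectrum: {spectrum.counts}")
print(f"dominant type:    {spectrum.dominant.name} "
      f"(invariants {spectrum.dominant.invariant_pair}, "
      f"frequency {spectrum.dominant_frequency:.2f})")
print(f"chirality:        {'+' if spectrum.dominant.chirality > 0 else '-'}"
      f"{spectrum.dominant.name}  (mean writhe {spectrum.mean_writhe:+.2f})")

core = knot_core(chain, n_closures=100, seed=1)
print(f"knot core:        residues {core.core_start}-{core.core_end}, "
      f"tails {core.n_tail}/{core.c_tail}, deep={core.deep}")
# A frequency near 1 means the open chain is unambiguously knotted; the
# core is the minimal span that still ties the trefoil.
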