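"""Knot-typing engine: Alexander invariants, KMT reduction, stochastic
closure, knot core and slipknot detection."""

import numpy as np
import pytest

from knotsol.chain import CalphaChain
from knotsol.knots import (
    alexander_invariants,
    classify_open_chain,
    closed_curve_invariants,
    detect_slipknot,
    kmt_reduce,
    knot_core,
)
from knotsol.synthetic import SolenoidSpec, make_ideal_solenoid, make_torus_knot

from conftest import torus_curve


@pytest.mark.parametrize("p,q,n,expected", [
    (1, 0, 100, (1, 1)),    # circle -> unknot
    (2, 3, 120, (3, 7)),    # trefoil
    (2, 5, 160, (5, 31)),   # cinquefoil 5_1
    (2, 7, 220, (7, 127)),  # 7_1: Delta(-1)=7, Delta(-2)=sum 4^k = 127
])
def test_torus_curve_invariants(p, q, n, expected):
    rng = np.random.default_rng(5)
    curve = torus_curve(p, q, n) + rng.normal(scale=0.01, size=(n, 3))
    assert alexander_invariants(curve, np.random.default_rng(1)) == expected


def test_figure_eight_invariants():
    t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    curve = 3.0 * np.column_stack([
        (2 + np.cos(2 * t)) * np.cos(3 * t),
        (2 + np.cos(2 * t)) * np.sin(3 * t),
        np.sin(4 * t),
    ])
    assert alexander_invariants(curve, np.random.default_rng(2)) == (5, 11)


def test_kmt_preserves_invariants_on_random_curves():
    """KMT reduction never changes the invariant pair of a closed curve."""
    rng = np.random.default_rng(0)
    cases = []
    for k in range(25):  # random smooth closed loops (mostly unknots)
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        coeffs = rng.normal(size=(3, 4, 2)) / (1.0 + np.arange(4))[None, :, None]
        pts = np.zeros((80, 3))
        for d in range(3):
            for m in range(4):
                pts[:, d] += (coeffs[d, m, 0] * np.cos((m + 1) * t)
                              + coeffs[d, m, 1] * np.sin((m + 1) * t))
        cases.append(10.0 * pts)
    for k in range(25):  # perturbed torus knots
        p, q = [(2, 3), (1, 0), (2, 5), (1, 2), (3, 2)][k % 5]
        pts = torus_curve(p, q, 140)
        cases.append(pts + rng.normal(scale=0.15, size=pts.shape))
    for curve in cases:
        before = alexander_invariants(curve, np.random.default_rng(7))
        reduced = kmt_reduce(curve, closed=True)
        after = alexander_invariants(reduced, np.random.default_rng(8))
        assert before == after
        assert len(reduced) <= len(curve)


def test_kmt_flattens_planar_zigzag():
    x = np.arange(100, dtype=float) * 3.8
    y = np.tile([0.0, 2.0], 50)[:100]
    pts = np.column_stack([x, y, np.zeros(100)])
    reduced = kmt_reduce(pts, closed=False)
    assert len(reduced) == 2
    assert np.allclose(reduced[0], pts[0]) and np.allclose(reduced[-1], pts[-1])


def test_kmt_leaves_three_points_unchanged():
    pts = np.array([[0.0, 0, 0], [1, 1, 0], [2, 0, 0]])
    assert np.array_equal(kmt_reduce(pts), pts)


def test_open_trefoil_classifies_3_1():
    chain = make_torus_knot(2, 3, 120, open_gap=6, seed=0)
    spec = classify_open_chain(chain, n_closures=200, seed=3)
    assert spec.dominant.name == "3_1"
    assert spec.dominant_frequency >= 0.9
    assert spec.dominant.chirality == +1  # standard (2,3) curve is right-handed
    assert sum(spec.counts.values()) == 200


def test_straight_chain_is_unknotted():
    coords = np.column_stack([np.arange(50) * 3.8,
                              np.zeros(50), np.zeros(50)])
    rng = np.random.default_rng(0)
    coords += rng.normal(scale=0.05, size=coords.shape)
    spec = classify_open_chain(coords, n_closures=100, seed=1)
    assert spec.dominant.name == "0_1"
    assert spec.dominant_frequency == 1.0


def test_mirror_reflection_flips_chirality():
    chain = make_torus_knot(2, 3, 120, open_gap=6, seed=0)
    mirrored = CalphaChain(coords=chain.coords * np.array([1.0, 1.0, -1.0]))
    left = classify_open_chain(mirrored, n_closures=150, seed=3)
    assert left.dominant.name == "3_1"
    assert left.dominant.chirality == -1


def test_closure_invariant_under_rigid_transform_and_reversal():
    chain = make_torus_knot(2, 3, 120, open_gap=6, seed=0)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=4).as_matrix()
    moved = chain.transformed(R, np.array([12.0, -5.0, 3.0]))
    rev = chain.reversed()
    for variant in (moved, rev):
        spec = classify_open_chain(variant, n_closures=150, seed=3)
        assert spec.dominant.name == "3_1"


def test_closed_curve_dominance_is_seedless():
    """A closed curve classifies identically for any closure seed."""
    curve = torus_curve(2, 3, 120)
    for seed in (0, 1, 99):
        name, pair, _ = closed_curve_invariants(
            curve + np.random.default_rng(5).normal(scale=0.01, size=curve.shape),
            np.random.default_rng(seed))
        assert (name, pair) == ("3_1", (3, 7))


def test_knot_core_excludes_inert_extensions(knotted_solenoid):
    """Straight tails glued on both termini are fully trimmed away."""
    coords = knotted_solenoid.coords
    n_ext = 20
    lead_dir = coords[0] - coords[1]
    lead_dir /= np.linalg.norm(lead_dir)
    tail_dir = coords[-1] - coords[-2]
    tail_dir /= np.linalg.norm(tail_dir)
    lead = coords[0] + lead_dir * 3.8 * np.arange(n_ext, 0, -1)[:, None]
    tail = coords[-1] + tail_dir * 3.8 * np.arange(1, n_ext + 1)[:, None]
    extended = CalphaChain(np.vstack([lead, coords, tail]))
    result = knot_core(extended, n_closures=60, seed=2)
    assert result.knot_type.name == "3_1"
    assert result.n_tail >= n_ext
    assert result.c_tail >= n_ext
    assert result.deep
    core_len = result.core_end - result.core_start + 1
    assert core_len <= len(knotted_solenoid)


def test_knot_core_rejects_unknot():
    coords = np.column_stack([np.arange(40) * 3.8, np.zeros(40), np.zeros(40)])
    coords += np.random.default_rng(1).normal(scale=0.05, size=coords.shape)
    with pytest.raises(ValueError, match="no core"):
        knot_core(CalphaChain(coords), n_closures=50, seed=0)


def test_slipknot_detection():
    # retract the final arc of an open trefoil back out of the loop:
    # take a knotted chain and append its own last segment reversed, so the
    # whole chain ends where the threading segment started
    chain = make_torus_knot(2, 3, 120, open_gap=6, seed=0)
    coords = chain.coords
    # retrace the last 25 residues back along their own path (slightly
    # offset): the threading segment withdraws, untying the whole chain
    # while the prefix subchain stays knotted
    hairpin = coords[-2:-27:-1] + np.array([0.9, 0.6, 0.8])
    slip = np.vstack([coords, hairpin])
    whole = classify_open_chain(slip, 60, seed=2).dominant.name
    assert whole == "0_1", "retraction should untie the whole chain"
    flag, rng_found = detect_slipknot(slip, grid_step=6, n_closures=40, seed=1)
    assert flag
    assert rng_found is not None
    # a straight chain has no slipknot
    line = np.column_stack([np.arange(40) * 3.8, np.zeros(40), np.zeros(40)])
    line += np.random.default_rng(0).normal(scale=0.05, size=line.shape)
    assert detect_slipknot(line, grid_step=6, n_closures=30, seed=1)[0] is False
    # a fully knotted chain is not a slipknot
    flag_knot, _ = detect_slipknot(chain, grid_step=8, n_closures=30, seed=1)
    assert flag_knot is False


def test_tail_trimming_never_creates_new_knots(knotted_solenoid):
    """Monotonicity: removing tail residues never knots an unknotted span."""
    coords = knotted_solenoid.coords
    types = [classify_open_chain(coords[i:], 40, seed=9).dominant.name
             for i in range(0, 40, 10)]
    # once the knot is lost by trimming it must not reappear
    seen_unknot = False
    for t in types:
        if t == "0_1":
            seen_unknot = True
        if seen_unknot:
            assert t == "0_1"
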