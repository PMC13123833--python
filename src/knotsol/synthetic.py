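"""Synthetic structures: parametric knots, ideal beta-solenoids and dimers.

The solenoid generator emulates the knotted-solenoid architecture: stacked
triangular coils of beta-strand-like C-alpha traces with ~4.8 A axial rise.
In the knotted variant the sequential coils occupy the order-shifted axial
levels (0, 1, 3, 2): the third coil skips a level, a long extended linker
descends around the outside of the barrel back to the skipped level, and
the C-terminal segment exits through the opening framed by the linker --
producing a right-handed +3_1 knot, asserted topologically at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


from .chain import AMINO_ACIDS, CA_BOND, CalphaChain


class RoutingError(ValueError):
    """Raised when a generated chain self-intersects or fails its
    build-time topological assertion."""


@dataclass
class SolenoidSpec:
    """Parameters of an ideal beta-solenoid.

    ``rise_per_coil`` is the axial displacement between stacked coils in
    Angstrom (~4.8 A for beta-solenoids); ``radius`` is the circumradius of
    the polygonal cross-section (derived from the 3.8 A virtual bond when
    omitted).  ``linker_length`` and ``cterm_thread_length`` only apply to
    the skip-and-backtrack variant.
    """

    n_coils: int = 4
    residues_per_side: int = 6
    sides: int = 3
    rise_per_coil: float = 4.8
    radius: float | None = None
    skip_and_backtrack: bool = False
    linker_length: int = 25
    cterm_thread_length: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coils < 2:
            raise ValueError("n_coils must be >= 2")
        if self.sides < 3:
            raise ValueError("sides must be >= 3")
        if self.rise_per_coil <= 0:
            raise ValueError("rise_per_coil must be positive")
        if self.skip_and_backtrack:
            if self.n_coils < 4:
                raise ValueError("skip_and_backtrack requires n_coils >= 4")
            if self.linker_length < 15:
                raise ValueError("skip_and_backtrack requires linker_length >= 15")
        if self.radius is None:
            side_len = self.residues_per_side * CA_BOND
            self.radius = side_len / (2.0 * math.sin(math.pi / self.sides))

    @property
    def levels(self) -> list[int]:
        """Axial level of each sequential coil."""
        if not self.skip_and_backtrack:
            return list(range(self.n_coils))
        return [0, 1, 3, 2] + list(range(4, self.n_coils))


def make_torus_knot(
    p: int,
    q: int,
    n_points: int = 120,
    scale: float | str = "auto",
    open_gap: int = 0,
    seed: int = 0,
) -> CalphaChain:
    """C-alpha chain tracing a (p, q) torus curve.

    ``(2, 3)`` is the right-handed trefoil, ``(1, 0)`` a circle (unknot).
    Points are uniform in the curve parameter and rescaled so consecutive
    spacing is ~3.8 A; ``open_gap`` trailing points are removed to open the
    chain.  A tiny seeded jitter (0.01 A) avoids degenerate projections of
    the perfectly symmetric curve.
    """
    if math.gcd(p, q) != 1:
        raise ValueError(f"(p, q) = ({p}, {q}) must be coprime")
    if n_points < 60:
        raise ValueError("n_points must be >= 60 to resolve crossings")
    if open_gap < 0 or open_gap > n_points - 10:
        raise ValueError("open_gap out of range")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    big, small = 2.0, 1.0
    radial = big + small * np.cos(q * theta)
    pts = np.column_stack([
        radial * np.cos(p * theta),
        radial * np.sin(p * theta),
        small * np.sin(q * theta),
    ])
    if scale == "auto":
        spacing = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())
        pts *= CA_BOND / spacing
    else:
        pts *= float(scale)
    rng = np.random.default_rng(seed)
    pts = pts + rng.normal(scale=0.01, size=pts.shape)
    if open_gap:
        pts = pts[: n_points - open_gap]
    return CalphaChain(coords=pts, chain_id="A")


def _cyl(theta: float, r: float, z: float) -> np.ndarray:
    return np.array([r * math.cos(theta), r * math.sin(theta), z])


def _coil_points(spec: SolenoidSpec, start_angle: float, z0: float) -> np.ndarray:
    """One planar polygonal coil at height z0."""
    sides, rps, R = spec.sides, spec.residues_per_side, spec.radius
    m = sides * rps
    verts = [
        _cyl(start_angle + 2.0 * math.pi * k / sides, R, 0.0)
        for k in range(sides + 1)
    ]
    pts = np.empty((m, 3))
    idx = 0
    for k in range(sides):
        a, b = verts[k], verts[k + 1]
        for t in range(rps):
            pts[idx] = a + (t / rps) * (b - a)
            idx += 1
    # uniform intra-coil junction ramp (the 'beta-arc'): the last three
    # residues climb toward the next level and the first three descend from
    # it, identically in every coil, so z(i + m) - z(i) is exactly one rise
    # within any contiguous stack
    z = np.full(m, z0)
    ramp = spec.rise_per_coil * np.array([0.1, 0.3, 0.5])
    z[-3:] += ramp
    z[:3] -= ramp[::-1]
    pts[:, 2] = z
    return pts


def _resample_path(waypoints: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a waypoint path into n interior points at uniform arclength
    (the two endpoint waypoints are dropped -- they belong to the coils)."""
    wp = np.asarray(waypoints, float)
    # Chaikin corner cutting: smooths sharp waypoint corners with bounded
    # curvature so equal-arclength samples keep near-equal chord lengths
    dense = wp
    for _ in range(4):
        a = dense[:-1]
        b = dense[1:]
        mid = np.empty((2 * len(a), 3))
        mid[0::2] = 0.75 * a + 0.25 * b
        mid[1::2] = 0.25 * a + 0.75 * b
        dense = np.vstack([dense[0], mid, dense[-1]])
    ds = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    target = np.linspace(0.0, ds[-1], n_points + 2)[1:-1]
    out = np.empty((n_points, 3))
    for d in range(3):
        out[:, d] = np.interp(target, ds, dense[:, d])
    return out


def _equalize_bonds(coords: np.ndarray, movable: np.ndarray,
                    target: float = CA_BOND, iters: int = 60,
                    lr: float = 0.25) -> np.ndarray:
    """Gentle relaxation pulling consecutive distances toward the target
    virtual bond; only ``movable`` residues (connectors, linker, thread)
    are adjusted, so coil geometry stays exact."""
    pts = coords.copy()
    for _ in range(iters):
        delta = np.diff(pts, axis=0)
        dist = np.linalg.norm(delta, axis=1, keepdims=True)
        unit = delta / np.maximum(dist, 1e-9)
        err = (dist - target) * unit          # force along each bond
        grad = np.zeros_like(pts)
        grad[:-1] += err
        grad[1:] -= err
        pts[movable] += lr * grad[movable]
    return pts


def _min_self_distance(coords: np.ndarray, skip: int = 2) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(6.0, output_type="ndarray")
    if len(pairs) == 0:
        return np.inf
    far = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) >= skip]
    if len(far) == 0:
        return np.inf
    d = np.linalg.norm(coords[far[:, 0]] - coords[far[:, 1]], axis=1)
    return float(d.min())


def make_ideal_solenoid(spec: SolenoidSpec, validate: bool = True) -> CalphaChain:
    """Ideal beta-solenoid C-alpha trace, regular or skip-and-backtrack.

    The regular variant stacks coils at axial levels 0, 1, 2, ...; the
    skip-and-backtrack variant uses levels (0, 1, 3, 2, ...), routes the
    backtracking linker around the outside of the barrel and threads the
    C-terminal segment through the opening it frames.  With ``validate``
    the knotted variant is classified by stochastic closure at build time
    and must come out a dominant right-handed 3_1 (RoutingError otherwise);
    the regular variant must come out unknotted.
    """
    h = spec.rise_per_coil
    R = spec.radius
    # start angle chosen so each coil crosses the -y direction at its
    # junction: the lateral-profile minima then sit at coil boundaries and
    # minima-delimited segments coincide with single coils
    theta0 = 1.5 * math.pi
    levels = spec.levels
    if spec.skip_and_backtrack and spec.n_coils != 4:
        raise RoutingError(
            "skip-and-backtrack routing is implemented for the canonical "
            "four-coil architecture (levels 0, 1, 3, 2); additional coils "
            "would collide with the backtracking linker"
        )

    # coil start angles: stacked coils stay in phase; the post-linker coil
    # starts where the 270-degree linker orbit lands
    m = spec.sides * spec.residues_per_side
    start_angles = []
    for c in range(spec.n_coils):
        if spec.skip_and_backtrack and c == 3:
            start_angles.append(theta0 - 2.0 * math.pi / m + _linker_sweep(spec))
        else:
            start_angles.append(theta0)

    blocks = [
        _coil_points(spec, start_angles[c], levels[c] * h)
        for c in range(spec.n_coils)
    ]

    pieces: list[np.ndarray] = []
    movable: list[np.ndarray] = []
    for c in range(spec.n_coils):
        pieces.append(blocks[c])
        movable.append(np.zeros(len(blocks[c]), dtype=bool))
        if c == spec.n_coils - 1:
            break
        dz = levels[c + 1] - levels[c]
        if dz == 1 and start_angles[c + 1] == start_angles[c]:
            pass  # the intra-coil ramps already join these levels
        elif spec.skip_and_backtrack and c == 2:
            pieces.append(_linker_path(spec, blocks[c][-1], start_angles[c + 1],
                                       levels[c] * h, levels[c + 1] * h))
            movable.append(np.ones(len(pieces[-1]), dtype=bool))
        else:
            pieces.append(_ascent_connector(spec, blocks[c][-1], blocks[c + 1][0]))
            movable.append(np.ones(len(pieces[-1]), dtype=bool))

    if spec.skip_and_backtrack:
        pieces.append(_thread_path(spec, blocks[3][-1], theta0))
        movable.append(np.ones(len(pieces[-1]), dtype=bool))

    coords = np.vstack(pieces)
    coords = _equalize_bonds(coords, np.concatenate(movable))
    # the raw routing traces a left-handed knot; reflect to make the
    # generated trefoil right-handed (+3_1)
    coords[:, 0] *= -1.0
    rng = np.random.default_rng(spec.seed)
    coords = coords + rng.normal(scale=0.02, size=coords.shape)

    if _min_self_distance(coords) < 2.0:
        raise RoutingError(
            f"routing failure: self-intersection within 2.0 A "
            f"(min non-bonded distance {_min_self_distance(coords):.2f} A)"
        )
    chain = CalphaChain(coords=coords, chain_id="A")
    if validate:
        from .knots import classify_open_chain

        spectrum = classify_open_chain(chain, n_closures=100, seed=spec.seed + 1)
        if spec.skip_and_backtrack:
            if spectrum.dominant.name != "3_1":
                raise RoutingError(
                    f"knotted-solenoid construction failed its topological "
                    f"assertion: dominant closure {spectrum.dominant.name} "
                    f"(frequency {spectrum.dominant_frequency:.2f})"
                )
            if spectrum.dominant.chirality < 0:
                raise RoutingError("construction produced a left-handed trefoil")
        elif spectrum.dominant.name != "0_1":
            raise RoutingError(
                f"regular solenoid classifies {spectrum.dominant.name}, expected unknot"
            )
    return chain


def _angle_of(p: np.ndarray) -> float:
    return math.atan2(p[1], p[0])


def _ascent_connector(spec: SolenoidSpec, p_from: np.ndarray,
                      p_to: np.ndarray) -> np.ndarray:
    """Short connector bridging the skipped level, routed through the
    channel interior: the backtracking coil later wraps around it, which
    is what threads the loop and lets the closed chain knot."""
    r_in = 0.6 * spec.radius * math.cos(math.pi / spec.sides)
    a_f = _angle_of(p_from)
    a_t = _angle_of(p_to)
    z_f, z_t = p_from[2], p_to[2]
    wps = np.array([
        p_from,
        _cyl(a_f + 0.4 * (a_t - a_f), r_in, z_f + 0.08 * (z_t - z_f)),
        _cyl(a_f + 0.7 * (a_t - a_f), r_in, z_t),
        p_to,
    ])
    contour = float(np.linalg.norm(np.diff(wps, axis=0), axis=1).sum())
    n_conn = max(2, int(round(contour / CA_BOND)) - 1)
    return _resample_path(wps, n_conn)


def _linker_sweep(spec: SolenoidSpec) -> float:
    """Angular extent of the linker orbit, sized so that linker_length
    residues at ~3.8 A trace it comfortably."""
    R = spec.radius
    contour = (spec.linker_length + 1) * 3.5
    sweep = (contour - 18.0 - spec.rise_per_coil) / (R + 9.0)
    return float(np.clip(sweep, 0.5 * math.pi, 1.9 * math.pi))


def _linker_path(spec: SolenoidSpec, p_from: np.ndarray, angle_to: float,
                 z_from: float, z_to: float) -> np.ndarray:
    """Backtracking linker: out of the wall, a descending orbit around the
    outside of the barrel, and steeply back in to the skipped level."""
    R, h = spec.radius, spec.rise_per_coil
    r_out = R + 9.0
    # unwrapped start angle of the orbit (atan2 would wrap at +/- pi)
    a_f = angle_to - _linker_sweep(spec)
    z_hi = z_from - 0.1 * h
    z_lo = z_to + 0.1 * h
    n_orbit = 12
    wps = [p_from, _cyl(a_f - 0.12, r_out, z_hi)]
    for k in range(1, n_orbit + 1):
        f = k / (n_orbit + 1)
        a = a_f + f * (angle_to - a_f)
        wps.append(_cyl(a, r_out, z_hi + f * (z_lo - z_hi)))
    wps.append(_cyl(angle_to, r_out, z_lo))
    wps.append(_cyl(angle_to, R, z_to))
    return _resample_path(np.array(wps), spec.linker_length)


CURL = 0.6


def _thread_path(spec: SolenoidSpec, p_from: np.ndarray,
                 theta0: float) -> np.ndarray:
    """C-terminal thread: slips back under the descending linker, climbs
    between the channel wall and the linker (piercing the opening the
    linker frames) and exits radially above the linker orbit."""
    R, h = spec.radius, spec.rise_per_coil
    m = spec.sides * spec.residues_per_side
    sweep = _linker_sweep(spec)
    angle_to = theta0 - 2.0 * math.pi / m + sweep   # backtracked-coil start
    a_e = angle_to - 2.0 * math.pi / m              # its end (mod 2 pi)
    a_cross = angle_to - 0.45 * sweep  # pierce the linker-wall ribbon here
    z_end = p_from[2]
    a_in = a_cross + math.pi  # descend into the channel opposite the ascent
    base = [
        p_from,
        _cyl(a_e, R + 4.0, z_end - 0.4 * h),
        _cyl(a_cross, R + 4.0, z_end - 0.45 * h),
        _cyl(a_cross, R + 4.5, z_end + 1.8 * h),
        _cyl(a_cross, R - 2.0, z_end + 1.9 * h),
        _cyl(0.5 * (a_cross + a_in), 2.5, z_end + 1.6 * h),
    ]
    # after piercing, the tail crosses over the rim and descends into the
    # channel, capping it: its native position is only reachable through
    # the loop, which is what makes folding and knotting inseparable.
    # The descent depth consumes whatever length the thread has left.
    fixed = float(np.linalg.norm(np.diff(np.array(base), axis=0), axis=1).sum())
    depth = min(1.2 * h, max(0.3 * h,
                             (spec.cterm_thread_length + 1) * 3.6 - fixed))
    base.append(_cyl(0.5 * (a_cross + a_in), 2.5, z_end + 1.6 * h - depth))
    return _resample_path(np.array(base), spec.cterm_thread_length)


def decorate_sequence(chain: CalphaChain, motif) -> CalphaChain:
    """Overwrite residue identities by tiling a motif; coordinates untouched.

    ``motif`` is a comma-separated string or sequence of 3-letter codes
    ('x' or '-' entries keep a generic GLY placeholder).
    """
    if isinstance(motif, str):
        motif = [tok.strip() for tok in motif.split(",") if tok.strip()]
    codes = []
    for tok in motif:
        name = tok.upper()
        if name in {"X", "-"}:
            name = "GLY"
        if name not in AMINO_ACIDS:
            raise ValueError(f"unknown 3-letter residue code: {tok!r}")
        codes.append(name)
    if not codes:
        raise ValueError("empty motif")
    names = [codes[i % len(codes)] for i in range(len(chain))]
    return CalphaChain(
        coords=chain.coords.copy(),
        residue_names=names,
        residue_numbers=chain.residue_numbers.copy(),
        chain_id=chain.chain_id,
    )


def coil_start_motif(spec: SolenoidSpec) -> list[str]:
    """Phe at the first position of each coil side, Cys three residues
    later -- the conserved repeat decorating the knotted-solenoid coils."""
    side = ["GLY"] * spec.residues_per_side
    side[0] = "PHE"
    if spec.residues_per_side > 3:
        side[3] = "CYS"
    return side


def make_dimer_assembly(
    chain: CalphaChain,
    separation: float = 10.0,
    orientation: str = "parallel",
) -> tuple[CalphaChain, CalphaChain]:
    """Side-by-side symmetric dimer from one chain.

    The second copy is generated by a 180-degree rotation about an axis
    parallel to the solenoid (z) axis for the parallel mode -- both chains
    then run N-to-C in the same direction -- or about a perpendicular axis
    for the antiparallel mode.  It is then translated laterally so that the
    nearest inter-copy C-alpha distance equals ``separation`` (the surface
    gap between the barrels).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if orientation not in {"parallel", "antiparallel"}:
        raise ValueError("orientation must be 'parallel' or 'antiparallel'")
    from scipy.optimize import brentq
    from scipy.spatial import cKDTree

    center = chain.coords.mean(axis=0)
    if orientation == "parallel":
        Rm = np.diag([-1.0, -1.0, 1.0])   # C2 about z
    else:
        Rm = np.diag([-1.0, 1.0, -1.0])   # C2 about y
    rotated = (chain.coords - center) @ Rm.T + center
    tree = cKDTree(chain.coords)
    # translate toward the chain's flattest lateral face (the azimuth with
    # the smallest maximal radius), so the barrels meet wall-to-wall rather
    # than linker-to-linker; the C2 copy's flat face then points back
    centred_xy = chain.coords[:, :2] - center[:2]
    angles = np.linspace(-np.pi, np.pi, 72, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    support = (centred_xy @ dirs.T).max(axis=0)   # support function h(d)
    ang = angles[int(np.argmin(support))]
    shift = np.array([np.cos(ang), np.sin(ang), 0.0])

    def gap(t: float) -> float:
        d, _ = tree.query(rotated + t * shift, k=1)
        return float(np.min(d)) - separation

    extent = float(np.ptp(chain.coords[:, 0]) + np.ptp(chain.coords[:, 1]))
    t_hi = 2.0 * extent + separation + 10.0
    t_star = brentq(gap, 0.0, t_hi) if gap(0.0) < 0 else 0.0
    coords_b = rotated + t_star * shift
    b = CalphaChain(
        coords=coords_b,
        residue_names=list(chain.residue_names),
        residue_numbers=chain.residue_numbers.copy(),
        chain_id="B",
    )
    dmin, _ = tree.query(coords_b, k=1)
    if float(np.min(dmin)) < 2.5:
        raise RoutingError(
            f"steric clash: inter-copy CA distance {float(np.min(dmin)):.2f} A < 2.5 A"
        )
    a = CalphaChain(
        coords=chain.coords.copy(),
        residue_names=list(chain.residue_names),
        residue_numbers=chain.residue_numbers.copy(),
        chain_id="A",
    )
    return a, b
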