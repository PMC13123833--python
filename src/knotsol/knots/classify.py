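"""Probabilistic knot typing of open chains: stochastic closure, knot core
location, depth assessment and slipknot detection.

Open protein backbones have no mathematically defined knot type; following
the KnotProt convention each chain is closed many times through a random
point on a large sphere, every closure is typed by its Alexander
invariants, and the chain is assigned the dominant type when it wins more
than half of the closures.  Chirality comes from the sign of the mean
projected writhe of the dominant-type closures (the Alexander polynomial
itself is blind to mirror symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chain import CalphaChain
from .alexander import closed_curve_invariants

#: closure sphere radius as a multiple of the maximal centroid distance
CLOSURE_FACTOR = 10.0
#: a type must win more than this fraction of closures to be assigned
DOMINANCE_THRESHOLD = 0.5
#: |mean writhe| below this reports undetermined chirality
WRITHE_FLOOR = 0.5
#: tails longer than this on both sides make a knot "deep"
DEEP_TAIL = 10


@dataclass
class KnotType:
    name: str
    invariant_pair: tuple[int, int]
    chirality: int = 0

    @property
    def is_knotted(self) -> bool:
        return self.name != "0_1"


@dataclass
class ClosureSpectrum:
    """Outcome of stochastic-closure typing of one open chain."""

    counts: dict[str, int]
    n_closures: int
    dominant: KnotType
    dominant_frequency: float
    mean_writhe: float = 0.0

    def to_dict(self) -> dict:
        return {
            "type": self.dominant.name,
            "invariant_pair": list(self.dominant.invariant_pair),
            "frequency": self.dominant_frequency,
            "chirality": self.dominant.chirality,
            "counts": dict(self.counts),
            "n_closures": self.n_closures,
        }


@dataclass
class KnotCoreResult:
    core_start: int            # author residue number
    core_end: int
    n_tail: int
    c_tail: int
    deep: bool
    knot_type: KnotType = field(default_factory=lambda: KnotType("0_1", (1, 1)))

    def to_dict(self) -> dict:
        return {
            "type": self.knot_type.name,
            "core": [self.core_start, self.core_end],
            "tails": [self.n_tail, self.c_tail],
            "deep": self.deep,
        }


def _as_coords(chain) -> np.ndarray:
    if isinstance(chain, CalphaChain):
        if chain.breaks:
            raise ValueError(
                "chain has break flags; pass allow_breaks=True to classify anyway"
            )
        return chain.coords
    return np.asarray(chain, float)


def _closure_points(coords: np.ndarray, n: int, rng: np.random.Generator,
                    closure_factor: float) -> np.ndarray:
    centroid = coords.mean(axis=0)
    radius = closure_factor * float(np.linalg.norm(coords - centroid, axis=1).max())
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return centroid + radius * v


def classify_open_chain(
    chain,
    n_closures: int = 200,
    seed: int | np.random.Generator | None = 0,
    closure_factor: float = CLOSURE_FACTOR,
    allow_breaks: bool = False,
) -> ClosureSpectrum:
    """Stochastic-closure knot spectrum of an open chain.

    Both termini are joined through a single uniformly random point on a
    sphere of radius ``closure_factor`` x (max chain extent) centred at the
    centroid; each closed curve is KMT-reduced and typed.
    """
    if isinstance(chain, CalphaChain) and chain.breaks and not allow_breaks:
        raise ValueError("chain has break flags; pass allow_breaks=True to classify anyway")
    coords = chain.coords if isinstance(chain, CalphaChain) else np.asarray(chain, float)
    if len(coords) < 10:
        raise ValueError("need at least 10 residues to classify")
    if n_closures < 1:
        raise ValueError("n_closures must be >= 1")
    rng = np.random.default_rng(seed)
    points = _closure_points(coords, n_closures, rng, closure_factor)
    # each terminus first extends radially away from the centroid to the
    # closure sphere (it cannot sweep through the structure), then both
    # extensions join at the random point
    centroid = coords.mean(axis=0)
    radius = closure_factor * float(np.linalg.norm(coords - centroid, axis=1).max())
    ext = []
    for term in (coords[-1], coords[0]):
        d = term - centroid
        norm = np.linalg.norm(d)
        d = d / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        ext.append(centroid + radius * d)
    ext_c, ext_n = ext
    counts: dict[str, int] = {}
    pairs: dict[str, tuple[int, int]] = {}
    writhes: dict[str, list[float]] = {}
    for k in range(n_closures):
        closed = np.vstack([coords, ext_c, 2.0 * points[k] - centroid, ext_n])
        try:
            name, pair, writhe = closed_curve_invariants(closed, rng)
        except ValueError:
            name, pair, writhe = "0_1", (1, 1), 0.0
        counts[name] = counts.get(name, 0) + 1
        pairs[name] = pair
        writhes.setdefault(name, []).append(writhe)
    dominant_name = max(counts, key=counts.get)
    freq = counts[dominant_name] / n_closures
    if freq <= DOMINANCE_THRESHOLD and dominant_name != "0_1":
        dominant = KnotType("0_1", (1, 1), 0)
        mean_w = 0.0
    else:
        mean_w = float(np.mean(writhes[dominant_name]))
        chirality = 0
        if dominant_name != "0_1" and abs(mean_w) >= WRITHE_FLOOR:
            chirality = 1 if mean_w > 0 else -1
        dominant = KnotType(dominant_name, pairs[dominant_name], chirality)
    return ClosureSpectrum(counts, n_closures, dominant, freq, mean_w)


def _subchain_type(coords: np.ndarray, n_closures: int, seed: int,
                   closure_factor: float = CLOSURE_FACTOR) -> str:
    spec = classify_open_chain(coords, n_closures, seed, closure_factor)
    return spec.dominant.name


def knot_core(
    chain: CalphaChain,
    n_closures: int = 100,
    seed: int = 0,
    core_closures: int | None = None,
) -> KnotCoreResult:
    """Minimal contiguous subchain that retains the chain's knot type.

    Residues are trimmed one at a time from the N-terminus until the
    dominant type is lost (the last knotted start is the core start), then
    independently from the C-terminus.  Each trim step reuses the same
    closure seed so the scan is reproducible.  Boundaries are reported in
    author residue numbering.
    """
    spectrum = classify_open_chain(chain, n_closures, seed)
    if not spectrum.dominant.is_knotted:
        raise ValueError("no core: chain is not knotted")
    target = spectrum.dominant.name
    nc = core_closures or max(20, n_closures // 2)
    coords = chain.coords
    n = len(coords)
    start = 0
    for i in range(1, n - 10):
        if _subchain_type(coords[i:], nc, seed) == target:
            start = i
        else:
            break
    end = n - 1
    for j in range(n - 1, start + 10, -1):
        if _subchain_type(coords[start:j], nc, seed) == target:
            end = j - 1
        else:
            break
    n_tail = start
    c_tail = n - 1 - end
    return KnotCoreResult(
        core_start=int(chain.residue_numbers[start]),
        core_end=int(chain.residue_numbers[end]),
        n_tail=n_tail,
        c_tail=c_tail,
        deep=(n_tail > DEEP_TAIL and c_tail > DEEP_TAIL),
        knot_type=spectrum.dominant,
    )


def detect_slipknot(
    chain,
    grid_step: int = 5,
    n_closures: int = 50,
    seed: int = 0,
    min_len: int = 15,
) -> tuple[bool, tuple[int, int] | None]:
    """Slipknot test: whole chain unknotted but some subchain knotted.

    Subchains are scanned on an (i, j) grid with step ``grid_step`` (a
    coarse knot fingerprint).  Returns the flag and the maximal knotted
    subchain as positional indices, or ``None``.
    """
    coords = _as_coords(chain) if not isinstance(chain, CalphaChain) else chain.coords
    n = len(coords)
    if n < 20:
        raise ValueError("need at least 20 residues")
    whole = _subchain_type(coords, n_closures, seed)
    best = None
    for i in range(0, n - min_len, grid_step):
        for j in range(n, i + min_len, -grid_step):
            if best is not None and (j - i) <= (best[1] - best[0]):
                break
            if _subchain_type(coords[i:j], n_closures, seed) != "0_1":
                best = (i, j)
                break
    if whole != "0_1":
        return False, best
    return best is not None, best
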