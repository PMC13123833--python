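"""Dimer-interface characterization and the knotted-solenoid-dimer rule.

The composite classifier operationalizes the feature set that singles out
knotted-solenoid dimers among beta-solenoid assemblies: two trefoil-knotted
chains, side-by-side with parallel N-to-C orientation, an interface of
predominantly hydrophobic residues concentrated in the central (coil) region,
and the beta-solenoid axial rise of 4.5-5.1 A per coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chain import HYDROPHOBIC, CalphaChain, kabsch_rmsd
from .geometry import CoilSegmentation

CONTACT_CUTOFF = 8.0
RISE_WINDOW = (4.5, 5.1)
HYDROPHOBIC_THRESHOLD = 0.5
CENTRAL_THRESHOLD = 0.5
PARALLEL_COS = 0.5
SYMMETRY_RMSD = 2.0


@dataclass
class InterfaceReport:
    contact_pairs: list[tuple[int, int]]
    region_labels: dict[str, list[str]]
    hydrophobic_fraction: float
    orientation: str
    central_fraction: float
    axial_rise_ok: bool
    symmetric: bool
    is_knotted_solenoid_dimer: bool
    features: dict[str, bool]

    @property
    def n_contacts(self) -> int:
        return len(self.contact_pairs)

    def to_dict(self) -> dict:
        return {
            "n_contacts": self.n_contacts,
            "hydrophobic_fraction": round(self.hydrophobic_fraction, 3),
            "orientation": self.orientation,
            "central_fraction": round(self.central_fraction, 3),
            "axial_rise_ok": self.axial_rise_ok,
            "symmetric": self.symmetric,
            "is_knotted_solenoid_dimer": self.is_knotted_solenoid_dimer,
            "features": dict(self.features),
        }


def interchain_contacts(a: CalphaChain, b: CalphaChain,
                        cutoff: float = CONTACT_CUTOFF) -> list[tuple[int, int]]:
    """All (i, j) positional pairs with |CA_i(a) - CA_j(b)| <= cutoff."""
    if a is b:
        raise ValueError("contacts require two distinct chains")
    tree = cKDTree(b.coords)
    pairs = []
    for i, neighbours in enumerate(tree.query_ball_point(a.coords, cutoff)):
        pairs.extend((i, j) for j in sorted(neighbours))
    return pairs


def classify_regions(chain: CalphaChain, seg: CoilSegmentation) -> list[str]:
    """'terminal' before the first / after the last coil, else 'central'."""
    in_coil = np.where(seg.coil_id > 0)[0]
    if len(in_coil) == 0:
        return ["terminal"] * len(chain)
    first, last = in_coil[0], in_coil[-1]
    return ["terminal" if (i < first or i > last) else "central"
            for i in range(len(chain))]


def chain_orientation(a: CalphaChain, b: CalphaChain, axis) -> str:
    """Parallel/antiparallel by the cosine of axis-projected N->C vectors."""
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 residues per chain")
    axis = np.asarray(axis, float)

    def projected_sign(chain: CalphaChain) -> float:
        """Sign of the axis-projected N->C displacement; 0 when the
        displacement is nearly perpendicular to the axis (projection below
        30% of the displacement length)."""
        d = chain.coords[-1] - chain.coords[0]
        norm = np.linalg.norm(d)
        if norm < 1e-9 or abs(d @ axis) < 0.3 * norm:
            return 0.0
        return float(np.sign(d @ axis))

    # the axis-projected displacement vectors are (anti)collinear by
    # construction, so their cosine is the product of the two signs
    cos = projected_sign(a) * projected_sign(b)
    if cos >= PARALLEL_COS:
        return "parallel"
    if cos <= -PARALLEL_COS:
        return "antiparallel"
    return "undetermined"


def hydrophobic_interface_fraction(contacts: list[tuple[int, int]],
                                   names_a: list[str],
                                   names_b: list[str]) -> float:
    """Fraction of distinct interface residues that are hydrophobic
    (Kyte-Doolittle-positive set)."""
    if not contacts:
        raise ValueError("empty contact set")
    residues = {("A", i) for i, _ in contacts} | {("B", j) for _, j in contacts}
    hydro = sum(
        1 for side, idx in residues
        if (names_a if side == "A" else names_b)[idx] in HYDROPHOBIC
    )
    return hydro / len(residues)


def classify_knotted_solenoid_dimer(
    chains: tuple[CalphaChain, CalphaChain],
    knot_names: tuple[str, str],
    segs: tuple[CoilSegmentation, CoilSegmentation],
    axis,
    rises: tuple[float, float],
    cutoff: float = CONTACT_CUTOFF,
) -> InterfaceReport:
    """Composite knotted-solenoid-dimer rule: a pure conjunction of
    per-feature booleans (all must hold).

    Features: both chains 3_1-knotted; parallel N-to-C orientation;
    hydrophobic interface fraction >= 0.5; per-chain mean axial rise within
    4.5-5.1 A; interface contacts predominantly central; inter-copy RMSD
    after superposition <= 2 A (symmetric dimer).
    """
    if len(chains) != 2:
        raise ValueError("dimer classification requires exactly two chains")
    a, b = chains
    contacts = interchain_contacts(a, b, cutoff)
    regions_a = classify_regions(a, segs[0])
    regions_b = classify_regions(b, segs[1])
    if contacts:
        hydro = hydrophobic_interface_fraction(
            contacts, a.residue_names, b.residue_names)
        interface_regions = ([regions_a[i] for i, _ in contacts]
                             + [regions_b[j] for _, j in contacts])
        central = float(np.mean([r == "central" for r in interface_regions]))
    else:
        hydro = 0.0
        central = 0.0
    orientation = chain_orientation(a, b, axis)
    symmetric = (len(a) == len(b)
                 and kabsch_rmsd(a.coords, b.coords) <= SYMMETRY_RMSD)
    features = {
        "both_knotted_3_1": knot_names[0] == "3_1" and knot_names[1] == "3_1",
        "parallel": orientation == "parallel",
        "hydrophobic_interface": hydro >= HYDROPHOBIC_THRESHOLD,
        "axial_rise_in_window": all(RISE_WINDOW[0] <= r <= RISE_WINDOW[1] for r in rises),
        "contacts_central": central > CENTRAL_THRESHOLD,
        "symmetric": symmetric,
    }
    return InterfaceReport(
        contact_pairs=contacts,
        region_labels={"A": regions_a, "B": regions_b},
        hydrophobic_fraction=hydro,
        orientation=orientation,
        central_fraction=central,
        axial_rise_ok=features["axial_rise_in_window"],
        symmetric=symmetric,
        is_knotted_solenoid_dimer=all(features.values()),
        features=features,
    )
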