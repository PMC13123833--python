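"""C-alpha structure-based (Go-type) model topology.

Reduced units: energy epsilon = 1, bead mass = 1, k_B = 1, length in
Angstrom; the time unit tau follows from these.  Bonded terms are harmonic
at their native values, dihedrals use the 1+3 cosine form, and native
contacts use the Gaussian well

    G(r) = eps * [(1 + (r_ex/r)^12) * (1 - exp(-(r - r0)^2 / (2 w^2))) - 1]

which is exactly -eps at the native distance and decays to zero, with a
hard excluded-volume core.  Non-contact pairs get the same (r_ex/r)^12
repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chain import CalphaChain
from .contacts import ResidueContact

K_BOND = 100.0      # eps / A^2
K_ANGLE = 20.0      # eps / rad^2
K_DIHEDRAL = 1.0    # eps
GAUSSIAN_WIDTH = 0.5   # A
R_EXCLUDED = 4.0       # A
TETHER_SCALE = 0.00005  # dimer COM spring = K_BOND * this


@dataclass
class SBMTopology:
    """Flat-array topology consumed by the dynamics kernel."""

    native: np.ndarray                 # (n, 3) native coordinates
    chain_of: np.ndarray               # (n,) chain index per bead
    chain_ids: list[str]
    bonds: np.ndarray                  # (nb, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray                 # (na, 3) int
    angle_t0: np.ndarray
    dihedrals: np.ndarray              # (nd, 4) int
    dihedral_p0: np.ndarray
    contacts: np.ndarray               # (nc, 2) int
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_inter: np.ndarray          # (nc,) bool
    exclusion: np.ndarray              # (n, n) uint8: skip excluded volume
    k_bond: float = K_BOND
    k_angle: float = K_ANGLE
    k_dihedral: float = K_DIHEDRAL
    gaussian_width: float = GAUSSIAN_WIDTH
    r_excluded: float = R_EXCLUDED
    tether_k: float = 0.0
    tether_r0: float = 0.0
    residue_names: list[str] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.native)

    def intra_contact_indices(self, chain_index: int) -> np.ndarray:
        mask = (~self.contact_inter
                & (self.chain_of[self.contacts[:, 0]] == chain_index))
        return np.where(mask)[0]

    @property
    def inter_contact_indices(self) -> np.ndarray:
        return np.where(self.contact_inter)[0]


def _angle(a, b, c):
    u = a - b
    v = c - b
    cos = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _dihedral(a, b, c, d):
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def build_sbm_topology(
    chains: list[CalphaChain],
    contacts: list[ResidueContact],
    tether: bool = False,
    contact_eps: float = 1.0,
) -> SBMTopology:
    """Assemble the coarse-grained topology from native chains + contacts.

    ``tether`` adds the soft center-of-mass spring used in dimer
    simulations (force constant = bond constant x 0.00005, reference
    length = native COM separation).
    """
    offsets = {}
    coords = []
    chain_of = []
    names = []
    for ci, ch in enumerate(chains):
        offsets[ch.chain_id] = len(coords)
        coords.extend(ch.coords)
        chain_of.extend([ci] * len(ch))
        names.extend(ch.residue_names)
    native = np.array(coords)
    chain_of = np.array(chain_of, dtype=np.int64)
    n = len(native)

    bonds, angles, dihedrals = [], [], []
    for ch in chains:
        off = offsets[ch.chain_id]
        m = len(ch)
        bonds.extend((off + i, off + i + 1) for i in range(m - 1))
        angles.extend((off + i, off + i + 1, off + i + 2) for i in range(m - 2))
        dihedrals.extend((off + i, off + i + 1, off + i + 2, off + i + 3)
                         for i in range(m - 3))
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    bond_r0 = np.array([np.linalg.norm(native[j] - native[i]) for i, j in bonds])
    angle_t0 = np.array([_angle(native[i], native[j], native[k]) for i, j, k in angles])
    dihedral_p0 = np.array([_dihedral(native[i], native[j], native[k], native[l])
                            for i, j, k, l in dihedrals])

    cpairs, cr0, cinter = [], [], []
    for c in contacts:
        if c.chain_a not in offsets or c.chain_b not in offsets:
            raise ValueError(f"contact references unknown chain {c!r}")
        i = offsets[c.chain_a] + c.res_a
        j = offsets[c.chain_b] + c.res_b
        if i >= n or j >= n:
            raise ValueError(f"contact references missing bead: {c!r}")
        r0 = c.distance
        if not np.isfinite(r0):
            r0 = float(np.linalg.norm(native[j] - native[i]))
        cpairs.append((i, j))
        cr0.append(r0)
        cinter.append(c.interchain)
    cpairs = np.array(cpairs, dtype=np.int64).reshape(-1, 2)
    cr0 = np.array(cr0)
    cinter = np.array(cinter, dtype=bool)

    # excluded-volume exclusions: bonded neighbours (|i-j| < 4 within a
    # chain) and native-contact pairs (their core is in the Gaussian term)
    exclusion = np.zeros((n, n), dtype=np.uint8)
    for ci in range(len(chains)):
        idx = np.where(chain_of == ci)[0]
        lo, hi = idx[0], idx[-1]
        for i in range(lo, hi + 1):
            exclusion[i, i:min(hi, i + 3) + 1] = 1
            exclusion[i:min(hi, i + 3) + 1, i] = 1
    for (i, j) in cpairs:
        exclusion[i, j] = 1
        exclusion[j, i] = 1

    tether_k = K_BOND * TETHER_SCALE if tether else 0.0
    tether_r0 = 0.0
    if tether:
        if len(chains) != 2:
            raise ValueError("COM tether requires exactly two chains")
        coms = [ch.coords.mean(axis=0) for ch in chains]
        tether_r0 = float(np.linalg.norm(coms[1] - coms[0]))

    return SBMTopology(
        native=native, chain_of=chain_of, chain_ids=[c.chain_id for c in chains],
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_t0=angle_t0,
        dihedrals=dihedrals, dihedral_p0=dihedral_p0,
        contacts=cpairs, contact_r0=cr0,
        contact_eps=np.full(len(cpairs), contact_eps),
        contact_inter=cinter, exclusion=exclusion,
        tether_k=tether_k, tether_r0=tether_r0,
        residue_names=names,
    )


def export_topology(topo: SBMTopology) -> str:
    """Documented plain-text export of the full parameter set."""
    lines = [
        "# knotsol SBM topology (reduced units: eps = 1, mass = 1, k_B = 1, length A)",
        f"# beads {topo.n_beads}  k_bond {topo.k_bond}  k_angle {topo.k_angle}"
        f"  k_dihedral {topo.k_dihedral}  gaussian_width {topo.gaussian_width}"
        f"  r_excluded {topo.r_excluded}",
        f"# tether_k {topo.tether_k}  tether_r0 {topo.tether_r0:.3f}",
        "[ beads ]",
    ]
    for i in range(topo.n_beads):
        x, y, z = topo.native[i]
        name = topo.residue_names[i] if topo.residue_names else "GLY"
        lines.append(f"{i}\t{topo.chain_ids[topo.chain_of[i]]}\t{name}"
                     f"\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    lines.append("[ bonds ]")
    lines.extend(f"{i}\t{j}\t{r0:.4f}\t{topo.k_bond}"
                 for (i, j), r0 in zip(topo.bonds, topo.bond_r0))
    lines.append("[ angles ]")
    lines.extend(f"{i}\t{j}\t{k}\t{t0:.5f}\t{topo.k_angle}"
                 for (i, j, k), t0 in zip(topo.angles, topo.angle_t0))
    lines.append("[ dihedrals ]")
    lines.extend(f"{i}\t{j}\t{k}\t{l}\t{p0:.5f}\t{topo.k_dihedral}"
                 for (i, j, k, l), p0 in zip(topo.dihedrals, topo.dihedral_p0))
    lines.append("[ contacts ]")
    lines.extend(
        f"{i}\t{j}\t{r0:.4f}\t{eps}\t{'inter' if inter else 'intra'}"
        for (i, j), r0, eps, inter in zip(topo.contacts, topo.contact_r0,
                                          topo.contact_eps, topo.contact_inter))
    return "\n".join(lines) + "\n"
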