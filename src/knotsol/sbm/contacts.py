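"""Native contact maps for structure-based models.

Two flavours: the shadow map (atom pairs within a cutoff count only when no
third atom occludes the line of sight within a shadowing radius, collapsed
to residue pairs) for full heavy-atom structures, and a plain C-alpha
distance-cutoff map for backbone-only inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..chain import HYDROPHOBIC, CalphaChain
from ..io import Structure

SHADOW_CUTOFF = 6.0
SHADOW_RADIUS = 1.0
CA_CUTOFF = 7.5
MIN_SEQ_SEP = 4


@dataclass(frozen=True)
class ResidueContact:
    chain_a: str
    res_a: int            # positional index within the chain
    chain_b: str
    res_b: int
    distance: float       # native CA-CA distance (Angstrom)

    @property
    def interchain(self) -> bool:
        return self.chain_a != self.chain_b


def _segment_occluded(a: np.ndarray, b: np.ndarray, others: np.ndarray,
                      radius: float) -> bool:
    """Does any sphere of ``radius`` around ``others`` intersect segment a-b?"""
    if len(others) == 0:
        return False
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return False
    t = np.clip((others - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", others - closest, others - closest)
    return bool(np.any(d2 < radius * radius))


def shadow_contact_map(
    structure: Structure,
    cutoff: float = SHADOW_CUTOFF,
    shadow_radius: float = SHADOW_RADIUS,
    min_seq_sep: int = MIN_SEQ_SEP,
) -> list[ResidueContact]:
    """Shadow native contact map over all chains of a heavy-atom structure.

    Atom pairs within ``cutoff`` are contacts unless a third atom's sphere
    of ``shadow_radius`` intersects the segment between them; atom contacts
    collapse to unique residue pairs.  Intra-chain pairs need sequence
    separation >= ``min_seq_sep``; all inter-chain pairs are kept.
    Raises on CA-only input (use :func:`ca_cutoff_map` instead).
    """
    atoms = []
    meta = []  # (chain_id, residue_positional_index, atom_index_global)
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for cid, residues in structure.chains.items():
        heavy_count = 0
        for ridx, res in enumerate(residues):
            for at in res.atoms:
                if at.element == "H":
                    continue
                atoms.append(at.pos)
                meta.append((cid, ridx))
                if at.name != "CA":
                    heavy_count += 1
                else:
                    ca_pos[(cid, ridx)] = at.pos
        if heavy_count == 0 and len(residues) > 1:
            raise ValueError(
                f"chain {cid!r} has only CA atoms; the shadow map needs heavy "
                "atoms -- use ca_cutoff_map for backbone-only input"
            )
    atoms = np.array(atoms)
    tree = cKDTree(atoms)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contact_res: dict[tuple, float] = {}
    for ia, ib in pairs:
        ca_meta, cb_meta = meta[ia], meta[ib]
        if ca_meta == cb_meta:
            continue
        if ca_meta[0] == cb_meta[0] and abs(ca_meta[1] - cb_meta[1]) < min_seq_sep:
            continue
        a, b = atoms[ia], atoms[ib]
        mid = 0.5 * (a + b)
        rad = 0.5 * np.linalg.norm(b - a) + shadow_radius
        near = [k for k in tree.query_ball_point(mid, rad) if k != ia and k != ib]
        if _segment_occluded(a, b, atoms[near], shadow_radius):
            continue
        key = (ca_meta[0], ca_meta[1], cb_meta[0], cb_meta[1])
        if (key[0], key[1]) > (key[2], key[3]):
            key = (key[2], key[3], key[0], key[1])
        if key not in contact_res:
            pa = ca_pos.get((key[0], key[1]))
            pb = ca_pos.get((key[2], key[3]))
            dist = float(np.linalg.norm(pa - pb)) if pa is not None and pb is not None else float("nan")
            contact_res[key] = dist
    return [ResidueContact(c0, r0, c1, r1, d)
            for (c0, r0, c1, r1), d in sorted(contact_res.items())]


def ca_cutoff_map(chains: list[CalphaChain], cutoff: float = CA_CUTOFF,
                  min_seq_sep: int = MIN_SEQ_SEP) -> list[ResidueContact]:
    """Plain distance-cutoff contact map on C-alpha traces (the fallback
    for backbone-only structures, e.g. generated solenoids)."""
    out = []
    for ci, chain in enumerate(chains):
        tree = cKDTree(chain.coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        for i, j in pairs:
            if abs(int(i) - int(j)) < min_seq_sep:
                continue
            d = float(np.linalg.norm(chain.coords[i] - chain.coords[j]))
            out.append(ResidueContact(chain.chain_id, int(i), chain.chain_id, int(j), d))
        for other in chains[ci + 1:]:
            otree = cKDTree(other.coords)
            inter = tree.query_ball_tree(otree, cutoff)
            for i, neigh in enumerate(inter):
                for j in neigh:
                    d = float(np.linalg.norm(chain.coords[i] - other.coords[j]))
                    out.append(ResidueContact(chain.chain_id, int(i),
                                              other.chain_id, int(j), d))
    return out


def count_hydrophobic(contacts: list[ResidueContact],
                      names: dict[str, list[str]]) -> int:
    """Contacts whose both residues are hydrophobic."""
    n = 0
    for c in contacts:
        if (names[c.chain_a][c.res_a] in HYDROPHOBIC
                and names[c.chain_b][c.res_b] in HYDROPHOBIC):
            n += 1
    return n
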