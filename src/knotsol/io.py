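"""Structure I/O: PDB/mmCIF reading, C-alpha trace extraction, minimal PDB
writing and biological-assembly expansion.

Parsing is delegated to gemmi; this module resolves altlocs (highest
occupancy wins, ties to the lexicographically first id), drops waters, and
keeps author residue numbering so reported knot-core boundaries match
deposited structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chain import CalphaChain

#: consecutive C-alpha distance beyond which a chain break is flagged
BREAK_CUTOFF = 4.5


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None


@dataclass
class Structure:
    chains: dict[str, list[Residue]]
    name: str = ""
    assembly_ops: list["AssemblyOp"] = field(default_factory=list)

    def chain_ids(self) -> list[str]:
        return list(self.chains)


@dataclass
class AssemblyOp:
    """Rigid transform of a biological-assembly operator."""

    rotation: np.ndarray
    translation: np.ndarray
    target_chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal within 1e-6")

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-9)
                and np.allclose(self.translation, 0.0, atol=1e-9))


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(max(group, key=lambda a: (a.occupancy, -ord((a.altloc or "~")[0]))))
    return out


def load_structure(path: str | Path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a Structure.

    Waters are excluded, altlocs resolved, and biological-assembly
    operators (REMARK 350 / _pdbx_struct_assembly_gen) collected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues = []
        for res in ch:
            if res.is_water():
                continue
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                     a.altloc, a.occ)
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            residues.append(Residue(res.seqid.num, res.seqid.icode.strip(), res.name, atoms))
        if residues:
            chains[ch.name] = residues
    has_protein = any(r.get("CA") is not None for rs in chains.values() for r in rs)
    if not chains or not has_protein:
        raise ValueError(f"{path}: no protein chains found")
    ops = []
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for oper in gen.operators:
                tr = oper.transform
                rot = np.array(tr.mat.tolist())
                vec = np.array(tr.vec.tolist())
                try:
                    ops.append(AssemblyOp(rot, vec, list(gen.chains)))
                except ValueError:
                    continue
        break  # first (author-preferred) assembly only
    return Structure(chains=chains, name=path.stem, assembly_ops=ops)


def get_ca_trace(structure: Structure, chain_id: str) -> CalphaChain:
    """Ordered C-alpha trace of one chain, with chain breaks flagged.

    Residues without a C-alpha are recorded as gaps and excluded; the
    author numbering is preserved.
    """
    if chain_id not in structure.chains:
        raise KeyError(
            f"chain {chain_id!r} not found; available: {structure.chain_ids()}"
        )
    coords, names, numbers = [], [], []
    for res in structure.chains[chain_id]:
        ca = res.get("CA")
        if ca is None:
            continue
        coords.append(ca.pos)
        names.append(res.name)
        numbers.append(res.number)
    if len(coords) < 2:
        raise ValueError(f"chain {chain_id!r} has fewer than 2 CA atoms")
    coords = np.array(coords)
    numbers = np.asarray(numbers)
    # de-duplicate / enforce strictly increasing author numbering (insertion
    # codes collapse onto the same number; keep first occurrence)
    keep = np.concatenate([[True], np.diff(numbers) > 0])
    coords, numbers = coords[keep], numbers[keep]
    names = [n for n, k in zip(names, keep) if k]
    gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1) > BREAK_CUTOFF
    return CalphaChain(
        coords=coords,
        residue_names=names,
        residue_numbers=numbers,
        chain_id=chain_id,
        breaks=[int(i) for i in np.where(gaps)[0]],
    )


def expand_assembly(structure: Structure, ops: list[AssemblyOp] | None = None) -> Structure:
    """Apply assembly operators, appending transformed copies as new chains.

    With ``ops=None`` the operators read from the file are used.  Identity
    operators are no-op copies (the original chains are kept once).
    """
    if ops is None:
        ops = structure.assembly_ops
    chains = {cid: residues for cid, residues in structure.chains.items()}
    next_ids = iter("BCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
    for op in ops:
        if op.is_identity:
            continue
        targets = op.target_chains or list(structure.chains)
        for cid in targets:
            if cid not in structure.chains:
                continue
            new_id = next(n for n in next_ids if n not in chains)
            new_residues = []
            for res in structure.chains[cid]:
                new_atoms = [
                    Atom(a.name, a.element, op.rotation @ a.pos + op.translation,
                         a.altloc, a.occupancy)
                    for a in res.atoms
                ]
                new_residues.append(Residue(res.number, res.icode, res.name, new_atoms))
            chains[new_id] = new_residues
    return Structure(chains=chains, name=structure.name, assembly_ops=[])


def write_pdb(path: str | Path, chains: list[CalphaChain]) -> None:
    """Write C-alpha traces as a minimal PDB file (ATOM/CA records only)."""
    with open(path, "w") as fh:
        serial = 1
        for chain in chains:
            for i in range(len(chain)):
                x, y, z = chain.coords[i]
                fh.write(
                    f"ATOM  {serial:5d}  CA  {chain.residue_names[i]:>3s} "
                    f"{chain.chain_id[:1]}{int(chain.residue_numbers[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f" C  \n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def structure_from_chains(chains: list[CalphaChain]) -> Structure:
    """Wrap C-alpha chains in a Structure (CA-only residues)."""
    out: dict[str, list[Residue]] = {}
    for ch in chains:
        residues = [
            Residue(int(ch.residue_numbers[i]), "", ch.residue_names[i],
                    [Atom("CA", "C", ch.coords[i].copy())])
            for i in range(len(ch))
        ]
        out[ch.chain_id] = residues
    return Structure(chains=out)
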