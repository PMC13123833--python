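"""Ordered C-alpha traces: the geometric substrate all analyses consume."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: three-letter codes accepted for residue decoration
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Kyte-Doolittle-positive (hydrophobic) residues
HYDROPHOBIC = {"ALA", "CYS", "PHE", "ILE", "LEU", "MET", "VAL", "TRP"}

#: target virtual-bond length for generated chains (Angstrom)
CA_BOND = 3.8


@dataclass
class CalphaChain:
    """An ordered C-alpha trace with residue identities.

    Coordinates are in Angstrom.  ``breaks`` lists indices ``i`` such that the
    bond ``i -> i+1`` spans a chain break (consecutive CA > 4.5 A in parsed
    structures); generated chains have none.
    """

    coords: np.ndarray
    residue_names: list[str] = field(default_factory=list)
    residue_numbers: np.ndarray | None = None
    chain_id: str = "A"
    breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = len(self.coords)
        if not self.residue_names:
            self.residue_names = ["GLY"] * n
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, n + 1)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if not (len(self.residue_names) == n == len(self.residue_numbers)):
            raise ValueError("coords, residue_names and residue_numbers must have equal length")
        if n > 1 and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def subchain(self, start: int, stop: int) -> "CalphaChain":
        """Positional slice [start, stop) preserving residue numbering."""
        return CalphaChain(
            coords=self.coords[start:stop].copy(),
            residue_names=list(self.residue_names[start:stop]),
            residue_numbers=self.residue_numbers[start:stop].copy(),
            chain_id=self.chain_id,
            breaks=[b - start for b in self.breaks if start <= b < stop - 1],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaChain":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(self, coords=self.coords @ R.T + t)

    def reversed(self) -> "CalphaChain":
        return CalphaChain(
            coords=self.coords[::-1].copy(),
            residue_names=list(reversed(self.residue_names)),
            residue_numbers=self.residue_numbers[::-1].max() + 1 - self.residue_numbers[::-1],
            chain_id=self.chain_id,
        )


def resample_by_arclength(points: np.ndarray, spacing: float = CA_BOND) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arclength spacing.

    The number of output points is chosen so the mean consecutive distance is
    as close as possible to ``spacing``; endpoints are preserved.
    """
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_out = max(2, int(round(total / spacing)) + 1)
    target = np.linspace(0.0, total, n_out)
    out = np.empty((n_out, 3))
    for d in range(3):
        out[:, d] = np.interp(target, s, points[:, d])
    return out


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two coordinate sets after optimal superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    S[-1] *= sign
    msd = max(0.0, (np.sum(ac**2) + np.sum(bc**2) - 2.0 * S.sum()) / len(a))
    return float(np.sqrt(msd))
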