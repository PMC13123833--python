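"""Order parameters and trajectory analysis for folding simulations:
fraction of native contacts Q, RMSD, knot/slipknot monitoring, and the
folding-outcome taxonomy for dimer campaigns."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chain import kabsch_rmsd
from ..knots import classify_open_chain, detect_slipknot
from .topology import SBMTopology

Q_TOLERANCE = 1.2        # a contact is formed when r < 1.2 r0
Q_FOLDED = 0.8           # per-chain folded threshold
INTERFACE_THRESHOLD = 0.5
KNOT_PERSISTENCE = 3     # consecutive knotted samples = committed knot


def fraction_native_contacts(frame: np.ndarray, pairs: np.ndarray,
                             r0: np.ndarray, tolerance: float = Q_TOLERANCE) -> float:
    """Q = fraction of native contacts with r < tolerance * r0."""
    if len(pairs) == 0:
        raise ValueError("contact set is empty")
    d = np.linalg.norm(frame[pairs[:, 1]] - frame[pairs[:, 0]], axis=1)
    return float(np.mean(d < tolerance * r0))


@dataclass
class ObservableSeries:
    """Per-frame observables of one trajectory."""

    times: np.ndarray
    q_chain: np.ndarray          # (n_frames, n_chains)
    q_interface: np.ndarray      # (n_frames,) NaN for monomers
    rmsd_chain: np.ndarray       # (n_frames, n_chains)
    knot_chain: np.ndarray | None = None      # (n_frames, n_chains) of str
    slipknot_chain: np.ndarray | None = None  # (n_frames, n_chains) bool
    outcome: str = ""
    extras: dict = field(default_factory=dict)

    def to_table(self) -> str:
        n_chains = self.q_chain.shape[1]
        cols = ["time"]
        cols += [f"q_{c}" for c in range(n_chains)]
        cols += ["q_interface"]
        cols += [f"rmsd_{c}" for c in range(n_chains)]
        if self.knot_chain is not None:
            cols += [f"knot_{c}" for c in range(n_chains)]
        rows = ["\t".join(cols)]
        for t in range(len(self.times)):
            row = [f"{self.times[t]:.3f}"]
            row += [f"{self.q_chain[t, c]:.4f}" for c in range(n_chains)]
            row += [f"{self.q_interface[t]:.4f}"]
            row += [f"{self.rmsd_chain[t, c]:.3f}" for c in range(n_chains)]
            if self.knot_chain is not None:
                row += [str(self.knot_chain[t, c]) for c in range(n_chains)]
            rows.append("\t".join(row))
        return "\n".join(rows) + "\n"


def compute_observables(topo: SBMTopology, frames: np.ndarray,
                        times: np.ndarray,
                        tolerance: float = Q_TOLERANCE) -> ObservableSeries:
    """Q (per chain and interface) and RMSD (per chain) for every frame."""
    n_chains = len(topo.chain_ids)
    chain_idx = [np.where(topo.chain_of == c)[0] for c in range(n_chains)]
    intra = [topo.intra_contact_indices(c) for c in range(n_chains)]
    inter = topo.inter_contact_indices
    nf = len(frames)
    q_chain = np.zeros((nf, n_chains))
    q_int = np.full(nf, np.nan)
    rmsd = np.zeros((nf, n_chains))
    for t in range(nf):
        x = frames[t]
        for c in range(n_chains):
            if len(intra[c]):
                q_chain[t, c] = fraction_native_contacts(
                    x, topo.contacts[intra[c]], topo.contact_r0[intra[c]], tolerance)
            rmsd[t, c] = kabsch_rmsd(x[chain_idx[c]], topo.native[chain_idx[c]])
        if len(inter):
            q_int[t] = fraction_native_contacts(
                x, topo.contacts[inter], topo.contact_r0[inter], tolerance)
    return ObservableSeries(times=times, q_chain=q_chain, q_interface=q_int,
                            rmsd_chain=rmsd)


def monitor_topology(topo: SBMTopology, frames: np.ndarray,
                     every_n_frames: int = 1, n_closures: int = 20,
                     seed: int = 0, slipknot: bool = False,
                     slipknot_grid: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Dominant knot type (and optional slipknot flag) per sampled frame
    and chain; unsampled frames repeat the previous sample."""
    n_chains = len(topo.chain_ids)
    chain_idx = [np.where(topo.chain_of == c)[0] for c in range(n_chains)]
    nf = len(frames)
    knots = np.empty((nf, n_chains), dtype=object)
    slips = np.zeros((nf, n_chains), dtype=bool)
    last = ["0_1"] * n_chains
    last_slip = [False] * n_chains
    for t in range(nf):
        if t % every_n_frames == 0:
            for c in range(n_chains):
                coords = frames[t][chain_idx[c]]
                try:
                    spec = classify_open_chain(coords, n_closures, seed + 1000 * t + c)
                    last[c] = spec.dominant.name
                except ValueError:
                    last[c] = "0_1"
                if slipknot:
                    try:
                        flag, _ = detect_slipknot(coords, grid_step=slipknot_grid,
                                                  n_closures=max(10, n_closures // 2),
                                                  seed=seed + 1000 * t + c)
                    except ValueError:
                        flag = False
                    last_slip[c] = flag
        for c in range(n_chains):
            knots[t, c] = last[c]
            slips[t, c] = last_slip[c]
    return knots, slips


def knotting_frame(knot_series: np.ndarray, target: str = "3_1",
                   persistence: int = KNOT_PERSISTENCE) -> int | None:
    """First frame index where ``target`` persists for >= ``persistence``
    consecutive samples; None if never."""
    run = 0
    for t, name in enumerate(knot_series):
        run = run + 1 if name == target else 0
        if run >= persistence:
            return t - persistence + 1
    return None


@dataclass
class OutcomeStatistics:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_trajectories: int
    mean_first_passage: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions": {k: round(v, 4) for k, v in self.fractions.items()},
            "n_trajectories": self.n_trajectories,
            "mean_first_passage": {k: round(v, 4)
                                   for k, v in self.mean_first_passage.items()},
        }


def classify_folding_outcomes(
    ensembles: list[ObservableSeries],
    q_folded: float = Q_FOLDED,
    interface_threshold: float = INTERFACE_THRESHOLD,
    require_knot: bool = True,
) -> OutcomeStatistics:
    """Dimer folding-outcome taxonomy.

    A: at least one chain folded (Q > q_folded, and knotted when knot
       monitoring is available); B: the second chain folds only after the
       interface Q first exceeds the threshold with one chain already
       folded; C: both chains fold before the interface forms; D: neither
       folds within the time budget.  Fractions of A-D and mean
       first-passage folding times (tau) are reported.
    """
    counts = {"A": 0, "B": 0, "C": 0, "D": 0}
    fp_times: dict[str, list[float]] = {"first_fold": [], "second_fold_assisted": [],
                                        "second_fold_independent": []}
    for obs in ensembles:
        if obs.knot_chain is None and require_knot:
            raise ValueError("knot-state channel missing; run monitor_topology first")
        nf, n_chains = obs.q_chain.shape
        fold_frame = []
        for c in range(n_chains):
            folded = obs.q_chain[:, c] > q_folded
            if require_knot and obs.knot_chain is not None:
                folded = folded & (obs.knot_chain[:, c] == "3_1")
            idx = np.where(folded)[0]
            fold_frame.append(int(idx[0]) if len(idx) else None)
        with np.errstate(invalid="ignore"):
            iface = np.where(obs.q_interface > interface_threshold)[0]
        iface_frame = int(iface[0]) if len(iface) else None
        done = [f for f in fold_frame if f is not None]
        if not done:
            counts["D"] += 1
            continue
        counts["A"] += 1
        first = min(done)
        fp_times["first_fold"].append(float(obs.times[first]))
        if len(done) == n_chains and n_chains == 2:
            second = max(done)
            if iface_frame is not None and iface_frame <= second and first <= iface_frame:
                counts["B"] += 1
                fp_times["second_fold_assisted"].append(
                    float(obs.times[second] - obs.times[iface_frame]))
            else:
                counts["C"] += 1
                fp_times["second_fold_independent"].append(float(obs.times[second]))
    n = len(ensembles)
    fractions = {k: v / n for k, v in counts.items()}
    mfp = {k: float(np.mean(v)) if v else float("nan") for k, v in fp_times.items()}
    return OutcomeStatistics(counts=counts, fractions=fractions,
                             n_trajectories=n, mean_first_passage=mfp)
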