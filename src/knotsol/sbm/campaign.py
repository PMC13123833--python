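"""Scaled-down folding campaigns for the knotted-solenoid model.

The campaigns run on the reduced knotted solenoid (4 residues per side)
with a widened Gaussian contact well (w = 1.5 A): with the 0.5 A analysis
default, an expanded chain essentially never finds the native basin on
single-CPU timescales.  Unfolded, topologically trivial starting
conformations come from a high-temperature unfolding run; folding runs at
a fixed fraction of the model's own folding temperature, located by a
stability scan.  Trajectory counts adapt to a wall-clock budget so the
campaign is usable both in quick tests and in longer reproduction runs.
"""

from __future__ import annotations

import time

import numpy as np

from ..knots import classify_open_chain, detect_slipknot
from ..synthetic import SolenoidSpec, make_dimer_assembly, make_ideal_solenoid
from .contacts import ca_cutoff_map
from .dynamics import SimParams, run_langevin
from .observables import compute_observables
from .topology import SBMTopology, build_sbm_topology

CAMPAIGN_SPEC = SolenoidSpec(residues_per_side=4, skip_and_backtrack=True,
                             linker_length=15, cterm_thread_length=10, seed=0)
CAMPAIGN_WIDTH = 1.5     # A; Gaussian contact well for folding runs
Q_FOLDED = 0.8
UNFOLD_TEMPERATURE = 3.2
FOLD_FRACTION = 0.4      # folding temperature = fraction x stability limit
CHUNK_STEPS = 1_000_000
MAX_CHUNKS = 8


def campaign_topology(dimer: bool = False) -> SBMTopology:
    chain = make_ideal_solenoid(CAMPAIGN_SPEC, validate=False)
    if dimer:
        a, b = make_dimer_assembly(chain, 6.0, "parallel")
        topo = build_sbm_topology([a, b], ca_cutoff_map([a, b]), tether=True)
    else:
        topo = build_sbm_topology([chain], ca_cutoff_map([chain]))
    topo.gaussian_width = CAMPAIGN_WIDTH
    return topo


def locate_folding_temperature(topo: SBMTopology, seed: int = 0,
                               window_steps: int = 200_000) -> float:
    """Highest scanned temperature at which the native state keeps
    Q > 0.5 over the observation window (a stability proxy for T_f)."""
    t_stable = 0.0
    for T in np.arange(1.5, 3.01, 0.5):
        traj = run_langevin(topo, SimParams(temperature=float(T),
                                            n_steps=window_steps,
                                            stride=window_steps // 4,
                                            seed=seed))
        obs = compute_observables(topo, traj.frames, traj.times)
        if obs.q_chain[-1].min() > 0.5:
            t_stable = float(T)
        else:
            break
    return t_stable if t_stable > 0 else 1.0


def unfolded_pool(topo: SBMTopology, seed: int, n_frames: int = 15,
                  q_max: float = 0.3) -> list[np.ndarray]:
    """Unfolded AND unknotted conformations from a thermal unfolding run."""
    steps = 100_000 * n_frames
    traj = run_langevin(topo, SimParams(temperature=UNFOLD_TEMPERATURE,
                                        n_steps=steps, stride=100_000,
                                        seed=seed))
    obs = compute_observables(topo, traj.frames, traj.times)
    chain_idx = [np.where(topo.chain_of == c)[0]
                 for c in range(len(topo.chain_ids))]
    pool = []
    for k in range(len(traj.frames)):
        if obs.q_chain[k].max() >= q_max:
            continue
        trivial = all(
            classify_open_chain(traj.frames[k][idx], 20, seed=seed + k).dominant.name
            == "0_1"
            for idx in chain_idx)
        if trivial:
            pool.append(traj.frames[k].copy())
    if not pool:  # fall back to the most unfolded unknotted-ish frame
        pool.append(traj.frames[int(np.argmin(obs.q_chain.max(axis=1)))].copy())
    return pool


def _run_one(topo, x0, temperature, seed, budget_end, knot_seed):
    """One budgeted folding trajectory; returns per-chunk records."""
    chain_idx = [np.where(topo.chain_of == c)[0]
                 for c in range(len(topo.chain_ids))]
    records = []
    pre_knot_frame = [None] * len(chain_idx)
    x = x0
    v = None
    for chunk in range(MAX_CHUNKS):
        traj = run_langevin(topo, SimParams(temperature=temperature,
                                            n_steps=CHUNK_STEPS,
                                            stride=CHUNK_STEPS // 4,
                                            seed=seed + 13 * chunk),
                            initial=x, velocities=v)
        obs = compute_observables(topo, traj.frames, traj.times)
        x = traj.frames[-1]
        v = traj.final_velocities
        for f in range(len(traj.frames)):
            rec = {"time": (chunk * CHUNK_STEPS * 0.0005)
                   + float(traj.times[f]),
                   "q": obs.q_chain[f].copy(),
                   "q_int": float(obs.q_interface[f])}
            knots = []
            for c, idx in enumerate(chain_idx):
                if rec["q"][c] > 0.5:
                    name = classify_open_chain(traj.frames[f][idx], 15,
                                               seed=knot_seed + f).dominant.name
                else:
                    name = "0_1"   # expanded chains are trivially unknotted
                if name == "0_1":
                    # remember the most recent pre-knot conformation: the
                    # slipknot check runs on it once the knot commits
                    pre_knot_frame[c] = traj.frames[f][idx].copy()
                knots.append(name)
            rec["knots"] = knots
            records.append(rec)
        folded = all(q > Q_FOLDED for q in records[-1]["q"]) and all(
            k == "3_1" for k in records[-1]["knots"])
        if folded or time.time() > budget_end:
            break
    return records, pre_knot_frame


def _slipknot_seen(topo, frames_chain) -> bool:
    try:
        flag, _ = detect_slipknot(frames_chain, grid_step=8, n_closures=15, seed=0)
    except ValueError:
        flag = False
    return flag


def monomer_campaign(seed: int = 0, budget_s: float = 400.0,
                     max_trajectories: int = 25,
                     temperature: float | None = None) -> dict:
    """Folding campaign of the reduced knotted-solenoid monomer.

    Each trajectory starts from a random unfolded unknotted conformation
    and runs in chunks until it is folded AND knotted, its step budget is
    exhausted, or the wall-clock budget runs out.  Reports the
    folded-and-knotted fraction, mean first-passage time of successes,
    and how often a slipknot state was seen before the knot committed.
    """
    t_end = time.time() + budget_s
    topo = campaign_topology(dimer=False)
    if temperature is None:
        temperature = FOLD_FRACTION * locate_folding_temperature(topo, seed)
    rng = np.random.default_rng(seed)
    pool = unfolded_pool(topo, seed + 1)
    n_done = 0
    n_success = 0
    slip_before = 0
    first_passage = []
    for t in range(max_trajectories):
        now = time.time()
        if n_done and now > t_end - 5:
            break
        # fair share of the remaining wall clock for this trajectory
        traj_end = now + (t_end - now) / max(1, max_trajectories - t)
        x0 = pool[int(rng.integers(len(pool)))]
        records, pre_knot = _run_one(topo, x0, temperature, seed + 100 * t,
                                     traj_end, knot_seed=seed + 7 * t)
        n_done += 1
        last = records[-1]
        success = (last["q"][0] > Q_FOLDED and last["knots"][0] == "3_1")
        if success:
            n_success += 1
            first_passage.append(last["time"])
            # the conformation recorded just before the knot committed
            # should already hold a knotted subchain (slipknot threading)
            if pre_knot[0] is not None and _slipknot_seen(topo, pre_knot[0]):
                slip_before += 1
    return {
        "n_trajectories": n_done,
        "n_successful": n_success,
        "folded_knotted_fraction": n_success / n_done if n_done else 0.0,
        "mean_first_passage_tau": float(np.mean(first_passage)) if first_passage else float("nan"),
        "slipknot_before_knot_fraction": slip_before / n_success if n_success else 0.0,
        "temperature": temperature,
    }


def dimer_campaign(seed: int = 0, budget_s: float = 300.0,
                   max_trajectories: int = 25,
                   temperature: float | None = None) -> dict:
    """Dimer folding campaign with the outcome taxonomy.

    Category A: at least one chain folded and knotted; B: the second chain
    folds only after the interface Q first exceeds 0.5 with one chain
    already folded; C: both fold before the interface forms; D: neither
    within the budget.  Also reports whether interface-assisted
    second-chain folding was faster on average than independent folding.
    """
    t_end = time.time() + budget_s
    topo = campaign_topology(dimer=True)
    if temperature is None:
        temperature = FOLD_FRACTION * locate_folding_temperature(topo, seed)
    rng = np.random.default_rng(seed)
    pool = unfolded_pool(topo, seed + 2)
    counts = {"A": 0, "B": 0, "C": 0, "D": 0}
    assisted, independent = [], []
    n_done = 0
    for t in range(max_trajectories):
        now = time.time()
        if n_done and now > t_end - 5:
            break
        traj_end = now + (t_end - now) / max(1, max_trajectories - t)
        x0 = pool[int(rng.integers(len(pool)))]
        records, _pre = _run_one(topo, x0, temperature, seed + 100 * t,
                                 traj_end, knot_seed=seed + 7 * t)
        n_done += 1
        fold_time = [None, None]
        iface_time = None
        for rec in records:
            for c in range(2):
                if (fold_time[c] is None and rec["q"][c] > Q_FOLDED
                        and rec["knots"][c] == "3_1"):
                    fold_time[c] = rec["time"]
            if iface_time is None and np.isfinite(rec["q_int"]) and rec["q_int"] > 0.5:
                iface_time = rec["time"]
        done = [ft for ft in fold_time if ft is not None]
        if not done:
            counts["D"] += 1
            continue
        counts["A"] += 1
        if len(done) == 2:
            first, second = sorted(done)
            if iface_time is not None and first <= iface_time <= second:
                counts["B"] += 1
                assisted.append(second - iface_time)
            else:
                counts["C"] += 1
                independent.append(second)
    fractions = {k: v / n_done for k, v in counts.items()} if n_done else counts
    assisted_faster = (bool(np.mean(assisted) < np.mean(independent))
                       if assisted and independent else False)
    return {
        "n_trajectories": n_done,
        "counts": counts,
        "fractions": fractions,
        "assisted_faster": assisted_faster,
        "mean_assisted_tau": float(np.mean(assisted)) if assisted else float("nan"),
        "mean_independent_tau": float(np.mean(independent)) if independent else float("nan"),
        "temperature": temperature,
    }
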