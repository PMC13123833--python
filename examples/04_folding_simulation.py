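"""A short structure-based folding simulation with topology monitoring.

Builds the C-alpha Go model of a reduced knotted solenoid (Gaussian native
contacts from the cutoff map), runs stochastic leap-frog dynamics from the
native state at a moderate temperature, and reports the fraction of native
contacts Q, the RMSD and the knot state over time.  At this temperature
the native trefoil stays formed; heating unfolds and unties it.
"""

from knotsol.sbm import (
    SimParams,
    build_sbm_topology,
    ca_cutoff_map,
    compute_observables,
    monitor_topology,
    run_langevin,
)
from knotsol.synthetic import SolenoidSpec, make_ideal_solenoid

spec = SolenoidSpec(residues_per_side=4, skip_and_backtrack=True,
                    linker_length=15, cterm_thread_length=10, seed=0)
chain = make_ideal_solenoid(spec)
topo = build_sbm_topology([chain], ca_cutoff_map([chain]))
print(f"{topo.n_beads} beads, {len(topo.contacts)} native contacts")

params = SimParams(temperature=1.0, n_steps=400_000, stride=40_000, seed=1)
traj = run_langevin(topo, params)
obs = compute_observables(topo, traj.frames, traj.times)
knots, _ = monitor_topology(topo, traj.frames, n_closures=20, seed=2)

print("  time/tau    Q      RMSD/A  knot")
for t in range(len(traj.times)):
    print(f"  {traj.times[t]:8.1f}  {obs.q_chain[t, 0]:.3f}  "
          f"{obs.rmsd_chain[t, 0]:6.2f}  {knots[t, 0]}")
# Q stays near 1 and the chain reports 3_1 in every frame: the folded
# knotted solenoid is stable at this temperature.
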