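"""Structure-based model: contact maps, topology building, dynamics
physics, order parameters and WHAM."""

import numpy as np
import pytest

from knotsol.chain import CalphaChain
from knotsol.io import Structure, Residue, Atom, structure_from_chains
from knotsol.sbm import (
    SimParams,
    WhamWindow,
    build_sbm_topology,
    ca_cutoff_map,
    classify_folding_outcomes,
    compute_observables,
    export_topology,
    fraction_native_contacts,
    run_langevin,
    shadow_contact_map,
    wham_free_energy,
)
from knotsol.sbm.contacts import ResidueContact, _segment_occluded
from knotsol.sbm.dynamics import potential_energy
from knotsol.sbm.observables import ObservableSeries


def _structure_from_atoms(positions, names=None, elements=None):
    residues = []
    for i, pos in enumerate(positions):
        name = (names or ["C"] * len(positions))[i]
        el = (elements or ["C"] * len(positions))[i]
        residues.append(Residue(i + 1, "", "ALA",
                                [Atom(name, el, np.asarray(pos, float))]))
    return Structure(chains={"A": residues})


class TestShadowMap:
    def test_unoccluded_pair_is_contact(self):
        st = _structure_from_atoms([[0, 0, 0], [5, 0, 0]])
        contacts = shadow_contact_map(st, min_seq_sep=1)
        assert len(contacts) == 1

    def test_occluding_middle_atom_blocks(self):
        st = _structure_from_atoms([[0, 0, 0], [2.95, 0, 0], [5.9, 0, 0]])
        contacts = shadow_contact_map(st, min_seq_sep=1)
        pairs = {(c.res_a, c.res_b) for c in contacts}
        assert (0, 2) not in pairs      # outer pair is shadowed
        assert (0, 1) in pairs and (1, 2) in pairs

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            pts = rng.uniform(0, 12, size=(30, 3))
            st = _structure_from_atoms(pts)
            got = {(c.res_a, c.res_b)
                   for c in shadow_contact_map(st, min_seq_sep=1)}
            expected = set()
            for i in range(30):
                for j in range(i + 1, 30):
                    d = np.linalg.norm(pts[i] - pts[j])
                    if d > 6.0:
                        continue
                    others = np.array([pts[k] for k in range(30)
                                       if k != i and k != j])
                    if not _segment_occluded(pts[i], pts[j], others, 1.0):
                        expected.add((i, j))
            assert got == expected

    def test_ca_only_input_directs_to_fallback(self, regular_solenoid):
        st = structure_from_chains([regular_solenoid])
        with pytest.raises(ValueError, match="ca_cutoff_map"):
            shadow_contact_map(st)


class TestTopology:
    def test_bonded_term_counts(self, small_knotted_solenoid):
        ch = small_knotted_solenoid
        topo = build_sbm_topology([ch], ca_cutoff_map([ch]))
        n = len(ch)
        assert len(topo.bonds) == n - 1
        assert len(topo.angles) == n - 2
        assert len(topo.dihedrals) == n - 3
        assert np.all(np.abs(topo.contacts[:, 0] - topo.contacts[:, 1]) >= 4)

    def test_contact_energy_minimum_and_asymptote(self):
        # two rigid 2-bead chains with one inter-chain contact: translating
        # chain B probes the Gaussian contact energy alone
        a = CalphaChain(np.array([[0.0, 0, 0], [3.8, 0, 0]]), chain_id="A")
        b = CalphaChain(np.array([[0.0, 12.0, 0], [3.8, 12.0, 0]]), chain_id="B")
        contact = [ResidueContact("A", 0, "B", 0, 12.0)]
        topo = build_sbm_topology([a, b], contact)
        native = np.vstack([a.coords, b.coords])
        far = native.copy()
        far[2:] += np.array([0.0, 120.0, 0.0])  # contact at ~10 x r0
        e_native = potential_energy(topo, native)
        e_far = potential_energy(topo, far)
        # the native contact contributes exactly -eps; at 10 r0 it vanishes
        assert e_native - e_far == pytest.approx(-1.0, abs=1e-4)

    def test_missing_bead_rejected(self, regular_solenoid):
        bad = [ResidueContact("A", 0, "A", 999, 5.0)]
        with pytest.raises(ValueError):
            build_sbm_topology([regular_solenoid], bad)

    def test_tether_parameters(self, small_knotted_solenoid):
        from knotsol.synthetic import make_dimer_assembly

        a, b = make_dimer_assembly(small_knotted_solenoid, 6.0, "parallel")
        topo = build_sbm_topology([a, b], ca_cutoff_map([a, b]), tether=True)
        assert topo.tether_k == pytest.approx(100.0 * 0.00005)
        expected_r0 = np.linalg.norm(a.coords.mean(0) - b.coords.mean(0))
        assert topo.tether_r0 == pytest.approx(expected_r0)
        text = export_topology(topo)
        assert "tether_k 0.005" in text
        assert "[ contacts ]" in text and "inter" in text


class TestDynamics:
    def test_native_start_at_zero_temperature_stays_native(self, small_knotted_solenoid):
        ch = small_knotted_solenoid
        topo = build_sbm_topology([ch], ca_cutoff_map([ch]))
        traj = run_langevin(topo, SimParams(temperature=0.0, n_steps=20000,
                                            stride=2000, seed=1))
        obs = compute_observables(topo, traj.frames, traj.times)
        assert obs.q_chain[-1, 0] == 1.0
        assert obs.rmsd_chain[-1, 0] < 0.1

    def test_harmonic_variance_matches_boltzmann(self):
        """Bond-length fluctuations follow kT/k; pooled over independent
        bonded pairs because the energy decorrelates only on the friction
        timescale."""
        chains = [CalphaChain(np.array([[60.0 * k, 0, 0],
                                        [60.0 * k + 3.8, 0, 0]]),
                              chain_id=chr(65 + k)) for k in range(12)]
        topo = build_sbm_topology(chains, [])
        T = 1.0
        traj = run_langevin(topo, SimParams(temperature=T, n_steps=1_200_000,
                                            stride=200, seed=4))
        ratios = []
        for k in range(12):
            d = np.linalg.norm(traj.frames[:, 2 * k + 1]
                               - traj.frames[:, 2 * k], axis=1)
            ratios.append(np.var(d[len(d) // 10:]))
        var = float(np.mean(ratios))
        assert var == pytest.approx(T / topo.k_bond, rel=0.05)

    def test_energy_conservation_frictionless(self):
        """gamma = 0, T = 0 noise: symplectic leap-frog conserves energy.

        The fixture is a curved 10-bead arc: straight-strand geometry puts
        native angles at ~180 degrees where the harmonic angle term is
        singular, which is a property of that geometry, not the integrator.
        """
        from knotsol.synthetic import make_torus_knot

        ch = make_torus_knot(2, 3, 120, seed=1).subchain(0, 10)
        topo = build_sbm_topology([ch], ca_cutoff_map([ch]))
        x0 = topo.native + np.random.default_rng(3).normal(scale=0.02, size=(10, 3))
        params = SimParams(temperature=0.0, n_steps=10000, stride=100,
                           inverse_friction=np.inf, seed=0)
        v0 = np.random.default_rng(4).normal(scale=0.15, size=(10, 3))
        traj = run_langevin(topo, params, initial=x0, velocities=v0)
        total = traj.potential + traj.kinetic
        drift = np.abs(total - total[0]).max()
        assert drift < 1e-4

    def test_same_seed_reproduces_trajectory(self, small_knotted_solenoid):
        ch = small_knotted_solenoid
        topo = build_sbm_topology([ch], ca_cutoff_map([ch]))
        p = SimParams(temperature=1.0, n_steps=20000, stride=5000, seed=9)
        t1 = run_langevin(topo, p)
        t2 = run_langevin(topo, SimParams(temperature=1.0, n_steps=20000,
                                          stride=5000, seed=9))
        assert np.array_equal(t1.frames, t2.frames)


class TestObservables:
    def test_q_native_and_extended(self, small_knotted_solenoid):
        ch = small_knotted_solenoid
        topo = build_sbm_topology([ch], ca_cutoff_map([ch]))
        assert fraction_native_contacts(topo.native, topo.contacts,
                                        topo.contact_r0) == 1.0
        n = topo.n_beads
        extended = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
        assert fraction_native_contacts(extended, topo.contacts,
                                        topo.contact_r0) < 0.05

    def test_q_half_by_construction(self):
        pairs = np.array([[0, 2], [1, 3]])
        r0 = np.array([5.0, 5.0])
        frame = np.array([[0.0, 0, 0], [0, 5.0, 0], [5.0, 0, 0], [0, 20.0, 0]])
        # pair (0,2) at r0, pair (1,3) at 3 r0
        assert fraction_native_contacts(frame, pairs, r0) == 0.5

    def test_outcome_taxonomy_on_labeled_toys(self):
        times = np.arange(10, dtype=float)

        def mk(q1, q2, qi, knots):
            return ObservableSeries(
                times=times,
                q_chain=np.column_stack([q1, q2]),
                q_interface=np.asarray(qi, float),
                rmsd_chain=np.zeros((10, 2)),
                knot_chain=np.array(knots, dtype=object),
            )

        knotted_when_folded = lambda q: np.where(np.asarray(q) > 0.8, "3_1", "0_1")
        low = np.full(10, 0.1)
        fold_at_3 = np.concatenate([np.full(3, 0.1), np.full(7, 0.95)])
        fold_at_7 = np.concatenate([np.full(7, 0.1), np.full(3, 0.95)])
        iface_at_5 = np.concatenate([np.full(5, 0.1), np.full(5, 0.9)])
        # A then B: first chain folds at 3, interface at 5, second at 7
        tA = mk(fold_at_3, fold_at_7, iface_at_5,
                np.column_stack([knotted_when_folded(fold_at_3),
                                 knotted_when_folded(fold_at_7)]))
        # C: both fold before the interface forms
        tC = mk(fold_at_3, fold_at_3, np.full(10, 0.1),
                np.column_stack([knotted_when_folded(fold_at_3)] * 2))
        # D: nothing folds
        tD = mk(low, low, low,
                np.column_stack([np.full(10, "0_1", object)] * 2))
        stats = classify_folding_outcomes([tA, tC, tD])
        assert stats.counts == {"A": 2, "B": 1, "C": 1, "D": 1}
        assert stats.fractions["A"] == pytest.approx(2 / 3)
        assert stats.fractions["D"] == pytest.approx(1 / 3)


class TestWham:
    def test_single_window_equals_direct_boltzmann_inversion(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(0, 1, size=2000)
        e = rng.normal(size=2000)
        edges = [np.linspace(0, 1, 11)]
        T = 0.85
        surf = wham_free_energy([WhamWindow(T, q[:, None], e)], edges)
        hist, _ = np.histogram(q, bins=edges[0])
        p = hist / hist.sum()
        direct = -T * np.log(p)
        direct -= direct.min()
        assert np.array_equal(surf.f, direct)

    def test_double_well_barrier_recovery(self):
        """Two-temperature WHAM recovers the analytic barrier of a 1D
        double well within 0.2 eps."""

        def potential(x):
            return 2.0 * (x ** 2 - 1.0) ** 2   # barrier height 2 eps at x=0

        grid = np.linspace(-2.2, 2.2, 4001)
        rng = np.random.default_rng(1)
        windows = []
        for T in (0.7, 1.2):
            w = np.exp(-potential(grid) / T)
            w /= w.sum()
            x = rng.choice(grid, size=120_000, p=w)
            windows.append(WhamWindow(T, x[:, None], potential(x)))
        edges = [np.linspace(-2.2, 2.2, 45)]
        surf = wham_free_energy(windows, edges, temperature_out=0.7)
        mids = 0.5 * (edges[0][:-1] + edges[0][1:])
        f = surf.f
        # analytic free energy at T=0.7 on the same bins
        ref = np.empty_like(mids)
        for k in range(len(mids)):
            mask = (grid >= edges[0][k]) & (grid < edges[0][k + 1])
            ref[k] = -0.7 * np.log(np.exp(-potential(grid[mask]) / 0.7).sum())
        ref -= ref.min()
        well = np.abs(mids + 1.0).argmin()
        barrier = f[np.abs(mids).argmin()] - f[well]
        ref_barrier = ref[np.abs(mids).argmin()] - ref[well]
        assert barrier == pytest.approx(ref_barrier, abs=0.2)

    def test_window_order_irrelevant(self):
        rng = np.random.default_rng(2)
        wins = []
        for T in (0.8, 1.0, 1.3):
            x = rng.normal(scale=np.sqrt(T), size=5000)
            wins.append(WhamWindow(T, x[:, None], 0.5 * x ** 2))
        edges = [np.linspace(-4, 4, 30)]
        f1 = wham_free_energy(wins, edges).f
        f2 = wham_free_energy(wins[::-1], edges).f
        ok = np.isfinite(f1) & np.isfinite(f2)
        assert np.allclose(f1[ok], f2[ok], atol=1e-10)

    def test_disjoint_windows_raise(self):
        w1 = WhamWindow(0.5, np.zeros((100, 1)), np.zeros(100))
        w2 = WhamWindow(5.0, np.ones((100, 1)), np.full(100, 100.0))
        with pytest.raises(ValueError, match="overlap"):
            wham_free_energy([w1, w2], [np.linspace(0, 1, 5)])
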