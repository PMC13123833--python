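"""Stochastic leap-frog dynamics for the C-alpha structure-based model.

The integrator is the impulse Langevin leap-frog: half-step velocities are
damped by exp(-gamma dt), kicked by the force, and refreshed with the
matching Ornstein-Uhlenbeck noise so the stationary distribution is the
Boltzmann ensemble at the requested temperature.  With gamma = 0 and T = 0
noise vanishes and the scheme reduces to plain (symplectic) leap-frog,
which is the validation mode used for energy-conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .topology import SBMTopology

DT = 0.0005              # tau
INVERSE_FRICTION = 1.0   # tau


@dataclass
class SimParams:
    temperature: float = 1.0     # eps / k_B
    n_steps: int = 100_000
    dt: float = DT
    inverse_friction: float = INVERSE_FRICTION
    stride: int = 1000           # steps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class Trajectory:
    """Frames plus per-frame energies of one run."""

    times: np.ndarray            # tau
    frames: np.ndarray           # (n_frames, n_beads, 3)
    potential: np.ndarray
    kinetic: np.ndarray
    final_velocities: np.ndarray = field(repr=False, default=None)


@njit(cache=True, fastmath=True)
def _forces(x, bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
            dihedrals, dihedral_c0, dihedral_s0, k_dih, contacts, contact_r0,
            contact_eps, width, r_ex, ev_pairs, n_ev, chain_of,
            tether_k, tether_r0, f):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pe = 0.0

    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        d0 = x[j, 0] - x[i, 0]
        d1 = x[j, 1] - x[i, 1]
        d2 = x[j, 2] - x[i, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        dr = r - bond_r0[b]
        pe += 0.5 * k_bond * dr * dr
        fmag = -k_bond * dr / r
        f[j, 0] += fmag * d0
        f[j, 1] += fmag * d1
        f[j, 2] += fmag * d2
        f[i, 0] -= fmag * d0
        f[i, 1] -= fmag * d1
        f[i, 2] -= fmag * d2

    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        u0 = x[i, 0] - x[j, 0]
        u1 = x[i, 1] - x[j, 1]
        u2 = x[i, 2] - x[j, 2]
        v0 = x[k, 0] - x[j, 0]
        v1 = x[k, 1] - x[j, 1]
        v2 = x[k, 2] - x[j, 2]
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        c = (u0 * v0 + u1 * v1 + u2 * v2) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - angle_t0[a]
        pe += 0.5 * k_angle * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = k_angle * dth / s
        fi0 = (coef / nu) * (v0 / nv - c * u0 / nu)
        fi1 = (coef / nu) * (v1 / nv - c * u1 / nu)
        fi2 = (coef / nu) * (v2 / nv - c * u2 / nu)
        fk0 = (coef / nv) * (u0 / nu - c * v0 / nv)
        fk1 = (coef / nv) * (u1 / nu - c * v1 / nv)
        fk2 = (coef / nv) * (u2 / nu - c * v2 / nv)
        f[i, 0] += fi0
        f[i, 1] += fi1
        f[i, 2] += fi2
        f[k, 0] += fk0
        f[k, 1] += fk1
        f[k, 2] += fk2
        f[j, 0] -= fi0 + fk0
        f[j, 1] -= fi1 + fk1
        f[j, 2] -= fi2 + fk2

    for d4 in range(dihedrals.shape[0]):
        ia, ib, ic, id_ = (dihedrals[d4, 0], dihedrals[d4, 1],
                           dihedrals[d4, 2], dihedrals[d4, 3])
        b10 = x[ib, 0] - x[ia, 0]
        b11 = x[ib, 1] - x[ia, 1]
        b12 = x[ib, 2] - x[ia, 2]
        b20 = x[ic, 0] - x[ib, 0]
        b21 = x[ic, 1] - x[ib, 1]
        b22 = x[ic, 2] - x[ib, 2]
        b30 = x[id_, 0] - x[ic, 0]
        b31 = x[id_, 1] - x[ic, 1]
        b32 = x[id_, 2] - x[ic, 2]
        n10 = b11 * b22 - b12 * b21
        n11 = b12 * b20 - b10 * b22
        n12 = b10 * b21 - b11 * b20
        n20 = b21 * b32 - b22 * b31
        n21 = b22 * b30 - b20 * b32
        n22 = b20 * b31 - b21 * b30
        n1sq = n10 * n10 + n11 * n11 + n12 * n12
        n2sq = n20 * n20 + n21 * n21 + n22 * n22
        nb2 = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        if n1sq < 1e-10 or n2sq < 1e-10:
            continue
        # m = n1 x (b2 / |b2|)
        m0 = (n11 * b22 - n12 * b21) / nb2
        m1 = (n12 * b20 - n10 * b22) / nb2
        m2 = (n10 * b21 - n11 * b20) / nb2
        yy = m0 * n20 + m1 * n21 + m2 * n22
        xx = n10 * n20 + n11 * n21 + n12 * n22
        hyp = np.sqrt(xx * xx + yy * yy)
        if hyp < 1e-12:
            continue
        cphi = xx / hyp
        sphi = yy / hyp
        # cos/sin of (phi - phi0) and of the tripled angle, trig-free
        cd = cphi * dihedral_c0[d4] + sphi * dihedral_s0[d4]
        sd = sphi * dihedral_c0[d4] - cphi * dihedral_s0[d4]
        c3 = 4.0 * cd * cd * cd - 3.0 * cd
        s3 = 3.0 * sd - 4.0 * sd * sd * sd
        pe += k_dih * (1.0 - cd) + 0.5 * k_dih * (1.0 - c3)
        dV = k_dih * sd + 1.5 * k_dih * s3
        ca_ = -dV * nb2 / n1sq
        cd_ = dV * nb2 / n2sq
        fa0 = ca_ * n10
        fa1 = ca_ * n11
        fa2 = ca_ * n12
        fd0 = cd_ * n20
        fd1 = cd_ * n21
        fd2 = cd_ * n22
        dot12 = (b10 * b20 + b11 * b21 + b12 * b22) / (nb2 * nb2)
        dot32 = (b30 * b20 + b31 * b21 + b32 * b22) / (nb2 * nb2)
        tb0 = -dot12 * fa0 + dot32 * fd0
        tb1 = -dot12 * fa1 + dot32 * fd1
        tb2 = -dot12 * fa2 + dot32 * fd2
        f[ia, 0] += fa0
        f[ia, 1] += fa1
        f[ia, 2] += fa2
        f[ib, 0] += -fa0 + tb0
        f[ib, 1] += -fa1 + tb1
        f[ib, 2] += -fa2 + tb2
        f[ic, 0] += -fd0 - tb0
        f[ic, 1] += -fd1 - tb1
        f[ic, 2] += -fd2 - tb2
        f[id_, 0] += fd0
        f[id_, 1] += fd1
        f[id_, 2] += fd2

    w2 = 2.0 * width * width
    for cc in range(contacts.shape[0]):
        i, j = contacts[cc, 0], contacts[cc, 1]
        d0 = x[j, 0] - x[i, 0]
        d1 = x[j, 1] - x[i, 1]
        d2 = x[j, 2] - x[i, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        r = np.sqrt(r2)
        eps = contact_eps[cc]
        r0 = contact_r0[cc]
        ratio2 = (r_ex * r_ex) / r2
        rep = ratio2 * ratio2 * ratio2
        rep = rep * rep
        g = np.exp(-(r - r0) * (r - r0) / w2)
        pe += eps * ((1.0 + rep) * (1.0 - g) - 1.0)
        drep = -12.0 * rep / r
        dg = -2.0 * (r - r0) / w2 * g
        dV = eps * (drep * (1.0 - g) - (1.0 + rep) * dg)
        fmag = -dV / r
        f[j, 0] += fmag * d0
        f[j, 1] += fmag * d1
        f[j, 2] += fmag * d2
        f[i, 0] -= fmag * d0
        f[i, 1] -= fmag * d1
        f[i, 2] -= fmag * d2

    # excluded volume over the active neighbour list
    cut2 = (2.5 * r_ex) * (2.5 * r_ex)
    shift = (1.0 / 2.5) ** 12
    for pp in range(n_ev):
            i = ev_pairs[pp, 0]
            j = ev_pairs[pp, 1]
            dx0 = x[j, 0] - x[i, 0]
            dx1 = x[j, 1] - x[i, 1]
            dx2 = x[j, 2] - x[i, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 > cut2:
                continue
            ratio2 = (r_ex * r_ex) / r2
            rep = ratio2 * ratio2 * ratio2
            rep = rep * rep
            pe += rep - shift
            fmag = 12.0 * rep / r2
            f[j, 0] += fmag * dx0
            f[j, 1] += fmag * dx1
            f[j, 2] += fmag * dx2
            f[i, 0] -= fmag * dx0
            f[i, 1] -= fmag * dx1
            f[i, 2] -= fmag * dx2

    if tether_k > 0.0:
        na = 0
        for i in range(n):
            if chain_of[i] == 0:
                na += 1
        coma = np.zeros(3)
        comb = np.zeros(3)
        for i in range(n):
            if chain_of[i] == 0:
                coma += x[i]
            else:
                comb += x[i]
        coma /= na
        comb /= (n - na)
        d = comb - coma
        r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - tether_r0
        pe += 0.5 * tether_k * dr * dr
        fmag = -tether_k * dr / r
        for i in range(n):
            if chain_of[i] == 0:
                f[i] -= (fmag / na) * d
            else:
                f[i] += (fmag / (n - na)) * d

    return f, pe


@njit(cache=True)
def _build_nlist(x, all_pairs, cut_skin2, out):
    m = 0
    for pp in range(all_pairs.shape[0]):
        i = all_pairs[pp, 0]
        j = all_pairs[pp, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        if dx0 * dx0 + dx1 * dx1 + dx2 * dx2 < cut_skin2:
            out[m, 0] = i
            out[m, 1] = j
            m += 1
    return m


@njit(cache=True)
def _integrate_chunk(x, v, f, xi, noise, damp, dt, nlist, n_ev,
                     bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
                     dihedrals, dihedral_c0, dihedral_s0, k_dih,
                     contacts, contact_r0, contact_eps, width, r_ex,
                     chain_of, tether_k, tether_r0):
    """Integrate len(xi) steps in place; returns (pe, ke) of the last step."""
    n = x.shape[0]
    steps = xi.shape[0]
    pe = 0.0
    ke = 0.0
    for step in range(steps):
        _, pe = _forces(x, bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
                        dihedrals, dihedral_c0, dihedral_s0, k_dih, contacts,
                        contact_r0, contact_eps, width, r_ex, nlist, n_ev,
                        chain_of, tether_k, tether_r0, f)
        last = step == steps - 1
        ke = 0.0
        for i in range(n):
            for d in range(3):
                vo = v[i, d]
                vn = damp * vo + f[i, d] * dt + noise * xi[step, i, d]
                v[i, d] = vn
                x[i, d] += vn * dt
                if last:
                    # on-step kinetic energy: the product of the two
                    # half-step velocities cancels the O((f dt)^2) bias
                    ke += 0.5 * vo * vn
    if not np.isfinite(x[0, 0] + x[n - 1, 2]):
        raise RuntimeError("force overflow: bead overlap / unstable step")
    return pe, ke


def _nonexcluded_pairs(topo: SBMTopology) -> np.ndarray:
    """Flat (i, j) pair list for the excluded-volume sum, cached."""
    cached = getattr(topo, "_ev_pairs", None)
    if cached is not None:
        return cached
    iu = np.triu_indices(topo.n_beads, k=1)
    keep = topo.exclusion[iu] == 0
    pairs = np.ascontiguousarray(
        np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int64))
    topo._ev_pairs = pairs
    return pairs


def _topo_args(topo: SBMTopology):
    return (topo.bonds, topo.bond_r0, topo.k_bond,
            topo.angles, topo.angle_t0, topo.k_angle,
            topo.dihedrals, np.cos(topo.dihedral_p0), np.sin(topo.dihedral_p0),
            topo.k_dihedral,
            topo.contacts, topo.contact_r0, topo.contact_eps,
            topo.gaussian_width, topo.r_excluded,
            _nonexcluded_pairs(topo), topo.chain_of,
            topo.tether_k, topo.tether_r0)


def potential_energy(topo: SBMTopology, x: np.ndarray) -> float:
    args = _topo_args(topo)
    pairs = args[15]
    f = np.zeros((topo.n_beads, 3))
    full = args[:16] + (len(pairs),) + args[16:] + (f,)
    _, pe = _forces(np.ascontiguousarray(x, dtype=np.float64), *full)
    return float(pe)


def run_langevin(
    topo: SBMTopology,
    params: SimParams,
    initial: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Integrate stochastic leap-frog dynamics; frames every ``stride`` steps.

    ``inverse_friction = 0`` is rejected; to run the frictionless
    validation mode set ``inverse_friction = inf`` (gamma = 0).
    """
    x = np.ascontiguousarray(
        topo.native if initial is None else initial, dtype=np.float64).copy()
    if x.shape != (topo.n_beads, 3):
        raise ValueError("initial coordinates have wrong shape")
    if not np.all(np.isfinite(x)):
        raise ValueError("initial coordinates must be finite")
    gamma = 0.0 if np.isinf(params.inverse_friction) else 1.0 / params.inverse_friction
    if velocities is None:
        rng = np.random.default_rng(params.seed + 7)
        if params.temperature > 0 and gamma > 0:
            v = rng.normal(scale=np.sqrt(params.temperature), size=x.shape)
        else:
            v = np.zeros_like(x)
    else:
        v = np.ascontiguousarray(velocities, dtype=np.float64).copy()

    args = _topo_args(topo)
    all_pairs = args[15]
    ff_args = args[:15] + args[16:]  # drop pair list (neighbour list instead)
    if gamma > 0.0:
        damp = float(np.exp(-gamma * params.dt))
        noise = float(np.sqrt((1.0 - damp * damp) * params.temperature))
    else:
        damp, noise = 1.0, 0.0

    n = topo.n_beads
    stride = params.stride
    n_frames = params.n_steps // stride
    frames = np.zeros((n_frames, n, 3))
    pe_out = np.zeros(n_frames)
    ke_out = np.zeros(n_frames)
    f = np.zeros((n, 3))
    # chunks of <= 10000 steps that tile each stride exactly; noise comes
    # from numpy's generator (fast bulk Gaussians, one seed per run)
    n_sub = max(1, -(-stride // 10_000))
    while stride % n_sub:
        n_sub += 1
    chunk = stride // n_sub
    rng = np.random.default_rng(params.seed)
    # Verlet neighbour list, 4 A skin: per-step displacements are ~1e-3 A
    # so rebuilding once per chunk is conservative
    cut_skin2 = (2.5 * topo.r_excluded + 4.0) ** 2
    nlist = np.empty_like(all_pairs)
    for frame in range(n_frames):
        for _ in range(n_sub):
            n_ev = _build_nlist(x, all_pairs, cut_skin2, nlist)
            xi = (rng.standard_normal((chunk, n, 3)) if noise > 0.0
                  else np.zeros((chunk, n, 3)))
            pe, ke = _integrate_chunk(x, v, f, xi, noise, damp, params.dt,
                                      nlist, n_ev, *ff_args)
        frames[frame] = x
        pe_out[frame] = pe
        ke_out[frame] = ke
    times = params.dt * stride * np.arange(1, n_frames + 1)
    return Trajectory(times=times, frames=frames, potential=pe_out,
                      kinetic=ke_out, final_velocities=v)
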