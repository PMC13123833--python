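"""Weighted histogram analysis method (WHAM) for multi-temperature data.

Samples from K temperatures are binned jointly over the order parameters
and the potential energy; the density of states is solved self-consistently

    Omega(x, E) = sum_k H_k(x, E) / sum_k N_k exp(f_k - beta_k E)
    exp(-f_k)   = sum_{x, E} Omega(x, E) exp(-beta_k E)

and re-weighted to the target temperature.  A single window degenerates to
the direct Boltzmann inversion F = -k_B T ln P, which is returned exactly
in that case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

F_TOL = 1e-6
MAX_ITER = 10_000


@dataclass
class FESurface:
    """Free-energy surface on an order-parameter grid (min-shifted to 0)."""

    f: np.ndarray                 # (n_bins...,) eps units; inf where unsampled
    edges: list[np.ndarray]
    temperature: float

    def projection(self, axis_index: int) -> np.ndarray:
        """1D projection F(x_axis) by Boltzmann-summing the other axes."""
        axes = tuple(i for i in range(self.f.ndim) if i != axis_index)
        if not axes:
            return self.f.copy()
        with np.errstate(over="ignore"):
            weight = np.exp(-self.f / self.temperature)
        weight[~np.isfinite(self.f)] = 0.0
        p = weight.sum(axis=axes)
        out = np.full(p.shape, np.inf)
        ok = p > 0
        out[ok] = -self.temperature * np.log(p[ok])
        return out - out[ok].min()


@dataclass
class WhamWindow:
    """Samples collected at one temperature."""

    temperature: float
    order_params: np.ndarray      # (n_samples, d)
    energies: np.ndarray          # (n_samples,)


def _histogram(window: WhamWindow, edges: list[np.ndarray],
               e_edges: np.ndarray) -> np.ndarray:
    data = np.column_stack([window.order_params, window.energies])
    hist, _ = np.histogramdd(data, bins=edges + [e_edges])
    return hist


def wham_free_energy(
    windows: list[WhamWindow],
    bins: list[np.ndarray],
    temperature_out: float | None = None,
    n_energy_bins: int = 60,
    tol: float = F_TOL,
    max_iter: int = MAX_ITER,
) -> FESurface:
    """Free-energy surface over the order-parameter grid ``bins``.

    ``bins`` is a list of bin-edge arrays (one per order parameter);
    ``temperature_out`` defaults to the lowest window temperature.
    Raises when the energy histograms of the windows do not overlap.
    """
    if not windows:
        raise ValueError("need at least one window")
    k_T = [w.temperature for w in windows]
    if temperature_out is None:
        temperature_out = min(k_T)
    if len(windows) == 1:
        w = windows[0]
        hist, _ = np.histogramdd(w.order_params, bins=bins)
        f = np.full(hist.shape, np.inf)
        ok = hist > 0
        p = hist / hist.sum()
        f[ok] = -w.temperature * np.log(p[ok])
        f -= f[ok].min()
        return FESurface(f=f, edges=[np.asarray(b) for b in bins],
                         temperature=w.temperature)

    e_all = np.concatenate([w.energies for w in windows])
    e_edges = np.linspace(e_all.min() - 1e-9, e_all.max() + 1e-9, n_energy_bins + 1)
    # overlap check: consecutive (sorted by T) windows must share energy bins
    order = np.argsort(k_T)
    e_hists = [np.histogram(windows[i].energies, bins=e_edges)[0] for i in order]
    for a, b in zip(order[:-1], order[1:]):
        ha = np.histogram(windows[a].energies, bins=e_edges)[0] > 0
        hb = np.histogram(windows[b].energies, bins=e_edges)[0] > 0
        if not np.any(ha & hb):
            raise ValueError(
                f"energy histograms of windows at T={k_T[a]:.4g} and "
                f"T={k_T[b]:.4g} do not overlap"
            )

    hists = np.stack([_histogram(w, [np.asarray(b) for b in bins], e_edges)
                      for w in windows])
    n_k = np.array([len(w.energies) for w in windows], float)
    betas = 1.0 / np.array(k_T)
    e_mid = 0.5 * (e_edges[:-1] + e_edges[1:])
    h_sum = hists.sum(axis=0)

    f_k = np.zeros(len(windows))
    for _ in range(max_iter):
        # log-denominator per energy bin: ln sum_k N_k exp(f_k - beta_k E)
        log_terms = (np.log(n_k)[:, None] + f_k[:, None]
                     - betas[:, None] * e_mid[None, :])
        log_denom = np.logaddexp.reduce(log_terms, axis=0)
        with np.errstate(divide="ignore"):
            log_omega = np.where(h_sum > 0, np.log(np.maximum(h_sum, 1e-300)), -np.inf)
        log_omega = log_omega - log_denom  # broadcast over the last (E) axis
        new_f = np.empty_like(f_k)
        for k in range(len(windows)):
            contrib = log_omega - betas[k] * e_mid
            flat = contrib[np.isfinite(contrib)]
            new_f[k] = -_logsumexp(flat)
        new_f -= new_f[0]
        if np.max(np.abs(new_f - f_k)) < tol:
            f_k = new_f
            break
        f_k = new_f

    log_terms = (np.log(n_k)[:, None] + f_k[:, None]
                 - betas[:, None] * e_mid[None, :])
    log_denom = np.logaddexp.reduce(log_terms, axis=0)
    with np.errstate(divide="ignore"):
        log_omega = np.where(h_sum > 0, np.log(np.maximum(h_sum, 1e-300)), -np.inf)
    log_omega = log_omega - log_denom
    beta_out = 1.0 / temperature_out
    log_p = np.full(h_sum.shape[:-1], -np.inf)
    it = np.nditer(log_p, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        contrib = log_omega[idx] - beta_out * e_mid
        flat = contrib[np.isfinite(contrib)]
        if len(flat):
            log_p[idx] = _logsumexp(flat)
    f = np.full(log_p.shape, np.inf)
    ok = np.isfinite(log_p)
    f[ok] = -temperature_out * log_p[ok]
    f -= f[ok].min()
    return FESurface(f=f, edges=[np.asarray(b) for b in bins],
                     temperature=temperature_out)


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))
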