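"""WHAM reweighting of umbrella windows and per-linker-length summaries.

Umbrella sampling along the fraction of native contacts Q gives biased
samples per window; the weighted-histogram analysis method (WHAM)
reconstructs the unbiased free-energy profile G(Q) and per-sample weights,
from which folded/unfolded populations (boundary Q = 0.5) and the mean
tether force exerted in each state are computed for every linker length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import KB

__all__ = [
    "FreeEnergyProfile",
    "EquilibriumSummary",
    "wham",
    "wham_block_bootstrap",
    "state_split",
    "mean_state_forces",
    "summarize_per_L",
]


@dataclass
class FreeEnergyProfile:
    """G(Q) on a uniform Q grid, defined up to an additive constant."""

    q_grid: np.ndarray        # bin centers
    g: np.ndarray             # kJ/mol; +inf on empty bins
    weight: np.ndarray        # unbiased probability mass per bin
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Q": self.q_grid, "G_kJmol": self.g,
                             "weight": self.weight})


class WHAMConvergenceError(RuntimeError):
    pass


def _histogram_overlap(q_a, q_b, bins) -> float:
    ha, _ = np.histogram(q_a, bins=bins)
    hb, _ = np.histogram(q_b, bins=bins)
    pa = ha / max(ha.sum(), 1)
    pb = hb / max(hb.sum(), 1)
    return float(np.minimum(pa, pb).sum())


def check_window_overlap(windows, bins=50, min_overlap=0.02) -> None:
    """Warn when adjacent windows (sorted by center) barely overlap in Q."""
    ws = sorted(windows, key=lambda w: w.center)
    edges = np.linspace(0.0, 1.0, bins + 1)
    for a, b in zip(ws, ws[1:]):
        ov = _histogram_overlap(a.q, b.q, edges)
        if ov < min_overlap:
            warnings.warn(
                f"umbrella windows at Q0={a.center:.3f} and {b.center:.3f} "
                f"share only {100 * ov:.1f}% histogram mass; WHAM may be "
                "unreliable", stacklevel=3)


def wham(windows, temperature: float | None = None, n_bins: int = 50,
         tolerance: float = 1e-7, max_iter: int = 100000):
    """Self-consistent WHAM over umbrella windows biased along Q.

    ``windows`` is a sequence of objects with attributes ``q`` (samples),
    ``k_umb`` (bias constant, kJ/mol, bias = k_umb*(Q-Q0)^2/2), ``center``
    (Q0) and ``temperature``.  Returns ``(profile, weights)`` where
    ``weights`` is the per-sample unbiased weight array (concatenated in
    window order, normalized to sum to 1).

    The window free energies f_k are iterated to self-consistency:

        p(b) ~ sum_k n_k(b) / sum_k N_k exp[-beta (W_k(b) - f_k)]
        exp(-beta f_k) = sum_b p(b) exp(-beta W_k(b))

    and convergence is declared when max |f_k - f_k'| < ``tolerance``.
    """
    windows = list(windows)
    if len(windows) == 0:
        raise ValueError("need at least one umbrella window")
    if temperature is None:
        temperature = windows[0].temperature
    beta = 1.0 / (KB * temperature)

    check_window_overlap(windows, bins=n_bins)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    q_all = np.concatenate([np.asarray(w.q, dtype=float) for w in windows])
    n_k = np.array([len(np.asarray(w.q)) for w in windows])
    counts = np.zeros(n_bins)
    for w in windows:
        h, _ = np.histogram(w.q, bins=edges)
        counts += h

    # bias energy of window k evaluated at every bin center
    w_kb = np.array([0.5 * w.k_umb * (centers - w.center) ** 2
                     for w in windows])
    boltz_kb = np.exp(-beta * w_kb)  # (K, B)

    f_k = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (n_k[:, None] * np.exp(beta * f_k)[:, None] * boltz_kb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b = np.where(denom > 0, counts / denom, 0.0)
        z_k = boltz_kb @ p_b
        f_new = -np.log(z_k) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f_k))
        f_k = f_new
        if delta < tolerance:
            break
    else:
        overlaps = [
            _histogram_overlap(a.q, b.q, edges)
            for a, b in zip(sorted(windows, key=lambda w: w.center),
                            sorted(windows, key=lambda w: w.center)[1:])
        ]
        raise WHAMConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last delta={delta:.2e}); adjacent-window overlaps: "
            + ", ".join(f"{o:.3f}" for o in overlaps))

    # per-sample unbiased weights: w_i ~ 1 / sum_k N_k exp[-beta(W_k(q_i)-f_k)]
    bias_at_q = np.array([0.5 * w.k_umb * (q_all - w.center) ** 2
                          for w in windows])  # (K, S)
    denom_s = (n_k[:, None] * np.exp(beta * f_k)[:, None]
               * np.exp(-beta * bias_at_q)).sum(axis=0)
    weights = 1.0 / denom_s
    weights /= weights.sum()

    mass = np.zeros(n_bins)
    idx = np.clip(np.digitize(q_all, edges) - 1, 0, n_bins - 1)
    np.add.at(mass, idx, weights)
    with np.errstate(divide="ignore"):
        g = np.where(mass > 0, -np.log(np.maximum(mass, 1e-300)) / beta, np.inf)
    g = g - np.min(g)
    profile = FreeEnergyProfile(centers, g, mass, temperature)
    return profile, weights


class _ResampledWindow:
    def __init__(self, base, q):
        self.q = q
        self.k_umb = base.k_umb
        self.center = base.center
        self.temperature = base.temperature


def wham_block_bootstrap(windows, n_boot: int = 20, n_blocks: int = 10,
                         n_bins: int = 50, tolerance: float = 1e-6,
                         seed: int = 0):
    """Per-bin statistical error of G(Q) by block bootstrap.

    Each window's sample series is cut into ``n_blocks`` contiguous blocks
    (blocks, not frames, are resampled, so autocorrelation within a block
    is respected) and WHAM is re-run on each bootstrap replicate.  Returns
    the per-bin standard deviation of G across replicates (NaN on bins not
    sampled in every replicate).
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            q = np.asarray(w.q, float)
            blocks = np.array_split(q, n_blocks)
            pick = rng.integers(0, len(blocks), size=len(blocks))
            resampled.append(_ResampledWindow(
                w, np.concatenate([blocks[b] for b in pick])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile, _ = wham(resampled, n_bins=n_bins, tolerance=tolerance)
        g = profile.g.copy()
        finite = np.isfinite(g)
        g[finite] -= g[finite].mean()
        profiles.append(g)
    g_mat = np.array(profiles)
    with np.errstate(invalid="ignore"):
        err = np.where(np.all(np.isfinite(g_mat), axis=0),
                       np.nanstd(g_mat, axis=0), np.nan)
    return err


def state_split(weights, q, boundary: float = 0.5):
    """Folded/unfolded populations from weighted samples of Q.

    P_f is the total unbiased weight at Q > ``boundary``; P_u = 1 - P_f.
    """
    weights = np.asarray(weights, dtype=float)
    q = np.asarray(q, dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive total mass")
    p_f = float(weights[q > boundary].sum() / wsum)
    p_u = 1.0 - p_f
    if p_f in (0.0, 1.0):
        warnings.warn(
            f"all statistical weight on one side of Q={boundary}: the "
            "other state was never sampled", stacklevel=2)
    return p_u, p_f


def mean_state_forces(weights, q, force_pn, boundary: float = 0.5):
    """Weight-conditioned mean tether force (pN) in each Q-state.

    Returns (F_u, F_f); an unsampled state yields NaN (its population is
    zero, so downstream population-weighted averages are unaffected).
    """
    weights = np.asarray(weights, dtype=float)
    q = np.asarray(q, dtype=float)
    f = np.asarray(force_pn, dtype=float)
    out = []
    for mask in (q <= boundary, q > boundary):
        wm = weights[mask]
        if wm.sum() > 0:
            out.append(float(np.average(f[mask], weights=wm)))
        else:
            warnings.warn("state with zero weight: mean force undefined",
                          stacklevel=2)
            out.append(float("nan"))
    return out[0], out[1]


@dataclass
class EquilibriumSummary:
    """Equilibrium observables of one linker length while arrested."""

    L: int
    p_u: float
    p_f: float
    f_u_pn: float
    f_f_pn: float
    profile: FreeEnergyProfile | None = None


def summarize_per_L(windows_per_L: dict, boundary: float = 0.5,
                    n_bins: int = 50, tolerance: float = 1e-7):
    """WHAM + state analysis for a family of linker lengths.

    ``windows_per_L`` maps L -> list of umbrella windows whose samples
    carry both ``q`` and ``force_pn`` arrays.  Returns a list of
    EquilibriumSummary sorted by L.
    """
    summaries = []
    for L in sorted(windows_per_L):
        windows = windows_per_L[L]
        profile, weights = wham(windows, n_bins=n_bins, tolerance=tolerance)
        q_all = np.concatenate([np.asarray(w.q, float) for w in windows])
        f_all = np.concatenate([np.asarray(w.force_pn, float)
                                for w in windows])
        p_u, p_f = state_split(weights, q_all, boundary)
        f_u, f_f = mean_state_forces(weights, q_all, f_all, boundary)
        summaries.append(EquilibriumSummary(L=L, p_u=p_u, p_f=p_f,
                                            f_u_pn=f_u, f_f_pn=f_f,
                                            profile=profile))
    return summaries


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([{
        "L": s.L, "P_u": s.p_u, "P_f": s.p_f,
        "F_u_pN": s.f_u_pn, "F_f_pN": s.f_f_pn,
    } for s in summaries])
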