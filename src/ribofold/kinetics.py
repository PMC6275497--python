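"""Force-dependent arrest-escape kinetics and the fraction full-length f_FL.

While translation is arrested, the nascent protein can fold (UA -> FA) and
unfold (FA -> UA) behind the stalled arrest peptide, and either state can
escape arrest with a force-dependent rate, producing full-length protein
(UA -> UR, FA -> FR; UR/FR absorbing).  The escape rate follows the Bell
model k_e(F) = k0 * exp(beta * F * dx), parameterized from optical-tweezer
measurements on the SecM arrest peptide.  f_FL(t) is the probability of
having escaped by the incubation time t, computed either by kinetic Monte
Carlo on the full four-state scheme or by a preequilibrium closed form
valid when folding/unfolding is fast compared with escape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .units import KB, force_from_pn

__all__ = [
    "BellParameters",
    "KineticScheme",
    "RateSet",
    "ForceProfile",
    "MFPTEstimate",
    "bell_rate",
    "mfpt_censored",
    "scale_rates",
    "kmc_ffl",
    "master_equation_ffl",
    "preeq_ffl",
    "assemble_profile",
    "profile_rmsd",
]

# Admissible ranges for the Bell parameters, from the optical-tweezer
# characterization of SecM escape kinetics (soft validation bounds).
_K0_RANGE = (0.5e-4, 20e-4)  # s^-1
_DX_RANGE = (0.1, 0.8)  # nm


@dataclass(frozen=True)
class BellParameters:
    """Parameters of the Bell escape-rate model k_e(F) = k0 exp(beta F dx).

    k0 is the zero-force escape rate (s^-1), dx the distance from the
    arrested state to the escape transition state (nm), temperature in K.
    """

    k0: float = 3.4e-4
    dx: float = 0.32
    temperature: float = 291.0

    def __post_init__(self):
        if self.k0 <= 0 or self.dx <= 0 or self.temperature <= 0:
            raise ValueError("BellParameters must be positive")
        if not (_K0_RANGE[0] <= self.k0 <= _K0_RANGE[1]):
            warnings.warn(
                f"k0={self.k0:g} s^-1 outside the experimentally admissible "
                f"range {_K0_RANGE}", stacklevel=2)
        if not (_DX_RANGE[0] <= self.dx <= _DX_RANGE[1]):
            warnings.warn(
                f"dx={self.dx:g} nm outside the experimentally admissible "
                f"range {_DX_RANGE}", stacklevel=2)

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


def bell_rate(force_pn, params: BellParameters = BellParameters()):
    """Force-dependent escape rate k_e(F) = k0 * exp(beta F dx), in s^-1.

    ``force_pn`` is the pulling force in pN (scalar or array); it is
    converted internally to kJ/mol/nm.
    """
    f = force_from_pn(np.asarray(force_pn, dtype=float))
    return params.k0 * np.exp(params.beta * f * params.dx)


@dataclass(frozen=True)
class MFPTEstimate:
    """Censoring-aware mean first-passage-time estimate.

    ``value`` is the maximum-likelihood MFPT
    [N_event * t_mean_event + (N - N_event) * t_sim] / N_event; when no
    events occurred it degrades to the censoring lower bound N * t_sim and
    ``lower_bound_only`` is set.
    """

    value: float
    n_events: int
    n_total: int
    t_sim: float
    lower_bound_only: bool = False

    @property
    def rate(self) -> float:
        return 1.0 / self.value


def mfpt_censored(first_passage_times, n_total: int, t_sim: float) -> MFPTEstimate:
    """Maximum-likelihood MFPT from (possibly censored) first-passage data.

    ``first_passage_times`` are the times of the trajectories that did reach
    the target within ``t_sim``; the remaining ``n_total - len(...)``
    trajectories are right-censored at ``t_sim``.
    """
    fpt = np.asarray(first_passage_times, dtype=float)
    n_event = fpt.size
    if n_event > n_total:
        raise ValueError("more first-passage events than trajectories")
    if t_sim <= 0:
        raise ValueError("t_sim must be positive")
    if np.any(fpt > t_sim + 1e-12 * t_sim):
        raise ValueError("first-passage time exceeds t_sim")
    if n_event == 0:
        return MFPTEstimate(n_total * t_sim, 0, n_total, t_sim,
                            lower_bound_only=True)
    value = (fpt.sum() + (n_total - n_event) * t_sim) / n_event
    return MFPTEstimate(value, n_event, n_total, t_sim)


@dataclass
class RateSet:
    """Per-linker-length folding/unfolding rates, raw and rescaled.

    Simulated rates (internal time units) are mapped to s^-1 with one global
    multiplicative factor per rate type, chosen so that at the anchor
    (largest) linker length the scaled unfolding rate equals the
    experimental unfolding rate of the isolated domain and the scaled
    kf/ku ratio equals ``stability_anchor`` (the model's own folded/unfolded
    equilibrium constant at that length).
    """

    L: np.ndarray
    kf_sim: np.ndarray
    ku_sim: np.ndarray
    kf: np.ndarray
    ku: np.ndarray
    factor_f: float
    factor_u: float
    k_u_iso_exp: float
    stability_anchor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "L": self.L, "kf_sim": self.kf_sim, "ku_sim": self.ku_sim,
            "kf_s": self.kf, "ku_s": self.ku,
        })


def scale_rates(L, kf_sim, ku_sim, k_u_iso_exp: float,
                stability_anchor: float) -> RateSet:
    """Globally rescale simulated rates to experimental units.

    The anchor is the largest L in the table: there the scaled ku equals
    ``k_u_iso_exp`` exactly and the scaled kf/ku equals
    ``stability_anchor`` (= P_f/P_u of the model at the anchor length, so
    the kinetic and equilibrium descriptions agree).  The same two factors
    apply at every L, so rate ratios between linker lengths are preserved.
    """
    L = np.asarray(L, dtype=float)
    kf_sim = np.asarray(kf_sim, dtype=float)
    ku_sim = np.asarray(ku_sim, dtype=float)
    if not (L.shape == kf_sim.shape == ku_sim.shape) or L.size == 0:
        raise ValueError("L, kf_sim, ku_sim must be equal-length, non-empty")
    if np.any(kf_sim <= 0) or np.any(ku_sim <= 0):
        raise ValueError("simulated rates must be positive")
    ia = int(np.argmax(L))
    factor_u = k_u_iso_exp / ku_sim[ia]
    factor_f = k_u_iso_exp * stability_anchor / kf_sim[ia]
    return RateSet(
        L=L, kf_sim=kf_sim, ku_sim=ku_sim,
        kf=kf_sim * factor_f, ku=ku_sim * factor_u,
        factor_f=factor_f, factor_u=factor_u,
        k_u_iso_exp=k_u_iso_exp, stability_anchor=stability_anchor,
    )


# Four-state arrest/escape scheme.  State order: UA, FA, UR, FR.
_UA, _FA, _UR, _FR = 0, 1, 2, 3


@dataclass(frozen=True)
class KineticScheme:
    """Rates of the four-state scheme {UA, FA, UR, FR} (all s^-1).

    UA <-> FA with rates kf/ku; UA -> UR at ke_u = k_e(F_u) and FA -> FR at
    ke_f = k_e(F_f); UR and FR are absorbing (released protein).
    """

    kf: float
    ku: float
    ke_u: float
    ke_f: float

    def __post_init__(self):
        if min(self.kf, self.ku, self.ke_u, self.ke_f) < 0:
            raise ValueError("rates must be non-negative")

    def generator(self) -> np.ndarray:
        """Master-equation rate matrix Q with Q[i, j] = rate i -> j."""
        q = np.zeros((4, 4))
        q[_UA, _FA] = self.kf
        q[_FA, _UA] = self.ku
        q[_UA, _UR] = self.ke_u
        q[_FA, _FR] = self.ke_f
        q[np.diag_indices(4)] = -q.sum(axis=1)
        return q


@dataclass
class KMCResult:
    f_fl: float
    se: float
    n_replicas: int
    escape_times: np.ndarray  # inf where still arrested at t_total

    def survival(self, times) -> np.ndarray:
        """S(t): fraction of replicas still arrested at each time."""
        t = np.asarray(times, dtype=float)
        return 1.0 - (self.escape_times[None, :] <= t[:, None]).mean(axis=1)


def kmc_ffl(scheme: KineticScheme, t_total: float = 900.0,
            n_replicas: int = 2000, seed: int = 0) -> KMCResult:
    """f_FL by kinetic Monte Carlo (BKL / n-fold way) on the 4-state scheme.

    Each replica starts in UA (unfolded, arrested) at t = 0, the moment the
    nascent chain emerges.  At every step a uniform random number selects
    the transition proportionally to its rate and the waiting time is
    sampled as dt = -ln(delta') / sum(k).  f_FL is the fraction of replicas
    in UR or FR at ``t_total`` (default 900 s, the 15-min incubation).
    """
    if t_total < 0:
        raise ValueError("t_total must be >= 0")
    if t_total > 0:
        if (scheme.kf + scheme.ke_u <= 0
                or (scheme.kf > 0 and scheme.ku + scheme.ke_f <= 0)):
            raise ValueError("non-absorbing state with zero total outflow")
    from ._kernels import kmc_four_state

    rng = np.random.default_rng(seed)
    escape_times = kmc_four_state(
        scheme.kf, scheme.ku, scheme.ke_u, scheme.ke_f,
        float(t_total), int(n_replicas),
        int(rng.integers(0, 2 ** 31 - 1)))
    if escape_times.size == 1 and escape_times[0] == -1.0:
        raise ValueError("non-absorbing state with zero total outflow")
    p = float((escape_times <= t_total).mean())
    se = float(np.sqrt(p * (1.0 - p) / n_replicas))
    return KMCResult(p, se, n_replicas, escape_times)


def master_equation_ffl(scheme: KineticScheme, t_total: float) -> float:
    """Exact f_FL(t) from the matrix exponential of the 4-state generator."""
    p0 = np.array([1.0, 0.0, 0.0, 0.0])
    pt = p0 @ expm(scheme.generator() * t_total)
    return float(pt[_UR] + pt[_FR])


def preeq_ffl(p_u: float, p_f: float, f_u_pn: float, f_f_pn: float,
              t: float, bell: BellParameters = BellParameters()) -> float:
    """Preequilibrium f_FL(t) = 1 - exp(-t [P_u k_e(F_u) + P_f k_e(F_f)]).

    Valid when folding/unfolding equilibrates fast relative to escape; the
    arrested protein then escapes with the population-weighted mean rate.
    """
    if not np.isclose(p_u + p_f, 1.0, atol=1e-8):
        raise ValueError("P_u + P_f must equal 1")
    # population-weighted escape rate, assembled in log space so that a
    # vanishing population suppresses an arbitrarily large state force
    # (P -> 0 wins against exp(beta F dx) -> inf)
    rate = 0.0
    for p, f in ((p_u, f_u_pn), (p_f, f_f_pn)):
        if p > 0:
            log_term = np.log(p) + np.log(bell.k0) \
                + bell.beta * force_from_pn(f) * bell.dx
            rate += np.exp(log_term)
    return float(1.0 - np.exp(-t * rate))


@dataclass
class ForceProfile:
    """Predicted f_FL per linker length, by both kinetic solvers."""

    table: pd.DataFrame  # columns L, f_fl_kmc, f_fl_se, f_fl_preeq, flagged
    t_incubation: float

    @property
    def L(self) -> np.ndarray:
        return self.table["L"].to_numpy()

    def peak_L(self, column: str = "f_fl_kmc") -> float:
        return float(self.table["L"].iloc[int(self.table[column].argmax())])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def assemble_profile(summaries, rates: RateSet,
                     bell: BellParameters = BellParameters(),
                     t: float = 900.0, n_replicas: int = 20000,
                     seed: int = 0, flag_tol: float = 0.05) -> ForceProfile:
    """Per-L f_FL by the full kinetic scheme and the preequilibrium model.

    ``summaries`` is an iterable of EquilibriumSummary-like objects with
    attributes L, p_u, p_f, f_u_pn, f_f_pn on the same L grid as ``rates``.
    L values where the two solvers disagree by more than ``flag_tol`` are
    flagged (the preequilibrium assumption is then suspect there).
    """
    summaries = list(summaries)
    sum_L = np.array([s.L for s in summaries], dtype=float)
    if sorted(sum_L.tolist()) != sorted(np.asarray(rates.L, float).tolist()):
        raise ValueError("summaries and rates must cover the same L grid")
    rate_by_L = {float(l): (kf, ku)
                 for l, kf, ku in zip(rates.L, rates.kf, rates.ku)}
    rows = []
    for i, s in enumerate(sorted(summaries, key=lambda s: s.L)):
        kf, ku = rate_by_L[float(s.L)]
        # unfolded states with empty folded basin carry F_f with weight 0
        f_f = s.f_f_pn if s.p_f > 0 else 0.0
        f_u = s.f_u_pn if s.p_u > 0 else 0.0
        # escape rates capped so that an unpopulated high-force state
        # cannot overflow the sampler (its occupancy is ~0 anyway)
        with np.errstate(over="ignore"):
            ke_u = float(np.minimum(bell_rate(f_u, bell), 1e9))
            ke_f = float(np.minimum(bell_rate(f_f, bell), 1e9))
        scheme = KineticScheme(kf=kf, ku=ku, ke_u=ke_u, ke_f=ke_f)
        kmc = kmc_ffl(scheme, t, n_replicas, seed=seed + i)
        pre = preeq_ffl(s.p_u, s.p_f, f_u, f_f, t, bell)
        rows.append({
            "L": s.L, "f_fl_kmc": kmc.f_fl, "f_fl_se": kmc.se,
            "f_fl_preeq": pre,
            "flagged": abs(kmc.f_fl - pre) > flag_tol,
        })
    return ForceProfile(pd.DataFrame(rows), t)


def profile_rmsd(predicted: pd.DataFrame, experimental: pd.DataFrame,
                 pred_col: str = "f_fl_kmc", exp_col: str = "f_fl") -> float:
    """RMS difference of f_FL between prediction and experiment on shared L.

    Both frames need an "L" column; ``experimental`` is typically read from
    a two-column (L, f_FL) TSV.
    """
    merged = pd.merge(predicted, experimental, on="L",
                      suffixes=("_pred", "_exp"))
    if len(merged) == 0:
        raise ValueError("no shared linker lengths between the profiles")
    pc = pred_col if pred_col in merged else pred_col + "_pred"
    ec = exp_col if exp_col in merged else exp_col + "_exp"
    d = merged[pc].to_numpy(float) - merged[ec].to_numpy(float)
    return float(np.sqrt(np.mean(d * d)))
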