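"""Transition-path statistics: phi-values and contact importance.

Transition paths (TPs) are the barrier-crossing segments of a trajectory,
delimited on the fraction-of-native-contacts coordinate Q: a folding TP
runs from the last frame with Q < q_low to the first subsequent frame with
Q > q_high (reversed for unfolding).  From an ensemble of TPs the folding
mechanism is quantified by

* phi(i): mean formation probability on TPs of residue i's native contacts,
* p(TP|q_ij)_nn = p(q_ij|TP) p(TP)_nn / p(q_ij)_nn (Bayes), the probability
  of being on a TP given contact (i, j) is formed, restricted to nonnative
  (unfolded + TP) frames,
* p(TP)_nn, the fraction of nonnative time on TPs, estimated from the mean
  TP time and mean first-passage times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "TPEnsemble",
    "MechanismReport",
    "extract_tps",
    "contact_states",
    "phi_values",
    "p_tp_nn",
    "p_tp_given_q",
    "compare_phi",
    "mechanism_report",
]

# frame labels
TP, UNFOLDED, FOLDED = 1, 0, 2


def extract_tps(q, q_low: float = 0.3, q_high: float = 0.7,
                direction: str = "folding"):
    """Maximal transition-path segments of a Q time series.

    Folding direction: each TP runs from the last frame with Q < ``q_low``
    before the chain first reaches Q > ``q_high``, up to and including that
    first crossing frame.  The unfolding direction swaps the roles of the
    two thresholds.  Returns a list of (start, stop) index pairs with
    inclusive ends; a trajectory that never crosses both thresholds yields
    an empty list.
    """
    q = np.asarray(q, dtype=float)
    if direction == "folding":
        in_reactant = q < q_low
        in_product = q > q_high
    elif direction == "unfolding":
        in_reactant = q > q_high
        in_product = q < q_low
    else:
        raise ValueError("direction must be 'folding' or 'unfolding'")
    segments = []
    last_reactant = None
    for t in range(q.size):
        if in_reactant[t]:
            last_reactant = t
        elif in_product[t]:
            if last_reactant is not None:
                segments.append((last_reactant, t))
                last_reactant = None
    return segments


def contact_states(distances, r0, lam: float = 1.2):
    """Binary contact-formation matrix: formed iff r_ij < lam * r0_ij.

    ``distances`` is (n_frames, n_contacts); the strict inequality makes a
    pair at exactly the switching midpoint count as not formed.  The
    criterion matches the midpoint of the smooth switching function used
    for Q, so the binary and smooth definitions agree on the same
    fluctuation allowance.
    """
    d = np.asarray(distances, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    return d < lam * r0[None, :]


@dataclass
class TPEnsemble:
    """Labeled frames with per-contact binary formation states.

    ``labels`` assigns each frame to TP (1), unfolded non-TP (0) or folded
    (2); folded frames are excluded from all nonnative ("nn") statistics.
    ``pairs`` holds the (i, j) residue indices of each contact column.
    """

    contact_formed: np.ndarray      # (n_frames, n_contacts) bool
    labels: np.ndarray              # (n_frames,) in {TP, UNFOLDED, FOLDED}
    pairs: np.ndarray               # (n_contacts, 2) int
    n_tp_segments: int = 0
    harvest: str = "folding"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.contact_formed = np.asarray(self.contact_formed, dtype=bool)
        self.labels = np.asarray(self.labels)
        self.pairs = np.asarray(self.pairs, dtype=int)

    @property
    def tp_frames(self) -> np.ndarray:
        return self.contact_formed[self.labels == TP]

    @property
    def nn_frames(self) -> np.ndarray:
        return self.contact_formed[self.labels != FOLDED]

    def p_q_given_tp(self) -> np.ndarray:
        tp = self.tp_frames
        if tp.shape[0] == 0:
            raise ValueError("ensemble contains no transition-path frames")
        return tp.mean(axis=0)

    def p_q_given_u(self) -> np.ndarray:
        u = self.contact_formed[self.labels == UNFOLDED]
        if u.shape[0] == 0:
            raise ValueError("ensemble contains no unfolded non-TP frames")
        return u.mean(axis=0)

    @classmethod
    def from_trajectory(cls, q, distances, r0, pairs, q_low=0.3, q_high=0.7,
                        harvest: str = "folding", lam: float = 1.2,
                        stop_at_first_fold: bool = True, **prov):
        """Label a single trajectory and collect its contact states.

        For a folding harvest, frames after the first folding event carry
        no nonnative information and are dropped when
        ``stop_at_first_fold`` (the trajectory portion up to the first time
        Q > q_high is used).
        """
        q = np.asarray(q, dtype=float)
        segs = extract_tps(q, q_low, q_high, direction=harvest)
        labels = np.full(q.size, UNFOLDED, dtype=int)
        labels[q > q_high] = FOLDED
        for a, b in segs:
            labels[a:b + 1] = TP
        formed = contact_states(distances, r0, lam)
        if harvest == "folding" and stop_at_first_fold:
            above = np.nonzero(q > q_high)[0]
            if above.size:
                stop = above[0] + 1
                labels = labels[:stop]
                formed = formed[:stop]
        return cls(formed, labels, pairs, n_tp_segments=len(segs),
                   harvest=harvest, provenance=prov)

    @staticmethod
    def merge(ensembles) -> "TPEnsemble":
        ensembles = list(ensembles)
        first = ensembles[0]
        return TPEnsemble(
            np.concatenate([e.contact_formed for e in ensembles]),
            np.concatenate([e.labels for e in ensembles]),
            first.pairs,
            n_tp_segments=sum(e.n_tp_segments for e in ensembles),
            harvest=first.harvest,
            provenance={"merged_from": len(ensembles)},
        )


def phi_values(ensemble: TPEnsemble, n_residues: int | None = None):
    """Per-residue phi(i): mean TP formation frequency of i's contacts.

    phi(i) = < p(q_ij | TP) > over the native contacts j of residue i.
    Residues without native contacts are reported as NaN (undefined), never
    zero-filled.
    """
    p_tp = ensemble.p_q_given_tp()
    pairs = ensemble.pairs
    if n_residues is None:
        n_residues = int(pairs.max()) + 1
    phi = np.full(n_residues, np.nan)
    for i in range(n_residues):
        mask = (pairs[:, 0] == i) | (pairs[:, 1] == i)
        if mask.any():
            phi[i] = p_tp[mask].mean()
    return phi


def p_tp_nn(t_tp: float, mfpt: float, harvest: str = "folding",
            p_u: float | None = None, p_f: float | None = None) -> float:
    """Fraction of nonnative time spent on transition paths.

    Folding harvest:    p(TP)_nn = 2 t_TP / (2 t_TP + t_F^mfpt)
    Unfolding harvest:  p(TP)_nn = 2 t_TP / (2 t_TP + (p_U/p_F) t_U^mfpt)

    where t_TP is the mean TP time and the MFPT is for folding (folding
    harvest) or unfolding (unfolding harvest; reweighted by the
    equilibrium populations from umbrella sampling).
    """
    if t_tp < 0 or mfpt <= 0:
        raise ValueError("times must be positive")
    if harvest == "folding":
        return 2 * t_tp / (2 * t_tp + mfpt)
    if harvest == "unfolding":
        if p_u is None or p_f is None:
            raise ValueError("unfolding harvest needs p_u and p_f")
        if p_f <= 0:
            raise ValueError("p_f must be positive for an unfolding harvest")
        return 2 * t_tp / (2 * t_tp + (p_u / p_f) * mfpt)
    raise ValueError("harvest must be 'folding' or 'unfolding'")


def p_tp_given_q(ensemble: TPEnsemble, ptp_nn: float,
                 pq_nn_mode: str | None = None):
    """Per-contact p(TP | q_ij)_nn by Bayes inversion.

    p(TP|q)_nn = p(q|TP) p(TP)_nn / p(q)_nn.  For a folding harvest the
    nonnative formation probability p(q)_nn is counted directly over the
    nonnative frames ("direct"); for an unfolding harvest the unfolded and
    TP frame sets do not occur in their equilibrium proportions, so
    p(q)_nn is reassembled as
    p(q|TP) p(TP)_nn + p(q|U) (1 - p(TP)_nn) ("reweighted").  Contacts
    never formed in nonnative frames are undefined (NaN); values pushed
    above 1 by sampling noise are clipped with a warning.
    """
    if pq_nn_mode is None:
        pq_nn_mode = "direct" if ensemble.harvest == "folding" else "reweighted"
    pq_tp = ensemble.p_q_given_tp()
    if pq_nn_mode == "direct":
        nn = ensemble.nn_frames
        pq_nn = nn.mean(axis=0)
    elif pq_nn_mode == "reweighted":
        pq_u = ensemble.p_q_given_u()
        pq_nn = pq_tp * ptp_nn + pq_u * (1.0 - ptp_nn)
    else:
        raise ValueError("pq_nn_mode must be 'direct' or 'reweighted'")
    out = np.full(pq_tp.shape, np.nan)
    ok = pq_nn > 0
    out[ok] = pq_tp[ok] * ptp_nn / pq_nn[ok]
    if np.any(out[ok] > 1.0):
        warnings.warn("p(TP|q)_nn exceeded 1 for some contacts "
                      "(sampling noise); clipped", stacklevel=2)
        out = np.clip(out, None, 1.0)
    return out


@dataclass
class PhiComparison:
    spearman_r: float        # NaN when < 3 surviving pairs
    pairs: pd.DataFrame      # residue, phi_sim, phi_exp, ddg


def compare_phi(phi_computed, reference: pd.DataFrame,
                ddg_filter_kj: float = 7.0) -> PhiComparison:
    """Rank-correlate computed phi-values against a reference table.

    ``reference`` needs columns (residue, phi_exp, ddg_kj); only mutations
    with |ddg| > ``ddg_filter_kj`` are retained, since phi-values from
    small stability changes are unreliable.  Spearman correlation is
    undefined (NaN) with fewer than 3 surviving pairs.
    """
    phi_computed = np.asarray(phi_computed, dtype=float)
    keep = reference[np.abs(reference["ddg_kj"]) > ddg_filter_kj].copy()
    res = keep["residue"].to_numpy(int)
    valid = (res >= 0) & (res < phi_computed.size)
    keep = keep[valid]
    res = res[valid]
    phi_sim = phi_computed[res]
    mask = ~np.isnan(phi_sim)
    table = pd.DataFrame({
        "residue": res[mask],
        "phi_sim": phi_sim[mask],
        "phi_exp": keep["phi_exp"].to_numpy(float)[mask],
        "ddg_kj": keep["ddg_kj"].to_numpy(float)[mask],
    })
    if len(table) < 3:
        return PhiComparison(float("nan"), table)
    r, _ = spearmanr(table["phi_sim"], table["phi_exp"])
    return PhiComparison(float(r), table)


@dataclass
class MechanismReport:
    phi: np.ndarray
    contacts: pd.DataFrame     # i, j, p_q_tp, p_q_nn, p_tp_q
    ptp_nn: float
    t_tp: float
    mfpt: float
    harvest: str

    def top_contacts(self, k: int = 10) -> pd.DataFrame:
        """Highest-p(TP|q)_nn contacts; ties broken by (i, j) order."""
        c = self.contacts.dropna(subset=["p_tp_q"])
        c = c.sort_values(["p_tp_q", "i", "j"],
                          ascending=[False, True, True], kind="mergesort")
        return c.head(k).reset_index(drop=True)


def mechanism_report(ensemble: TPEnsemble, t_tp: float, mfpt: float,
                     p_u: float | None = None, p_f: float | None = None,
                     n_residues: int | None = None) -> MechanismReport:
    """Assemble phi-values and contact-importance statistics in one report."""
    ptpnn = p_tp_nn(t_tp, mfpt, harvest=ensemble.harvest, p_u=p_u, p_f=p_f)
    phi = phi_values(ensemble, n_residues)
    pq_tp = ensemble.p_q_given_tp()
    ptpq = p_tp_given_q(ensemble, ptpnn)
    if ensemble.harvest == "folding":
        pq_nn = ensemble.nn_frames.mean(axis=0)
    else:
        pq_nn = pq_tp * ptpnn + ensemble.p_q_given_u() * (1 - ptpnn)
    contacts = pd.DataFrame({
        "i": ensemble.pairs[:, 0], "j": ensemble.pairs[:, 1],
        "p_q_tp": pq_tp, "p_q_nn": pq_nn, "p_tp_q": ptpq,
    })
    return MechanismReport(phi=phi, contacts=contacts, ptp_nn=ptpnn,
                           t_tp=t_tp, mfpt=mfpt, harvest=ensemble.harvest)
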