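"""Synthetic fixtures: toy foldable chains, toy exit tunnels, and
synthetic transition-path ensembles with known ground truth.

These stand in for the real inputs (an Ig-domain structure and a large
ribosomal subunit) so that the whole pipeline -- model building, Langevin
sampling, WHAM, kinetics and pathway statistics -- can be exercised and
validated offline at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pathway
from .model import NativeContactMap
from .structures import (BEAD_RADII, BeadModel, RibosomeScaffold,
                         TunnelAnnotation)

__all__ = [
    "make_toy_protein",
    "make_toy_tunnel",
    "make_toy_system",
    "TOY_PARAMS",
    "SyntheticTrajectorySpec",
    "make_synthetic_tp_ensemble",
]

# beta-strand zig-zag geometry: bond length 0.38 nm, backbone angle 120 deg
_BOND = 0.38
_DX = 0.3291   # advance per residue along the strand axis
_DZ = 0.1900   # zig-zag amplitude
_STRAND_SEP = 0.55  # inter-strand distance of the hairpin, nm


def _hairpin_coords(n: int) -> np.ndarray:
    m = n // 2
    pos = np.zeros((n, 3))
    for i in range(m):
        pos[i] = (i * _DX, 0.0, (i % 2) * _DZ)
    for j in range(n - m):
        k = m - 1 - j
        pos[m + j] = (k * _DX, _STRAND_SEP, (k % 2) * _DZ)
    return pos


def _helix_pair_coords(n: int) -> np.ndarray:
    m = n // 2
    omega = np.deg2rad(99.6)
    radius, rise, sep = 0.23, 0.15, 0.85
    pos = np.zeros((n, 3))
    for i in range(m):
        pos[i] = (radius * np.cos(i * omega), radius * np.sin(i * omega),
                  rise * i)
    top = rise * (m - 1)
    # second helix antiparallel, phased so its first bead faces helix 1
    # (keeps the inter-helix turn bond short)
    for j in range(n - m):
        pos[m + j] = (sep - radius * np.cos(j * omega),
                      -radius * np.sin(j * omega), top - rise * j)
    return pos


#: calibrated contact strengths / contact criteria per toy fold at 291 K
#: (chosen so the Q histogram is bimodal with both basins populated)
_FOLD_DEFAULTS = {
    "hairpin": {"contact_energy": 3.8, "contact_cutoff": 0.7,
                "min_seq_sep": 4},
    "helix-pair": {"contact_energy": 5.0, "contact_cutoff": 0.75,
                   "min_seq_sep": 6},
}


def make_toy_protein(n_residues: int = 16, fold: str = "hairpin",
                     contact_energy: float | None = None, seed: int = 1,
                     contact_cutoff: float | None = None,
                     min_seq_sep: int | None = None,
                     jitter: float = 0.01):
    """A compact two-state toy chain with a defined native contact map.

    Returns ``(beads, contact_map)``: a mobile bead chain in its native
    geometry (a beta-hairpin or a packed helix pair) plus the contact map
    found by a brute-force all-pairs distance scan (pairs closer than
    ``contact_cutoff`` nm at sequence separation >= ``min_seq_sep``), with
    uniform well depth ``contact_energy`` kJ/mol.  A small seeded jitter
    breaks exact geometric degeneracies; output is bit-reproducible for a
    fixed seed.
    """
    if n_residues < 10:
        raise ValueError("toy protein needs at least 10 residues")
    if fold not in _FOLD_DEFAULTS:
        raise ValueError("fold must be 'hairpin' or 'helix-pair'")
    dflt = _FOLD_DEFAULTS[fold]
    contact_energy = (dflt["contact_energy"] if contact_energy is None
                      else contact_energy)
    contact_cutoff = (dflt["contact_cutoff"] if contact_cutoff is None
                      else contact_cutoff)
    min_seq_sep = dflt["min_seq_sep"] if min_seq_sep is None else min_seq_sep
    if fold == "hairpin":
        pos = _hairpin_coords(n_residues)
    elif fold == "helix-pair":
        pos = _helix_pair_coords(n_residues)
    rng = np.random.default_rng(seed)
    pos = pos + jitter * rng.standard_normal(pos.shape)
    pairs, r0 = [], []
    for i in range(n_residues):
        for j in range(i + min_seq_sep, n_residues):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < contact_cutoff:
                pairs.append((i, j))
                r0.append(d)
    cmap = NativeContactMap(np.array(pairs, int).reshape(-1, 2),
                            np.array(r0),
                            eps=np.full(len(pairs), float(contact_energy)),
                            min_separation=min_seq_sep,
                            criterion="toy-distance-scan")
    beads = BeadModel(
        kind=np.array(["protein-CA"] * n_residues, dtype=object),
        res_id=np.arange(1, n_residues + 1),
        chain_id=np.array(["TOY"] * n_residues, dtype=object),
        position=pos,
        radius=np.full(n_residues, BEAD_RADII["protein-CA"]),
        mobile=np.ones(n_residues, dtype=bool),
    )
    return beads, cmap


def make_toy_tunnel(length: float = 6.0, radius: float = 0.5,
                    bead_spacing: float = 0.45, n_shells: int = 1,
                    shell_gap: float = 0.22,
                    cap: bool = True) -> RibosomeScaffold:
    """A cylindrical exit-tunnel scaffold of immobile repulsive beads.

    The tunnel axis runs along +x from the buried end (the anchor bead, a
    stand-in for the A-site tRNA P atom, at the origin) to the open exit at
    ``(length, 0, 0)``.  Wall beads sit on ``n_shells`` concentric shells
    starting at ``radius``; the soft excluded volume is shallow, so more
    than one staggered shell is needed to make the wall effectively
    impenetrable in long runs.  A bead disk caps the buried end; the exit
    end is open.
    """
    if length <= 0 or radius <= 0 or bead_spacing <= 0:
        raise ValueError("length, radius and bead_spacing must be positive")
    kinds, chains, pos = [], [], []

    def add(p, role):
        kinds.append("protein-CA")
        chains.append(role)
        pos.append(p)

    add((0.0, 0.0, 0.0), "ANCHOR")
    n_rings = int(np.floor(length / bead_spacing)) + 1
    for s in range(n_shells):
        r = radius + s * shell_gap
        n_ring = max(6, int(np.ceil(2 * np.pi * r / bead_spacing)))
        stagger = (s % 2) * 0.5
        for k in range(n_rings):
            x = k * bead_spacing + (s % 2) * 0.5 * bead_spacing
            if x > length:
                continue
            phase = 2 * np.pi * (stagger + (k % 2) * 0.5) / n_ring
            for a in range(n_ring):
                ang = 2 * np.pi * a / n_ring + phase
                add((x, r * np.cos(ang), r * np.sin(ang)), "WALL")
    if cap:
        # disk at the buried end, just behind the anchor
        rr = bead_spacing
        while rr < radius + (n_shells - 1) * shell_gap + 1e-9:
            n_ring = max(6, int(np.ceil(2 * np.pi * rr / bead_spacing)))
            for a in range(n_ring):
                ang = 2 * np.pi * a / n_ring
                add((-bead_spacing, rr * np.cos(ang), rr * np.sin(ang)),
                    "CAP")
            rr += bead_spacing
        add((-bead_spacing, 0.0, 0.0), "CAP")
    n = len(pos)
    beads = BeadModel(
        kind=np.array(kinds, dtype=object),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(chains, dtype=object),
        position=np.array(pos, dtype=float),
        radius=np.full(n, BEAD_RADII["protein-CA"]),
        mobile=np.zeros(n, dtype=bool),
    )
    tunnel = TunnelAnnotation(start=np.zeros(3),
                              exit=np.array([length, 0.0, 0.0]))
    return RibosomeScaffold(beads, anchor=0, tunnel=tunnel)


#: calibrated two-state parameters of the toy chain at 291 K: contact wells
#: of 3.8 kJ/mol plus a many-body cooperativity of 80 kJ/mol give a bimodal
#: Q distribution with both basins populated and regular barrier crossings
TOY_PARAMS = None  # set below, after GoParameters import resolves


def make_toy_system(n_residues: int = 16, fold: str = "hairpin",
                    scaffold: RibosomeScaffold | None = None,
                    L: int | None = None, seed: int = 1,
                    params=None):
    """Convenience builder: toy protein -> ready-to-run CGSystem.

    With a scaffold and a linker length ``L``, the domain is wired to the
    toy tunnel exactly as the real construct is to the ribosome: linker
    appended C-terminally, chain end tethered to the anchor bead.
    """
    from .model import attach_linker_and_tether, build_go_system

    from .model import GoParameters

    if params is None:
        d = _FOLD_DEFAULTS[fold]
        params = GoParameters(eps_contact=d["contact_energy"],
                              coop_strength=80.0,
                              min_seq_sep=d["min_seq_sep"])
    beads, cmap = make_toy_protein(n_residues, fold,
                                   contact_energy=params.eps_contact,
                                   seed=seed)
    system = build_go_system(beads, cmap, scaffold=scaffold, params=params)
    if fold == "helix-pair":
        # rigid helices, flexible inter-helix hinge: the docking interface
        # is then only satisfiable by the true side-by-side geometry, which
        # is what a confining tunnel must exclude
        m = n_residues // 2
        span_a = ((system.angles < m).any(axis=1)
                  & (system.angles >= m).any(axis=1))
        span_d = ((system.dihedrals < m).any(axis=1)
                  & (system.dihedrals >= m).any(axis=1))
        system.angle_k = np.where(span_a, 5.0, 80.0)
        system.dihedral_k = np.where(span_d, 0.0, 8.0)
    if L is not None:
        system = attach_linker_and_tether(system, L)
    return system


@dataclass
class SyntheticTrajectorySpec:
    """Ground-truth specification of a synthetic transition-path ensemble.

    Frames are labeled TP or unfolded; contact k is formed independently
    with probability ``p_tp[k]`` on TP frames and ``p_nontp[k]`` on
    unfolded (nonnative, non-TP) frames.  The TP frames amount to a
    fraction ``ptp_nn`` of all frames and come in contiguous segments of
    ``tp_segment_len``.  The empirical frequencies of the generated
    ensemble converge to these values as n_frames grows.
    """

    n_contacts: int
    p_tp: np.ndarray
    p_nontp: np.ndarray
    ptp_nn: float = 0.1
    n_frames: int = 20000
    tp_segment_len: int = 20
    seed: int = 0
    pairs: np.ndarray | None = None

    def __post_init__(self):
        self.p_tp = np.broadcast_to(
            np.asarray(self.p_tp, float), (self.n_contacts,)).copy()
        self.p_nontp = np.broadcast_to(
            np.asarray(self.p_nontp, float), (self.n_contacts,)).copy()
        for name, p in (("p_tp", self.p_tp), ("p_nontp", self.p_nontp)):
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.ptp_nn <= 1:
            raise ValueError("ptp_nn must lie in [0, 1]")
        if self.pairs is None:
            # chain-like pairs at the minimum sequence separation
            self.pairs = np.column_stack([
                np.arange(self.n_contacts),
                np.arange(self.n_contacts) + 4])
        self.pairs = np.asarray(self.pairs, dtype=int)

    # analytic values the estimators must recover
    def true_pq_nn(self) -> np.ndarray:
        return self.ptp_nn * self.p_tp + (1 - self.ptp_nn) * self.p_nontp

    def true_p_tp_given_q(self) -> np.ndarray:
        pq_nn = self.true_pq_nn()
        out = np.full(self.n_contacts, np.nan)
        ok = pq_nn > 0
        out[ok] = self.p_tp[ok] * self.ptp_nn / pq_nn[ok]
        return out

    def true_phi(self, n_residues: int | None = None) -> np.ndarray:
        if n_residues is None:
            n_residues = int(self.pairs.max()) + 1
        phi = np.full(n_residues, np.nan)
        for i in range(n_residues):
            m = (self.pairs[:, 0] == i) | (self.pairs[:, 1] == i)
            if m.any():
                phi[i] = self.p_tp[m].mean()
        return phi


def make_synthetic_tp_ensemble(spec: SyntheticTrajectorySpec):
    """Generate a labeled ensemble from a SyntheticTrajectorySpec.

    Returns a ``pathway.TPEnsemble`` whose empirical statistics converge
    to the spec's analytic ground truth (binomial sampling error).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n_tp = int(round(spec.ptp_nn * n))
    labels = np.full(n, pathway.UNFOLDED, dtype=int)
    # contiguous TP segments spread evenly through the trajectory
    n_seg = max(1, n_tp // spec.tp_segment_len) if n_tp else 0
    placed = 0
    for s in range(n_seg):
        seg_len = (n_tp - placed) // (n_seg - s)
        start = int(np.floor(s * n / max(n_seg, 1)))
        labels[start:start + seg_len] = pathway.TP
        placed += seg_len
    p = np.where((labels == pathway.TP)[:, None], spec.p_tp[None, :],
                 spec.p_nontp[None, :])
    formed = rng.random((n, spec.n_contacts)) < p
    return pathway.TPEnsemble(
        contact_formed=formed, labels=labels, pairs=spec.pairs,
        n_tp_segments=n_seg, harvest="folding",
        provenance={"synthetic": True, "seed": spec.seed},
    )


def _init_toy_params():
    from .model import GoParameters
    return GoParameters(eps_contact=3.8, coop_strength=80.0)


TOY_PARAMS = _init_toy_params()
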