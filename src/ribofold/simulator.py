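"""Langevin dynamics, the reaction coordinate Q, and umbrella sampling.

The trajectory is propagated with a BAOAB-split Langevin integrator at
friction 0.1 ps^-1 and a 10 fs time step (defaults); all chain bonds are
constrained by iterative projection, the force-reporting tether being the
single unconstrained bond.  The folding coordinate is the smooth fraction
of native contacts

    Q = (1/N) sum_ij 1 / (1 + exp[gamma (r_ij - lam r_ij^0)])

with gamma = 50 nm^-1 and lam = 1.2.  Umbrella sampling applies a harmonic
bias k_umb (Q - Q0)^2 / 2 in windows spanning [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .model import CGSystem, NativeContactMap
from .units import KB, KJ_PER_KCAL, PN_PER_KJ_MOL_NM

__all__ = [
    "QParameters",
    "TrajectoryRecord",
    "UmbrellaWindow",
    "compute_Q",
    "step_langevin",
    "run_trajectory",
    "run_umbrella",
    "extended_configuration",
    "folded_configuration",
]

#: default umbrella force constant, 600 kcal/mol in kJ/mol
K_UMB_DEFAULT = 600.0 * KJ_PER_KCAL


@dataclass(frozen=True)
class QParameters:
    """Switching-function parameters of the smooth Q."""

    gamma: float = 50.0     # steepness, nm^-1
    lam: float = 1.2        # fluctuation allowance on the native distance
    contacts: NativeContactMap | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.lam < 1.0:
            raise ValueError("lam must be >= 1")


def compute_Q(positions, qparams: QParameters):
    """Smooth fraction of native contacts of one or more configurations.

    ``positions`` is (n_beads, 3) or (n_frames, n_beads, 3) in nm;
    ``qparams.contacts`` supplies the native pairs and distances.
    """
    cmap = qparams.contacts
    if cmap is None or len(cmap) == 0:
        raise ValueError("compute_Q needs a non-empty native contact map")
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    d = np.linalg.norm(pos[:, cmap.pairs[:, 0]] - pos[:, cmap.pairs[:, 1]],
                       axis=-1)
    q = 1.0 / (1.0 + np.exp(qparams.gamma * (d - qparams.lam * cmap.r0)))
    q = q.mean(axis=1)
    return float(q[0]) if single else q


@dataclass
class TrajectoryRecord:
    """Reduced-observable time series with full provenance metadata."""

    time: np.ndarray          # ps
    q: np.ndarray
    x: np.ndarray             # tether extension, nm
    force_pn: np.ndarray      # pulling force, pN; positive when x > x0
    energy: np.ndarray        # total (potential + kinetic), kJ/mol
    metadata: dict = field(default_factory=dict)
    positions: np.ndarray | None = None   # (n_frames, n, 3) when saved
    final_positions: np.ndarray | None = None
    final_velocities: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self):
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ps": self.time, "Q": self.q, "x_nm": self.x,
                             "F_pN": self.force_pn})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class UmbrellaWindow:
    """Samples of one umbrella window biased at Q0 = ``center``."""

    center: float
    k_umb: float              # kJ/mol
    q: np.ndarray
    force_pn: np.ndarray
    temperature: float
    metadata: dict = field(default_factory=dict)

    def bias_energy(self, q=None) -> np.ndarray:
        q = self.q if q is None else np.asarray(q, float)
        return 0.5 * self.k_umb * (q - self.center) ** 2


_EMPTY = {
    "i2": np.zeros((0, 2), dtype=np.int64),
    "i3": np.zeros((0, 3), dtype=np.int64),
    "i4": np.zeros((0, 4), dtype=np.int64),
    "f": np.zeros(0, dtype=np.float64),
}


def _build_cell_list(sc_pos, cutoff):
    if len(sc_pos) == 0:
        return (np.zeros(3), 1.0, np.ones(3, dtype=np.int64),
                np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
                np.zeros(0, dtype=np.int64))
    origin = sc_pos.min(axis=0) - cutoff
    upper = sc_pos.max(axis=0) + cutoff
    dims = np.maximum(np.floor((upper - origin) / cutoff).astype(np.int64) + 1,
                      1)
    idx = np.floor((sc_pos - origin) / cutoff).astype(np.int64)
    idx = np.minimum(np.maximum(idx, 0), dims - 1)
    flat = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    ncell = int(np.prod(dims))
    start = np.zeros(ncell, dtype=np.int64)
    count = np.zeros(ncell, dtype=np.int64)
    sorted_flat = flat[order]
    uniq, first, cnt = np.unique(sorted_flat, return_index=True,
                                 return_counts=True)
    start[uniq] = first
    count[uniq] = cnt
    return origin.astype(float), float(cutoff), dims, start, count, order


class _Packed:
    """Kernel-ready array bundle for one CGSystem."""

    def __init__(self, system: CGSystem):
        p = system.params
        self.system = system
        self.mass = np.full(system.n_mobile, p.mass, dtype=float)
        self.ang_idx = (system.angles.astype(np.int64)
                        if len(system.angles) else _EMPTY["i3"])
        self.theta0 = np.asarray(system.theta0, float)
        self.k_ang = (np.asarray(system.angle_k, float).copy()
                      if system.angle_k is not None
                      else np.full(len(self.theta0), p.k_angle))
        self.dih_idx = (system.dihedrals.astype(np.int64)
                        if len(system.dihedrals) else _EMPTY["i4"])
        self.phi0 = np.asarray(system.phi0, float)
        self.k_dih = (np.asarray(system.dihedral_k, float).copy()
                      if system.dihedral_k is not None
                      else np.full(len(self.phi0), p.k_dihedral_eff))
        cm = system.contacts
        self.con_idx = (cm.pairs.astype(np.int64) if len(cm)
                        else _EMPTY["i2"])
        self.con_r0 = np.asarray(cm.r0, float)
        self.con_eps = (np.asarray(cm.eps, float) if cm.eps is not None
                        else np.zeros(len(cm)))
        self.rep_idx = (system.rep_pairs.astype(np.int64)
                        if len(system.rep_pairs) else _EMPTY["i2"])
        self.rep_sig = np.asarray(system.rep_sigma, float)
        self.eps_rep = float(p.eps_repulsive)
        if system.scaffold is not None:
            sc = system.scaffold.beads
            self.sc_pos = np.asarray(sc.position, float)
            sig = 0.5 * (np.asarray(system.beads.radius, float)[:, None]
                         + np.asarray(sc.radius, float)[None, :])
            self.sc_sig_row = np.ascontiguousarray(sig.ravel())
            cutoff = _kernels.REP_CUTOFF_FACTOR * float(sig.max())
            (self.grid_origin, self.grid_cell, self.grid_dims,
             self.cell_start, self.cell_count,
             self.cell_beads) = _build_cell_list(self.sc_pos, cutoff)
        else:
            self.sc_pos = np.zeros((0, 3))
            self.sc_sig_row = _EMPTY["f"]
            (self.grid_origin, self.grid_cell, self.grid_dims,
             self.cell_start, self.cell_count,
             self.cell_beads) = _build_cell_list(self.sc_pos, 1.0)
        self.hp_idx = (system.hp_pairs.astype(np.int64)
                       if len(system.hp_pairs) else _EMPTY["i2"])
        self.hp_sigma = float(p.sigma_hp)
        self.hp_eps = float(p.eps_hp)
        if system.tether is not None:
            self.teth_i = int(system.tether.end_bead)
            self.ks = float(system.tether.ks)
            self.x0 = float(system.tether.x0)
            self.anchor = np.asarray(system.anchor_xyz(), float)
        else:
            self.teth_i = -1
            self.ks = 0.0
            self.x0 = 0.0
            self.anchor = np.zeros(3)
        self.cons_idx = (system.bonds.astype(np.int64)
                         if len(system.bonds) else _EMPTY["i2"])
        self.cons_r0 = np.asarray(system.bond_r0, float)

    def force_args(self, q_gamma, q_lam, k_umb, q0):
        return (self.ang_idx, self.theta0, self.k_ang,
                self.dih_idx, self.phi0, self.k_dih,
                self.con_idx, self.con_r0, self.con_eps,
                self.rep_idx, self.rep_sig, self.eps_rep,
                self.sc_pos, self.sc_sig_row, self.grid_origin,
                self.grid_cell, self.grid_dims,
                self.cell_start, self.cell_count, self.cell_beads,
                self.hp_idx, self.hp_sigma, self.hp_eps,
                self.teth_i, self.anchor, self.ks, self.x0,
                float(q_gamma), float(q_lam), float(k_umb), float(q0),
                -float(self.system.params.coop_strength),
                float(self.system.params.coop_center))


def pack_system(system: CGSystem) -> _Packed:
    return _Packed(system)


def potential_energy_and_forces(system: CGSystem, positions,
                                qparams: QParameters = QParameters(),
                                bias=None):
    """Potential energy, forces (-grad V), Q and tether extension."""
    packed = pack_system(system)
    pos = np.ascontiguousarray(positions, dtype=float)
    frc = np.zeros_like(pos)
    k_umb, q0 = bias if bias is not None else (0.0, 0.0)
    epot, q, x = _kernels._forces(
        pos, frc, *packed.force_args(qparams.gamma, qparams.lam, k_umb, q0))
    return epot, frc, q, x


def _load_axis(system: CGSystem) -> np.ndarray:
    """Unit vector along which the nascent chain pulls on the tether."""
    if system.scaffold is not None:
        return system.scaffold.tunnel.axis
    anchor = system.anchor_xyz()
    v = system.positions[-1] - anchor
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])


class DivergenceError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""

    def __init__(self, step, positions):
        self.positions = positions
        super().__init__(
            f"non-finite coordinates after step {step}; last frame attached")


def run_trajectory(system: CGSystem, n_steps: int, dt: float = 0.01,
                   friction: float = 0.1, temperature: float | None = None,
                   stride: int = 100, seed: int = 0, bias=None,
                   start=None, velocities=None, save_positions: bool = False,
                   qparams: QParameters | None = None,
                   constraint_tol: float = 1e-8) -> TrajectoryRecord:
    """Propagate Langevin dynamics and record reduced observables.

    ``bias`` is an optional (k_umb, Q0) umbrella restraint on Q.  Initial
    positions default to the system's native coordinates; initial
    velocities are drawn from the Maxwell-Boltzmann distribution with the
    given seed, so a (system, seed) pair reruns bit-identically.
    """
    if temperature is None:
        temperature = system.params.temperature
    if qparams is None:
        qparams = QParameters(contacts=system.contacts)
    packed = pack_system(system)
    pos = np.ascontiguousarray(
        system.positions.copy() if start is None else np.array(start, float))
    rng = np.random.default_rng(seed)
    if velocities is None:
        sd = np.sqrt(KB * temperature / packed.mass)
        vel = rng.standard_normal(pos.shape) * sd[:, None]
    else:
        vel = np.array(velocities, dtype=float)
    k_umb, q0 = bias if bias is not None else (0.0, 0.0)
    n_rec = n_steps // stride
    rec_t = np.zeros(n_rec)
    rec_q = np.zeros(n_rec)
    rec_x = np.zeros(n_rec)
    rec_dx = np.zeros((n_rec, 3))
    rec_e = np.zeros(n_rec)
    rec_pos = (np.zeros((n_rec, pos.shape[0], 3)) if save_positions
               else np.zeros((0, pos.shape[0], 3)))
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    nrec = _kernels.run_md(
        pos, vel, packed.mass, float(dt), float(friction),
        KB * float(temperature), int(n_steps), int(stride), kernel_seed,
        *packed.force_args(qparams.gamma, qparams.lam, k_umb, q0),
        packed.cons_idx, packed.cons_r0, float(constraint_tol),
        rec_t, rec_q, rec_x, rec_dx, rec_e, save_positions, rec_pos)
    if nrec < 0:
        raise DivergenceError(n_steps, pos)
    if packed.teth_i >= 0:
        # tension transmitted along the load axis: project the per-frame
        # spring-force vector ks (x - x0) dhat onto the pulling direction,
        # so an isotropically fluctuating slack bond averages to zero force
        axis = _load_axis(system)
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = (rec_dx @ axis) / np.where(rec_x > 0, rec_x, 1.0)
        force_pn = packed.ks * (rec_x - packed.x0) * proj * PN_PER_KJ_MOL_NM
    else:
        force_pn = np.zeros(n_rec)
    return TrajectoryRecord(
        time=rec_t[:nrec], q=rec_q[:nrec], x=rec_x[:nrec],
        force_pn=force_pn[:nrec], energy=rec_e[:nrec],
        metadata={
            "seed": seed, "dt": dt, "friction": friction,
            "temperature": temperature, "stride": stride,
            "bias": None if bias is None else
            {"k_umb": k_umb, "q0": q0},
            "n_steps": n_steps,
        },
        positions=rec_pos[:nrec] if save_positions else None,
        final_positions=pos, final_velocities=vel)


def step_langevin(system: CGSystem, positions, velocities, dt: float = 0.01,
                  friction: float = 0.1, temperature: float | None = None,
                  seed: int = 0, bias=None, n_steps: int = 1):
    """Advance the state by ``n_steps`` integration steps.

    Returns (positions, velocities).  Immobile scaffold beads are not part
    of the integrated state and never move.
    """
    rec = run_trajectory(system, n_steps=n_steps, dt=dt, friction=friction,
                         temperature=temperature, stride=max(n_steps, 1),
                         seed=seed, bias=bias, start=positions,
                         velocities=velocities)
    return rec.final_positions, rec.final_velocities


def minimize_positions(system: CGSystem, positions, n_iter: int = 500,
                       max_disp: float = 0.01,
                       qparams: QParameters | None = None):
    """Relax clashes by displacement-capped steepest descent."""
    if qparams is None:
        qparams = QParameters(contacts=system.contacts)
    packed = pack_system(system)
    pos = np.ascontiguousarray(np.array(positions, dtype=float))
    _kernels.minimize(pos, packed.mass, int(n_iter), float(max_disp),
                      *packed.force_args(qparams.gamma, qparams.lam, 0.0, 0.0),
                      packed.cons_idx, packed.cons_r0, 1e-8)
    return pos


def _zigzag_offsets(k):
    """Alternating transverse offset giving 0.38 nm bonds at 120 deg."""
    return 0.095 * (-1.0) ** k


def extended_configuration(system: CGSystem) -> np.ndarray:
    """Fully extended chain; threaded along the tunnel axis when arrested.

    The chain leaves the anchor along the tunnel axis in a shallow zig-zag
    (so backbone angles are regular, not collinear) and continues out of
    the exit; without a scaffold it extends along +x from the anchor point
    (or the origin for untethered systems).
    """
    n = system.n_mobile
    if system.scaffold is not None:
        origin = system.scaffold.anchor_position
        axis = system.scaffold.tunnel.axis
    else:
        origin = (system.anchor_point if system.anchor_point is not None
                  else np.zeros(3))
        axis = np.array([1.0, 0.0, 0.0])
    perp = np.array([0.0, 1.0, 0.0])
    if abs(axis @ perp) > 0.9:
        perp = np.array([0.0, 0.0, 1.0])
    perp = perp - (perp @ axis) * axis
    perp /= np.linalg.norm(perp)
    x0 = system.tether.x0 if system.tether is not None else 0.38
    pos = np.zeros((n, 3))
    for m in range(n):
        k = n - 1 - m          # chain-end bead sits nearest the anchor
        d = x0 + 0.329 * k     # bond 0.38 nm with the +-0.095 nm zig-zag
        pos[m] = origin + axis * d + perp * _zigzag_offsets(k)
    return pos


def folded_configuration(system: CGSystem) -> np.ndarray:
    """Native domain placed outside the exit, linker threading the tunnel.

    The domain is rigidly rotated so its C terminus points back toward the
    exit and translated so the C-terminal bead sits one bond length outside
    it; linker beads run along the axis toward the anchor.  When the linker
    is too short to reach, the tether starts stretched (the physically
    relevant high-force regime); a short minimization then relaxes clashes.
    """
    nd = system.n_domain
    n = system.n_mobile
    native = system.positions[:nd].copy()
    if system.scaffold is None:
        return system.positions.copy()
    tun = system.scaffold.tunnel
    axis = tun.axis
    anchor = system.scaffold.anchor_position
    cterm = native[nd - 1]
    centroid = native.mean(axis=0)
    v = centroid - cterm
    vn = np.linalg.norm(v)
    v = v / vn if vn > 1e-9 else axis
    rot = _rotation_between(v, axis)
    native = (native - cterm) @ rot.T
    exit_pos = tun.exit + axis * 0.2
    native = native + exit_pos
    pos = np.zeros((n, 3))
    pos[:nd] = native
    L = n - nd
    if L > 0:
        gap = np.linalg.norm(exit_pos - anchor)
        spacing = min(0.329, max(0.1, (gap - system.tether.x0) / L))
        amp = np.sqrt(max(0.38 ** 2 - spacing ** 2, 1e-4)) / 2.0
        perp = np.array([0.0, 1.0, 0.0])
        if abs(axis @ perp) > 0.9:
            perp = np.array([0.0, 0.0, 1.0])
        perp = perp - (perp @ axis) * axis
        perp /= np.linalg.norm(perp)
        for j in range(L):
            # linker bead nd+j, chain distance j+1 from the domain C-term
            d = np.linalg.norm(exit_pos - anchor) - spacing * (j + 1)
            pos[nd + j] = anchor + axis * max(d, 0.05) \
                + perp * amp * ((-1.0) ** j + 1.0) / 2.0
    return pos


def _rotation_between(a, b):
    """Rotation matrix sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def run_umbrella(system: CGSystem, centers=None, k_umb: float = K_UMB_DEFAULT,
                 steps_per_window: int = 20000, equil_steps: int = 4000,
                 dt: float = 0.01, friction: float = 0.1,
                 temperature: float | None = None, stride: int = 50,
                 seed: int = 0, min_overlap: float = 0.02):
    """Umbrella sampling along Q, one window per bias center.

    Default 16 centers evenly spaced on [0, 1] with k_umb = 600 kcal/mol.
    Windows are seeded sequentially from the native basin downward (each
    window starts from the previous window's final frame), which keeps
    adjacent histograms overlapping.  Adjacent windows sharing less than
    ``min_overlap`` histogram mass trigger a warning.
    """
    from .equilibrium import check_window_overlap

    if centers is None:
        centers = np.linspace(0.0, 1.0, 16)
    centers = np.sort(np.asarray(centers, dtype=float))[::-1]  # high Q first
    if temperature is None:
        temperature = system.params.temperature
    if system.scaffold is not None:
        start = folded_configuration(system)
        if system.tether is not None:
            # a linker too short to let the folded domain sit outside
            # leaves the tether stretched by nanometers; such a start is
            # mechanically violent, so begin from the threaded extended
            # chain instead and let the bias pull each window into place
            x = np.linalg.norm(start[system.tether.end_bead]
                               - system.anchor_xyz())
            if x - system.tether.x0 > 0.5:
                start = extended_configuration(system)
    else:
        start = system.positions.copy()
    start = minimize_positions(system, start, n_iter=500)
    windows = []
    vel = None
    for w, q0 in enumerate(centers):
        rec = run_trajectory(
            system, n_steps=equil_steps + steps_per_window, dt=dt,
            friction=friction, temperature=temperature, stride=stride,
            seed=seed + 1000 * w, bias=(k_umb, float(q0)), start=start,
            velocities=vel)
        n_equil_rec = equil_steps // stride
        windows.append(UmbrellaWindow(
            center=float(q0), k_umb=float(k_umb),
            q=rec.q[n_equil_rec:], force_pn=rec.force_pn[n_equil_rec:],
            temperature=float(temperature),
            metadata={**rec.metadata, "equil_steps": equil_steps}))
        start = rec.final_positions
        vel = rec.final_velocities
    windows = windows[::-1]
    check_window_overlap(windows, min_overlap=min_overlap)
    return windows
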