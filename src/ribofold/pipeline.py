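"""End-to-end pipeline: build -> umbrella per L -> WHAM -> rates -> f_FL.

Reproduces the per-variant workflow of a force-profile study: build the
coarse-grained system for each linker length, sample its arrested
equilibrium by umbrella sampling, reweight with WHAM into folded/unfolded
populations and state-conditioned tether forces, estimate folding and
unfolding rates from direct first-passage simulations, rescale them to
experimental units, and predict the fraction full-length protein per L by
both kinetic solvers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import summarize_per_L, summaries_to_frame, EquilibriumSummary
from .fixtures import make_toy_system, make_toy_tunnel
from .kinetics import (BellParameters, assemble_profile, mfpt_censored,
                       scale_rates)
from .model import (CGSystem, add_hydrophobic_surface_attraction,
                    weaken_residue_contacts)
from .simulator import (extended_configuration, folded_configuration,
                        minimize_positions, run_trajectory, run_umbrella)

__all__ = ["PipelineConfig", "run_pipeline", "variant_apply"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    # system
    structure: str = "toy"            # "toy" or a path to a PDB/mmCIF file
    fold: str = "helix-pair"
    n_residues: int = 20
    tunnel_length: float = 6.0
    tunnel_radius: float = 0.55
    tunnel_spacing: float = 0.22
    tunnel_shells: int = 2
    L_grid: tuple = (10, 14, 18, 22, 26, 30)
    variant: dict = field(default_factory=lambda: {"kind": "wild-type"})
    # sampling
    dt: float = 0.01
    friction: float = 0.1
    temperature: float = 291.0
    umbrella_steps: int = 20000
    umbrella_equil: int = 5000
    umbrella_stride: int = 50
    n_windows: int = 16
    rate_runs: int = 2
    rate_steps: int = 100000
    # kinetics
    bell: BellParameters = field(default_factory=BellParameters)
    k_u_iso_exp: float = 4.9e-4       # s^-1, isolated-domain unfolding rate
    incubation_s: float = 900.0       # 15-min incubation; 1800 for 30 min
    kmc_replicas: int = 1500
    # bookkeeping
    seed: int = 1
    outdir: str = "ribofold_run"
    resume: bool = True

    def __post_init__(self):
        if len(self.L_grid) < 1 or min(self.L_grid) < 1:
            raise ValueError("L_grid must contain linker lengths >= 1")
        if self.incubation_s <= 0 or self.kmc_replicas < 1:
            raise ValueError("invalid kinetics settings")
        if self.variant.get("kind") not in (
                "wild-type", "weaken", "delete-segment",
                "hydrophobic-surface"):
            raise ValueError(f"unknown variant: {self.variant}")

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["bell"] = dataclasses.asdict(self.bell)
        return json.dumps(doc, indent=1, default=list)


def variant_apply(config: PipelineConfig, system: CGSystem) -> CGSystem:
    """Apply the configured variant to a built system.

    * wild-type: identity
    * weaken(residue, factor): scale the residue's native contacts
    * delete-segment(n_terminal): drop the first n residues (an
      N-terminal-strand deletion), pruning the contact map
    * hydrophobic-surface(surface_beads, protein_residues): add 12-6
      attractions to ribosome surface beads
    """
    kind = config.variant.get("kind", "wild-type")
    if kind == "wild-type":
        return system
    if kind == "weaken":
        return weaken_residue_contacts(system, int(config.variant["residue"]),
                                       float(config.variant["factor"]))
    if kind == "delete-segment":
        return _delete_n_terminal(system, int(config.variant["n_terminal"]))
    if kind == "hydrophobic-surface":
        return add_hydrophobic_surface_attraction(
            system, config.variant["surface_beads"],
            config.variant["protein_residues"],
            sigma_hp=config.variant.get("sigma_hp"),
            eps_hp=config.variant.get("eps_hp"))
    raise ValueError(f"unknown variant kind: {kind}")


def _delete_n_terminal(system: CGSystem, n_del: int) -> CGSystem:
    """Remove the first ``n_del`` domain residues, pruning all terms."""
    from .model import NativeContactMap, build_go_system
    from .structures import BeadModel

    if system.linker_length:
        raise ValueError("apply deletions before attaching the linker")
    if system.n_domain - n_del < 10:
        raise ValueError("deletion would leave fewer than 10 residues")
    keep = slice(n_del, system.n_domain)
    b = system.beads
    beads = BeadModel(b.kind[keep], b.res_id[keep], b.chain_id[keep],
                      b.position[keep], b.radius[keep], b.mobile[keep])
    cm = system.contacts
    mask = (cm.pairs[:, 0] >= n_del) & (cm.pairs[:, 1] >= n_del)
    cmap = NativeContactMap(cm.pairs[mask] - n_del, cm.r0[mask],
                            None if cm.eps is None else cm.eps[mask],
                            cm.min_separation, cm.criterion)
    out = build_go_system(beads, cmap, scaffold=system.scaffold,
                          params=system.params)
    out.provenance = {**system.provenance, "deleted_n_terminal": n_del}
    return out


def _build_system(config: PipelineConfig, L: int | None) -> CGSystem:
    if config.structure != "toy":
        raise NotImplementedError(
            "file-based structures are wired through the library API "
            "(read_structure/coarse_grain/build_go_system); the driver "
            "currently orchestrates the toy family")
    scaffold = make_toy_tunnel(config.tunnel_length, config.tunnel_radius,
                               config.tunnel_spacing,
                               n_shells=config.tunnel_shells)
    system = make_toy_system(config.n_residues, config.fold,
                             scaffold=scaffold)
    system = variant_apply(config, system)
    if L is not None:
        from .model import attach_linker_and_tether
        system = attach_linker_and_tether(system, L)
    return system


def _stage_path(outdir: Path, name: str) -> Path:
    return outdir / name


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run (or resume) every stage; returns a results dict.

    Stage outputs are TSV files under ``config.outdir`` plus a JSON
    manifest recording the configuration, seeds and output hashes.  With
    ``resume=True`` a stage whose output file already exists is loaded
    instead of recomputed, so deleting an intermediate file recomputes only
    that stage and everything downstream of it.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}

    # stage 1: equilibrium (umbrella + WHAM) per L
    eq_path = _stage_path(outdir, "equilibrium.tsv")
    if config.resume and eq_path.exists():
        eq = pd.read_csv(eq_path, sep="\t")
        summaries = [EquilibriumSummary(int(r.L), r.P_u, r.P_f,
                                        r.F_u_pN, r.F_f_pN)
                     for r in eq.itertuples()]
    else:
        centers = np.linspace(0.0, 1.0, config.n_windows)
        wins = {}
        for L in config.L_grid:
            system = _build_system(config, L)
            wins[L] = run_umbrella(
                system, centers=centers,
                steps_per_window=config.umbrella_steps,
                equil_steps=config.umbrella_equil, dt=config.dt,
                friction=config.friction, temperature=config.temperature,
                stride=config.umbrella_stride, seed=config.seed + 100 * L)
        summaries = summarize_per_L(wins)
        summaries_to_frame(summaries).to_csv(eq_path, sep="\t", index=False)
    results["summaries"] = summaries

    # stage 2: folding/unfolding rates per L (censored MFPT estimates)
    rates_path = _stage_path(outdir, "rates.tsv")
    if config.resume and rates_path.exists():
        rt = pd.read_csv(rates_path, sep="\t")
        kf_sim = rt["kf_sim"].to_numpy()
        ku_sim = rt["ku_sim"].to_numpy()
    else:
        kf_sim, ku_sim = [], []
        for L in config.L_grid:
            system = _build_system(config, L)
            kf, ku = _mfpt_rates(system, config, L)
            kf_sim.append(kf)
            ku_sim.append(ku)
        pd.DataFrame({"L": config.L_grid, "kf_sim": kf_sim,
                      "ku_sim": ku_sim}).to_csv(rates_path, sep="\t",
                                                index=False)
    s_anchor = max(summaries, key=lambda s: s.L)
    anchor_K = s_anchor.p_f / max(s_anchor.p_u, 1e-12)
    rates = scale_rates(list(config.L_grid), kf_sim, ku_sim,
                        config.k_u_iso_exp, anchor_K)
    results["rates"] = rates

    # stage 3: force profile by both solvers
    prof_path = _stage_path(outdir, "force_profile.tsv")
    if config.resume and prof_path.exists():
        table = pd.read_csv(prof_path, sep="\t")
        from .kinetics import ForceProfile
        profile = ForceProfile(table, config.incubation_s)
    else:
        profile = assemble_profile(summaries, rates, config.bell,
                                   t=config.incubation_s,
                                   n_replicas=config.kmc_replicas,
                                   seed=config.seed + 77)
        profile.to_tsv(prof_path)
    results["profile"] = profile

    manifest = {
        "config": json.loads(config.to_json()),
        "stages": {p.name: _hash_file(p)
                   for p in (eq_path, rates_path, prof_path) if p.exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results


def _mfpt_rates(system: CGSystem, config: PipelineConfig, L: int):
    """Folding/unfolding rates (internal units) from first-passage runs."""
    from .simulator import DivergenceError

    ext = extended_configuration(system)
    folded = folded_configuration(system)
    # short linkers leave the folded-outside placement under extreme
    # tether tension; relax harder before propagating
    stretch = 0.0
    if system.tether is not None:
        stretch = float(np.linalg.norm(folded[system.tether.end_bead]
                                       - system.anchor_xyz())
                        - system.tether.x0)
    folded = minimize_positions(system, folded,
                                n_iter=2000 if stretch > 0.5 else 300)
    t_max = config.rate_steps * config.dt
    fpt_f, fpt_u = [], []
    for s in range(config.rate_runs):
        try:
            rec = run_trajectory(system, n_steps=config.rate_steps,
                                 dt=config.dt, friction=config.friction,
                                 temperature=config.temperature, stride=50,
                                 seed=config.seed + 7000 + 10 * L + s,
                                 start=ext)
            hit = np.nonzero(rec.q > 0.7)[0]
            if hit.size:
                fpt_f.append(rec.time[hit[0]])
        except DivergenceError:
            pass  # no folding event resolvable from this replica
        try:
            rec = run_trajectory(system, n_steps=config.rate_steps,
                                 dt=config.dt, friction=config.friction,
                                 temperature=config.temperature, stride=50,
                                 seed=config.seed + 8000 + 10 * L + s,
                                 start=folded)
            hit = np.nonzero(rec.q < 0.3)[0]
            if hit.size:
                fpt_u.append(rec.time[hit[0]])
        except DivergenceError:
            # mechanical rupture faster than the integrator can resolve:
            # count an immediate unfolding event
            fpt_u.append(50 * config.dt)
    kf = mfpt_censored(fpt_f, config.rate_runs, t_max).rate
    ku = mfpt_censored(fpt_u, config.rate_runs, t_max).rate
    return kf, ku
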