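# ribofold

Coarse-grained simulation and kinetic modelling of cotranslational protein
folding, for people who study folding on the ribosome with arrest-peptide
(AP) force-profile experiments and want a quantitative, simulation-based
interpretation of them.

## The problem

An arrest peptide stalls translation; pulling force on the nascent chain
accelerates escape from arrest, so the fraction of full-length protein
produced in a fixed incubation, `f_FL`, reports the force on the chain.
When a domain is placed `L` residues upstream of the AP, it can fold near
the exit tunnel only by stretching the linker that tethers it to the
peptidyl-transferase center — folding generates force, and `f_FL(L)`
peaks at the linker lengths where folding is possible but still strained.
`ribofold` reproduces this chain of inference computationally:

1. **Model building** — a structure-based (Go) model of the domain (one
   bead per C-alpha; 12-10 native-contact wells; constrained bonds), a
   repulsive unstructured linker, a fixed coarse ribosome scaffold (three
   beads per RNA nucleotide, one per amino acid), and a stiff harmonic
   tether (k_s = 3000 kJ/mol/nm², x₀ = 0.38 nm) whose extension reports
   the pulling force F = k_s(x − x₀).
2. **Equilibrium analysis** — Langevin dynamics with umbrella sampling
   along the fraction of native contacts
   Q = (1/N) Σ 1/(1 + exp[γ(r_ij − λr_ij⁰)]) (γ = 50 nm⁻¹, λ = 1.2),
   WHAM-reweighted into G(Q), folded/unfolded populations P_f, P_u
   (boundary Q = 0.5) and state-conditioned mean tether forces F_f, F_u,
   per linker length.
3. **Arrest-escape kinetics** — the Bell model
   k_e(F) = k₀·exp(βFΔx‡) (k₀ = 3.4 × 10⁻⁴ s⁻¹, Δx‡ = 0.32 nm) feeds a
   four-state scheme {unfolded/folded × arrested/released} solved by
   kinetic Monte Carlo (BKL), or by the preequilibrium closed form
   f_FL(t) = 1 − exp{−t[P_u·k_e(F_u) + P_f·k_e(F_f)]}; folding and
   unfolding rates come from censored mean-first-passage-time estimates,
   globally rescaled to match experimental anchors.
4. **Pathway analysis** — transition paths (Q crossing 0.3 → 0.7),
   per-residue ϕ-values ϕ(i) ≈ ⟨p(q_ij|TP)⟩, and the contact-importance
   statistic p(TP|q_ij)_nn = p(q_ij|TP)·p(TP)_nn / p(q_ij)_nn.

Everything is testable offline: a synthetic-fixtures module generates
two-state toy chains, a toy exit tunnel of immobile beads, and labeled
trajectory ensembles with analytically known pathway statistics.

## Worked example

Tether the calibrated two-state toy domain in a toy exit tunnel at linker
length L = 22, measure its arrested equilibrium, and predict `f_FL`:

```python
import numpy as np
from ribofold import (make_toy_tunnel, bell_rate, preeq_ffl,
                      KineticScheme, kmc_ffl, master_equation_ffl)
from ribofold.fixtures import make_toy_system
from ribofold.simulator import run_umbrella
from ribofold.equilibrium import wham, state_split, mean_state_forces

tunnel = make_toy_tunnel(length=6.0, radius=0.55, bead_spacing=0.22,
                         n_shells=2)
system = make_toy_system(20, "helix-pair", scaffold=tunnel, L=22)

windows = run_umbrella(system, steps_per_window=16000, equil_steps=4000,
                       seed=42)
profile, weights = wham(windows)
q = np.concatenate([w.q for w in windows])
f = np.concatenate([w.force_pn for w in windows])
p_u, p_f = state_split(weights, q)
f_u, f_f = mean_state_forces(weights, q, f)
print(f"L=22: P_f = {p_f:.2f}, F_u = {f_u:.1f} pN, F_f = {f_f:.1f} pN")

f_fl = preeq_ffl(p_u, p_f, f_u, f_f, t=900.0)
print(f"preequilibrium f_FL(15 min) = {f_fl:.2f}")

scheme = KineticScheme(kf=0.14, ku=4.9e-4,
                       ke_u=float(bell_rate(f_u)),
                       ke_f=float(bell_rate(f_f)))
res = kmc_ffl(scheme, t_total=900.0, n_replicas=20000, seed=1)
print(f"full-scheme f_FL = {res.f_fl:.2f} +- {res.se:.3f} "
      f"(exact {master_equation_ffl(scheme, 900.0):.3f})")
```

Output:

```
L=22: P_f = 0.29, F_u = 25.8 pN, F_f = 22.8 pN
preequilibrium f_FL(15 min) = 0.89
full-scheme f_FL = 0.85 +- 0.003 (exact 0.849)
```

At this linker length the domain folds part of the time (P_f = 0.29 in
this run; window-to-window sampling noise at this desk-scale budget is
substantial) and both states pull with ~20–26 pN, so escape is strongly
accelerated over the zero-force baseline f_FL = 1 − e^(−k₀·900 s) ≈ 0.26.
The kinetic Monte Carlo result agrees with the matrix-exponential solution
of the same scheme to Monte-Carlo precision, and with the preequilibrium
approximation to a few percent.

The full per-linker-length workflow (umbrella sampling per L → WHAM →
rates → force profile, with TSV outputs and a provenance manifest) runs
through `ribofold.pipeline.run_pipeline` or the CLI:

```
ribofold all --outdir family_run --seed 1 --l-grid 10,16,20,24,30
```

Real structures enter through the same library surface: `read_structure`
(PDB/mmCIF via biotite) → `coarse_grain` → `select_scaffold` /
`contact_map_from_structure` → `build_go_system` →
`attach_linker_and_tether`.

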