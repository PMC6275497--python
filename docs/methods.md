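# Methods

`ribofold` models how a protein domain folds while it is still attached to
the ribosome, and how the mechanical force generated by that folding
controls escape from translational arrest. This note documents the models,
the parameters that matter, the synthetic systems used for validation, and
the numerical choices.

## The physical picture

An arrest peptide (AP) such as SecM stalls its own translation; a pulling
force on the nascent chain accelerates escape from arrest. If a domain
placed `L` residues upstream of the AP can fold only by stretching the
linker that connects it to the peptidyl-transferase center (PTC), folding
exerts force, and the experimentally measured fraction of full-length
protein, `f_FL`, rises. The pipeline predicts `f_FL(L)` from molecular
simulation plus a small kinetic model, and characterizes the folding
mechanism on and off the ribosome through transition-path statistics.

## Coarse-grained model

* **Representation.** One bead per amino acid at the C-alpha position;
  three beads per RNA nucleotide (P, C4', N3). Bead radii: amino acid
  0.45 nm, phosphate 0.32 nm, sugar 0.51 nm, base 0.45 nm. Ribosome
  (scaffold) beads are fixed in space; only the beads near the exit tunnel
  are retained (default: within 2.0 nm of the tunnel axis plus a 6.0 nm
  hemispherical cap at the exit, configurable).
* **Intraprotein potential.** A structure-based (Go) model: all chain
  bonds constrained to their native lengths; harmonic angles
  (k = 40 kJ/mol/rad^2) and native-centered dihedrals
  (V = k[(1-cos dphi) + (1-cos 3 dphi)/2], k = eps_c/2 by default) from
  the native geometry; native contacts attract through 12-10 wells
  `eps_c [5 (r0/r)^12 - 6 (r0/r)^10]` with the minimum at the native
  distance. Contacts come from a 4.5 A all-heavy-atom criterion at
  sequence separation >= 4 (C-alpha fallback, flagged, for CA-only
  inputs).
* **Excluded volume.** Every other pair — nonnative intraprotein pairs,
  linker against everything, protein against ribosome — interacts through
  the soft 12-10-6 form `eps_ij [A r^-12 - B r^-10 + C r^-6]` with
  eps_ij = 0.001 kJ/mol. The printed mixing rules for (A, B, C) are
  typographically ambiguous; the default uses a single effective radius
  sigma_ij = (sigma_i + sigma_j)/2 with A = s^12, B = 2 s^10, C = s^6,
  which crosses zero at r = s, is strongly repulsive below ~0.78 s (above
  kT below ~0.45 s at the default strength), and is negligible
  (|V| < 1e-4 kJ/mol) beyond 1.5 s. The literal printed coefficients are
  available behind a switch. With eps_ij this small the interaction is
  soft excluded volume; the mixing algebra is not load-bearing.
* **Many-body cooperativity.** An additive Go model at the 16-20 bead
  scale folds downhill: its Q distribution is unimodal at every
  temperature, which makes "folded population" ill-defined and transition
  paths meaningless. The package therefore includes an optional
  cooperativity term `V = -c (Q - 1/2)^2 / 2` acting on the smooth Q
  (`GoParameters.coop_strength`, default 0 — off). It penalizes
  half-formed interfaces and is the standard minimal device for restoring
  two-state behavior in small structure-based models. The toy systems use
  c = 80 kJ/mol. Forces follow exactly by the chain rule through the
  switching function, sharing the umbrella-bias code path.
* **Tether.** The chain end is tied to the anchor bead (the last P atom
  of the A-site tRNA, or the buried axial bead of a toy tunnel) by a stiff
  harmonic bond, `V = ks (x - x0)^2 / 2` with ks = 3000 kJ/mol/nm^2 and
  x0 = 0.38 nm — stiff enough that displacements stay below 1 A up to
  ~500 pN. This is the only unconstrained bond and reports the pulling
  force. A subtlety: the scalar estimator `ks(<x> - x0)` carries a +21 pN
  offset for a *slack* bond, because the radial Jacobian of a 3D spring
  shifts `<x>` above x0 by 2kT/(ks x0) even with zero transmitted tension.
  The package reports the spring-force vector projected on the load axis
  (the tunnel axis), which averages to zero for a slack bond and to the
  transmitted tension under load, with F > 0 meaning pulling.
* **Mutants.** Destabilizing point mutations are modeled by scaling all
  native contacts of the mutated residue by (1 - factor), default factor
  0.4; N-terminal strand deletions remove beads and prune the contact
  map; attractive domain-ribosome interactions (for mutants exposing a
  hydrophobic patch) are 12-6 Lennard-Jones pairs with sigma = 0.6 nm and
  eps = 5 kJ/mol between the exposed residues and hydrophobic ribosome
  surface beads.

## Dynamics and sampling

* **Integrator.** BAOAB-split Langevin dynamics at T = 291 K, friction
  0.1 ps^-1, time step 0.01 ps, with iterative bond-constraint projection
  (tolerance 1e-8 nm) and velocity projection along constraints. In the
  zero-friction limit it reduces to velocity Verlet with constraints and
  conserves energy to < 1e-4 kJ/mol per step per bead on the toy system.
  Bead masses are uniform (110 internal units); simulation time is
  internal and never interpreted in seconds — all rates are rescaled
  against experimental anchors (below), as the scale separation between
  coarse-grained and experimental kinetics requires anyway.
* **Reaction coordinate.** The smooth fraction of native contacts
  `Q = (1/N) sum 1/(1 + exp[gamma (r_ij - lam r_ij0)])` with
  gamma = 50 nm^-1 and lam = 1.2. The binary contact-formed criterion
  used by the pathway statistics is r < lam r0 (strict), the switching
  midpoint, so the smooth and binary definitions agree on the same
  fluctuation allowance.
* **Umbrella sampling.** Harmonic bias `k_umb (Q - Q0)^2 / 2` with
  k_umb = 600 kcal/mol in 16 windows evenly spanning [0, 1]. Windows run
  sequentially from the native basin downward, each starting from the
  previous window's final frame; adjacent windows sharing < 2% histogram
  mass trigger a warning. For linkers too short to place the folded
  domain outside the tunnel, the native-placement start would stretch the
  tether by nanometers, so the sweep starts from the threaded extended
  chain instead.
* **WHAM.** Standard binned self-consistent iteration (50 uniform Q bins,
  tolerance 1e-7 on window free energies), returning G(Q) and per-sample
  unbiased weights. Folded/unfolded populations split at Q = 0.5; state
  forces are weight-conditioned means. Validated against an analytic
  double-well density sampled under known biases (agreement within
  0.1 kT on well-sampled bins).
* **Neighbor handling.** The scaffold never moves, so its beads are
  hashed once into a static cell grid; excluded-volume pairs are cut off
  at 1.4 sigma_ij where |V| < 1e-4 kJ/mol.

## Kinetic model for f_FL

While arrested, the protein hops between unfolded (UA) and folded (FA)
states with linker-length-dependent rates `kf(L)`, `ku(L)`; each state can
escape arrest irreversibly (UA -> UR, FA -> FR) with the Bell rate
`k_e(F) = k0 exp(beta F dx)` evaluated at that state's mean tether force.
Defaults k0 = 3.4e-4 s^-1 and dx = 0.32 nm come from optical-tweezer
characterization of SecM escape; values outside the experimentally
admissible ranges (0.5-20 x 1e-4 s^-1, 0.1-0.8 nm) are warned about.

* **Rates from simulation.** `kf` and `ku` are inverse mean first-passage
  times from direct folding (extended start, first Q > 0.7) and unfolding
  (native start, first Q < 0.3) runs, using the censoring-aware
  maximum-likelihood estimator
  `[N_ev t_mean + (N - N_ev) t_sim] / N_ev`; with zero events the
  censoring lower bound is used and flagged. Simulated rates are mapped
  to s^-1 by one global factor per rate type, anchored so that at the
  longest linker the scaled `ku` equals the isolated-domain experimental
  unfolding rate (4.9e-4 s^-1 for the Ig domain) and the scaled `kf/ku`
  equals the model's own folded/unfolded equilibrium constant there —
  the kinetic and equilibrium descriptions then agree at the anchor.
* **Solvers.** The full scheme is solved by BKL kinetic Monte Carlo
  (waiting time -ln(u)/sum k; transition chosen by a uniform variate
  against cumulative rates), cross-checked against the matrix exponential
  of the 4-state generator; and by the preequilibrium closed form
  `f_FL(t) = 1 - exp{-t [P_u k_e(F_u) + P_f k_e(F_f)]}`, valid when
  folding exchange is fast compared with escape. The profile assembler
  flags linker lengths where the two disagree by > 0.05. The
  preequilibrium product is assembled in log space and KMC escape rates
  are capped at 1e9 s^-1 so that an unpopulated, absurdly high-force
  state (short linkers under bias) cannot overflow; its population weight
  suppresses it correctly. Default incubation 900 s (15 min; 1800 s
  optional).

## Pathway statistics

Transition paths are the trajectory segments from the last frame with
Q < 0.3 to the first subsequent frame with Q > 0.7 (reversed for
unfolding harvests). From an ensemble of TPs:

* `phi(i)` = mean TP formation frequency of residue i's native contacts;
  residues without contacts are reported missing, never zero-filled.
* `p(TP|q_ij)_nn = p(q_ij|TP) p(TP)_nn / p(q_ij)_nn` ranks contacts by
  how diagnostic their formation is of being on a productive folding
  path, restricted to nonnative (unfolded + TP) frames; folded frames are
  excluded since native contacts are trivially formed there.
* `p(TP)_nn` = 2 t_TP / (2 t_TP + t_F^mfpt) for folding harvests, and
  2 t_TP / (2 t_TP + (p_U/p_F) t_U^mfpt) for unfolding harvests (the
  population reweighting corrects for harvesting in the wrong
  direction); `p(q)_nn` is counted directly for folding harvests and
  reassembled as the p(TP)_nn-weighted mixture for unfolding harvests.
* Computed phi-values can be rank-correlated (Spearman) against an
  external reference table, keeping only mutations with |ddG| > 7 kJ/mol;
  fewer than 3 surviving pairs leaves the correlation undefined.

All estimators are validated against a synthetic generator that draws
per-contact Bernoulli formation states with prescribed probabilities on
TP and unfolded frames, for which every statistic has a closed form.

## Toy systems: what they emulate and what they do not

The synthetic fixtures make the whole pipeline testable offline:

* **Toy chains.** A 16-bead beta-hairpin (zig-zag strands, bond 0.38 nm,
  backbone angle 120 deg) and a 20-bead antiparallel helix pair. Contact
  maps come from a brute-force distance scan (< 0.7 / 0.75 nm at
  separation >= 4 / 6). Calibrated contact strengths at 291 K
  (hairpin 3.8, helix pair 5.0 kJ/mol, both with cooperativity
  c = 80 kJ/mol) give bimodal Q distributions with both basins populated
  and tens of spontaneous barrier crossings per 1e6 steps. The helix
  pair additionally uses rigid helices (angle k = 80, dihedral k = 8)
  with a flexible inter-helix hinge, so that its native contact patch can
  only be satisfied by the true side-by-side docking — without this, a
  squeezed chain can reform all native pair distances *inside* a
  confining tube, which no real domain's tertiary core can do.
* **Toy tunnel.** A cylindrical wall of immobile beads (default length
  6 nm, radius 0.55 nm, spacing 0.22 nm), open at the exit, capped and
  anchored at the buried end. Because the excluded volume is soft, the
  default uses two staggered shells; a single shell (all wall beads
  exactly at the configured radius) is available for geometric tests.
  The geometry emulates the ~100 A exit tunnel at roughly half scale so
  that the folding onset falls at desk-affordable linker lengths
  (L ~ 18-20 of the 10-30 grid).
* **What carries over, and what does not.** The family reproduces the
  qualitative mechanism: short linkers cannot fold (P_f ~ 0, baseline
  force only), the onset linker folds by stretching the tether (high
  F_f), and longer linkers relax (F_f falls, P_f -> its off-ribosome
  value), producing a single interior maximum in f_FL(L). Two features
  of the toy family differ from the real system: the unfolded-state
  force grows mildly with L (entropic pull of the growing outside
  segment through a narrow pore — the toy tunnel is narrower, relative
  to the chain, than the real one), and the long-L decline of f_FL is
  shallower because the folded-state force does not fully vanish on the
  desk-scale grid. Passing toy tests therefore validates the machinery
  and the mechanism's direction, not the absolute force scale of the
  real ribosome.

## Numerical choices and degenerate inputs

* Constraint solver: iterative projection, position tolerance 1e-8 nm
  (bond deviations stay < 1e-6 nm per step), velocity tolerance 1e-10.
* Divergent dynamics (non-finite coordinates) raise with the last frame
  attached rather than silently truncating.
* WHAM with a single unbiased window degenerates to -kT log(histogram);
  a state with zero statistical weight yields NaN state force with a
  warning, and downstream weighting by the zero population keeps the
  profile finite.
* Ties: the top-contact ranking breaks ties lexicographically by (i, j);
  a contact exactly at the switching midpoint counts as not formed.
* Seeds: every stochastic routine takes an explicit seed; a (system,
  seed) pair reruns bit-identically on the same software stack.

## Problem sizes used in the shipped validation

The default validation runs (test suite and acceptance script) use the
desk-scale study conditions: 16 umbrella windows x 16,000-20,000 steps
per window per linker length on the 5-6 point toy grid, 2 first-passage
runs per direction per linker of 80,000-100,000 steps, 1,200-40,000
kinetic Monte Carlo replicas per scheme, and 1e5-frame synthetic
ensembles. The full-scale configuration (the real Ig domain on the 50S
subunit, linker grid 21-61) uses the same code paths with the structure
files supplied by the user.
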