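"""Structure-based (Go) model construction.

The simulatable system couples a structure-based protein model (bonded
terms from the native geometry, attractive 12-10 wells at native contacts)
to an immobile ribosome scaffold through soft 12-10-6 excluded-volume
repulsion, an unstructured repulsive linker, and a stiff harmonic tether to
the anchor bead that reports the pulling force on the arrest peptide.

Interaction forms (r in nm, energies kJ/mol):

* native contact:      V = eps_c [5 (r0/r)^12 - 6 (r0/r)^10]
* excluded volume:     V = eps_ij [A r^-12 - B r^-10 + C r^-6]
* hydrophobic surface: V = 4 eps [(sigma/r)^12 - (sigma/r)^6]
* tether:              V = ks (x - x0)^2 / 2,  F = -ks (x - x0)
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .structures import AtomicStructure, BeadModel, RibosomeScaffold, BEAD_RADII

__all__ = [
    "NativeContactMap",
    "GoParameters",
    "Tether",
    "CGSystem",
    "contact_map_from_structure",
    "repulsion_coefficients",
    "build_go_system",
    "attach_linker_and_tether",
    "weaken_residue_contacts",
    "add_hydrophobic_surface_attraction",
    "residues_near",
]


@dataclass
class NativeContactMap:
    """Native contacts (i, j) with native distances and per-pair strengths.

    Indices are 0-based positions along the bead chain; ``r0`` is the
    native C-alpha--C-alpha distance in nm, ``eps`` the well depth in
    kJ/mol (may be NaN until a uniform strength is assigned at build time).
    """

    pairs: np.ndarray          # (n, 2) int, i < j
    r0: np.ndarray             # nm
    eps: np.ndarray | None = None
    min_separation: int = 4
    criterion: str = "heavy-atom"

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("contact pairs must satisfy i < j")
        sep = self.pairs[:, 1] - self.pairs[:, 0]
        if np.any(sep < self.min_separation):
            raise ValueError("contact pair below minimum sequence separation")
        if np.any(self.r0 <= 0):
            raise ValueError("native distances must be positive")
        if self.eps is not None:
            self.eps = np.asarray(self.eps, dtype=float)

    def __len__(self):
        return len(self.pairs)

    def contacts_of(self, i: int) -> np.ndarray:
        """Indices of contacts involving residue i (symmetric access)."""
        return np.nonzero((self.pairs[:, 0] == i) | (self.pairs[:, 1] == i))[0]

    def copy(self) -> "NativeContactMap":
        return NativeContactMap(self.pairs.copy(), self.r0.copy(),
                                None if self.eps is None else self.eps.copy(),
                                self.min_separation, self.criterion)


def contact_map_from_structure(structure, heavy_atom_cutoff: float = 0.45,
                               min_separation: int = 4,
                               ca_fallback_cutoff: float = 0.7,
                               chain=None) -> NativeContactMap:
    """Native contact map from an all-atom structure.

    A pair of residues is in contact when any two heavy atoms are closer
    than ``heavy_atom_cutoff`` (nm) and the residues are at least
    ``min_separation`` apart in sequence; r0 is the native C-alpha
    distance.  Structures carrying only C-alpha atoms fall back to a
    C-alpha distance criterion (< ``ca_fallback_cutoff``) with a warning;
    the fallback is flagged in the returned map's ``criterion``.
    """
    residues = [(ch, rid, name, idxs) for ch, rid, name, idxs
                in structure.residues(chain) if np.any(
                    structure.atom_name[idxs] == "CA")]
    n = len(residues)
    ca = np.array([structure.coord[idxs[structure.atom_name[idxs] == "CA"][0]]
                   for _, _, _, idxs in residues]) / 10.0
    heavy = []
    for _, _, _, idxs in residues:
        el = structure.element[idxs]
        heavy.append(structure.coord[idxs[(el != "H") & (el != "D")]] / 10.0)
    ca_only = all(h.shape[0] <= 1 for h in heavy)
    if ca_only:
        warnings.warn(
            "structure carries no side-chain heavy atoms; falling back to "
            f"a C-alpha distance criterion (< {ca_fallback_cutoff} nm)",
            stacklevel=2)
    pairs, r0 = [], []
    for i in range(n):
        for j in range(i + min_separation, n):
            if ca_only:
                hit = np.linalg.norm(ca[i] - ca[j]) < ca_fallback_cutoff
            else:
                d = np.linalg.norm(heavy[i][:, None, :] - heavy[j][None, :, :],
                                   axis=-1)
                hit = d.min() < heavy_atom_cutoff
            if hit:
                pairs.append((i, j))
                r0.append(np.linalg.norm(ca[i] - ca[j]))
    return NativeContactMap(np.array(pairs, int).reshape(-1, 2),
                            np.array(r0), min_separation=min_separation,
                            criterion="ca-fallback" if ca_only
                            else "heavy-atom")


def repulsion_coefficients(sigma_i: float, sigma_j: float,
                           mode: str = "effective"):
    """Coefficients (A, B, C) of the 12-10-6 excluded-volume potential.

    Default "effective" mixing uses a single effective radius
    sigma_ij = (sigma_i + sigma_j)/2 with A = sigma^12, B = 2 sigma^10,
    C = sigma^6, giving a soft repulsive barrier near r = sigma_ij (the
    residual well between the r^-10 and r^-6 terms is of depth ~0.3
    eps_ij, i.e. ~3e-4 kJ/mol at the default strength -- negligible).
    The "literal" mode applies the printed mixing expressions verbatim for
    comparison.
    """
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("bead radii must be positive")
    if mode == "effective":
        s = 0.5 * (sigma_i + sigma_j)
        return s ** 12, 2.0 * s ** 10, s ** 6
    if mode == "literal":
        return (sigma_i ** 12 * sigma_j ** 12,
                2.0 * (sigma_i ** -10 + sigma_j ** -10),
                sigma_i ** 6 * sigma_j ** 6)
    raise ValueError("mode must be 'effective' or 'literal'")


@dataclass(frozen=True)
class GoParameters:
    """Tunable constants of the coarse-grained model (kJ/mol, nm, K)."""

    eps_contact: float = 4.0          # native-contact well depth
    eps_repulsive: float = 0.001      # excluded-volume strength
    k_angle: float = 40.0             # kJ/mol/rad^2
    k_dihedral: float | None = None   # None -> eps_contact / 2
    ks: float = 3000.0                # tether spring, kJ/mol/nm^2
    x0: float = 0.38                  # tether rest length, nm
    sigma_hp: float = 0.6             # hydrophobic-attraction range, nm
    eps_hp: float = 5.0               # hydrophobic-attraction depth, kJ/mol
    weaken_factor: float = 0.4        # mutant contact weakening
    contact_cutoff: float = 0.45      # heavy-atom contact criterion, nm
    min_seq_sep: int = 4
    # many-body cooperativity: V = -coop_strength (Q - coop_center)^2 / 2,
    # a quadratic-in-Q term that sharpens two-state behavior by penalizing
    # half-formed interfaces; 0 disables it
    coop_strength: float = 0.0
    coop_center: float = 0.5
    temperature: float = 291.0
    mass: float = 110.0               # per-bead mass (internal time units)
    mixing: str = "effective"

    @property
    def k_dihedral_eff(self) -> float:
        return self.eps_contact / 2 if self.k_dihedral is None else self.k_dihedral


@dataclass(frozen=True)
class Tether:
    """Stiff harmonic tether from the chain-end bead to the anchor point."""

    end_bead: int
    ks: float = 3000.0
    x0: float = 0.38


@dataclass
class CGSystem:
    """The simulatable coarse-grained system.

    Mobile beads are the protein domain followed by the (optional) linker;
    the scaffold, when present, is immobile.  All chain bonds are
    constrained to their native lengths; the tether is the single
    unconstrained, force-reporting bond.
    """

    beads: BeadModel                    # mobile beads, chain order
    n_domain: int
    bonds: np.ndarray                   # (nb, 2) int, constrained
    bond_r0: np.ndarray
    angles: np.ndarray                  # (na, 3) int
    theta0: np.ndarray
    dihedrals: np.ndarray               # (nd, 4) int
    phi0: np.ndarray
    contacts: NativeContactMap
    rep_pairs: np.ndarray               # (nr, 2) intra-chain excluded volume
    rep_sigma: np.ndarray
    params: GoParameters
    # optional per-term bonded constants (None -> uniform from params);
    # used e.g. to combine rigid secondary-structure segments with a
    # flexible hinge in toy systems
    angle_k: np.ndarray | None = None
    dihedral_k: np.ndarray | None = None
    scaffold: RibosomeScaffold | None = None
    tether: Tether | None = None
    hp_pairs: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 2), dtype=int))
    anchor_point: np.ndarray | None = None   # used when scaffold is None
    provenance: dict = field(default_factory=dict)

    @property
    def n_mobile(self) -> int:
        return len(self.beads)

    @property
    def linker_length(self) -> int:
        return self.n_mobile - self.n_domain

    @property
    def positions(self) -> np.ndarray:
        return self.beads.position

    def anchor_xyz(self) -> np.ndarray | None:
        if self.scaffold is not None:
            return self.scaffold.anchor_position
        return self.anchor_point

    def copy(self) -> "CGSystem":
        return _copy.deepcopy(self)

    def to_json(self, path) -> None:
        """Serialize the topology and coordinates to self-describing JSON."""
        import json
        from pathlib import Path

        doc = {
            "units": {"length": "nm", "energy": "kJ/mol"},
            "n_domain": int(self.n_domain),
            "params": self.params.__dict__.copy(),
            "beads": {
                "kind": [str(k) for k in self.beads.kind],
                "res_id": self.beads.res_id.tolist(),
                "chain": [str(c) for c in self.beads.chain_id],
                "position": self.beads.position.tolist(),
                "radius": self.beads.radius.tolist(),
            },
            "bonds": {"pairs": self.bonds.tolist(),
                      "r0": self.bond_r0.tolist(), "constrained": True},
            "angles": {"triples": self.angles.tolist(),
                       "theta0": self.theta0.tolist()},
            "dihedrals": {"quads": self.dihedrals.tolist(),
                          "phi0": self.phi0.tolist()},
            "contacts": {"pairs": self.contacts.pairs.tolist(),
                         "r0": self.contacts.r0.tolist(),
                         "eps": (None if self.contacts.eps is None
                                 else self.contacts.eps.tolist())},
            "tether": (None if self.tether is None else
                       {"end_bead": self.tether.end_bead,
                        "ks": self.tether.ks, "x0": self.tether.x0}),
            "hp_pairs": self.hp_pairs.tolist(),
            "provenance": {k: str(v) for k, v in self.provenance.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _chain_bonded_terms(pos):
    n = len(pos)
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r0 = np.linalg.norm(pos[1:] - pos[:-1], axis=1)
    angles = np.column_stack([np.arange(n - 2), np.arange(1, n - 1),
                              np.arange(2, n)])
    theta0 = np.array([_angle(pos[i], pos[j], pos[k]) for i, j, k in angles])
    dihedrals = np.column_stack([np.arange(n - 3), np.arange(1, n - 2),
                                 np.arange(2, n - 1), np.arange(3, n)])
    phi0 = np.array([_dihedral(pos[i], pos[j], pos[k], pos[l])
                     for i, j, k, l in dihedrals])
    return bonds, bond_r0, angles, theta0, dihedrals, phi0


def _angle(a, b, c):
    u, v = a - b, c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def _rep_pairs_for_chain(n, contacts: NativeContactMap, min_sep: int = 4):
    """All chain pairs at sequence separation >= min_sep that are not
    native contacts (those get the attractive well instead)."""
    contact_set = {tuple(p) for p in contacts.pairs}
    pairs = [(i, j) for i in range(n) for j in range(i + min_sep, n)
             if (i, j) not in contact_set]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def build_go_system(beads: BeadModel, contacts: NativeContactMap,
                    scaffold: RibosomeScaffold | None = None,
                    params: GoParameters = GoParameters()) -> CGSystem:
    """Assemble a structure-based model from beads and a contact map.

    Bonded terms (constrained bonds, harmonic angles, native dihedrals) are
    taken from the native bead geometry; native contacts get 12-10 wells of
    depth ``params.eps_contact`` (unless the map carries per-pair
    strengths); every other intra-chain pair at sequence separation >= 4,
    and every protein--scaffold pair, interacts through the soft 12-10-6
    excluded volume.
    """
    n = len(beads)
    if len(contacts) and contacts.pairs.max() >= n:
        raise ValueError("contact map references a bead outside the chain")
    pos = np.asarray(beads.position, dtype=float)
    bonds, bond_r0, angles, theta0, dihedrals, phi0 = _chain_bonded_terms(pos)
    cmap = contacts.copy()
    if cmap.eps is None or np.all(np.isnan(cmap.eps)):
        cmap.eps = np.full(len(cmap), params.eps_contact)
    rep_pairs = _rep_pairs_for_chain(n, cmap, params.min_seq_sep)
    radii = np.asarray(beads.radius, dtype=float)
    rep_sigma = (0.5 * (radii[rep_pairs[:, 0]] + radii[rep_pairs[:, 1]])
                 if len(rep_pairs) else np.zeros(0))
    mobile_beads = BeadModel(beads.kind.copy(), beads.res_id.copy(),
                             beads.chain_id.copy(), pos.copy(),
                             radii.copy(), np.ones(n, dtype=bool))
    return CGSystem(
        beads=mobile_beads, n_domain=n,
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, theta0=theta0,
        dihedrals=dihedrals, phi0=phi0,
        contacts=cmap, rep_pairs=rep_pairs, rep_sigma=rep_sigma,
        params=params, scaffold=scaffold,
        provenance={"n_domain": n, "params": params.__dict__.copy()},
    )


def attach_linker_and_tether(system: CGSystem, L: int,
                             linker_sequence: str | None = None) -> CGSystem:
    """Append an L-residue repulsive linker and the force-reporting tether.

    The linker carries no native contacts, angles or dihedrals; it
    interacts with everything only through the excluded-volume repulsion.
    The chain-end bead is tethered to the scaffold anchor (or to a fixed
    point for scaffold-free systems) with the stiff harmonic (ks, x0); this
    bond is the only unconstrained one and reports F = -ks (x - x0).
    """
    if L < 1:
        raise ValueError("linker length L must be >= 1")
    if linker_sequence is not None and len(linker_sequence) < L:
        raise ValueError("linker sequence shorter than requested L")
    sys2 = system.copy()
    n0 = sys2.n_mobile
    params = sys2.params
    pos = sys2.beads.position
    cterm = pos[n0 - 1]
    if sys2.scaffold is not None:
        tun = sys2.scaffold.tunnel
        axis = tun.axis
        anchor = sys2.scaffold.anchor_position
        # thread the linker along the tunnel axis from the C terminus
        # toward the anchor; the tether absorbs any leftover gap
        direction = -axis
    else:
        direction = _away_direction(pos)
        anchor = cterm + direction * (params.x0 + L * 0.38)
        sys2.anchor_point = anchor
    lpos = np.array([cterm + direction * 0.38 * (k + 1) for k in range(L)])
    seq = (linker_sequence[-L:] if linker_sequence is not None else "G" * L)
    lbeads = BeadModel(
        kind=np.array(["protein-CA"] * L, dtype=object),
        res_id=np.arange(1, L + 1),
        chain_id=np.array(["LINKER"] * L, dtype=object),
        position=lpos,
        radius=np.full(L, BEAD_RADII["protein-CA"]),
        mobile=np.ones(L, dtype=bool),
    )
    beads = BeadModel(
        np.concatenate([sys2.beads.kind, lbeads.kind]),
        np.concatenate([sys2.beads.res_id, lbeads.res_id]),
        np.concatenate([sys2.beads.chain_id, lbeads.chain_id]),
        np.concatenate([sys2.beads.position, lbeads.position]),
        np.concatenate([sys2.beads.radius, lbeads.radius]),
        np.concatenate([sys2.beads.mobile, lbeads.mobile]),
    )
    n = n0 + L
    bonds = np.vstack([sys2.bonds,
                       np.column_stack([np.arange(n0 - 1, n - 1),
                                        np.arange(n0, n)])])
    bond_r0 = np.concatenate([sys2.bond_r0, np.full(L, 0.38)])
    rep_pairs = _rep_pairs_for_chain(n, sys2.contacts, params.min_seq_sep)
    radii = beads.radius
    rep_sigma = 0.5 * (radii[rep_pairs[:, 0]] + radii[rep_pairs[:, 1]])
    return replace(
        sys2, beads=beads, bonds=bonds, bond_r0=bond_r0,
        rep_pairs=rep_pairs, rep_sigma=rep_sigma,
        tether=Tether(end_bead=n - 1, ks=params.ks, x0=params.x0),
        provenance={**sys2.provenance, "L": L, "linker_sequence": seq},
    )


def _away_direction(pos):
    """Unit vector from the chain centroid through the C-terminal bead."""
    v = pos[-1] - pos.mean(axis=0)
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])


def weaken_residue_contacts(system: CGSystem, residue: int,
                            factor: float) -> CGSystem:
    """Scale all native contacts of one residue by (1 - factor).

    ``residue`` is a 0-based chain index of the domain; ``factor`` = 0.4
    reproduces the 40% weakening used to model destabilizing point
    mutations.  Raises if the residue has no native contacts.
    """
    idx = system.contacts.contacts_of(residue)
    if idx.size == 0:
        raise ValueError(f"residue {residue} has no native contacts")
    sys2 = system.copy()
    sys2.contacts.eps[idx] = sys2.contacts.eps[idx] * (1.0 - factor)
    sys2.provenance = {**sys2.provenance,
                       "weakened": (int(residue), float(factor))}
    return sys2


def add_hydrophobic_surface_attraction(
        system: CGSystem, surface_bead_indices, protein_residues,
        sigma_hp: float | None = None,
        eps_hp: float | None = None) -> CGSystem:
    """Add 12-6 Lennard-Jones attractions to ribosome surface beads.

    ``surface_bead_indices`` index beads of the scaffold (hydrophobic
    surface residues of uL23/uL29 in the real system); ``protein_residues``
    are 0-based chain indices of the attracted protein beads (those whose
    heavy atoms neighbor the mutated site in the native state).  Defaults
    sigma = 0.6 nm, eps = 5 kJ/mol.
    """
    if system.scaffold is None:
        raise ValueError("hydrophobic surface attraction needs a scaffold")
    surface = np.asarray(surface_bead_indices, dtype=int)
    protein = np.asarray(protein_residues, dtype=int)
    if surface.size == 0 or protein.size == 0:
        raise ValueError("empty residue set for hydrophobic attraction")
    sys2 = system.copy()
    pairs = np.array([(p, s) for p in protein for s in surface], dtype=int)
    sys2.hp_pairs = np.vstack([sys2.hp_pairs, pairs])
    p = sys2.params
    sys2.params = replace(
        p,
        sigma_hp=p.sigma_hp if sigma_hp is None else sigma_hp,
        eps_hp=p.eps_hp if eps_hp is None else eps_hp)
    return sys2


def residues_near(structure: AtomicStructure, residue_id: int,
                  cutoff: float = 0.45, chain=None):
    """0-based chain indices of residues with any heavy atom within
    ``cutoff`` (nm) of the named residue's heavy atoms (native state)."""
    residues = [(ch, rid, name, idxs) for ch, rid, name, idxs
                in structure.residues(chain)]
    target = None
    for k, (_, rid, _, idxs) in enumerate(residues):
        if rid == residue_id:
            target = idxs
            break
    if target is None:
        raise ValueError(f"residue {residue_id} not found")
    el = structure.element
    t_xyz = structure.coord[target[(el[target] != "H")]] / 10.0
    out = []
    for k, (_, rid, _, idxs) in enumerate(residues):
        xyz = structure.coord[idxs[(el[idxs] != "H")]] / 10.0
        d = np.linalg.norm(t_xyz[:, None, :] - xyz[None, :, :], axis=-1)
        if d.min() < cutoff:
            out.append(k)
    return np.array(out, dtype=int)
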