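"""Atomic structures and their coarse-grained bead representation.

Proteins are reduced to one bead per residue at the C-alpha position; RNA
to three beads per nucleotide (phosphate P, sugar C4', base N3).  Bead
radii follow the fixed table: amino acid 0.45 nm, phosphate 0.32 nm, sugar
0.51 nm, base 0.45 nm.  Ribosome beads are immobile; only the subset near
the exit tunnel is retained in the simulated scaffold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AtomicStructure",
    "BeadModel",
    "RibosomeScaffold",
    "TunnelAnnotation",
    "BEAD_RADII",
    "read_structure",
    "coarse_grain",
    "select_scaffold",
]

#: bead radii sigma_i in nm per bead kind
BEAD_RADII = {
    "protein-CA": 0.45,
    "rna-P": 0.32,
    "rna-C4p": 0.51,
    "rna-N3": 0.45,
}

_RNA_RESIDUES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class AtomicStructure:
    """Flat atom table (positions in Angstrom, 1-based residue indices)."""

    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray         # (n, 3) Angstrom
    hetero: np.ndarray        # bool flags for HETATM records

    def __post_init__(self):
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite atom coordinates")

    def __len__(self):
        return len(self.atom_name)

    def chains(self):
        return list(dict.fromkeys(self.chain_id.tolist()))

    def residues(self, chain=None):
        """Iterate (chain_id, res_id, res_name, atom index array)."""
        sel = np.ones(len(self), dtype=bool)
        if chain is not None:
            sel &= self.chain_id == chain
        keys = {}
        for idx in np.nonzero(sel)[0]:
            key = (self.chain_id[idx], int(self.res_id[idx]))
            keys.setdefault(key, []).append(idx)
        for (ch, rid), idxs in keys.items():
            yield ch, rid, self.res_name[idxs[0]], np.array(idxs)

    def n_amino_acids(self) -> int:
        return sum(1 for _, _, name, _ in self.residues() if name in _AA3)


def read_structure(path, fmt: str | None = None) -> AtomicStructure:
    """Read a PDB or mmCIF file into an AtomicStructure.

    First model only; for alternate locations, altloc A is preferred.
    Raises ValueError with the underlying parser message for files that do
    not parse under the named standard.
    """
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio
    from biotite.structure.io.pdbx import get_structure as pdbx_get

    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            f = pdbio.PDBFile.read(str(path))
            atoms = f.get_structure(model=1, altloc="first")
        elif fmt in ("mmcif", "cif"):
            f = pdbxio.CIFFile.read(str(path))
            atoms = pdbx_get(f, model=1, altloc="first")
        else:
            raise ValueError(f"unknown structure format: {fmt}")
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return AtomicStructure(
        element=np.asarray(atoms.element, dtype=object),
        atom_name=np.asarray(atoms.atom_name, dtype=object),
        res_name=np.asarray(atoms.res_name, dtype=object),
        res_id=np.asarray(atoms.res_id, dtype=int),
        chain_id=np.asarray(atoms.chain_id, dtype=object),
        coord=np.asarray(atoms.coord, dtype=float),
        hetero=np.asarray(atoms.hetero, dtype=bool),
    )


@dataclass
class BeadModel:
    """Coarse-grained bead table (positions in nm)."""

    kind: np.ndarray          # bead kind strings, keys of BEAD_RADII
    res_id: np.ndarray        # source residue index (1-based)
    chain_id: np.ndarray
    position: np.ndarray      # (n, 3) nm
    radius: np.ndarray        # sigma_i, nm
    mobile: np.ndarray        # bool

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.mobile = np.asarray(self.mobile, dtype=bool)

    def __len__(self):
        return len(self.kind)

    def subset(self, index) -> "BeadModel":
        index = np.asarray(index)
        return BeadModel(self.kind[index], self.res_id[index],
                         self.chain_id[index], self.position[index],
                         self.radius[index], self.mobile[index])

    def to_json(self, path) -> None:
        """Serialize to a self-describing JSON record (positions in nm)."""
        doc = {
            "units": {"length": "nm"},
            "beads": [
                {"kind": str(k), "res_id": int(r), "chain": str(c),
                 "position": [float(x) for x in p],
                 "radius": float(s), "mobile": bool(m)}
                for k, r, c, p, s, m in zip(
                    self.kind, self.res_id, self.chain_id, self.position,
                    self.radius, self.mobile)
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "BeadModel":
        doc = json.loads(Path(path).read_text())
        b = doc["beads"]
        return cls(
            kind=np.array([x["kind"] for x in b], dtype=object),
            res_id=np.array([x["res_id"] for x in b], dtype=int),
            chain_id=np.array([x["chain"] for x in b], dtype=object),
            position=np.array([x["position"] for x in b], dtype=float),
            radius=np.array([x["radius"] for x in b], dtype=float),
            mobile=np.array([x["mobile"] for x in b], dtype=bool),
        )


class CoarseGrainError(ValueError):
    """Raised with a per-residue listing of missing required atoms."""

    def __init__(self, missing):
        self.missing = missing
        lines = [f"  chain {ch} residue {rid} ({name}): missing {atoms}"
                 for ch, rid, name, atoms in missing]
        super().__init__("cannot coarse-grain; required atoms missing:\n"
                         + "\n".join(lines))


def coarse_grain(structure: AtomicStructure, selection=None) -> BeadModel:
    """Reduce an atomic structure to the bead representation.

    One protein-CA bead per amino-acid residue; P, C4' and N3 beads per RNA
    nucleotide.  ``selection`` optionally restricts to a set of chain ids.
    Positions are converted from Angstrom to nm.  Residues missing required
    atoms are reported together in a CoarseGrainError.
    """
    kinds, res_ids, chains, pos = [], [], [], []
    missing = []
    for ch, rid, name, idxs in structure.residues():
        if selection is not None and ch not in selection:
            continue
        names = structure.atom_name[idxs]
        if name in _AA3:
            ca = idxs[names == "CA"]
            if ca.size == 0:
                missing.append((ch, rid, name, ["CA"]))
                continue
            kinds.append("protein-CA")
            res_ids.append(rid)
            chains.append(ch)
            pos.append(structure.coord[ca[0]] / 10.0)
        elif name in _RNA_RESIDUES:
            need = {"rna-P": "P", "rna-C4p": "C4'", "rna-N3": "N3"}
            absent = [a for a in need.values() if not np.any(names == a)]
            if absent:
                missing.append((ch, rid, name, absent))
                continue
            for kind, atom in need.items():
                kinds.append(kind)
                res_ids.append(rid)
                chains.append(ch)
                pos.append(structure.coord[idxs[names == atom][0]] / 10.0)
        # other residues (water, ligands) are skipped
    if missing:
        raise CoarseGrainError(missing)
    radii = np.array([BEAD_RADII[k] for k in kinds])
    return BeadModel(
        kind=np.array(kinds, dtype=object),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chains, dtype=object),
        position=np.array(pos, dtype=float).reshape(-1, 3),
        radius=radii,
        mobile=np.zeros(len(kinds), dtype=bool),
    )


def write_ca_pdb(beads: BeadModel, path) -> None:
    """Write the protein-CA beads of a bead model as a C-alpha-only PDB.

    Positions are converted from nm back to Angstrom; useful for
    round-trip tests and for visualizing toy systems.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    sel = np.array([k == "protein-CA" for k in beads.kind])
    n = int(sel.sum())
    atoms = struc.AtomArray(n)
    atoms.coord = beads.position[sel] * 10.0
    atoms.atom_name = np.full(n, "CA", dtype="U6")
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.res_name = np.full(n, "ALA", dtype="U5")
    atoms.res_id = beads.res_id[sel].astype(int)
    atoms.chain_id = np.full(n, "A", dtype="U4")
    atoms.hetero = np.zeros(n, dtype=bool)
    f = pdbio.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


@dataclass
class TunnelAnnotation:
    """Exit-tunnel geometry: axis from the buried (PTC) end to the exit."""

    start: np.ndarray   # nm, buried end (near the tether anchor)
    exit: np.ndarray    # nm, tunnel exit into the cytosol

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)

    @property
    def axis(self) -> np.ndarray:
        v = self.exit - self.start
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.exit - self.start))


@dataclass
class RibosomeScaffold:
    """Immobile coarse beads of the large subunit (or a toy tunnel).

    ``anchor`` indexes the bead to which the nascent chain is tethered (the
    last P atom of the A-site tRNA in the real system; the buried-end axial
    bead of a toy tunnel).
    """

    beads: BeadModel
    anchor: int
    tunnel: TunnelAnnotation

    def __post_init__(self):
        if np.any(self.beads.mobile):
            raise ValueError("scaffold beads must all be immobile")
        if not (0 <= self.anchor < len(self.beads)):
            raise ValueError("anchor bead index out of range")

    @property
    def anchor_position(self) -> np.ndarray:
        return self.beads.position[self.anchor]


def _distance_to_segment(points, a, b):
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    proj = a + np.atleast_1d(t)[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def select_scaffold(beads: BeadModel, tunnel: TunnelAnnotation,
                    anchor: int, cutoff_radius: float = 2.0,
                    exit_cap_radius: float = 6.0) -> RibosomeScaffold:
    """Retain only scaffold beads near the exit tunnel.

    Keeps beads within ``cutoff_radius`` (nm) of the tunnel axis segment or
    within ``exit_cap_radius`` of the exit point (a hemispherical cap
    covering the ribosome surface a folding domain can touch).  The anchor
    bead is always retained; its index is remapped to the reduced set.
    Larger cutoffs retain supersets of smaller ones.
    """
    d_axis = _distance_to_segment(beads.position, tunnel.start, tunnel.exit)
    d_exit = np.linalg.norm(beads.position - tunnel.exit, axis=1)
    keep = (d_axis <= cutoff_radius) | (d_exit <= exit_cap_radius)
    keep[anchor] = True
    index = np.nonzero(keep)[0]
    new_anchor = int(np.searchsorted(index, anchor))
    sub = beads.subset(index)
    sub.mobile[:] = False
    return RibosomeScaffold(sub, new_anchor, tunnel)
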