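"""Protein structure container and PDB I/O.

The in-memory model is a light hierarchy (StructureModel -> Residue -> Atom) holding
Cartesian coordinates in Angstrom.  Parsing and serialisation go through gemmi;
alternate locations are resolved to the highest-occupancy conformer at read time and
multi-model (NMR) files default to the first MODEL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .params import STANDARD_AA, THREE_TO_ONE, atomic_masses

logger = logging.getLogger(__name__)

#: (chain_id, resnum, insertion_code) — the unique residue key.
ResidueKey = tuple[str, int, str]


class EmptyStructureError(ValueError):
    """Raised when a file contains no protein residues."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for {self.name}")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    resnum: int
    insertion_code: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resnum, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.resname in STANDARD_AA and not self.het

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.resname} {self.key}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.resnum, self.insertion_code,
                       self.resname, [a.copy() for a in self.atoms], self.het)


@dataclass
class StructureModel:
    identifier: str
    chains: dict[str, list[Residue]]
    resolution: float | None = None
    experimental_method: str | None = None

    def __post_init__(self) -> None:
        if not any(self.chains.values()):
            raise EmptyStructureError(f"structure {self.identifier!r} has no residues")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_standard]

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.chains.get(key[0], []):
            if r.resnum == key[1] and r.insertion_code == key[2]:
                return r
        raise KeyError(f"residue {key} not found")

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.resname, "X") for r in self.standard_residues())

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.identifier,
            {cid: [r.copy() for r in chain] for cid, chain in self.chains.items()},
            self.resolution, self.experimental_method)

    def transform(self, rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> "StructureModel":
        """Rigid-body transformed copy (rotation about the origin, then translation)."""
        out = self.copy()
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        for a in out.atoms():
            a.coords = R @ a.coords + t
        return out


def center_of_mass(atoms: list[Atom]) -> np.ndarray:
    """Mass-weighted mean position of a non-empty atom collection (Angstrom)."""
    if not atoms:
        raise ValueError("center_of_mass of an empty atom collection")
    masses = atomic_masses()
    w = np.array([masses[a.element.upper()] for a in atoms])
    xyz = np.array([a.coords for a in atoms])
    return (w[:, None] * xyz).sum(axis=0) / w.sum()


def residues_within(model: StructureModel, center: np.ndarray, radius: float,
                    standard_only: bool = True) -> list[Residue]:
    """Residues whose centre of mass lies strictly within ``radius`` of ``center``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, float)
    pool = model.standard_residues() if standard_only else model.residues()
    return [r for r in pool
            if np.linalg.norm(center_of_mass(r.atoms) - center) < radius]


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc letter."""
    by_name: dict[str, list[Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        out.append(best)
    return out


def read_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Selects one MODEL (default the first), resolves altlocs to the highest-occupancy
    conformer, drops hydrogens and waters, and flags HETATM / non-standard residues.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)})")
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name == "HOH":
                continue
            raw = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                raw.append(Atom(serial=at.serial, name=at.name,
                                element=(at.element.name or at.name[0]).upper(),
                                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                                occupancy=min(max(at.occ, 0.0), 1.0),
                                altloc=at.altloc if at.altloc != "\x00" else "",
                                bfactor=at.b_iso))
            if not raw:
                continue
            het = res.het_flag == "H"
            residues.append(Residue(chain.name, res.seqid.num, res.seqid.icode.strip(),
                                    res.name, _resolve_altlocs(raw),
                                    het=het or res.name not in STANDARD_AA))
        if residues:
            chains[chain.name] = residues

    if not any(r.is_standard for ch in chains.values() for r in ch):
        raise EmptyStructureError(f"{path} contains no protein residues")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method = dict(st.info.items()).get("_exptl.method") or None
    return StructureModel(identifier=st.name or path.stem, chains=chains,
                          resolution=resolution, experimental_method=method)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB ATOM/HETATM records (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = model.identifier
    if model.resolution is not None:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.resname
            gr.seqid = gemmi.SeqId(r.resnum, r.insertion_code or " ")
            gr.het_flag = "H" if r.het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc
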