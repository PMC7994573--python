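"""Bundled parameter tables: masses, vdW radii, LJ/charge sets, background frequencies.

All tables ship as plain-text TSV under :mod:`burion.data` and may be overridden by
passing an alternative path to the loader functions.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Gas constant / Boltzmann constant in kcal/(mol*K).
KB_KCAL = 1.987204e-3

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = tuple(sorted(THREE_TO_ONE))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("burion.data").joinpath(name)))


def _read_table(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    return rows


@functools.lru_cache(maxsize=None)
def atomic_masses(path: str | None = None) -> dict[str, float]:
    """Element -> mass in amu."""
    p = Path(path) if path else _data_path("atomic_masses.tsv")
    return {el.upper(): float(m) for el, m in _read_table(p)}


@functools.lru_cache(maxsize=None)
def vdw_radii(path: str | None = None) -> dict[str, float]:
    """Element -> van der Waals radius in Angstrom (united heavy atoms)."""
    p = Path(path) if path else _data_path("vdw_radii.tsv")
    return {el.upper(): float(r) for el, r in _read_table(p)}


@functools.lru_cache(maxsize=None)
def lj_params(path: str | None = None) -> dict[str, tuple[float, float]]:
    """Element -> (epsilon kcal/mol, Rmin/2 Angstrom)."""
    p = Path(path) if path else _data_path("lj_params.tsv")
    return {el.upper(): (float(e), float(r)) for el, e, r in _read_table(p)}


@functools.lru_cache(maxsize=None)
def sidechain_charges(path: str | None = None) -> dict[tuple[str, str], float]:
    """(resname, atom name) -> side-chain partial charge in e."""
    p = Path(path) if path else _data_path("charges.tsv")
    return {(res, atom): float(q) for res, atom, q in _read_table(p)}


#: Backbone partial charges (all residues): amide N with implicit H, CA, carbonyl.
BACKBONE_CHARGES = {"N": -0.16, "CA": 0.16, "C": 0.51, "O": -0.51}


@functools.lru_cache(maxsize=None)
def background_frequencies(path: str | None = None) -> dict[str, float]:
    """Residue -> background frequency (normalised to sum 1)."""
    p = Path(path) if path else _data_path("aa_background.tsv")
    raw = {res: float(f) for res, f in _read_table(p)}
    total = sum(raw.values())
    return {res: f / total for res, f in raw.items()}
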