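"""Low-level peptide building from ideal internal coordinates (backbone + templates)."""

from __future__ import annotations

import numpy as np

from . import geometry, templates
from .structure import Atom, Residue

# ideal backbone internal coordinates (Engh/Huber-like)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def make_atom(serial: int, name: str, pos: np.ndarray) -> Atom:
    return Atom(serial=serial, name=name, element=templates.element_of(name), coords=pos)


def peptide_chain(sequence: list[str], phi: float, psi: float, chain_id: str = "A",
                  start_resnum: int = 1, start_serial: int = 1,
                  chi_overrides: dict[int, dict[str, float]] | None = None,
                  ) -> list[Residue]:
    """Build a loopless peptide with uniform (phi, psi) and template side chains.

    ``chi_overrides`` maps 0-based residue index -> {atom name: dihedral deg}.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one residue")
    for rn in sequence:
        if rn not in templates.SIDECHAIN_ZMAT:
            raise ValueError(f"unknown residue code {rn!r}")
    residues: list[Residue] = []
    serial = start_serial
    prev = None
    for i, rn in enumerate(sequence):
        if prev is None:
            n = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            c = geometry.place_atom(np.array([-1.0, 1.0, 0.0]), n, ca,
                                    BOND_CA_C, ANGLE_N_CA_C, 0.0)
        else:
            pn, pca, pc = prev
            n = geometry.place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psi)
            ca = geometry.place_atom(pca, pc, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = geometry.place_atom(pc, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        o = geometry.place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        bb = {"N": n, "CA": ca, "C": c}
        atoms = [make_atom(serial + j, name, pos)
                 for j, (name, pos) in enumerate((("N", n), ("CA", ca), ("C", c), ("O", o)))]
        serial += 4
        overrides = (chi_overrides or {}).get(i)
        for name, pos in templates.build_sidechain(bb, rn, overrides):
            atoms.append(make_atom(serial, name, pos))
            serial += 1
        residues.append(Residue(chain_id, start_resnum + i, "", rn, atoms))
        prev = (n, ca, c)
    return residues


def chi1_variants(resname: str) -> list[dict[str, float] | None]:
    """Chi-override dicts for the three staggered chi1 rotamers.

    The first entry (None) is the template's own rotamer; the others rotate
    every atom placed directly off CB by +/-120 deg (branched side chains keep
    their mutual offsets).  Residues without a chi1 get the single template.
    """
    entries = templates.SIDECHAIN_ZMAT[resname]
    cb_children = [(name, dihed) for name, (_, _, c), _, _, dihed in entries
                   if c == "CB"]
    if not cb_children:
        return [None]
    variants: list[dict[str, float] | None] = [None]
    for delta in (120.0, -120.0):
        variants.append({name: dihed + delta for name, dihed in cb_children})
    return variants


def replace_sidechain(residue: Residue, new_resname: str,
                      chi_overrides: dict[str, float] | None = None) -> Residue:
    """Rebuild a residue with a template side chain for ``new_resname``.

    Backbone atoms (N, CA, C, O) are carried over bit-identically; the side chain
    is placed at the most-common rotamer unless chi overrides are given.
    """
    for name in ("N", "CA", "C", "O"):
        if not residue.has_atom(name):
            raise ValueError(
                f"residue {residue.key} lacks backbone atom {name}; cannot mutate")
    bb_atoms = [residue.atom(n).copy() for n in ("N", "CA", "C", "O")]
    bb = {a.name: a.coords for a in bb_atoms}
    serial = max(a.serial for a in bb_atoms) + 1
    atoms = bb_atoms[:]
    for name, pos in templates.build_sidechain(bb, new_resname, chi_overrides):
        atoms.append(make_atom(serial, name, pos))
        serial += 1
    return Residue(residue.chain_id, residue.resnum, residue.insertion_code,
                   new_resname, atoms, residue.het)
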