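"""Ideal internal-coordinate side-chain templates (heavy atoms, most-common rotamer).

Each side chain is defined as a Z-matrix: every atom is placed from three previously
built atoms by bond length (A), bond angle (deg) and dihedral (deg).  Chi dihedrals
are baked in at their most common rotameric values, so template building is fully
deterministic.  CB is placed with the L-configuration improper
dihedral(CB, CA, N, C) = -120 deg, matching ideal reference residue geometry.

Ring closures (Phe/Tyr/Trp/His/Pro) are approximate: ring atoms are chained through
the Z-matrix and the closing bond is recorded in :data:`EXTRA_BONDS` for the
exclusion topology, not re-idealised.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom

# (atom, (a, b, c), bond, angle, dihedral): atom is placed bonded to c.
ZMatEntry = tuple[str, tuple[str, str, str], float, float, float]

_CB: ZMatEntry = ("CB", ("C", "N", "CA"), 1.53, 110.5, -120.0)

SIDECHAIN_ZMAT: dict[str, list[ZMatEntry]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 110.5, -60.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 113.0, -60.0)],
    "THR": [_CB,
            ("OG1", ("N", "CA", "CB"), 1.42, 109.5, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, -180.0)],
    "VAL": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.52, 110.5, 175.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, -65.0)],
    "LEU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 116.3, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, 175.0),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, -65.0)],
    "ILE": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.53, 110.4, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 180.0),
            ("CD1", ("CA", "CB", "CG1"), 1.51, 113.8, 170.0)],
    "MET": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.9, 180.0)],
    "PRO": [_CB,
            ("CG", ("N", "CA", "CB"), 1.50, 104.5, 30.0),
            ("CD", ("CA", "CB", "CG"), 1.51, 106.1, -35.0)],
    "PHE": [_CB,
            ("CG", ("N", "CA", "CB"), 1.51, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.3, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.3, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.6, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.6, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [_CB,
            ("CG", ("N", "CA", "CB"), 1.51, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.3, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.3, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.6, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.6, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.36, 119.9, 180.0)],
    "TRP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.50, 113.6, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, -90.0),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, 90.0),
            ("NE1", ("CB", "CG", "CD1"), 1.37, 110.2, 180.0),
            ("CE2", ("CG", "CD1", "NE1"), 1.37, 109.0, 0.0),
            ("CE3", ("CD1", "CG", "CD2"), 1.40, 133.9, 180.0),
            ("CZ2", ("CD1", "NE1", "CE2"), 1.40, 128.8, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, 180.0),
            ("CH2", ("NE1", "CE2", "CZ2"), 1.37, 117.5, 180.0)],
    "HIS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.50, 113.8, -65.0),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, -75.0),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, 105.0),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
            ("NE2", ("CG", "ND1", "CE1"), 1.32, 108.4, 0.0)],
    "ASP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 112.6, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, -15.0),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, 165.0)],
    "ASN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 112.7, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, -60.0),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, 120.0)],
    "GLU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, -15.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, 165.0)],
    "GLN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.7, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, -60.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, 120.0)],
    "LYS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, 180.0)],
    "ARG": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
}

#: Ring-closure / cyclisation bonds not implied by the Z-matrix parent chain.
EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("CE2", "CD2"), ("CH2", "CZ3")],
    "HIS": [("NE2", "CD2")],
    "PRO": [("CD", "N")],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Side-chain atoms carrying the formal charge, per charged residue type.
CHARGED_GROUP_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}


def sidechain_atom_names(resname: str) -> list[str]:
    if resname not in SIDECHAIN_ZMAT:
        raise KeyError(f"no side-chain template for residue {resname!r}")
    return [e[0] for e in SIDECHAIN_ZMAT[resname]]


def build_sidechain(backbone: dict[str, np.ndarray], resname: str,
                    chi_overrides: dict[str, float] | None = None,
                    ) -> list[tuple[str, np.ndarray]]:
    """Build side-chain heavy atoms from backbone coordinates.

    Parameters
    ----------
    backbone : dict with at least N, CA, C coordinates (3-vectors).
    resname : standard 3-letter code.
    chi_overrides : optional map atom-name -> dihedral (deg) replacing the
        template value for that placement (used for rotamer searches).

    Returns the placed atoms in build order.
    """
    coords: dict[str, np.ndarray] = {k: np.asarray(v, float) for k, v in backbone.items()}
    out: list[tuple[str, np.ndarray]] = []
    for name, (a, b, c), bond, ang, dihed in SIDECHAIN_ZMAT[resname]:
        if chi_overrides and name in chi_overrides:
            dihed = chi_overrides[name]
        pos = place_atom(coords[a], coords[b], coords[c], bond, ang, dihed)
        coords[name] = pos
        out.append((name, pos))
    return out


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Intra-residue heavy-atom bond list (backbone + side chain + closures)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for name, (_, _, parent), *_ in SIDECHAIN_ZMAT.get(resname, []):
        bonds.append((parent, name))
    bonds.extend(EXTRA_BONDS.get(resname, []))
    return bonds


def element_of(atom_name: str) -> str:
    """Element symbol from a standard PDB protein heavy-atom name."""
    return atom_name.strip()[0].upper()
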