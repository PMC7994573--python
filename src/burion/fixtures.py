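"""Synthetic inputs for every pipeline: ideal helical bundles with implanted
ion-pairs, composition-biased structure sets, two-state unfolding curves, and
spin-relaxation tables with known ground truth.

All generators are deterministic per seed and return their ground truth
alongside the data.  Bundles are loopless multi-chain four-helix scaffolds that
emulate the geometry class of minimal de novo helical proteins, not any
deposited model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import builder, geometry, ionpairs, templates
from .params import KB_KCAL, STANDARD_AA, background_frequencies
from .structure import Residue, StructureModel, center_of_mass
from .unfolding import UnfoldingCurve

#: chi-defining atom groups per residue type; atoms in one group rotate together
#: (their template dihedrals keep a fixed mutual offset).
CHI_GROUPS: dict[str, list[tuple[str, ...]]] = {
    "GLU": [("CG",), ("CD",), ("OE1", "OE2")],
    "ASP": [("CG",), ("OD1", "OD2")],
    "LYS": [("CG",), ("CD",), ("CE",), ("NZ",)],
    "ARG": [("CG",), ("CD",), ("NE",), ("CZ",)],
    "GLN": [("CG",), ("CD",), ("OE1", "NE2")],
    "ASN": [("CG",), ("OD1", "ND2")],
}


def build_ideal_helix(sequence: list[str], phi: float = -57.0, psi: float = -47.0,
                      chain_id: str = "A") -> StructureModel:
    """Ideal alpha-helix from internal coordinates (default phi/psi -57/-47)."""
    if len(sequence) < 3:
        raise ValueError("helix needs at least three residues")
    residues = builder.peptide_chain(list(sequence), phi, psi, chain_id)
    return StructureModel(identifier="ideal-helix", chains={chain_id: residues})


@dataclass
class BundleSpec:
    n_helices: int = 4
    residues_per_helix: int = 17
    bundle_radius: float = 7.5           # A, helix axes from the bundle axis
    sequence: list[str] | None = None    # per-helix sequence; default poly-Leu
    ion_pair_positions: list[tuple[int, int, str]] = field(default_factory=list)
    phi: float = -57.0
    psi: float = -47.0
    rng_seed: int = 0

    def helix_sequence(self, h: int) -> list[str]:
        seq = list(self.sequence) if self.sequence is not None \
            else ["LEU"] * self.residues_per_helix
        for helix, idx, resname in self.ion_pair_positions:
            if helix == h:
                if not 0 <= idx < len(seq):
                    raise ValueError(f"ion-pair position {idx} outside helix bounds")
                seq[idx] = resname
        return seq


def _helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit axis (unit vector, centroid) through CA coordinates."""
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    u = vt[0]
    if np.dot(ca[-1] - ca[0], u) < 0:
        u = -u
    return u, centroid


def _facing_index(spec: BundleSpec, h: int) -> int:
    for helix, idx, _ in spec.ion_pair_positions:
        if helix == h:
            return idx
    return spec.residues_per_helix // 2


def build_bundle(spec: BundleSpec | None = None) -> StructureModel:
    """Antiparallel-alternating helical bundle on a circle of ``bundle_radius``.

    Each helix is rotated about its own axis so the facing residue (the implanted
    position, else the midpoint) points at the bundle axis, and shifted so facing
    residues share z = 0.  Implanted acidic/basic side chains are then snapped
    into contact by a deterministic rotamer search.
    """
    spec = spec or BundleSpec()
    chain_ids = [chr(ord("A") + h) for h in range(spec.n_helices)]
    chains: dict[str, list[Residue]] = {}
    serial = 1
    for h in range(spec.n_helices):
        seq = spec.helix_sequence(h)
        residues = builder.peptide_chain(seq, spec.phi, spec.psi, chain_ids[h],
                                         start_serial=serial)
        serial += sum(len(r.atoms) for r in residues)
        coords = np.array([r.atom("CA").coords for r in residues])
        u, centroid = _helix_axis(coords)
        R1 = geometry.align_vectors(u, np.array([0.0, 0.0, 1.0]))
        if h % 2 == 1:  # antiparallel alternation
            R1 = geometry.rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi) @ R1

        def apply(R, t=np.zeros(3)):
            for r in residues:
                for a in r.atoms:
                    a.coords = R @ (a.coords - centroid) + t

        apply(R1)
        centroid = np.zeros(3)

        # azimuth: the facing residue's CA sits on the inward side of the helix
        face = residues[_facing_index(spec, h)]
        v = face.atom("CA").coords.copy()
        v[2] = 0.0
        theta_h = 2.0 * np.pi * h / spec.n_helices
        target = -np.array([np.cos(theta_h), np.sin(theta_h), 0.0])
        if np.linalg.norm(v) > 1e-9:
            ang = np.arctan2(target[1], target[0]) - np.arctan2(v[1], v[0])
            apply(geometry.rotation_about_axis(np.array([0.0, 0.0, 1.0]), ang))
        pos = spec.bundle_radius * np.array([np.cos(theta_h), np.sin(theta_h), 0.0])
        shift = np.array([pos[0], pos[1], -face.atom("CA").coords[2]])
        apply(np.eye(3), shift)
        chains[chain_ids[h]] = residues

    model = StructureModel(identifier="synthetic-bundle", chains=chains)
    _check_backbone_clashes(model, spec)
    if len(spec.ion_pair_positions) >= 2:
        _snap_ion_pairs(model, spec, chain_ids)
    return model


def ca_mean(residues: list[Residue]) -> np.ndarray:
    return np.array([r.atom("CA").coords for r in residues]).mean(axis=0)


def _check_backbone_clashes(model: StructureModel, spec: BundleSpec) -> None:
    chains = list(model.chains.values())
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            ca_i = np.array([r.atom("CA").coords for r in chains[i]])
            ca_j = np.array([r.atom("CA").coords for r in chains[j]])
            d = np.linalg.norm(ca_i[:, None] - ca_j[None, :], axis=-1)
            if d.min() < 3.0:
                raise ValueError(
                    f"backbone clash between helices ({d.min():.2f} A CA-CA); "
                    f"increase bundle_radius above {spec.bundle_radius} A")


def _chi_atom_offsets(resname: str) -> list[list[tuple[str, float]]]:
    """Per chi group: (atom, dihedral offset relative to the group's first atom)."""
    zmat = {e[0]: e[4] for e in templates.SIDECHAIN_ZMAT[resname]}
    groups = []
    for group in CHI_GROUPS[resname]:
        base = zmat[group[0]]
        groups.append([(a, zmat[a] - base) for a in group])
    return groups


def _snap_ion_pairs(model: StructureModel, spec: BundleSpec,
                    chain_ids: list[str]) -> None:
    """Deterministic greedy rotamer search bringing implanted acidic/basic
    side chains to a ~2.8 A O-N contact."""
    implants = [(chain_ids[h], idx + 1, resname)
                for h, idx, resname in spec.ion_pair_positions]
    acidic = [(c, n) for c, n, rn in implants if rn in ("GLU", "ASP")]
    basic = [(c, n) for c, n, rn in implants if rn in ("LYS", "ARG")]
    if not acidic or not basic:
        return

    other_xyz = []
    implant_keys = {(c, n, "") for c, n, _ in implants}
    for r in model.residues():
        if r.key not in implant_keys:
            other_xyz.append(r.coords())
    other = np.vstack(other_xyz)

    def contact_atoms(res: Residue) -> np.ndarray:
        names = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"),
                 "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}[res.resname]
        return np.array([res.atom(n).coords for n in names])

    def objective() -> float:
        total = 0.0
        for (ca_, na_) in acidic:
            ra = model.residue((ca_, na_, ""))
            best = np.inf
            for (cb_, nb_) in basic:
                rb = model.residue((cb_, nb_, ""))
                d = np.linalg.norm(contact_atoms(ra)[:, None]
                                   - contact_atoms(rb)[None, :], axis=-1).min()
                best = min(best, d)
            total += (best - 2.8) ** 2
        # clash penalty of implant side chains against the rest
        for c_, n_, rn in implants:
            res = model.residue((c_, n_, ""))
            sc = np.array([a.coords for a in res.atoms
                           if a.name not in templates.BACKBONE_ATOMS])
            d = np.linalg.norm(sc[:, None] - other[None, :], axis=-1)
            overlap = np.clip(2.6 - d, 0.0, None)
            total += 2.0 * float((overlap ** 2).sum())
        return total

    current_chis: dict[tuple[str, int], dict[str, float]] = {}
    for c_, n_, rn in implants:
        zmat = {e[0]: e[4] for e in templates.SIDECHAIN_ZMAT[rn]}
        current_chis[(c_, n_)] = {g[0]: zmat[g[0]] for g in CHI_GROUPS[rn]}

    def rebuild(c_, n_, rn) -> None:
        chis = current_chis[(c_, n_)]
        overrides: dict[str, float] = {}
        for group in _chi_atom_offsets(rn):
            base_atom = group[0][0]
            for atom, off in group:
                overrides[atom] = chis[base_atom] + off
        chain = model.chains[c_]
        for i, r in enumerate(chain):
            if r.key == (c_, n_, ""):
                chain[i] = builder.replace_sidechain(r, rn, overrides)
                return

    grid = np.arange(-180.0, 180.0, 15.0)
    for _sweep in range(3):
        for c_, n_, rn in implants:
            for group in CHI_GROUPS[rn]:
                base_atom = group[0]
                best_val = current_chis[(c_, n_)][base_atom]
                best_obj = np.inf
                for v in grid:
                    current_chis[(c_, n_)][base_atom] = float(v)
                    rebuild(c_, n_, rn)
                    obj = objective()
                    if obj < best_obj - 1e-12:
                        best_obj = obj
                        best_val = float(v)
                current_chis[(c_, n_)][base_atom] = best_val
                rebuild(c_, n_, rn)


def glu_lys_bundle(spec: BundleSpec | None = None,
                   ) -> tuple[StructureModel, "ionpairs.IonPair"]:
    """Default four-helix fixture with one buried Glu/Lys pair, plus the detected pair."""
    if spec is None:
        spec = BundleSpec(ion_pair_positions=[(0, 8, "GLU"), (1, 8, "LYS")])
    model = build_bundle(spec)
    pairs = ionpairs.detect_ion_pairs(model)
    if not pairs:
        raise RuntimeError("fixture bundle failed to form an ion-pair contact")
    pairs.sort(key=lambda p: p.min_contact_distance)
    return model, pairs[0]


def synth_neighbor_dataset(n_structures: int,
                           composition_bias: dict[str, float] | None = None,
                           rng_seed: int = 0, r_thr: float = 15.0,
                           spec: BundleSpec | None = None,
                           ) -> tuple[list[StructureModel], dict]:
    """Bundles whose residues near the implanted pair follow a biased composition.

    Residues (other than the pair) with centre of mass inside ``r_thr`` of the
    pair centre are drawn from background frequencies multiplied by
    ``composition_bias`` (renormalised); the rest from the plain background.
    Returns the models and a ground-truth record (bias, background, pair keys).
    """
    composition_bias = composition_bias or {}
    if any(v <= 0 for v in composition_bias.values()):
        raise ValueError("composition multipliers must be positive")
    base_model, pair = glu_lys_bundle(spec)
    bg = background_frequencies()
    aas = list(STANDARD_AA)
    p_bg = np.array([bg[a] for a in aas])
    p_near = np.array([bg[a] * composition_bias.get(a, 1.0) for a in aas])
    p_near /= p_near.sum()

    rng = np.random.default_rng(rng_seed)
    pair_keys = {pair.acidic, pair.basic}
    near_keys = {r.key for r in base_model.standard_residues()
                 if r.key not in pair_keys
                 and np.linalg.norm(center_of_mass(r.atoms) - pair.pair_com) < r_thr}
    models = []
    for s in range(n_structures):
        m = base_model.copy()
        m.identifier = f"synthetic-neighbors-{s}"
        m.resolution = 2.0
        for cid, chain in m.chains.items():
            for i, res in enumerate(chain):
                if res.key in pair_keys:
                    continue
                p = p_near if res.key in near_keys else p_bg
                new = aas[rng.choice(len(aas), p=p)]
                if new != res.resname:
                    chain[i] = builder.replace_sidechain(res, new)
        models.append(m)
    truth = {"bias": dict(composition_bias), "background": {a: bg[a] for a in aas},
             "p_near": {a: float(v) for a, v in zip(aas, p_near)},
             "pair": (pair.acidic, pair.basic), "r_thr": r_thr,
             "rng_seed": rng_seed}
    return models, truth


def synth_unfolding_curve(dG0: float, m: float, y_N: float = -20.0,
                          y_D: float = -2.0, noise_sd: float = 0.0,
                          conc_grid: np.ndarray | None = None,
                          temperature: float = 293.15,
                          rng_seed: int = 0) -> UnfoldingCurve:
    """Two-state chemical unfolding curve with known (dG0, m-value).

    f_D(c) = 1/(1 + exp((dG0 - m*c)/(R*T))); y = y_N + f_D*(y_D - y_N) + noise.
    """
    if m <= 0:
        raise ValueError("m-value must be positive")
    if conc_grid is None:
        conc_grid = np.linspace(0.0, 8.0, 33)
    conc_grid = np.asarray(conc_grid, float)
    f_d = 1.0 / (1.0 + np.exp((dG0 - m * conc_grid) / (KB_KCAL * temperature)))
    y = y_N + f_d * (y_D - y_N)
    if noise_sd > 0:
        y = y + np.random.default_rng(rng_seed).normal(0.0, noise_sd, y.shape)
    # the generator knows its baselines; they ride along as ground truth
    return UnfoldingCurve(x=conc_grid, y=y, y_N=y_N, y_D=y_D,
                          temperature=temperature)


def synth_melting_curve(tm: float, slope: float = 2.5, y_N: float = -20.0,
                        y_D: float = -2.0, noise_sd: float = 0.0,
                        temp_grid: np.ndarray | None = None,
                        rng_seed: int = 0) -> UnfoldingCurve:
    """Sigmoidal thermal melt with known midpoint (same axis units as temp_grid)."""
    if temp_grid is None:
        temp_grid = np.linspace(20.0, 100.0, 41)
    temp_grid = np.asarray(temp_grid, float)
    y = y_N + (y_D - y_N) / (1.0 + np.exp((tm - temp_grid) / slope))
    if noise_sd > 0:
        y = y + np.random.default_rng(rng_seed).normal(0.0, noise_sd, y.shape)
    return UnfoldingCurve(x=temp_grid, y=y)


def synth_relaxation_table(n_residues: int = 20,
                           T1_range: tuple[float, float] = (0.4, 0.8),
                           T1rho_range: tuple[float, float] = (0.05, 0.15),
                           spinlock_khz: float = 1.5,
                           offset_range_hz: tuple[float, float] = (-600.0, 600.0),
                           error_frac: float = 0.0,
                           rng_seed: int = 0) -> pd.DataFrame:
    """Random physical relaxation records with ground-truth T2 (column T2_true)."""
    from .relax import RelaxationRecord, t2_from_t1rho
    if min(T1_range) <= 0 or min(T1rho_range) <= 0 or spinlock_khz <= 0:
        raise ValueError("ranges and spin-lock amplitude must be positive")
    rng = np.random.default_rng(rng_seed)
    t1 = rng.uniform(*T1_range, n_residues)
    t1r = rng.uniform(*T1rho_range, n_residues)
    off = rng.uniform(*offset_range_hz, n_residues)
    rows = []
    for i in range(n_residues):
        rec = RelaxationRecord.from_lab_units(
            label=f"R{i+1}", T1=t1[i], T1rho=t1r[i],
            spinlock_khz=spinlock_khz, offset_hz=off[i])
        rows.append({"residue": f"R{i+1}", "T1": t1[i],
                     "T1_err": error_frac * t1[i],
                     "T1rho": t1r[i], "T1rho_err": error_frac * t1r[i],
                     "offset_hz": off[i], "T2_true": t2_from_t1rho(rec)})
    return pd.DataFrame(rows)
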