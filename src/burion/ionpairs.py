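"""Ion-pair detection, burial classification, and microenvironment statistics.

A salt bridge is recorded whenever any listed acidic side-chain oxygen lies within
the contact cutoff of any listed basic side-chain nitrogen (default 3.2 A, the
common plugin default).  Around each pair the residues within a threshold-radius
sphere of the pair's charged-group centre of mass are counted, and occurrence
probabilities computed as

    p_aa(r_thr) = N_aa(r_thr) / sum_i N_i(r_thr)

pooled over all pairs.  Enrichments divide these probabilities by a background
amino-acid frequency (dataset-wide unless supplied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import STANDARD_AA
from .sasa import relative_sasa
from .structure import Residue, ResidueKey, StructureModel, center_of_mass

logger = logging.getLogger(__name__)

DEFAULT_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
DEFAULT_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_BASIC_ATOMS = {"HIS": ("ND1", "NE2")}

#: atoms defining the charged-group centre of mass of a pair member
CHARGED_GROUP = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}


@dataclass
class IonPairConfig:
    contact_cutoff: float = 3.2              # A, O-N
    acidic_atoms: dict = field(default_factory=lambda: dict(DEFAULT_ACIDIC_ATOMS))
    basic_atoms: dict = field(default_factory=lambda: dict(DEFAULT_BASIC_ATOMS))
    include_his: bool = False
    resolution_cutoff: float = 3.5           # A, strict <
    sphere_radius: float = 15.0              # A, r_thr
    burial_rel_sasa: float = 0.2
    count_pair_members: bool = False

    def __post_init__(self) -> None:
        for v in (self.contact_cutoff, self.resolution_cutoff,
                  self.sphere_radius, self.burial_rel_sasa):
            if v <= 0:
                raise ValueError("all cutoffs must be positive")
        if not self.acidic_atoms or not self.basic_atoms:
            raise ValueError("atom maps must be non-empty")
        if self.include_his and "HIS" not in self.basic_atoms:
            self.basic_atoms = {**self.basic_atoms, **HIS_BASIC_ATOMS}


@dataclass
class IonPair:
    acidic: ResidueKey
    basic: ResidueKey
    acidic_resname: str
    basic_resname: str
    min_contact_distance: float
    pair_com: np.ndarray
    buried: bool | None = None

    @property
    def pair_type(self) -> str:
        return f"{self.acidic_resname}-{self.basic_resname}"


@dataclass
class NeighborCounts:
    r_thr: float
    counts: dict[str, int]
    n_pairs_pooled: int


@dataclass
class ProbabilityProfile:
    r_thr: float
    p: dict[str, float]
    background: dict[str, float] | None = None


def filter_dataset(models: list[StructureModel],
                   config: IonPairConfig | None = None) -> list[StructureModel]:
    """Keep structures with a known resolution strictly below the cutoff."""
    config = config or IonPairConfig()
    kept, dropped = [], 0
    for m in models:
        if m.resolution is not None and m.resolution < config.resolution_cutoff:
            kept.append(m)
        else:
            dropped += 1
    logger.info("filter_dataset: kept %d, dropped %d (resolution < %.2f A)",
                len(kept), dropped, config.resolution_cutoff)
    return kept


def _charged_group_atoms(res: Residue) -> list:
    names = CHARGED_GROUP.get(res.resname, ())
    return [res.atom(n) for n in names if res.has_atom(n)]


def detect_ion_pairs(model: StructureModel,
                     config: IonPairConfig | None = None) -> list[IonPair]:
    """All acidic/basic residue combinations with an O-N contact under the cutoff."""
    config = config or IonPairConfig()
    acidic = [r for r in model.standard_residues() if r.resname in config.acidic_atoms]
    basic = [r for r in model.standard_residues() if r.resname in config.basic_atoms]
    pairs: list[IonPair] = []
    for ra in acidic:
        o_atoms = [ra.atom(n) for n in config.acidic_atoms[ra.resname] if ra.has_atom(n)]
        if not o_atoms:
            continue
        o_xyz = np.array([a.coords for a in o_atoms])
        for rb in basic:
            n_atoms = [rb.atom(n) for n in config.basic_atoms[rb.resname] if rb.has_atom(n)]
            if not n_atoms:
                continue
            n_xyz = np.array([a.coords for a in n_atoms])
            d = np.linalg.norm(o_xyz[:, None, :] - n_xyz[None, :, :], axis=-1)
            dmin = float(d.min())
            if dmin < config.contact_cutoff:
                group = _charged_group_atoms(ra) + _charged_group_atoms(rb)
                pairs.append(IonPair(
                    acidic=ra.key, basic=rb.key,
                    acidic_resname=ra.resname, basic_resname=rb.resname,
                    min_contact_distance=dmin,
                    pair_com=center_of_mass(group)))
    return pairs


def classify_burial(pair: IonPair, model: StructureModel,
                    config: IonPairConfig | None = None,
                    rel_sasa: dict[ResidueKey, float] | None = None) -> IonPair:
    """Set ``buried`` = both members' relative SASA below the burial threshold.

    ``rel_sasa`` may be supplied to reuse a precomputed accessibility map.
    """
    config = config or IonPairConfig()
    if rel_sasa is None:
        rel_sasa = relative_sasa(model)
    for key, resname in ((pair.acidic, pair.acidic_resname),
                         (pair.basic, pair.basic_resname)):
        if key not in rel_sasa:
            raise KeyError(f"no relative-SASA reference for residue {resname} {key}")
    pair.buried = (rel_sasa[pair.acidic] < config.burial_rel_sasa
                   and rel_sasa[pair.basic] < config.burial_rel_sasa)
    return pair


def neighbor_counts(model: StructureModel, pairs: list[IonPair], r_thr: float,
                    config: IonPairConfig | None = None) -> NeighborCounts:
    """Residue-type counts within r_thr of each pair's centre, pooled over pairs.

    Membership is by residue centre of mass, strictly inside the sphere; the two
    pair members themselves are excluded unless the config says otherwise.
    """
    if r_thr <= 0:
        raise ValueError("r_thr must be positive")
    config = config or IonPairConfig()
    counts: dict[str, int] = {}
    residues = model.standard_residues()
    coms = np.array([center_of_mass(r.atoms) for r in residues]) if residues else np.zeros((0, 3))
    for pair in pairs:
        d = np.linalg.norm(coms - pair.pair_com, axis=1)
        for r, dist in zip(residues, d):
            if dist >= r_thr:
                continue
            if not config.count_pair_members and r.key in (pair.acidic, pair.basic):
                continue
            counts[r.resname] = counts.get(r.resname, 0) + 1
    return NeighborCounts(r_thr=r_thr, counts=counts, n_pairs_pooled=len(pairs))


def pool_counts(parts: list[NeighborCounts]) -> NeighborCounts:
    """Sum neighbour counts over structures (same r_thr)."""
    if not parts:
        raise ValueError("nothing to pool")
    r_thr = parts[0].r_thr
    if any(abs(p.r_thr - r_thr) > 1e-9 for p in parts):
        raise ValueError("cannot pool counts at different threshold radii")
    counts: dict[str, int] = {}
    n = 0
    for p in parts:
        n += p.n_pairs_pooled
        for aa, c in p.counts.items():
            counts[aa] = counts.get(aa, 0) + c
    return NeighborCounts(r_thr=r_thr, counts=counts, n_pairs_pooled=n)


def probability_profile(counts: NeighborCounts) -> ProbabilityProfile:
    """Occurrence probabilities p_aa = N_aa / sum_i N_i."""
    total = sum(counts.counts.values())
    if total == 0:
        raise ValueError("all neighbour counts are zero; no profile can be formed")
    p = {aa: c / total for aa, c in counts.counts.items()}
    return ProbabilityProfile(r_thr=counts.r_thr, p=p)


def background_frequencies_of(models: list[StructureModel]) -> dict[str, float]:
    """Amino-acid frequency over all standard residues of a structure set."""
    counts: dict[str, int] = {}
    for m in models:
        for r in m.standard_residues():
            counts[r.resname] = counts.get(r.resname, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues in dataset")
    return {aa: c / total for aa, c in counts.items()}


def enrichment_profile(profile: ProbabilityProfile,
                       background: dict[str, float]) -> dict[str, float]:
    """Per-amino-acid ratio p_aa / background_aa."""
    ssum = sum(background.values())
    if abs(ssum - 1.0) > 1e-6:
        raise ValueError(f"background frequencies must be normalised (sum={ssum:.6f})")
    out = {}
    for aa, p in profile.p.items():
        bg = background.get(aa, 0.0)
        if bg <= 0:
            raise ValueError(f"background frequency for {aa} is zero; ratio undefined")
        out[aa] = p / bg
    return out


def stratify_by_pair_type(model: StructureModel, pairs: list[IonPair], r_thr: float,
                          config: IonPairConfig | None = None,
                          ) -> dict[str, ProbabilityProfile]:
    """Independent probability profiles per pair type (GLU-LYS, ASP-ARG, ...)."""
    by_type: dict[str, list[IonPair]] = {}
    for p in pairs:
        by_type.setdefault(p.pair_type, []).append(p)
    out = {}
    for ptype, plist in by_type.items():
        nc = neighbor_counts(model, plist, r_thr, config)
        if sum(nc.counts.values()) > 0:
            out[ptype] = probability_profile(nc)
    return out


def profile_as_rows(profile: ProbabilityProfile,
                    counts: NeighborCounts | None = None,
                    background: dict[str, float] | None = None,
                    enrichment: dict[str, float] | None = None) -> list[dict]:
    """Tabular view (one row per amino acid) for TSV output."""
    rows = []
    for aa in STANDARD_AA:
        rows.append({
            "aa": aa,
            "count": counts.counts.get(aa, 0) if counts else None,
            "p": profile.p.get(aa, 0.0),
            "background": background.get(aa) if background else None,
            "enrichment": enrichment.get(aa) if enrichment else None,
        })
    return rows
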