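"""Directed Monte Carlo design of the surroundings of a buried ion-pair.

Each step proposes a random point mutation in a design region around the charged
element, rebuilds the side chain from ideal templates, relaxes it against the
fixed remainder of the protein, re-scores the structure with the weighted
nonbonded score, and accepts or rejects by the Metropolis criterion at the
design temperature (default 310 K).  Every random draw is logged so trajectories
replay bit-for-bit from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import energy
from .builder import chi1_variants, replace_sidechain
from .ionpairs import IonPair
from .params import KB_KCAL, STANDARD_AA, atomic_masses
from .structure import ResidueKey, StructureModel, center_of_mass
from .templates import build_sidechain, element_of


def _mass_of(atom_name: str) -> float:
    return atomic_masses()[element_of(atom_name)]

#: polar + charged residue classes (the charge-compatible substitution set)
POLAR_CHARGED = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS",
                           "GLN", "ASN", "SER", "THR", "TYR"})
AMPHIPHILE_CLASSES = {
    "gln_asn": frozenset({"GLN", "ASN"}),
    "tyr": frozenset({"TYR"}),
    "ser_thr": frozenset({"SER", "THR"}),
}
HYDROPHOBIC = frozenset(STANDARD_AA) - POLAR_CHARGED


class ConfigurationError(ValueError):
    pass


@dataclass
class DesignConfig:
    design_region: list[ResidueKey] | tuple | None = None  # keys or (center, radius)
    weights: tuple[float, float, float] = energy.DEFAULT_WEIGHTS
    temperature: float = 310.0              # K
    n_steps: int = 60
    minimize_steps: int = 5000
    restraint_k: float = 1.0                # kcal/mol/A^2 backbone tether
    rng_seed: int = 0
    excluded_targets: frozenset[str] = frozenset()
    forbid_mutating_pair: bool = True
    shell_radius: float = 6.0               # A, "first solvation sphere" for statistics
    relax_radius: float = 0.0               # also relax side chains within this radius
    relax_pair: bool = True                 # relax the pair side chains in-loop
    rotamer_search: bool = False            # try all three staggered chi1 rotamers
    minimize_tol: float = 0.1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        bad = set(self.excluded_targets) - set(STANDARD_AA)
        if bad:
            raise ConfigurationError(f"unknown excluded targets: {sorted(bad)}")


@dataclass
class Mutation:
    residue: ResidueKey
    from_resname: str
    to_resname: str

    def __post_init__(self) -> None:
        if self.from_resname == self.to_resname:
            raise ValueError("mutation must change the residue type")
        for rn in (self.from_resname, self.to_resname):
            if rn not in STANDARD_AA:
                raise ValueError(f"non-standard residue code {rn!r}")


@dataclass
class DesignStep:
    index: int
    mutation: Mutation
    score_before: energy.ScoreBreakdown
    score_after: energy.ScoreBreakdown
    accepted: bool
    acceptance_probability: float
    random_draw: float
    dist_to_pair: float     # A, mutated-residue COM to pair COM after relaxation


@dataclass
class DesignTrajectory:
    config: DesignConfig
    pair: IonPair
    start_sequence: str
    start_resnames: dict[ResidueKey, str] = field(default_factory=dict)
    steps: list[DesignStep] = field(default_factory=list)
    final_model: StructureModel | None = None
    final_sequence: str = ""


def resolve_design_region(model: StructureModel, pair: IonPair,
                          config: DesignConfig) -> list[ResidueKey]:
    """Expand the configured design region into residue keys."""
    region = config.design_region
    pair_keys = {pair.acidic, pair.basic}
    if region is None:
        # default: the pair's immediate surroundings
        region = (pair.pair_com, 8.0)
    if isinstance(region, tuple) and len(region) == 2 and not isinstance(region[0], str):
        center, radius = np.asarray(region[0], float), float(region[1])
        keys = [r.key for r in model.standard_residues()
                if np.linalg.norm(center_of_mass(r.atoms) - center) < radius]
    else:
        keys = list(region)  # explicit keys
    if config.forbid_mutating_pair:
        keys = [k for k in keys if k not in pair_keys]
    if not keys:
        raise ConfigurationError("design region is empty")
    return keys


def propose_mutation(model: StructureModel, region: list[ResidueKey],
                     config: DesignConfig, rng: np.random.Generator) -> Mutation:
    """Uniform position over the region; uniform target over the other 19 types."""
    if not region:
        raise ConfigurationError("design region is empty")
    key = region[rng.integers(len(region))]
    res = model.residue(key)
    targets = [aa for aa in STANDARD_AA
               if aa != res.resname and aa not in config.excluded_targets]
    if not targets:
        raise ConfigurationError("no mutation targets remain after exclusions")
    to = targets[rng.integers(len(targets))]
    return Mutation(residue=key, from_resname=res.resname, to_resname=to)


def apply_mutation(model: StructureModel, mutation: Mutation,
                   chi_overrides: dict[str, float] | None = None) -> StructureModel:
    """Swap the side chain at one position using the ideal template rotamer.

    Backbone atoms are carried over bit-identically; requires an intact backbone.
    """
    out = model.copy()
    chain = out.chains[mutation.residue[0]]
    for i, res in enumerate(chain):
        if res.key == mutation.residue:
            if res.resname != mutation.from_resname:
                raise ValueError(
                    f"residue {res.key} is {res.resname}, expected {mutation.from_resname}")
            chain[i] = replace_sidechain(res, mutation.to_resname, chi_overrides)
            return out
    raise KeyError(f"residue {mutation.residue} not found")


def metropolis_accept(delta_score: float, temperature: float,
                      rng: np.random.Generator) -> tuple[bool, float, float]:
    """Metropolis rule: accept with probability min(1, exp(-delta/kB*T)).

    Returns (accepted, probability, uniform draw) so decisions replay exactly.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    arg = -delta_score / (KB_KCAL * temperature)
    prob = 1.0 if arg >= 0 else float(np.exp(arg))
    draw = float(rng.random())
    return draw < prob, prob, draw


def run_design(model: StructureModel, pair: IonPair,
               config: DesignConfig) -> DesignTrajectory:
    """Run one directed-design trajectory (deterministic given config.rng_seed).

    Per step: propose a mutation, rebuild the side chain from its template
    (optionally trying all three staggered chi1 rotamers), relax the movable
    side chains against the fixed remainder, score, and accept by the
    Metropolis criterion.  The reference state is relaxed under identical
    settings before comparison, so the score difference carries no relaxation
    asymmetry.  Rejected steps leave the current model untouched.
    """
    rng = np.random.default_rng(config.rng_seed)
    region = resolve_design_region(model, pair, config)
    weights = energy.normalise_weights(config.weights)
    pair_keys = [pair.acidic, pair.basic]

    current = model.copy()
    cur_sys = energy.ParameterizedSystem(current)
    score_cur = energy.design_score(current, pair, weights=weights, system=cur_sys)
    e_total_cur = score_cur.e_total
    traj = DesignTrajectory(config=config, pair=pair,
                            start_sequence=model.sequence(),
                            start_resnames={r.key: r.resname
                                            for r in model.standard_residues()})

    def _score_on(sys, xyz, movable_keys, e_total_rest):
        ia = sys.atom_indices(pair_keys)
        rest = np.setdiff1d(np.arange(sys.n), ia)
        e_self = sys.block_energy(ia, xyz=xyz)
        e_env = sys.block_energy(ia, rest, xyz=xyz)
        rows = sys.sidechain_indices(movable_keys)
        e_total = e_total_rest + sys.rows_energy(rows, xyz=xyz)
        score = weights[0] * e_self + weights[1] * e_env + weights[2] * e_total
        return energy.ScoreBreakdown(e_self, e_env, e_total, weights, score)

    for i in range(config.n_steps):
        mutation = propose_mutation(current, region, config, rng)
        movable_keys = [mutation.residue]
        if config.relax_pair:
            # pair side chains relax with the mutated residue: substitutions
            # that fail to stabilise the charged element pay through e_self
            movable_keys += pair_keys
        if config.relax_radius > 0:
            mut_com = center_of_mass(current.residue(mutation.residue).atoms)
            movable_keys += [r.key for r in current.standard_residues()
                             if r.key != mutation.residue
                             and r.key not in pair_keys
                             and np.linalg.norm(center_of_mass(r.atoms) - mut_com)
                             < config.relax_radius]

        # energy of everything not involving the movable side chains is shared
        # between reference and trial; e_total is updated incrementally
        rows_cur = cur_sys.sidechain_indices(movable_keys)
        e_total_rest = e_total_cur - cur_sys.rows_energy(rows_cur)

        def _relax_and_score(sys, xyz0=None):
            mov = sys.sidechain_indices(movable_keys)
            xyz, _, _, _ = energy.minimize_system(
                sys, mov, config.minimize_steps, config.restraint_k,
                config.minimize_tol, xyz0=xyz0)
            return xyz, _score_on(sys, xyz, movable_keys, e_total_rest)

        # reference state relaxed under the same settings as the trial
        _, score_ref = _relax_and_score(cur_sys)

        # trial: best of the three staggered chi1 rotamers, all relaxed
        trial0 = apply_mutation(current, mutation, None)
        trial_sys = energy.ParameterizedSystem(trial0)
        span = trial_sys.spans[mutation.residue]
        trial_res = trial0.residue(mutation.residue)
        bb = {nm: trial_res.atom(nm).coords for nm in ("N", "CA", "C")}
        variants = chi1_variants(mutation.to_resname) if config.rotamer_search \
            else [None]
        best = None
        for overrides in variants:
            xyz0 = trial_sys.xyz.copy()
            if overrides is not None:
                placed = build_sidechain(bb, mutation.to_resname, overrides)
                for j, (_, pos) in enumerate(placed):
                    xyz0[span[0] + 4 + j] = pos  # rows after N, CA, C, O
            xyz, score = _relax_and_score(trial_sys, xyz0=xyz0)
            if best is None or score.score < best[1].score:
                best = (xyz, score)
        xyz_new, score_new = best

        delta = score_new.score - score_ref.score
        accepted, prob, draw = metropolis_accept(delta, config.temperature, rng)
        mut_atoms = np.arange(span[0], span[1])
        masses = np.array([_mass_of(trial_sys.atom_names[a]) for a in mut_atoms])
        com = (masses[:, None] * xyz_new[mut_atoms]).sum(0) / masses.sum()
        dist = float(np.linalg.norm(com - pair.pair_com))
        traj.steps.append(DesignStep(
            index=i, mutation=mutation, score_before=score_ref,
            score_after=score_new, accepted=accepted,
            acceptance_probability=prob, random_draw=draw, dist_to_pair=dist))
        if accepted:
            energy.write_coords(trial0, trial_sys, xyz_new)
            current = trial0
            trial_sys.xyz = xyz_new.copy()
            cur_sys = trial_sys
            e_total_cur = score_new.e_total
            score_cur = score_new

    traj.final_model = current
    traj.final_sequence = current.sequence()
    return traj


@dataclass
class SubstitutionStats:
    counts: dict[str, int]
    fractions: dict[str, float]
    class_fractions: dict[str, float]
    n_counted: int
    shell_radius: float


def substitution_distribution(trajectories: list[DesignTrajectory],
                              shell_radius: float = 6.0,
                              mode: str = "final") -> SubstitutionStats:
    """Pooled distribution of substitutions within the first solvation sphere.

    Membership is by the mutated residue's centre of mass lying within
    ``shell_radius`` of the pair's charged-group centre of mass.  Modes:

    ``final`` (default)
        Per designed construct: every position of a trajectory's final model
        whose residue type differs from the start model counts once with its
        final type.  This matches reporting substitutions *introduced in the
        designed constructs*.
    ``accepted``
        Every accepted Monte Carlo substitution counts (transient
        substitutions that are later overwritten included).
    ``proposals``
        Every proposal counts, accepted or not.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    if mode not in ("final", "accepted", "proposals"):
        raise ValueError(f"unknown counting mode {mode!r}")
    counts: dict[str, int] = {}
    for traj in trajectories:
        if mode == "final":
            for res in traj.final_model.standard_residues():
                start = traj.start_resnames.get(res.key)
                if start is None or res.resname == start:
                    continue
                d = float(np.linalg.norm(center_of_mass(res.atoms)
                                         - traj.pair.pair_com))
                if d < shell_radius:
                    counts[res.resname] = counts.get(res.resname, 0) + 1
        else:
            for step in traj.steps:
                if mode == "accepted" and not step.accepted:
                    continue
                if step.dist_to_pair >= shell_radius:
                    continue
                aa = step.mutation.to_resname
                counts[aa] = counts.get(aa, 0) + 1
    n = sum(counts.values())
    fractions = {aa: c / n for aa, c in counts.items()} if n else {}

    def frac(group) -> float:
        return sum(fractions.get(aa, 0.0) for aa in group)

    class_fractions = {
        "polar_charged": frac(POLAR_CHARGED),
        "hydrophobic": frac(HYDROPHOBIC),
        "amphiphile": frac(AMPHIPHILE_CLASSES["gln_asn"]
                           | AMPHIPHILE_CLASSES["tyr"]
                           | AMPHIPHILE_CLASSES["ser_thr"]),
    }
    for name, group in AMPHIPHILE_CLASSES.items():
        class_fractions[name] = frac(group)
    return SubstitutionStats(counts=counts, fractions=fractions,
                             class_fractions=class_fractions,
                             n_counted=n, shell_radius=shell_radius)
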