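"""Simplified nonbonded energetics, the weighted design score, restrained
steepest-descent minimisation, and an analytic Born transfer estimate.

The energy function is a united heavy-atom surrogate: Coulomb with a constant
protein dielectric (default eps_r = 4) plus Lennard-Jones 12-6, switched off
smoothly between 10 and 12 A.  Both terms are evaluated at a capped distance of
0.6*Rmin below that separation, so mutation-induced clashes give large finite
penalties instead of overflow.  Intra-residue 1-2/1-3 pairs and the 1-2/1-3
pairs across each peptide bond are excluded.

The design score is the weighted sum used to steer the Monte Carlo search:
w_self * E(ion-pair internal) + w_env * E(pair <-> rest) + w_total * E(all),
with default weights (0.48, 0.48, 0.02) renormalised to sum 1.  Lower is better.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .params import COULOMB_CONSTANT, BACKBONE_CHARGES, lj_params, sidechain_charges
from .structure import ResidueKey, StructureModel
from .templates import BACKBONE_ATOMS, residue_bonds


class ParameterisationError(KeyError):
    """An atom cannot be typed or charged under the bundled parameter set."""


@dataclass
class ForceFieldParams:
    eps_r: float = 4.0                      # relative dielectric of the protein interior
    cutoff: float = 12.0                    # A
    switch_on: float = 10.0                 # A
    lj_cap_factor: float = 0.6              # evaluate below 0.6*Rmin at 0.6*Rmin
    coulomb_k: float = COULOMB_CONSTANT     # kcal*A/(mol*e^2)
    use_lj: bool = True
    use_coulomb: bool = True
    charge_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eps_r < 1:
            raise ValueError("eps_r must be >= 1")
        if not 0 < self.switch_on < self.cutoff:
            raise ValueError("need 0 < switch_on < cutoff")


@dataclass
class ScoreBreakdown:
    e_self: float       # kcal/mol, ion-pair internal nonbonded
    e_env: float        # kcal/mol, ion-pair <-> rest of protein
    e_total: float      # kcal/mol, all nonbonded within the protein
    weights: tuple[float, float, float]
    score: float


@dataclass
class BornParams:
    charge: float = 1.0      # e
    born_radius: float = 2.0  # A
    eps_in: float = 4.0
    eps_out: float = 80.0

    def __post_init__(self) -> None:
        if self.born_radius <= 0:
            raise ValueError("born_radius must be positive")
        if self.eps_in < 1 or self.eps_out < 1:
            raise ValueError("dielectric constants must be >= 1")


@functools.lru_cache(maxsize=None)
def _excluded_name_pairs(resname: str) -> frozenset[tuple[str, str]]:
    """1-2 and 1-3 atom-name pairs within a residue type."""
    adj: dict[str, set[str]] = {}
    for a, b in residue_bonds(resname):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    pairs: set[tuple[str, str]] = set()
    for a, nbrs in adj.items():
        for b in nbrs:
            pairs.add(tuple(sorted((a, b))))
            for c in adj[b]:
                if c != a:
                    pairs.add(tuple(sorted((a, c))))
    return frozenset(pairs)


class ParameterizedSystem:
    """Arrays + exclusion topology for the standard residues of one model."""

    def __init__(self, model: StructureModel, params: ForceFieldParams | None = None):
        self.params = params or ForceFieldParams()
        self.model = model
        ljt = lj_params()
        sct = sidechain_charges()

        xyz, q, eps, rmin2, keys = [], [], [], [], []
        spans: dict[ResidueKey, tuple[int, int]] = {}
        names: list[str] = []
        residues = model.standard_residues()
        if not residues:
            raise ParameterisationError("model has no standard residues to parameterise")
        for res in residues:
            start = len(xyz)
            for a in res.atoms:
                el = a.element.upper()
                if el not in ljt:
                    raise ParameterisationError(
                        f"no LJ parameters for element {el!r} "
                        f"(atom {a.name} in {res.resname} {res.key})")
                override = self.params.charge_overrides.get((res.resname, a.name))
                if override is not None:
                    charge = override
                elif a.name in BACKBONE_CHARGES:
                    charge = BACKBONE_CHARGES[a.name]
                elif (res.resname, a.name) in sct:
                    charge = sct[(res.resname, a.name)]
                else:
                    raise ParameterisationError(
                        f"no partial charge for atom {a.name!r} in {res.resname} {res.key}")
                xyz.append(a.coords)
                q.append(charge)
                e, rh = ljt[el]
                eps.append(e)
                rmin2.append(rh)
                keys.append(res.key)
                names.append(a.name)
            spans[res.key] = (start, len(xyz))

        self.xyz = np.array(xyz, float)
        self.q = np.array(q)
        self.eps = np.array(eps)
        self.rmin_half = np.array(rmin2)
        self.res_keys = keys
        self.atom_names = names
        self.spans = spans
        self.n = len(keys)
        self.excl = self._build_exclusions(residues)
        self.backbone_mask = np.array([nm in BACKBONE_ATOMS for nm in names])

    def _build_exclusions(self, residues) -> np.ndarray:
        n = self.n
        excl = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(excl, True)
        index_of: dict[tuple[ResidueKey, str], int] = {
            (k, nm): i for i, (k, nm) in enumerate(zip(self.res_keys, self.atom_names))}

        def _x(i: int | None, j: int | None) -> None:
            if i is not None and j is not None:
                excl[i, j] = excl[j, i] = True

        for res in residues:
            for a, b in _excluded_name_pairs(res.resname):
                _x(index_of.get((res.key, a)), index_of.get((res.key, b)))
        # 1-2/1-3 across each peptide bond (consecutive residues of one chain)
        for chain in self.model.chains.values():
            std = [r for r in chain if r.is_standard]
            for r1, r2 in zip(std, std[1:]):
                if not (r1.has_atom("C") and r2.has_atom("N")):
                    continue
                if np.linalg.norm(r1.atom("C").coords - r2.atom("N").coords) > 2.0:
                    continue  # chain break
                for a_name, b_name in (("C", "N"), ("O", "N"), ("CA", "N"),
                                       ("C", "CA"), ("C", "CD")):
                    _x(index_of.get((r1.key, a_name)), index_of.get((r2.key, b_name)))
        return excl

    def atom_indices(self, keys: list[ResidueKey]) -> np.ndarray:
        idx: list[int] = []
        for k in keys:
            if k not in self.spans:
                raise KeyError(f"residue {k} not in parameterised system")
            s, e = self.spans[k]
            idx.extend(range(s, e))
        return np.array(idx, dtype=int)

    def sidechain_indices(self, keys: list[ResidueKey]) -> np.ndarray:
        idx = self.atom_indices(keys)
        return idx[~self.backbone_mask[idx]]

    # --- pair interaction kernel -------------------------------------------------

    def _pair_terms(self, xyz: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                    want_grad: bool = False):
        """Energy (and dE/dr) for the ia x ib pair block.

        Returns (E matrix, dEdr matrix or None, diff vectors, r).  Excluded and
        out-of-cutoff pairs carry zero.
        """
        p = self.params
        diff = xyz[ia][:, None, :] - xyz[ib][None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        live = ~self.excl[np.ix_(ia, ib)] & (r < p.cutoff) & (r > 1e-12)

        rmin = self.rmin_half[ia][:, None] + self.rmin_half[ib][None, :]
        rcap = p.lj_cap_factor * rmin
        reff = np.maximum(r, rcap)

        V = np.zeros_like(r)
        dVdr = np.zeros_like(r)
        if p.use_coulomb:
            qq = self.q[ia][:, None] * self.q[ib][None, :]
            Vc = p.coulomb_k * qq / (p.eps_r * reff)
            V += Vc
            dVdr += -Vc / reff
        if p.use_lj:
            epsij = np.sqrt(self.eps[ia][:, None] * self.eps[ib][None, :])
            sr6 = (rmin / reff) ** 6
            V += epsij * (sr6 ** 2 - 2.0 * sr6)
            dVdr += epsij * 12.0 * (sr6 - sr6 ** 2) / reff

        # below the cap radius the potential continues linearly with its slope
        # at rcap: clashes stay finite but keep a restoring force
        capped = r < rcap
        V = np.where(capped, V + dVdr * (r - rcap), V)

        # CHARMM-style switching between switch_on and cutoff
        ron2, roff2 = p.switch_on ** 2, p.cutoff ** 2
        denom = (roff2 - ron2) ** 3
        A = roff2 - r ** 2
        S = np.where(r <= p.switch_on, 1.0,
                     np.where(r >= p.cutoff, 0.0,
                              A ** 2 * (roff2 + 2 * r ** 2 - 3 * ron2) / denom))
        E = np.where(live, V * S, 0.0)
        if not want_grad:
            return E, None, diff, r
        dSdr = np.where((r > p.switch_on) & (r < p.cutoff),
                        12.0 * r * A * (ron2 - r ** 2) / denom, 0.0)
        dEdr = np.where(live, dVdr * S + V * dSdr, 0.0)
        return E, dEdr, diff, r

    def block_energy(self, ia: np.ndarray, ib: np.ndarray | None = None,
                     xyz: np.ndarray | None = None) -> float:
        """Nonbonded energy of a selection (internal if ib is None) in kcal/mol."""
        xyz = self.xyz if xyz is None else xyz
        if ib is None or (len(ia) == len(ib) and np.array_equal(np.sort(ia), np.sort(ib))):
            E, *_ = self._pair_terms(xyz, ia, ia)
            return float(np.triu(E, k=1).sum())
        if np.intersect1d(ia, ib).size:
            raise ValueError("selections must be disjoint or identical")
        E, *_ = self._pair_terms(xyz, ia, ib)
        return float(E.sum())

    def total_energy(self, xyz: np.ndarray | None = None) -> float:
        return self.block_energy(np.arange(self.n), xyz=xyz)

    def rows_energy(self, rows: np.ndarray, xyz: np.ndarray | None = None) -> float:
        """Energy of all pairs involving ``rows`` (row-row pairs counted once)."""
        xyz = self.xyz if xyz is None else xyz
        E, *_ = self._pair_terms(xyz, rows, np.arange(self.n))
        col_in = np.isin(np.arange(self.n), rows)
        return float(E[:, ~col_in].sum() + 0.5 * E[:, col_in].sum())


def nonbonded_energy(model: StructureModel, selection_a: list[ResidueKey],
                     selection_b: list[ResidueKey],
                     params: ForceFieldParams | None = None) -> float:
    """Coulomb + LJ interaction energy between (or within) residue selections."""
    sys = ParameterizedSystem(model, params)
    ia = sys.atom_indices(list(selection_a))
    same = sorted(selection_a) == sorted(selection_b)
    ib = None if same else sys.atom_indices(list(selection_b))
    return sys.block_energy(ia, ib)


def normalise_weights(weights) -> tuple[float, float, float]:
    w = np.asarray(weights, float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be three non-negative numbers, not all zero")
    w = w / w.sum()
    return (float(w[0]), float(w[1]), float(w[2]))


DEFAULT_WEIGHTS = (0.48, 0.48, 0.02)


def design_score(model: StructureModel, pair, params: ForceFieldParams | None = None,
                 weights=DEFAULT_WEIGHTS,
                 system: ParameterizedSystem | None = None) -> ScoreBreakdown:
    """Weighted interaction score of a model around one ion-pair (lower is better)."""
    w = normalise_weights(weights)
    sys = system if system is not None else ParameterizedSystem(model, params)
    pair_keys = [pair.acidic, pair.basic]
    ia = sys.atom_indices(pair_keys)
    rest = np.setdiff1d(np.arange(sys.n), ia)
    e_self = sys.block_energy(ia)
    e_env = sys.block_energy(ia, rest)
    e_total = sys.total_energy()
    score = w[0] * e_self + w[1] * e_env + w[2] * e_total
    return ScoreBreakdown(e_self=e_self, e_env=e_env, e_total=e_total,
                          weights=w, score=score)


@dataclass
class MinimizationResult:
    model: StructureModel
    energies: list[float]          # objective at accepted iterates
    converged: bool
    n_iterations: int
    max_backbone_displacement: float


def make_objective(sys: ParameterizedSystem, mov: np.ndarray,
                   backbone_restraint_k: float = 0.0,
                   x0: np.ndarray | None = None):
    """Closure computing (objective, gradient on movable atoms) for a coordinate
    set.  The objective is the movable-involved part of the total nonbonded
    energy plus harmonic restraints tethering movable backbone atoms to ``x0``.
    Pair parameters are hoisted out of the per-evaluation path."""
    x0 = sys.xyz.copy() if x0 is None else x0.copy()
    restrained = mov[sys.backbone_mask[mov]]
    col_in_mov = np.isin(np.arange(sys.n), mov)
    p = sys.params

    live0 = ~sys.excl[mov, :]
    weight = np.where(col_in_mov[None, :], 0.5, 1.0) * live0
    qq_k = (p.coulomb_k / p.eps_r) * sys.q[mov][:, None] * sys.q[None, :] \
        if p.use_coulomb else None
    epsij = np.sqrt(sys.eps[mov][:, None] * sys.eps[None, :]) if p.use_lj else None
    rmin = sys.rmin_half[mov][:, None] + sys.rmin_half[None, :]
    rcap = p.lj_cap_factor * rmin
    ron2, roff2 = p.switch_on ** 2, p.cutoff ** 2
    denom = (roff2 - ron2) ** 3
    rest_sel = np.isin(mov, restrained)

    def objective_and_grad(xyz):
        diff = xyz[mov][:, None, :] - xyz[None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        live = live0 & (r < p.cutoff) & (r > 1e-12)
        reff = np.maximum(r, rcap)
        V = np.zeros_like(r)
        dVdr = np.zeros_like(r)
        if qq_k is not None:
            Vc = qq_k / reff
            V += Vc
            dVdr -= Vc / reff
        if epsij is not None:
            sr6 = (rmin / reff) ** 6
            V += epsij * (sr6 ** 2 - 2.0 * sr6)
            dVdr += epsij * 12.0 * (sr6 - sr6 ** 2) / reff
        V = np.where(r < rcap, V + dVdr * (r - rcap), V)
        A = roff2 - r ** 2
        sw = (r > p.switch_on) & (r < p.cutoff)
        S = np.where(r <= p.switch_on, 1.0,
                     np.where(sw, A ** 2 * (roff2 + 2 * r ** 2 - 3 * ron2) / denom, 0.0))
        dSdr = np.where(sw, 12.0 * r * A * (ron2 - r ** 2) / denom, 0.0)
        E = np.where(live, V * S, 0.0)
        dEdr = np.where(live, dVdr * S + V * dSdr, 0.0)
        e = (E * weight).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(r > 1e-12, dEdr / r, 0.0)
        g = (coef[..., None] * diff).sum(axis=1)
        if restrained.size and backbone_restraint_k > 0:
            disp = xyz[restrained] - x0[restrained]
            e += 0.5 * backbone_restraint_k * (disp ** 2).sum()
            g[rest_sel] += backbone_restraint_k * disp
        return float(e), g

    return objective_and_grad


def minimize_system(sys: ParameterizedSystem, mov: np.ndarray,
                    n_steps: int, backbone_restraint_k: float = 1.0,
                    tol: float = 0.1, max_step: float = 0.5,
                    xyz0: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, list[float], bool, int]:
    """Core steepest-descent loop on a parameterised system.

    Moves the atom indices in ``mov``; restrains any backbone atoms among them
    to their starting positions.  Returns (final coords, objective trace,
    converged flag, iterations).  The objective (the movable-involved part of
    the total nonbonded energy plus restraints) never increases.
    """
    xyz = sys.xyz.copy() if xyz0 is None else xyz0.copy()
    if mov.size == 0:
        return xyz, [], True, 0
    objective_and_grad = make_objective(sys, mov, backbone_restraint_k, xyz)

    e, g = objective_and_grad(xyz)
    energies = [e]
    step = 0.05
    converged = False
    it = 0
    while it < n_steps:
        it += 1
        gmax = np.abs(g).max()
        if gmax < tol:
            converged = True
            break
        trial = xyz.copy()
        trial[mov] = xyz[mov] - (step / gmax) * g
        e_trial, g_trial = objective_and_grad(trial)
        if e_trial <= e:
            xyz, e, g = trial, e_trial, g_trial
            energies.append(e)
            step = min(step * 1.2, max_step)
        else:
            step *= 0.5
            if step < 1e-7:
                converged = np.abs(g).max() < tol
                break
    return xyz, energies, converged, it


def minimize(model: StructureModel, n_steps: int = 5000,
             backbone_restraint_k: float = 1.0, tol: float = 0.1,
             params: ForceFieldParams | None = None,
             movable_residues: list[ResidueKey] | None = None,
             move_backbone: bool = True,
             max_step: float = 0.5) -> MinimizationResult:
    """Steepest-descent relaxation with adaptive step length.

    Side-chain atoms of ``movable_residues`` (default: every standard residue)
    move freely; backbone atoms move only when ``move_backbone`` and are tethered
    to their input positions by a harmonic restraint of force constant
    ``backbone_restraint_k`` (kcal/mol/A^2).  Stops after ``n_steps`` accepted or
    attempted steps, or when the largest gradient component falls below ``tol``
    (kcal/mol/A).  The objective never increases between accepted iterates.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if backbone_restraint_k < 0:
        raise ValueError("restraint force constant must be >= 0")
    sys = ParameterizedSystem(model, params)
    if movable_residues is None:
        movable_residues = [r.key for r in model.standard_residues()]
    all_idx = sys.atom_indices(movable_residues)
    if move_backbone:
        mov = all_idx
    else:
        mov = all_idx[~sys.backbone_mask[all_idx]]
    if mov.size == 0:
        return MinimizationResult(model.copy(), [sys.total_energy()], True, 0, 0.0)

    xyz, energies, converged, it = minimize_system(
        sys, mov, n_steps, backbone_restraint_k, tol, max_step)

    out = model.copy()
    write_coords(out, sys, xyz)
    restrained = mov[sys.backbone_mask[mov]]
    bb_disp = 0.0
    if restrained.size:
        bb_disp = float(np.linalg.norm(xyz[restrained] - sys.xyz[restrained],
                                       axis=1).max())
    return MinimizationResult(out, energies, converged, it, bb_disp)


def write_coords(model: StructureModel, sys: ParameterizedSystem,
                 xyz: np.ndarray) -> None:
    """Copy system coordinates back onto the model's standard residues in place."""
    for res in model.residues():
        span = sys.spans.get(res.key)
        if span is None:
            continue
        for a, i in zip(res.atoms, range(span[0], span[1])):
            a.coords = xyz[i].copy()


def born_transfer_energy(p: BornParams) -> float:
    """Born free energy (kcal/mol) of moving a charge from eps_out into eps_in.

    dG = (k*q^2 / 2a) * (1/eps_in - 1/eps_out); positive when eps_in < eps_out.
    """
    return (COULOMB_CONSTANT * p.charge ** 2 / (2.0 * p.born_radius)
            * (1.0 / p.eps_in - 1.0 / p.eps_out))
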