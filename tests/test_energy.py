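"""Nonbonded energetics, design score, minimisation, Born estimate."""

import numpy as np
import pytest

from burion import energy
from burion.energy import (BornParams, ForceFieldParams, ParameterizedSystem,
                           born_transfer_energy, design_score, minimize,
                           nonbonded_energy, normalise_weights)
from burion.fixtures import build_ideal_helix
from burion.geometry import rotation_about_axis
from burion.structure import Residue, StructureModel

from conftest import make_atom

COULOMB_K = 332.0636


def _two_particle_model(r, names=("CB", "CB")):
    a = Residue("A", 1, "", "ALA", [make_atom(1, names[0], [0, 0, 0])])
    b = Residue("B", 1, "", "ALA", [make_atom(2, names[1], [r, 0, 0])])
    return StructureModel(identifier="dimer", chains={"A": [a], "B": [b]})


class TestNonbonded:
    def test_coulomb_closed_form_unit_charges(self):
        m = _two_particle_model(3.0)
        params = ForceFieldParams(eps_r=4.0, use_lj=False, charge_overrides={
            ("ALA", "CB"): 0.0})
        # override per selection: give +1 to chain A's CB, -1 to chain B's CB
        # charges are templated per (resname, atom), so use two residue types
        a = Residue("A", 1, "", "SER", [make_atom(1, "OG", [0, 0, 0])])
        b = Residue("B", 1, "", "CYS", [make_atom(2, "SG", [3.0, 0, 0])])
        m = StructureModel(identifier="q", chains={"A": [a], "B": [b]})
        params = ForceFieldParams(eps_r=4.0, use_lj=False, charge_overrides={
            ("SER", "OG"): 1.0, ("CYS", "SG"): -1.0})
        e = nonbonded_energy(m, [("A", 1, "")], [("B", 1, "")], params)
        assert e == pytest.approx(-COULOMB_K / (4.0 * 3.0), abs=1e-6)

    def test_selection_swap_symmetry(self, bundle_and_pair):
        model, pair = bundle_and_pair
        e_ab = nonbonded_energy(model, [pair.acidic], [pair.basic])
        e_ba = nonbonded_energy(model, [pair.basic], [pair.acidic])
        assert e_ab == pytest.approx(e_ba, abs=1e-10)

    def test_brute_force_oracle(self):
        """Independent pure-python double loop with the same exclusion rule,
        switching function and cap."""
        model = build_ideal_helix(
            ["ALA", "GLU", "LEU", "LYS", "SER", "ASN", "VAL", "THR"])
        params = ForceFieldParams()
        sys = ParameterizedSystem(model, params)
        got = sys.total_energy()

        n = sys.n
        expect = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if sys.excl[i, j]:
                    continue
                r = float(np.linalg.norm(sys.xyz[i] - sys.xyz[j]))
                if r >= params.cutoff:
                    continue
                rmin = sys.rmin_half[i] + sys.rmin_half[j]
                rcap = params.lj_cap_factor * rmin
                reff = max(r, rcap)
                v = COULOMB_K * sys.q[i] * sys.q[j] / (params.eps_r * reff)
                dv = -v / reff
                epsij = np.sqrt(sys.eps[i] * sys.eps[j])
                sr6 = (rmin / reff) ** 6
                v += epsij * (sr6 ** 2 - 2 * sr6)
                dv += epsij * 12.0 * (sr6 - sr6 ** 2) / reff
                if r < rcap:
                    v += dv * (r - rcap)
                ron2, roff2 = params.switch_on ** 2, params.cutoff ** 2
                if r <= params.switch_on:
                    s = 1.0
                else:
                    s = ((roff2 - r * r) ** 2 * (roff2 + 2 * r * r - 3 * ron2)
                         / (roff2 - ron2) ** 3)
                expect += v * s
        assert got == pytest.approx(expect, rel=1e-10)

    def test_partition_decomposition(self, bundle_and_pair):
        model, _ = bundle_and_pair
        keys = [r.key for r in model.standard_residues()]
        a, b = keys[:10], keys[10:]
        e_a = nonbonded_energy(model, a, a)
        e_b = nonbonded_energy(model, b, b)
        e_ab = nonbonded_energy(model, a, b)
        e_all = nonbonded_energy(model, keys, keys)
        assert e_a + e_b + e_ab == pytest.approx(e_all, rel=1e-10)

    def test_rigid_motion_invariance(self):
        model = build_ideal_helix(["GLU", "LEU", "LYS", "GLN"])
        e0 = nonbonded_energy(model, [r.key for r in model.residues()],
                              [r.key for r in model.residues()])
        R = rotation_about_axis(np.array([0.2, 0.9, -0.4]), 2.0)
        moved = model.transform(rotation=R, translation=np.array([3.0, -8.0, 1.0]))
        e1 = nonbonded_energy(moved, [r.key for r in moved.residues()],
                              [r.key for r in moved.residues()])
        assert e1 == pytest.approx(e0, rel=1e-8)

    def test_untypable_atom_names_it(self):
        res = Residue("A", 1, "", "ALA", [make_atom(1, "QQ", [0, 0, 0], element="Q")])
        m = StructureModel(identifier="bad", chains={"A": [res]})
        with pytest.raises(energy.ParameterisationError, match="QQ|Q"):
            ParameterizedSystem(m)


class TestDesignScore:
    def test_weight_one_on_self(self, bundle_and_pair):
        model, pair = bundle_and_pair
        sb = design_score(model, pair, weights=(1.0, 0.0, 0.0))
        assert sb.score == pytest.approx(sb.e_self)

    def test_weight_arithmetic_with_renormalisation(self):
        # raw weights 0.48/0.48/0.02 sum to 0.98 and are scaled to sum 1
        w = normalise_weights((0.48, 0.48, 0.02))
        assert sum(w) == pytest.approx(1.0, abs=1e-12)
        assert w[0] == pytest.approx(0.48 / 0.98, abs=1e-12)
        score = w[0] * (-10) + w[1] * (-5) + w[2] * (-100)
        assert score == pytest.approx(-9.2 / 0.98)

    def test_default_weights_sum_exactly_one(self, bundle_and_pair):
        model, pair = bundle_and_pair
        sb = design_score(model, pair, weights=(0.48, 0.48, 0.02))
        assert sum(sb.weights) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            normalise_weights((0.0, 0.0, 0.0))

    def test_charged_pair_self_energy_below_neutral(self, bundle_and_pair):
        """The Glu-/Lys+ contact is electrostatically favourable: zeroing the
        charges must raise the pair's internal energy."""
        model, pair = bundle_and_pair
        e_charged = nonbonded_energy(model, [pair.acidic, pair.basic],
                                     [pair.acidic, pair.basic])
        zeroed = ForceFieldParams(charge_overrides={
            ("GLU", a): 0.0 for a in ("CD", "OE1", "OE2")} | {
            ("LYS", a): 0.0 for a in ("CE", "NZ")})
        e_neutral = nonbonded_energy(model, [pair.acidic, pair.basic],
                                     [pair.acidic, pair.basic], zeroed)
        assert e_charged < e_neutral


class TestMinimize:
    def test_lj_dimer_relaxes_to_rmin(self):
        params = ForceFieldParams(use_coulomb=False)
        rmin = 2 * 2.10  # two united carbons
        m = _two_particle_model(0.8 * rmin)
        res = minimize(m, n_steps=2000, params=params, tol=1e-4)
        d = np.linalg.norm(res.model.atoms()[0].coords - res.model.atoms()[1].coords)
        assert d == pytest.approx(rmin, rel=0.01)

    def test_already_minimal_dimer_unchanged(self):
        params = ForceFieldParams(use_coulomb=False)
        rmin = 2 * 2.10
        m = _two_particle_model(rmin)
        res = minimize(m, n_steps=200, params=params)
        d = np.linalg.norm(res.model.atoms()[0].coords - res.model.atoms()[1].coords)
        assert d == pytest.approx(rmin, rel=1e-3)

    def test_energy_trace_monotone_non_increasing(self, bundle_and_pair):
        model, pair = bundle_and_pair
        res = minimize(model, n_steps=40, movable_residues=[pair.acidic],
                       move_backbone=False)
        diffs = np.diff(res.energies)
        assert np.all(diffs <= 1e-9)

    def test_gradient_matches_finite_differences(self, bundle_and_pair):
        model, pair = bundle_and_pair
        sys = ParameterizedSystem(model)
        mov = sys.sidechain_indices([pair.acidic, pair.basic])
        obj = energy.make_objective(sys, mov)
        xyz = sys.xyz
        _, g = obj(xyz)
        h = 1e-5
        g_num = np.zeros_like(g)
        for ii in range(len(mov)):
            for k in range(3):
                xp, xm = xyz.copy(), xyz.copy()
                xp[mov[ii], k] += h
                xm[mov[ii], k] -= h
                g_num[ii, k] = (obj(xp)[0] - obj(xm)[0]) / (2 * h)
        assert np.abs(g - g_num).max() <= 1e-4 * max(1.0, np.abs(g_num).max())

    def test_backbone_restraint_limits_displacement(self, bundle_and_pair):
        model, pair = bundle_and_pair
        res = minimize(model, n_steps=50, backbone_restraint_k=1.0,
                       movable_residues=[pair.acidic], move_backbone=True)
        assert res.max_backbone_displacement < 2.0


class TestBorn:
    def test_equal_dielectrics_zero(self):
        assert born_transfer_energy(BornParams(eps_in=20, eps_out=20)) == 0.0

    def test_hand_value_water_to_protein(self):
        p = BornParams(charge=1.0, born_radius=2.0, eps_in=4.0, eps_out=80.0)
        expected = (COULOMB_K / 4.0) * (0.25 - 0.0125)
        assert born_transfer_energy(p) == pytest.approx(expected, abs=1e-6)
        assert born_transfer_energy(p) == pytest.approx(19.716, abs=5e-3)

    def test_doubling_radius_halves_penalty(self):
        p1 = BornParams(born_radius=2.0)
        p2 = BornParams(born_radius=4.0)
        assert born_transfer_energy(p1) == pytest.approx(
            2 * born_transfer_energy(p2))
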