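"""Directed Monte Carlo design: proposals, mutation building, Metropolis rule,
trajectories, and substitution statistics."""

import hashlib

import numpy as np
import pytest

from burion import design, geometry, templates
from burion.design import (DesignConfig, Mutation, apply_mutation,
                           metropolis_accept, propose_mutation,
                           resolve_design_region, run_design,
                           substitution_distribution)
from burion.params import KB_KCAL, STANDARD_AA


def _model_hash(model):
    h = hashlib.sha256()
    for r in model.residues():
        h.update(r.resname.encode())
        for a in r.atoms:
            h.update(a.name.encode())
            h.update(np.ascontiguousarray(a.coords).tobytes())
    return h.hexdigest()


class TestPropose:
    def test_never_proposes_identity(self, bundle_and_pair):
        model, _ = bundle_and_pair
        region = [model.standard_residues()[0].key]
        cfg = DesignConfig()
        rng = np.random.default_rng(0)
        seen = {propose_mutation(model, region, cfg, rng).to_resname
                for _ in range(200)}
        assert model.standard_residues()[0].resname not in seen
        assert seen <= set(STANDARD_AA)
        assert len(seen) == 19

    def test_position_frequencies_uniform(self, bundle_and_pair):
        model, _ = bundle_and_pair
        region = [r.key for r in model.standard_residues()[:5]]
        cfg = DesignConfig()
        rng = np.random.default_rng(1)
        n = 10_000
        counts = {k: 0 for k in region}
        for _ in range(n):
            counts[propose_mutation(model, region, cfg, rng).residue] += 1
        p = 1.0 / len(region)
        sigma = np.sqrt(p * (1 - p) / n)
        for k in region:
            assert abs(counts[k] / n - p) <= 3 * sigma

    def test_fixed_seed_reproducible(self, bundle_and_pair):
        model, _ = bundle_and_pair
        region = [r.key for r in model.standard_residues()[:7]]
        cfg = DesignConfig()
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        s1 = [propose_mutation(model, region, cfg, rng1) for _ in range(50)]
        s2 = [propose_mutation(model, region, cfg, rng2) for _ in range(50)]
        assert [(m.residue, m.to_resname) for m in s1] == \
               [(m.residue, m.to_resname) for m in s2]

    def test_exhausted_target_set_raises(self, bundle_and_pair):
        model, _ = bundle_and_pair
        res = model.standard_residues()[0]
        cfg = DesignConfig(excluded_targets=frozenset(
            aa for aa in STANDARD_AA if aa != res.resname))
        with pytest.raises(design.ConfigurationError):
            propose_mutation(model, [res.key], cfg, np.random.default_rng(0))


class TestApplyMutation:
    def test_to_glycine_removes_side_chain(self, bundle_and_pair):
        model, _ = bundle_and_pair
        res = next(r for r in model.standard_residues() if r.resname == "LEU")
        mut = Mutation(res.key, "LEU", "GLY")
        out = apply_mutation(model, mut)
        new = out.residue(res.key)
        assert {a.name for a in new.atoms} == {"N", "CA", "C", "O"}

    def test_identity_mutation_disallowed(self):
        with pytest.raises(ValueError):
            Mutation(("A", 1, ""), "ALA", "ALA")

    def test_backbone_bit_identical(self, bundle_and_pair):
        model, _ = bundle_and_pair
        res = next(r for r in model.standard_residues() if r.resname == "LEU")
        out = apply_mutation(model, Mutation(res.key, "LEU", "PHE"))
        new = out.residue(res.key)
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(new.atom(name).coords, res.atom(name).coords)

    def test_template_readback(self, bundle_and_pair):
        """Rebuilt side-chain internal coordinates match the template to 1e-3."""
        model, _ = bundle_and_pair
        res = next(r for r in model.standard_residues() if r.resname == "LEU")
        out = apply_mutation(model, Mutation(res.key, "LEU", "GLU"))
        new = out.residue(res.key)
        coords = {a.name: a.coords for a in new.atoms}
        for name, (a, b, c), bond, ang, dihed in templates.SIDECHAIN_ZMAT["GLU"]:
            d = np.linalg.norm(coords[name] - coords[c])
            assert d == pytest.approx(bond, abs=1e-3)
            assert geometry.angle(coords[name], coords[c], coords[b]) == \
                pytest.approx(ang, abs=0.1)
            measured = geometry.dihedral(coords[name], coords[c], coords[b], coords[a])
            assert abs(((measured - dihed + 180) % 360) - 180) < 0.1


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        acc, prob, _ = metropolis_accept(-1.0, 310.0, rng)
        assert prob == 1.0 and acc

    def test_half_acceptance_at_kT_ln2(self):
        T = 310.0
        delta = KB_KCAL * T * np.log(2.0)
        rng = np.random.default_rng(5)
        n = 10_000
        hits = sum(metropolis_accept(delta, T, rng)[0] for _ in range(n))
        sigma = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) <= 3 * sigma

    def test_zero_temperature_limit(self):
        rng = np.random.default_rng(0)
        _, prob, _ = metropolis_accept(+1.0, 1e-9, rng)
        assert prob == pytest.approx(0.0, abs=1e-300)

    def test_boltzmann_occupancy_two_state_landscape(self):
        """Long Metropolis chain on a frozen two-level system matches the
        Boltzmann weight within 3 sigma."""
        T = 310.0
        gap = 0.5  # kcal/mol
        rng = np.random.default_rng(123)
        state = 0
        n = 100_000
        visits = 0
        for _ in range(n):
            delta = gap if state == 0 else -gap
            acc, _, _ = metropolis_accept(delta, T, rng)
            if acc:
                state = 1 - state
            visits += state
        p1 = np.exp(-gap / (KB_KCAL * T))
        expected = p1 / (1 + p1)
        sigma = np.sqrt(expected * (1 - expected) / n) * 10  # autocorrelated chain
        assert abs(visits / n - expected) <= 3 * sigma


class TestRunDesign:
    def test_zero_steps_is_identity(self, bundle_and_pair):
        model, pair = bundle_and_pair
        traj = run_design(model, pair, DesignConfig(n_steps=0, rng_seed=1))
        assert traj.steps == []
        assert traj.final_sequence == model.sequence()
        assert _model_hash(traj.final_model) == _model_hash(model)

    def test_bit_reproducible(self, bundle_and_pair):
        model, pair = bundle_and_pair
        cfg = DesignConfig(n_steps=4, rng_seed=77, minimize_steps=40)
        t1 = run_design(model, pair, cfg)
        t2 = run_design(model, pair, cfg)
        assert t1.final_sequence == t2.final_sequence
        assert _model_hash(t1.final_model) == _model_hash(t2.final_model)
        for s1, s2 in zip(t1.steps, t2.steps):
            assert s1.random_draw == s2.random_draw
            assert s1.score_after.score == s2.score_after.score
            assert s1.accepted == s2.accepted

    def test_replay_reproduces_accept_flags(self, design_trajectories):
        for traj in design_trajectories[:10]:
            T = traj.config.temperature
            for s in traj.steps:
                delta = s.score_after.score - s.score_before.score
                prob = min(1.0, float(np.exp(-delta / (KB_KCAL * T))))
                assert s.acceptance_probability == pytest.approx(prob, rel=1e-12)
                assert s.accepted == (s.random_draw < prob)

    def test_zero_temperature_scores_monotone(self, bundle_and_pair):
        model, pair = bundle_and_pair
        cfg = DesignConfig(n_steps=25, rng_seed=3, minimize_steps=60,
                           temperature=1e-6)
        traj = run_design(model, pair, cfg)
        accepted = [s.score_after.score for s in traj.steps if s.accepted]
        assert all(b <= a + 1e-9 for a, b in zip(accepted, accepted[1:]))

    def test_rejected_steps_leave_model_untouched(self, bundle_and_pair):
        model, pair = bundle_and_pair
        cfg = DesignConfig(n_steps=12, rng_seed=2, minimize_steps=40,
                           temperature=1.0)  # near-zero T: many rejections
        traj = run_design(model, pair, cfg)
        rejected = [s for s in traj.steps if not s.accepted]
        assert rejected, "expected at least one rejection at low temperature"
        # replay: applying only accepted mutations reproduces the final sequence
        seq = {r.key: r.resname for r in model.standard_residues()}
        for s in traj.steps:
            if s.accepted:
                assert seq[s.mutation.residue] == s.mutation.from_resname
                seq[s.mutation.residue] = s.mutation.to_resname
        final = {r.key: r.resname for r in traj.final_model.standard_residues()}
        assert seq == final

    def test_forbids_mutating_the_pair(self, bundle_and_pair):
        model, pair = bundle_and_pair
        region = resolve_design_region(model, pair, DesignConfig())
        assert pair.acidic not in region
        assert pair.basic not in region

    def test_accepted_scores_trend_downhill(self, design_trajectories):
        """Directionality: the design drives the score down (sign test over
        trajectories on first vs last accepted score)."""
        downs = ups = 0
        for traj in design_trajectories:
            acc = [s.score_after.score for s in traj.steps if s.accepted]
            if len(acc) >= 2:
                if acc[-1] < acc[0]:
                    downs += 1
                elif acc[-1] > acc[0]:
                    ups += 1
        from scipy import stats
        p = stats.binomtest(downs, downs + ups, 0.5,
                            alternative="greater").pvalue
        assert p < 0.05


class TestSubstitutionDistribution:
    def test_single_in_shell_substitution(self, design_trajectories):
        traj = design_trajectories[0]
        stats = substitution_distribution([traj], shell_radius=6.0, mode="final")
        assert stats.n_counted >= 0
        if stats.n_counted:
            assert sum(stats.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, design_trajectories):
        stats = substitution_distribution(design_trajectories, shell_radius=6.0)
        assert sum(stats.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_class_aggregates_equal_member_sums(self, design_trajectories):
        stats = substitution_distribution(design_trajectories, shell_radius=6.0)
        polar = sum(stats.counts.get(aa, 0) for aa in design.POLAR_CHARGED)
        hydro = sum(stats.counts.get(aa, 0) for aa in design.HYDROPHOBIC)
        assert polar + hydro == stats.n_counted
        assert stats.class_fractions["polar_charged"] == \
            pytest.approx(polar / stats.n_counted)
        amph = sum(stats.counts.get(aa, 0)
                   for aa in ("GLN", "ASN", "TYR", "SER", "THR"))
        assert stats.class_fractions["amphiphile"] == \
            pytest.approx(amph / stats.n_counted)

    def test_accepted_mode_counts_every_accepted_in_shell_event(
            self, design_trajectories):
        stats = substitution_distribution(design_trajectories, shell_radius=6.0,
                                          mode="accepted")
        expect = sum(1 for t in design_trajectories for s in t.steps
                     if s.accepted and s.dist_to_pair < 6.0)
        assert stats.n_counted == expect
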