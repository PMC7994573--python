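# burion

Buried ion-pairs — salt bridges sealed inside a protein's hydrophobic core —
are thermodynamically expensive (the Born desolvation penalty of moving a
charge from water, ε ≈ 80, into the low-dielectric interior, ε ≈ 4–10) yet
indispensable for function in proton pumps, chaperones and designed
proteins. `burion` is a toolkit for studying how such charges are stabilised,
aimed at protein designers and structural bioinformaticians working with
minimal helical-bundle scaffolds:

* **Detection & statistics** — find salt bridges in PDB structures (acidic
  side-chain O within 3.2 Å of basic side-chain N), classify burial by
  relative solvent accessibility (Shrake–Rupley), and quantify the amino-acid
  composition around each pair: counting all residues within a threshold
  radius r_thr of the pair's centre of mass, the occurrence probability of
  amino acid *aa* is

      p_aa(r_thr) = N_aa(r_thr) / Σ_i N_i(r_thr)

  with enrichments p_aa / background.
* **Directed Monte Carlo design** — optimise the surroundings of a buried
  ion-pair by random point mutations, template side-chain rebuilding,
  restrained steepest-descent relaxation, and Metropolis acceptance at
  T = 310 K on the weighted nonbonded score
  `0.48·E(pair) + 0.48·E(pair↔rest) + 0.02·E(total)` (weights renormalised
  to 1). The design discovers the charge-shielding principle: polar and
  charged residues accumulate in the pair's first solvation sphere.
* **Biophysical analyses** — two-state chemical unfolding by the linear
  extrapolation method (ΔG = −RT ln[f_D/(1−f_D)], extrapolated to 0 M
  denaturant), sigmoid melting temperatures, NMR T2 from T1ρ/T1 with
  spin-lock offset correction (1/T2 = R1ρ/sin²θ − R1/tan²θ, tanθ = ω1/Ω),
  hetNOE ratios, and an analytic Born transfer estimate.
* **Synthetic fixtures** — ideal helices and four-helix bundles with
  implanted, contact-snapped Glu/Lys pairs, biased neighbourhood
  compositions, unfolding curves and relaxation tables, all with ground
  truth and bit-reproducible per seed.

See `docs/methods.md` for the models, parameters and limitations.

## Worked example

```python
from burion import energy, ionpairs, sasa
from burion.fixtures import glu_lys_bundle

model, pair = glu_lys_bundle()          # 4-helix bundle, implanted E/K pair
print(pair.pair_type, pair.min_contact_distance)   # GLU-LYS 2.80

rel = sasa.relative_sasa(model)
print(rel[pair.acidic], rel[pair.basic])           # 0.051 0.036  -> buried

model = energy.minimize(model, n_steps=500, move_backbone=False).model
pair = ionpairs.detect_ion_pairs(model)[0]
sb = energy.design_score(model, pair)
print(sb.e_self, sb.e_env, sb.score)   # -28.03 -19.13 -20.17 (kcal/mol)
```

The pair sits at a 2.80 Å O–N contact with relative accessibilities of 0.05
(Glu) and 0.04 (Lys) — both under the 0.2 burial threshold — and after
side-chain relaxation the charged contact is strongly favourable
(E(pair) = −28 kcal/mol; total score −20.2, lower is better). Running
directed design around it,

```python
from burion.design import DesignConfig, run_design, substitution_distribution
trajs = [run_design(model, pair, DesignConfig(n_steps=60, rng_seed=s,
                                              minimize_steps=150))
         for s in range(1, 51)]
stats = substitution_distribution(trajs, shell_radius=6.0)
print(stats.class_fractions["polar_charged"])   # ~0.80
```

about 80% of the substitutions introduced within 6 Å of the buried pair are
polar or charged — the amphiphilic-shielding signature.

Analysis pipelines are also exposed as a CLI:

```
burion ionpairs --in structures/ --out scan --cutoff 3.2 --rthr 15
burion design --pdb bundle.pdb --steps 60 --seed 1 --out run/
burion unfold --in unfolding.tsv --mode chemical --out fit.json
burion relax --in relaxation.tsv --spinlock-khz 1.5 --out t2.tsv
burion fixtures bundle --out fx/
```

For a synthetic two-state curve generated with ΔG_H₂O = 5 kcal/mol,
m = 2 kcal·mol⁻¹·M⁻¹ and 0.1-unit signal noise, the unfolding pipeline
prints `dG0 = 5.06 ± 0.04 kcal/mol, m = 2.02 ± 0.01` — an unbiased recovery
of the generator's parameters.

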