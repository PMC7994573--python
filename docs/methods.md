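# Methods

`burion` analyses and designs buried ion-pairs (salt bridges shielded from
bulk water) in helical-bundle proteins. This note records the models behind
each module, the parameters that matter, and the limits of what the synthetic
test bed can show.

## Structures, geometry, and solvent accessibility

Structures are held as a plain chain → residue → atom hierarchy with
coordinates in Å. PDB parsing and serialisation go through gemmi; multi-model
(NMR) files default to the first MODEL, alternate locations are collapsed to
the highest-occupancy conformer (ties broken alphabetically by altloc), and
hydrogens and waters are dropped at read time. HETATM and non-standard
residues are kept in the model but excluded from statistics, energetics and
design. Residues are keyed by (chain, residue number, insertion code).

Solvent-accessible surface area uses the Shrake–Rupley construction: a probe
of radius 1.4 Å rolled over united heavy-atom van der Waals spheres
(C 1.9, N 1.7, O 1.5, S 1.8 Å; hydrogens are implicit in the radii), sampled
on a deterministic golden-spiral lattice (default 960 points/atom, ~1–2%
per-residue sampling accuracy; rotation of the model changes totals by ≲0.5%
at ≥2000 points). Relative accessibility divides a residue's SASA by the SASA
of the same residue type X in an extended Gly-X-Gly tripeptide built from the
package's own templates, computed at run time and cached — this keeps the
burial scale self-consistent with the radii instead of importing a reference
table computed with different parameters. A residue (or ion-pair) is "buried"
below a relative SASA of 0.2 (configurable).

## Ion-pair detection and microenvironment statistics

A salt bridge is any acidic side-chain oxygen (Asp OD1/OD2, Glu OE1/OE2)
within 3.2 Å of a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
His optional and off by default because its protonation state is unknown in
most depositions). The 3.2 Å O–N default matches the common analysis-plugin
convention; it and the atom sets are configurable. Dataset filtering keeps
structures with a reported resolution strictly below 3.5 Å; structures
without a resolution record are dropped and logged.

Around each pair, residues are counted inside a threshold radius r_thr
(default 15 Å) of the pair's charged-group centre of mass. Membership is by
residue centre of mass with a strict inequality, the two pair members are
excluded from their own counts (they would otherwise dominate small spheres),
and counts are pooled over pairs before normalising once:

    p_aa(r_thr) = N_aa(r_thr) / Σ_i N_i(r_thr)

Enrichments divide p_aa by a background frequency, computed over all standard
residues of the filtered dataset unless supplied. Profiles can be stratified
by pair type (GLU-LYS, ASP-ARG, …). Pooled counting (not per-structure
averaging) is recorded in the run metadata; per-pair counts are exposed so a
per-structure average can be formed if wanted.

## Energy model

The scoring engine is a deliberately simple united heavy-atom nonbonded
surrogate:

* Coulomb term `332.0636·q_i·q_j/(ε_r·r)` with a constant protein-interior
  dielectric ε_r = 4 (the conventional low-dielectric core value; a
  distance-dependent dielectric is not currently implemented).
* Lennard-Jones 12-6 with per-element parameters (C: ε 0.12 kcal/mol,
  Rmin/2 2.10 Å — united CH/CH2/CH3 scale; N 0.17/1.85; O 0.12/1.70;
  S 0.45/2.00), Lorentz-like combination Rmin_ij = Rmin/2_i + Rmin/2_j,
  ε_ij = √(ε_i ε_j).
* Partial charges per residue template, heavy atoms only, with polar
  hydrogens folded into their carriers so donors are net positive and
  acceptors net negative (e.g. Lys NZ +0.75/CE +0.25; carboxylate O −0.55
  each; amide C=O −0.55/+0.31 with NH2 +0.24). Backbone: N −0.16, CA +0.16,
  C +0.51, O −0.51. Each template nets an integer formal charge.
* Smooth switching of both terms between 10 and 12 Å; pairs beyond 12 Å are
  ignored.
* Both terms are evaluated at a capped distance of 0.6·Rmin below that
  separation and continued linearly in r with the slope at the cap, so
  mutation-induced clashes produce large finite penalties while keeping a
  restoring force for the minimiser (a flat cap would leave deeply
  overlapping atoms with zero gradient and stall relaxation).
* Exclusions: 1-2 and 1-3 bonded pairs within each residue, plus the 1-2/1-3
  pairs across every peptide bond. Bond topology comes from the side-chain
  templates; ring closures (Phe/Tyr/Trp/His/Pro) are included in the
  topology.

The design score around one ion-pair is the weighted sum

    score = w_self·E(pair internal) + w_env·E(pair ↔ rest) + w_total·E(all)

with default raw weights (0.48, 0.48, 0.02) renormalised to sum exactly 1
(the raw triple sums to 0.98). Lower is better.

Minimisation is steepest descent with an adaptive step (grow ×1.2 on
acceptance up to 0.5 Å, halve on rejection), a gradient-infinity-norm
stopping tolerance of 0.1 kcal·mol⁻¹·Å⁻¹ and a default budget of 5000 steps.
Side chains move freely; backbone atoms move only on request and are then
tethered to their input positions by a harmonic restraint with
k = 1 kcal·mol⁻¹·Å⁻² per atom. The objective is non-increasing across
accepted iterates by construction.

A single-charge Born transfer estimate,
ΔG = (332.0636·q²/2a)·(1/ε_in − 1/ε_out), is provided for desolvation
book-keeping (defaults ε_in = 4, ε_out = 80); with q = 1 e and a = 2 Å it
gives +19.7 kcal/mol for water → core transfer.

## Directed Monte Carlo design

Each step of a trajectory:

1. draws a position uniformly from the design region (default: residues whose
   centre of mass lies within 8 Å of the pair's charged-group centre — the
   pair's immediate surroundings; the two pair members are never mutated) and
   a target uniformly from the 19 other residue types;
2. rebuilds the side chain from ideal internal-coordinate templates at the
   most common rotamer (optionally the best of the three staggered χ1
   rotamers);
3. relaxes the movable set — the mutated side chain plus, by default, the two
   ion-pair side chains — against the fixed remainder (default in-loop budget
   150 steepest-descent steps, which the tolerance criterion normally cuts
   short); the reference state is re-relaxed under identical settings so the
   score difference carries no relaxation asymmetry;
4. accepts with the Metropolis probability min(1, exp(−Δscore/k_BT)) at
   T = 310 K, k_B = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹.

Relaxing the pair side chains with the mutated residue matters: substitutions
that fail to stabilise the charged element let the pair strain or drift and
pay through the heavily weighted self-interaction term; with a frozen pair
that channel is inert. Every uniform draw is logged, so a trajectory replays
bit-for-bit from its seed, rejected steps restore the previous state exactly,
and the acceptance decisions can be re-derived from the logged deltas and
draws.

Substitution statistics pool trajectories and classify substitutions whose
residue centre of mass lies within the "first solvation sphere" — 6 Å of the
pair centre by default (the radius is a package choice; the notion is
qualitative in the design narrative). The default counting unit is the
designed construct: every position of a trajectory's final model whose type
differs from the start model counts once with its final type. This matches
reporting substitutions introduced in designed constructs; per-acceptance and
per-proposal counting are available, and per-acceptance counts run ~10–15
percentage points lower in polar/charged share because transient
near-neutral hydrophobic acceptances (Δ ≈ 0 is accepted with probability ~1)
dilute the pool before being overwritten.

Residue classes: polar+charged = {D,E,K,R,H,Q,N,S,T,Y}; amphiphile
subclasses Gln/Asn, Tyr, Ser/Thr; hydrophobic = the remaining ten types.

## Two-state unfolding

Chemical unfolding: f_D = (y−y_N)/(y_D−y_N) from scalar baselines (default:
mean of the three lowest-x and three highest-x points; generator-made curves
carry their true baselines); K = f_D/(1−f_D); ΔG = −RT·ln K for points with
f_D in [0.05, 0.95] (outside the window ln K diverges and the two-state read
is meaningless); ordinary least squares of ΔG against denaturant
concentration gives ΔG_H₂O as the intercept and the m-value as minus the
slope, with standard errors from the fit covariance. Default temperature
293.15 K (measurements at 20 °C). Melting curves are fit with a
four-parameter sigmoid; Tm is its midpoint, reported in °C, with a
no-transition flag when the fitted amplitude is under 3× the residual scale
and a flagged (not raised) non-convergence path.

## NMR relaxation

T2 is recovered from rotating-frame relaxation with the spin-lock offset
correction 1/T2 = R1ρ/sin²θ − R1/tan²θ, tanθ = ω1/Ω, θ = π/2 on resonance.
Angular quantities are rad/s internally; the table reader accepts the field
amplitude in kHz and offsets in Hz (×2π). Only sin²θ and tan²θ enter, so the
offset sign is irrelevant. Records with computed 1/T2 ≤ 0 are flagged
non-physical and withheld, never imputed. Uncertainties come from Monte
Carlo propagation (default 1000 draws) with independent Gaussian noise on T1
and T1ρ at their stated errors; non-physical draws are dropped and counted.
hetNOE ratios I_sat/I_ref carry an error of twice the spectral-noise SD
propagated to first order.

## Synthetic fixtures

The generators produce every input the pipelines need, with ground truth
attached:

* Ideal α-helices (φ = −57°, ψ = −47°, ω = 180°, Engh–Huber-like bond
  geometry) and antiparallel-alternating four-helix bundles on a circle of
  radius 7.5 Å, 17 residues per helix, poly-Leu by default. Implanted
  Glu/Lys positions face the bundle axis and share z = 0; a deterministic
  greedy χ-grid search (15° steps, three sweeps) snaps the carboxylate and
  ammonium groups to a ~2.8 Å contact. The default fixture's pair is buried
  (relative SASA ≈ 0.04–0.06 raw, ~0 after side-chain relaxation).
* Composition-biased structure sets: residues near the implanted pair drawn
  from background frequencies times a user bias (renormalised), the rest from
  the background; used to verify enrichment recovery.
* Two-state unfolding curves from the closed-form f_D(c) and sigmoidal melts.
* Relaxation tables with physical (T1, T1ρ, offset) draws and exact T2.

What the fixtures do not emulate: loops between helices, backbone
flexibility, crystallographic disorder, solvent, and realistic rotamer
statistics. Tests passing on these fixtures demonstrate the correctness of
the algorithms and the qualitative physics (charge complementarity, burial,
polar shielding), not quantitative agreement with experimental energetics.

## Problem sizes and numerical choices

The packaged design experiment runs 50 trajectories × 60 MC steps on the
~550-atom bundle fixture with a 150-step in-loop relaxation budget — sizes
chosen to give ~100–200 counted substitutions, enough for class fractions
with a few-percent standard error. The one-time fixture relaxation uses 500
steps. Ties in the rotamer grid search resolve to the first-scanned value;
the minimiser's line search halts below a 10⁻⁷ Å step. Degenerate inputs
(empty selections, all-zero weights, zero-count profiles, flat melting
curves, non-physical relaxation records) raise typed errors or set flags as
documented rather than returning silent defaults.

## Known limitations

* The energy surrogate has no solvation physics beyond the constant interior
  dielectric; absolute energies are not comparable to experiment, only
  orderings under mutation are meaningful.
* Buried polar groups without hydrogen-bond partners are not penalised (no
  desolvation term), which biases the design loop mildly toward tolerating
  stray polar insertions relative to a solvated treatment.
* Side-chain placement is single-rotamer templates plus local minimisation;
  ring closure in the Z-matrix templates is approximate (≤ ~0.3 Å closure
  error), adequate for packing and electrostatics at this resolution.
* The burial scale depends on the bundled radii; with other radius tables the
  Gly-X-Gly references are recomputed automatically but thresholds may need
  revisiting.
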