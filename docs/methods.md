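# Methods

This note documents the models, parameters and numerical choices behind
`urethanefold`, in the spirit of a package's own methods appendix.  Nothing
here states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Molecular model

Oligourethanes are Boc-capped chains of carbamate-linked amino-alcohol
units, `Boc–[NH–CγH(R)–CβH2–O–C(=O)]n–1–NH–CγH(R)–CβH2–OH`, with side
chain R = benzyl (P unit) or methyl (M unit) and an S or R stereocenter at
Cγ.  The representation is heavy-atom explicit with explicit polar
hydrogens (urethane N–H, phenol and terminal O–H) because hydrogen-bond
geometry needs them; aliphatic/aromatic hydrogens are united into their
carbons but counted in molecular formulas.  BPA is modelled as two
para-phenol rings on a gem-dimethyl quaternary carbon (C15H16O2, 17 heavy
atoms, 2 hydroxyl donors), rings in a ~45° propeller.

Geometry is built from internal coordinates (NeRF chain construction) with
idealized bond lengths/angles (e.g. C–C 1.53 Å, C(=O)–N 1.35 Å, aromatic
C–C 1.39 Å, sp2 angles 120°).  The urethane group is planar: ψ (C–O) and
ω (C–N) are fixed at exactly 180°, reflecting amide-like resonance; the
three rotatable backbone torsions per residue are φ (N–Cγ), ξ (Cγ–Cβ) and
χ (Cβ–O) (the terminal residue's χ rotates its hydroxyl hydrogen).
Torsions follow the IUPAC sign convention (cis = 0°) on (−180°, 180°].

**Chirality convention.** The stereo flag is encoded geometrically: S ⇔
negative signed volume det[v_N, v_side, v_Cβ] of the substituent vectors
about Cγ.  The builder places the side chain at φ − 120° (S) or φ + 120°
(R) about the N–Cγ bond; the round trip build → signed-volume assignment
is exact for all 2⁵ pentamer stereo-sequences and torsional moves cannot
invert a center.

**Default composition.** Mass arithmetic pins the pentamer composition at
2 P + 3 M; the default arrangement is `PMMPM` (P at positions 1 and 4) and
is configurable — all formula/mass results are arrangement-invariant.

**Mass arithmetic.** Monoisotopic atomic masses to ≥ 6 decimals; adduct
m/z as M + proton (with the [M+Na]+ convention Na − H + proton), Boc loss
modelled as elimination of C4H8 + CO2; reported values rounded half-even
to 2 decimals, matching routine LC-MS readout.

## Energy model

A deliberately simple, fully reproducible molecular-mechanics potential
(`data/forcefield_default.json`, versioned).  These are this package's own
parameters, not those of any published force field.

| term | form | defaults |
|---|---|---|
| van der Waals | 4ε[(σ/r)¹² − (σ/r)⁶], Lorentz–Berthelot | σ 2.96–3.75 Å, ε 0.02–0.21 kcal/mol by type |
| electrostatics | 332.06·qiqj/(εr·r) | rule-table charges, interior ε 1 |
| torsions | k(1 + cos 3θ) on rotatable torsions | k = 0.3 kcal/mol |
| GB polar | −166·(1/ε_in − 1/ε_solv)·Σij qiqj/f_GB | ε_solv = 4.81 (chloroform) |
| nonpolar | γ·SASA + β | γ = 0.005 kcal/(mol·Å²), β = 0 |

Exclusions: 1-2 and 1-3 pairs omitted, 1-4 scaled by 0.5 (LJ and Coulomb).
Partial charges come from a small rule table (carbonyl C/O, ester O,
urethane N/H, hydroxyl O/H, Cβ/Cγ) and are shifted uniformly within each
molecule so net molecular charge is exactly zero.  Any non-excluded pair
closer than 0.1 Å raises an error (outside model validity); during
sampling such moves are simply rejected.

**Generalized Born.** Effective radii by HCT-style pairwise descreening
(intrinsic radius = Bondi radius − 0.09 Å offset, neighbour scale 0.8) with
the Still cross term f_GB = sqrt(r² + a_i a_j exp(−r²/4a_i a_j)); self
terms included.  An isolated ion reduces exactly to the Born equation, and
well-separated molecules decouple to their individual terms.

**SASA.** Shrake–Rupley-style numerical surface with a deterministic
960-point golden-spiral set per atom, probe 1.4 Å, Bondi radii.  The point
set is oriented in each molecule's canonical principal-axes frame (with a
deterministic sign convention), which makes the areas bit-reproducible,
exactly invariant under rigid motions of each molecule, and exactly
additive for separated molecules — the property the binding decomposition's
non-interacting limit relies on.

## Sampling protocol

A Monte Carlo analog of a multiple-simulated-annealing workflow, in the
complex's natural degrees of freedom (backbone torsions + rigid-body BPA
pose).  Moves: one random torsion perturbed by N(0, δ) (δ = 30° while
annealing, 10° in production), BPA translation N(0, 0.5 Å) per axis, BPA
rotation about a random axis by N(0, 10°); Metropolis acceptance
min(1, e^(−ΔE/kBT)), with only downhill moves accepted at T = 0.

Each repeat: random initial torsions and a random clash-free ligand pose
4–8 Å from the oligomer centroid → anneal (linear heat 298 → 500 K,
equilibrate, linear cool to 0 K) → production at 298 K, frames recorded
every `stride` sweeps, the first 10% discarded as equilibration.  Per-repeat
random streams derive from one master seed via `default_rng([master_seed,
repeat])`, so ensembles are bit-reproducible and repeats independent.

Sampling runs on the fast potential (LJ + Coulomb screened by the solvent
dielectric + torsion terms); GB/SASA solvation is applied when frames are
rescored by the binding module — the usual sample-then-rescore split, here
chosen so a sweep costs milliseconds.  Desk-scale defaults (order 10²
sweeps, a handful of repeats) are study-size choices exposed in config; the
statistical tests (Boltzmann occupancy, detailed balance) run on analytic
toy systems at 10⁵ sweeps where exact references exist.

## Ensemble analysis

**Clustering.** Pairwise minimal RMSD (Kabsch SVD superposition; frames
fitted on the oligomer backbone, measured over all heavy atoms), then
average-linkage agglomerative clustering cut at 2.0 Å.  All tie-breaks are
deterministic: labels dense in order of first appearance, medoid = member
minimizing summed within-cluster RMSD (lowest index on ties).  Top-k
summaries (default k = 5) report populations and joint coverage.

**Torsion statistics.** Most-probable angles via fixed-width (10°)
circular histograms wrapping at ±180° (the wrap bin reports +180°), ties
toward the smaller absolute angle — a deterministic alternative to kernel
density.  Both per-cluster and pooled-ensemble modes are available since
either aggregation is defensible.  The stereo sign rule is scored as the
per-residue fraction of frames with sign(φ) matching the configuration
(S → φ < 0).

**Helix heuristics.** Regularity = 1 − mean circular variance of {φ, ξ, χ}
across residues; handedness from the sign of the circular-mean virtual
dihedral over consecutive Cγ quadruples (positive = right-handed), reported
only when regularity ≥ 0.7.  These are this package's constructions for
flagging repeating backbone geometry — thresholds are config, and the
metrics are heuristics, not a secondary-structure assignment.

**Hydrogen bonds.** Geometric criteria D···A ≤ 3.5 Å and D–H···A ≥ 135°
(both configurable); donor–acceptor pairs within 2 bonds excluded; at most
one bond per donor per frame (best angle wins) so bifurcated contacts are
not double-counted.  Bonds are classed intra (both partners oligomer) vs
inter (one partner BPA); ensemble means equal population-weighted cluster
means by construction.

**Binding decomposition.** Single-trajectory MM-GBSA-style: each Δ-component
is component(complex) − component(oligomer) − component(BPA) at the
in-complex geometries, so internal torsional terms cancel exactly and
ΔG_bind = ΔE_vdW + ΔE_el + ΔG_solv.polar + ΔG_solv.nonpolar.  No entropy
term is estimated.  Spread is reported as SD plus 5–95 percentiles.

## Titration analysis

Linear Stern–Volmer model F₀/F = 1 + Q/K_d; (F₀/F − 1) is regressed on Q
through the origin (the model fixes the intercept at 1), slope = K_SV =
1/K_d = K_a.  Requires ≥ 3 points with Q > 0; a non-positive slope raises a
"no detectable quenching" error.  Trend concordance between computed
ΔG_bind and measured K_a is a Kendall-type pairwise fraction: a sequence
pair is concordant when the more negative ΔG_bind has the larger K_a;
exact ties count one half.  This explicit pairwise definition is the
package's operationalization of "trend prediction success".

## Synthetic data

Generators emulate each input with known ground truth: planted ensembles
(k stereo-consistent torsion templates, separated by ≥ 60° in at least one
torsion, plus independent Gaussian torsional noise, default SD 5°);
complex poses at controlled centroid separation (clash-free by retry);
titration curves F = F₀/(1 + Q/K_d)·(1 + ε), ε ~ N(0, 2%) on a 12-point
0–11 mM grid with 68 µM oligomer metadata — mirroring a realistic
fluorescence titration window.  Gaussian independent torsional noise is a
statistical convenience that makes recovery tests exact, not a physical
claim: real ensembles have correlated torsions, anharmonic wells and
solvent friction, so passing recovery tests validates the analysis
machinery, not force-field realism.

## Known limitations

- The potential is intentionally minimal: no bonded flexibility (bond
  lengths/angles fixed), no explicit solvent, no entropy in ΔG_bind, and
  absolute binding energies are not comparable to published MD values —
  only relative, within-package comparisons are meaningful.
- Kinetics are not modelled; Monte Carlo move sizes are tuned for mixing
  (acceptance near 30–60%), not physical dynamics.
- Helix metrics and H-bond cutoffs are heuristics with configurable
  thresholds; conclusions sensitive to them should be checked across
  settings.
- Desk-scale ensembles (tens of frames) carry large statistical spread;
  the pipeline reports SD/percentiles so that spread is visible.
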