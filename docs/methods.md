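# Methods

This note documents the models implemented in `champ`, their
assumptions, the parameters that matter, and the choices made where the
design space was genuinely open. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

Coordinates are Å in a right-handed frame; the membrane normal is +z,
bilayer center z = 0; residue numbering is 1-based, sequences run N→C;
intervals are closed unless stated. Chain A is the target helix,
chain B the binder.

## Crick parameterization (geometry module)

Two-helix geometry uses the Crick coiled-coil equations in the
antiparallel special case. Helix A winds around the z axis at
superhelical radius `r0` (frequency `w0` deg/residue) while its CA
minor helix winds at radius `r1` (frequency `w1`); the axial rise per
residue is `r0·w0/tan(alpha)`. Helix B is generated from the same
equations, rotated 180° about x (a proper rotation — chirality is
preserved), and shifted by `z_offset`; its superhelical phase `dphi0`
is measured after that rotation. Sign conventions: left-handed
supercoils carry `alpha < 0` and `w0 < 0`; the signed crossing angle is
measured from helix A's axis direction to helix B's by the right-hand
rule about the inter-axis vector at closest approach, so the tight
antiparallel left-handed template sits at −175°, not +175°.

Schematically (viewed down +z):

```
        +y
         |      B (N→C into the page)
         |     o
  ───────+─────────── +x
         |     ^ 2·r0 between axes
         o     |
        A (N→C out of the page)
```

Defaults: rise 1.51 Å/res, twist 100°/res, CA radius 2.26 Å (textbook
values, config-overridable); the template's minor frequency is
720/7 ≈ 102.86°/res, matching the 3.5-residue repeat of a
small-X6-small interface. `CrickParams.from_pair_geometry(d, Ω, Δz)`
maps the printed descriptors to parameters (`r0 = d/2`,
`alpha = −(180−|Ω|)/2`, `w0` from the rise relation).

**Backbone dressing.** N, C and O are placed on coaxial helices whose
cylindrical offsets are re-solved (least squares) per (rise, twist) so
that N-CA, CA-C, the peptide C-N bond and the N-CA-C angle keep ideal
values; the chirality constant (improper dihedral C-N-CA-CB = +122.6°)
matches L-amino acids.

**Axis extraction.** A helix axis is the least-squares line through
rolling 4-CA centroids (robust to end fraying). Per-residue twist is
measured from second differences of the CA trace, which lie exactly in
the plane perpendicular to the axis — this measurement is free of the
axis-fit end bias and round-trips the construction twist to 1e-6°.

**Fitting.** `fit_crick` minimizes CA RMSD between the data and a
rigidly corrected ideal pair over all nine shape parameters plus a
residual rigid transform, after pre-aligning the data to the canonical
frame using descriptor estimates. The minor phases are multi-started
(the one genuinely multi-modal direction). Bounds derived from the
axis-based descriptors keep the weakly identified supercoil parameters
from drifting: on a 25-residue window the superhelical arc is only
~23°, so under 0.3 Å coordinate noise `r0` is only determined to a few
Å (the noisy-fit test freezes Monte-Carlo-derived tolerances of 3 Å /
3° / 1 Å); noiseless round trips recover all parameters to < 1e-3.
Grossly unequal helix lengths are truncated symmetrically to the
shorter length. A single helix is the degenerate case `r0 = 0`
(flagged; only r1/w1 are meaningful).

## Implicit membrane

The bilayer is a slab of hydrophobic half-thickness 15 Å (a 30 Å core)
with a sigmoid burial profile of width 2 Å; each residue contributes
`g_aa · burial(|z_CA|)` with per-residue transfer pseudo-energies
(apolars negative, charged residues strongly positive — simplified
hydrophobicity-scale values, config-exposed). Orientation optimizes
only (z shift, tilt, tilt azimuth) by a deterministic grid
(2 Å / 5° / 30°) with ties broken toward zero tilt and depth, then
Nelder-Mead refinement constrained to the TM regime (|z| ≤ 12.5 Å,
tilt ≤ 44°).

A pure per-residue transfer potential has a pathology: any uniformly
hydrophobic helix can always lower its energy by tilting flat into the
slab. Real TM helices pay an elastic price for hydrophobic mismatch,
so the objective adds `TILT_PENALTY·(1 − cos tilt)` with a default
weight (60) large enough that uniform hydrophobes stay near-upright
while charged flanks still drive z-shifts and modest tilts. Surface-
adsorbed orientations are out of scope.

## Binder placement and position designation

The binder is placed by generating the idealized template pair,
superposing template helix A onto the oriented target so that the
target's small-X6-small motif faces the partner (the template's minor
phase puts its central residue on the interface), and carrying helix B
along. The binder (24 residues, polyalanine) is trimmed to the window
whose start is congruent mod 7 with the most-buried template position —
so the binder's own motif frame lands on positions 1-8-15-22 — and
which is best centered in the slab.

"Embedded" binder positions are those with CA inside the hydrophobic
slab plus a 6 Å interfacial (headgroup) shell; on the template complex
this is all 24. Burial is the CB distance to the *finite* target axis
segment (clamped projection, so positions overhanging the target's ends
read as less buried). The motif frame is the 4-deep spacing-7 frame of
lowest mean burial; other embedded positions with burial < 9.0 Å are
"interface". The cutoff is calibrated so the template complex yields
13/24 interfacial (4 motif + 9 interface) — this calibration is
deliberately circular with respect to that count (SASA-style burial
rules used by layer-design protocols have no single closed form); the
nearest burial values sit ~0.5 Å on either side of the cutoff, so the
designation is stable to small geometric perturbations.

## Packing engine and design

Side chains are built from ideal internal coordinates with a
backbone-independent rotamer library (≤ 9 rotamers/residue, chi angles
from {−60°, 60°, 180°}; phenylalanine ring chi2 ∈ {30°, 90°}). The
design alphabet {G,A,S,T,C,V,L,I,F,M} carries full heavy-atom
topologies; other residue types are represented as CB plus a sized
centroid pseudo-atom and appear only in threading clash screens.

Energy: a soft 6-12 steric term (contact distance 0.95·(r_i+r_j),
well depth 0.15, repulsion capped), a geometric hydrogen bond
(O/N heavy-atom pairs < 3.5 Å with donor-base angle > 120° score −1),
and per-residue reference energies that make large residues pay for
their contacts (so neither polyalanine nor all-phenylalanine is
degenerate). Self and pairwise energies are precomputed into tables;
simulated annealing (geometric cooling 5 → 0.05, 60 sweeps) and
exhaustive enumeration share the same tables, which is what makes the
95/100-seed optimality check meaningful. Design packs classes in order
(motif → +interface → all), then tries rigid-body micro-perturbations
of the binder (±0.5 Å, ±5°) with rotamer-only repacks, keeping the best
pose. Everything is reproducible per seed.

The packing-quality score is a PackStat-style void metric: probe radii
{0.9, 1.2, 1.5, 1.8 Å} occupancy fractions averaged over a shell of
grid points (0.7 Å spacing) near the surface of both chains at the
interface; the grid frame is derived from the interface atoms
themselves, making the score rigid-motion invariant to 1e-6. Higher
means fewer interfacial voids; separating the helices strictly lowers
it.

Selection takes the top 10% by packing score (ties broken toward the
lexicographically smallest sequence, rounded up to ≥ 1), clusters them
by average linkage on a BLOSUM-similarity distance
`1 − s_ab/√(s_aa·s_bb)` — the matrix chosen nearest the set's average
pairwise identity from the available set {45, 50, 62, 80, 90} — and
reports each cluster's best-scoring member. Clusters whose consensus
motif letters cannot be packed on the template below a strain threshold
are flagged `geometry_strain` (an explicit geometric stand-in for the
one human model-inspection step), never silently dropped.

Lipid-facing randomization draws letters i.i.d. from
{A: 0.10, I: 0.10, V: 0.10, F: 0.10, L: 0.60} and rejects whole draws
while any Ala-X3-Ala or Ala-X6-Ala pair involving a lipid-facing
position exists. Rejection perturbs the alanine marginal slightly below
its nominal weight; the chi-square marginal test therefore samples the
raw distribution, and the rejection rule is tested separately as a
constraint.

## No-design control derivation

The control sequence copies the donor helix's interface letters
verbatim, redraws lipid-facing letters from the same weighted apolar
scheme, and appends Ala-Leu so the small-X6-small run reaches depth 4
with leucine (not alanine) as the final apolar residue; draws are
rejected until the motif count is exactly 4 and no forbidden Ala pair
involves a variable position. The bundled donor helix is synthetic
(the natural donor's exact TM span is not printed; its identity is a
config choice), with lipid positions biased toward letters outside the
draw set so that the copied-interface fraction dominates identity —
the derived controls average near half identity to the donor.

## Assay models

**FRET titration design.** Donor-labeled target at fixed concentration;
acceptor-labeled binder replaces unlabeled binder at fixed total
peptide, up to a 2:1 acceptor:donor ratio (the partner pool is twice
the donor pool, so acceptor fraction f = ratio/2). Relative donor
intensity: dimer `1 − bEf` (one partner per donor), trimer
`1 − bE(1 − (1−f)²)` (two partners), monomer 1. Micelle crowding
multiplies by `1 − E_c(1 − e^(−λf))`, where λ is the Poisson mean of
peptides per micelle from the crowding model (micelles =
(total detergent − CMC)/aggregation number). Because the dimer curve is
linear, only the product b·E is identifiable from dimer data; fits
report both with the product exact. Model selection uses AICc; flat
titrations select the monomer model with a warning. Bound fraction and
efficiency are both capped at 1.

**Disulfide exchange.** UV peak areas are converted to species moles
(response proportional to peptide count unless extinction weights are
given) and normalized over {AA, AB, BB}. The heterodimer enrichment
`f_AB/(2√(f_AA·f_BB))` equals 1 exactly under equimolar random pairing
(1:2:1) at any scale and diverges when a homodimer is absent (reported
as infinity with a flag, never as a number).

**CSP / NIC.** Per-atom Δδ = |bound − free| over matched
(residue, atom) keys; duplicates are errors, unmatched keys are
reported. Normalization is 0–1 to the largest numeric shift; residues
broadened beyond detection are carried as flags and excluded from both
normalization and periodicity fitting, never imputed as zeros. The
combined amide CSP uses the standard convention's nitrogen weight 0.14
(config-exposed). NIC is
the per-target-residue minimum interhelical CA-CA distance, min-max
normalized over membrane-core residues — this formula is this
repository's documented definition of the metric. Periodicity is a
cosine fit with the period bounded to [3.0, 4.5] residues (grid search
over the period with linear harmonics, then local refinement), with
Pearson correlation against NIC closeness reported when available.

## Synthetic data and what passing tests show

The fixture generators emulate: helix-pair libraries as Gaussian
perturbations (σ = 0.3 Å coordinates; 0.15 Å / 1.5° / 0.3 Å on the
archetype descriptors) around three geometry archetypes; titrations as
the theoretical curves plus i.i.d. Gaussian noise (σ = 0.02, 9 points);
species tables as scaled fractions; CSP tables as a cosine or
NIC-derived pattern scaled to 0.6 ppm on a CA baseline. They do not
emulate: real rotamer statistics or packing defects, lipid-specific
effects, chromatogram baselines or peak overlap, NMR exchange-regime
lineshapes, or correlated/systematic noise. Recovery tests on these
fixtures therefore demonstrate correctness of the estimators under
their own generating models — identifiability, normalization and
selection logic — not performance on experimental data.

Problem sizes used by the default suite and acceptance script
(25-residue helices, 24-entry libraries, 100-seed recovery studies,
100,000 categorical draws) are the package's chosen desk-scale
defaults; all are config- or argument-scalable.

## Known limitations

- The packing energy is not a calibrated force field; scores rank
  designs, they do not predict affinities.
- The Crick fit's supercoil radius is weakly identified on single-TM
  length segments under coordinate noise (see above).
- The implicit membrane has no lipid specificity, charge-state or pH
  handling; the tilt elasticity weight is a modeling constant, not a
  fitted quantity.
- Bundled sequences are constraint-faithful synthetic stand-ins, not
  database extracts; analyses that depend on the real residues beyond
  the documented constraints need user-supplied sequences/structures.
- No n > 2 helix bundles, bent/kinked helices, or off-target negative
  design.
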