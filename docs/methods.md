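# Methods

This note records the conventions, parameter choices and numerical
decisions behind `foldeval`, and what the synthetic fixtures do and do
not establish about real data.

## Geometry conventions

Dihedrals are signed IUPAC torsions in (−π, π]: cis = 0, trans = π,
computed with the two-plane-normal atan2 construction and guarded
against zero-length bonds and collinear triples (an explicit
`GeometryError`, never a silent 0). The test suite checks the routine
against an independently coded projection construction and under random
global rigid motions.

Backbone frames use the Gram–Schmidt construction on (N, CA, C) with
the origin at CA: ê₁ along CA→C, ê₂ the CA→N component orthogonal to
ê₁, ê₃ = ê₁ × ê₂. This is the de-facto standard frame for
frame-aligned losses; the frame inverse therefore places CA at the
origin, C on +x and N in the upper xy-plane, which the tests assert
numerically.

χ-defining atom quadruples follow the standard rotamer convention
(e.g. ARG χ₁ = N-CA-CB-CG). The π-periodic terminal angles — ASP χ₂,
GLU χ₃, PHE χ₂, TYR χ₂ — carry an explicit symmetry flag. Whether a
training loss should min-correct these flips is genuinely open, so the
correction is a switch: off by default in `angle_loss` (the raw printed
formula), on by default in the evaluation statistics (`chi_accuracy`,
`sequence_confidence`), where flip-forgiveness is the field's standard
practice. Missing χ-defining atoms mask that χ and everything downstream
of it, with a warning record rather than a zero-fill.

Nonstandard residues with an unambiguous parent (MSE→MET, SEP→SER, …)
are mapped; anything else is skipped by the PDB reader with a
`ParseReport` entry. Altloc conflicts resolve to highest occupancy,
ties to the lowest altloc letter.

## Loss components

**Torsion recursion.** The conditioned error uses
f(a, b) = a + b − ab/2 on [0, 2]². Algebraically f is bounded by 2
(f(a,b) ≤ 2 ⇔ (2−a)(2−b) ≥ 0), monotone in both arguments
(∂f/∂a = 1 − b/2 ≥ 0) and dominates both inputs; 2 is absorbing. The
availability mask must be a prefix pattern per residue — χₖ without
χₖ₋₁ is chemically impossible and rejected. The loss divides by the
total residue count N, not the number of residues possessing each χ.

**FAPE.** Implemented exactly as the clamped L2 norm of the
local-coordinate difference (the prose word "squared" in some
descriptions refers to the ‖·‖₂ notation; a squared quantity could not
clamp at 10 Å). The scalar is the arithmetic mean over all
(frame, point) pairs. An optional `length_scale` divisor exists but is
off by default. The weighted variant multiplies each term by
w(d_{i,r(j)}) where r(j) is the residue owning atom j — the weight is
defined on residue pairs, atoms inherit it. Self-pairs use the mode
matrix's zero diagonal, hence the maximal weight ≈ 1 + h; aggregation is
the plain mean of weighted terms, with `normalize_by_weight_sum` as a
documented alternative since neither convention is canonical.

**Cross-entropies.** Probabilities are floored at 1e-8 before the log —
pure numerical hygiene; results are insensitive to the floor anywhere
above 1e-12. Rows must be on the simplex to 1e-6. The confidence score
bins are uniform half-open intervals over [0, 1] with the last bin
closed so s = 1 is representable.

**Combined objective.** c₁…c₄ default to 1.0. These are library
placeholders, not values any trained model used; the published defaults
are only known for the six auxiliary weights
(0.5, 0.3, 2.0, 0.01, 0.01, 1.0). Callers doing anything quantitative
with the combination must set c₁…c₄ themselves (YAML config or
`LossWeights`).

## Distograms

Bins are defined by an ascending edge array: bin k spans
[edgeₖ, edgeₖ₊₁), the last bin is open-ended. Representative distances
are midpoints; the open bin uses last edge + half the previous width.
The default layout is 64 bins spanning 2.3125–21.6875 Å (the standard
distogram-head span); both the layout and the midpoint convention are
package choices — mode distances are therefore accurate only to half a
bin width (~0.15 Å at the default layout), which is immaterial against
the gentle slope of w(d). Argmax ties break toward the lower bin.
The synthetic generator discretizes a Gaussian (σ = mean bin width /
`sharpness`) around true Cβ distances, with optional seeded simplex
noise; GLY falls back to CA, as everywhere Cβ is needed.

## Evaluation

**χ-accuracy** uses strict inequality at the threshold (default 10°) so
the boundary case is deterministic; `wrap_angle` passes values already
in (−π, π] through exactly to keep that determinism.

**Alignment quality** collects native pairs with author-numbering
separation ≥ 4 and Cβ distance < 8 Å; a collected pair with an unaligned
endpoint stays in the denominator as a failure, so the ratio reflects
both alignment coverage and geometric fidelity. The distance atom is Cβ
(CA for GLY) — consistent with the distogram convention; the reference
procedure does not name the atom.

**Z-scores.** Standardization uses the sample standard deviation
(ddof = 1): three groups at (10, 20, 30) give Z = (−1, 0, +1). Default
is the long-standing CASP two-pass scheme — exclude first-pass Z < −2,
re-standardize against the survivors, floor the final Z at −2 — with a
one-pass switch since assessments differ in this detail. Zero spread
gives Z = 0 for every group. Lower-is-better metrics (SCerror,
Molprobity, BBerror, DipDiff) are negated before standardizing.
`assessor_sum_z` skips domains missing any of the ten metrics, with a
warning.

## Synthetic fixtures

`make_peptide` builds backbones by natural-extension placement from
ideal internal coordinates (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å;
canonical helix φ/ψ = −57°/−47°, extended −139°/135°, ω trans) and grows
side chains along the χ-defining chains with generic bond geometry, χ
drawn uniformly on the circle from the seed. `perturb_chi` rotates each
available χ about its bond axis by Gaussian noise and reports exact
deltas by re-extracting torsions from both structures, so
confidence/accuracy statistics can be validated against ground truth to
machine precision. `perturb_rigid` applies per-residue random
translations (RMS norm = target) plus small rotations about CA
(0.1 rad/Å of target).

What these fixtures establish: the losses and statistics compute the
stated formulas, with correct masking, symmetry handling, clamping and
invariances. What they do not establish: behaviour on real structures
with clashes, alternative conformations, chain breaks, non-ideal
geometry or realistic rotamer distributions — the peptides are
idealized and clash-free by construction. The PDB reader's
altloc/HETATM handling is tested on hand-written records, not on the
full diversity of deposited files.

## Problem sizes and determinism

All generators and perturbations are pure functions of (arguments,
seed). The test suite runs on peptides of 10–80 residues, 2000 residues
for the uniform-noise accuracy check (binomial tolerance 3 sd), 10⁵
points for the recursion-algebra grid, and 100–1000 instances for the
oracle-equivalence and invariance suites — sizes at which every
assertion is sharp while the whole suite stays interactive.

## Known limitations

- Losses are values only; no gradients, so this is an analysis/QA tool,
  not a training library.
- Single-chain models; no insertion-code-aware alignment mapping
  (alignments index ungapped sequence positions).
- FAPE aggregation conventions (mean vs weight-sum) and the c₁…c₄
  weights must be chosen by the caller for cross-study comparability.
- The distogram format is package-defined; converters from predictor
  pickle outputs are out of scope.
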