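# foldeval

Loss functions and assessment statistics for protein structure
prediction, computable on plain coordinates — no neural network
required.

Modern folding models are trained with objectives that go beyond
backbone superposition: side-chain torsions, local frame errors,
distance-dependent weighting, secondary structure and per-residue
confidence all enter the loss. Assessing such models likewise needs
statistics beyond GDT. `foldeval` implements a coherent set of both, for
method developers who want to score structures (real or synthetic)
against a reference, and for anyone reproducing CASP-style rankings from
raw metric tables.

## What it computes

**Sequentially conditioned torsion loss.** Side-chain torsions
χ₁…χ₄ are chained: the position of every atom defining χₖ depends on
χₖ₋₁. With the per-angle chord error
E_χₖ = ‖(cos χₖ, sin χₖ) − (cos χ̂ₖ, sin χ̂ₖ)‖ ∈ [0, 2], the conditioned
("pre-torsion") error propagates upstream mistakes:

    Ẽ_χ₁ = E_χ₁,   Ẽ_χₖ = Ẽ_χₖ₋₁ + E_χₖ − Ẽ_χₖ₋₁ E_χₖ / 2   (k = 2, 3, 4)

so a correctly predicted χ₂ still incurs error when χ₁ is wrong; the map
keeps [0, 2] invariant and 2 is absorbing. The loss is
L_angle = (ΣE_χ₁ + ΣẼ_χ₂ + ΣẼ_χ₃ + ΣẼ_χ₄)/N over N residues.

**Weighted FAPE.** Frame-aligned point error expresses every atom xⱼ in
every residue's backbone frame Tᵢ and clamps the local discrepancy:

    L_FAPE(Tᵢ, xⱼ) = min(‖Tᵢ⁻¹ xⱼ − Tᵢ⁻¹⁽ᵗʳᵘᵉ⁾ xⱼ⁽ᵗʳᵘᵉ⁾‖, 10 Å)

The weighted variant multiplies each term by
w(d) = 1/(1 + e^(−2(v − d))) + h with v = 12.0 Å, h = 1.5, where d is
the mode (argmax-probability) Cβ–Cβ distance from a distogram — close
pairs weigh up to 1 + h, distant ones decay to h.

**Secondary-structure and confidence losses.** Mean cross-entropy over
the 8-state DSSP alphabet; a side-chain confidence
s = 1/(1 + (δ/δ₀)²) on the χ₁ error with δ₀ = 12°, discretized into 50
bins with its own cross-entropy; and the combined objective
L = c₁L_angle + c₂L_WFAPE + c₃L_secondary + c₄L_sc + c·L_others with the
six auxiliary losses entering as caller-supplied scalars.

**Evaluation statistics.** χₖ-accuracy at the 10° criterion
(π-flip-corrected for two-fold symmetric end groups), per-sequence mean
confidence, a template alignment-quality ratio (fraction of native
contact pairs — separation > 3, distance < 8 Å — whose distance the
aligned template reproduces within 3 Å), and CASP-style assessment:
per-(domain, metric) Z-scores across groups (two-pass, floored at −2)
aggregated as

    sum Z = 1/6 (GDT-HA + reLLG + ASE) + 1/16 (LDDT + AA + SG + SCerror)
          + 1/12 (Molprobity + BBerror + DipDiff)

whose weights sum to exactly 1 per domain.

A deterministic fixture generator (`make_peptide`, `perturb_chi`,
`perturb_rigid`) builds idealized peptides with known ground-truth
torsions so every quantity is testable end to end.

## Worked example

```sh
$ foldeval simulate --sequence SRLFKDEYWQ --chi-noise 20 --rigid-noise 1.0 \
      --seed 7 --out demo
$ foldeval losses --native demo/native.pdb --model demo/model.pdb \
      --distogram demo/native.dgram
{
  "FAPE": 1.5324679606841647,
  "L_WFAPE": 3.6688602398919716,
  "L_angle": 1.3441600403769054,
  "L_combined": 5.0130202802688775
}
$ foldeval chi-acc --native demo/native.pdb --model demo/model.pdb --k 1
0.200000
```

The simulated "model" perturbs each χ by ~20° of Gaussian noise and
jitters residues rigidly by ~1 Å: the mean clamped local-frame error is
1.53 Å, the distogram-weighted variant scales it by per-pair weights in
(1.5, 2.5), the torsion loss of 1.34 reflects the chained χ errors, and
only 20 % of χ₁ angles land within the 10° criterion at this noise
level. (`demo/native.dgram` above was written with
`distogram_from_structure(native, sharpness=20.0)`; the combined value
uses the library's placeholder unit weights c₁…c₄.)

The `examples/` directory holds one narrative script per capability
(torsion loss, weighted FAPE, confidence losses, template quality, CASP
ranking); each prints its numbers with a line on what they mean.

## Layout

- `src/foldeval/geometry.py` — dihedrals, χ extraction, backbone frames
- `src/foldeval/losses.py` — all loss components and the combined objective
- `src/foldeval/distogram.py` — distance-bin tensors and mode distances
- `src/foldeval/evaluation.py` — χ-accuracy, alignment quality, Z-scores
- `src/foldeval/io_formats.py` — PDB / FASTA / distogram / CSV / SS readers
- `src/foldeval/fixtures.py` — synthetic peptides and perturbations
- `src/foldeval/cli.py` — the `foldeval` command
- `docs/methods.md` — model details, conventions and limitations
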