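# Methods

This note documents the models, conventions and design choices behind
trpmhc, in the order the pipeline applies them.

## Structure model

PDB text is parsed with gemmi and reduced to heavy atoms of model 1.
Waters are always dropped; other HETATM records are dropped by default
(no glycans are modelled). Alternate locations resolve to the
highest-occupancy conformer, ties to the lexicographically first altloc
code. Insertion codes are preserved verbatim; all residue matching is by
(author number, insertion code) and no renumbering is ever applied.
Because gemmi tolerates malformed coordinate fields, `parse_pdb` runs its
own pre-check of the three coordinate columns so that a corrupt record
fails loudly with its line number.

Chain roles (MHC α/β, β2-microglobulin, peptide, TR α/β) come from a
user map; an optional fallback promotes the shortest unmapped chain of
8–25 residues to peptide. MHC class is II exactly when both MHC α and β
chains are present. Truncation cuts each annotated complex into the two
rigid units the rest of the pipeline consumes — the pMHC interface (groove
domains plus the whole peptide) and the TR variable domains — using
per-role residue ranges. The defaults (MHC-I α 1–180; MHC-II α 1–85,
β 1–95; TR Vα/Vβ 1–115) follow standard domain boundaries and are
configurable; they are a choice, since no canonical ranges exist for
this truncation.

## Contacts and conservation

A contact is a residue pair, one residue per unit, with any heavy-atom
distance ≤ 5.0 Å (configurable). 5 Å is the conventional criterion for
TR/pMHC contact tables; the minimum atom distance is recorded per pair.
The paratope/epitope are the unique TR-side/pMHC-side residues of the
contact list.

Conservation is profiled over a supplied common numbering (an IMGT-style
3-column TSV) rather than by running a multiple aligner; this removes an
external-tool dependency while preserving the analysis. Per common
position, `occupancy` is the fraction of structures in which the position
is contacted and `conservation` is the modal-residue count over all
structures. A position is "conserved" at ≥80% occupancy regardless of
identity; a residue is "conserved" when identical in 100% of structures
and "mostly conserved" at ≥90% — matching the qualitative usage these
terms have in interface-conservation tables.

## Binding energy

The potential is a symmetric table ū(tᵢ, tⱼ, bin) over distance bins with
ū = 0 at and beyond the last edge (r_cut); distances below the first edge
score in bin 0. Typing is residue-level by default (an atom carries its
parent residue's 3-letter code) with an atom-level scheme available.
Binding energy sums ū once per unordered cross-unit atom pair — the
rigid-body ΔG_bind = G(AB) − G(A) − G(B) collapses to exactly this sum,
which also realises the ½ double-counting factor of the per-structure
free-energy sum. Unknown atom types are skipped and counted (or raise,
per policy). An O(n²) brute-force evaluator ships as an independent
oracle; the KD-tree implementation must agree with it exactly on small
complexes.

The packaged toy table (7 residue types, 2 Å bins to 8 Å: opposite
charges attract, like charges repel, mild generic attraction) exists to
exercise the machinery on synthetic complexes; its absolute scale is
arbitrary. For realistic tables, `train_dfire_table` derives a DFIRE-form
potential — distance-scaled ideal-gas reference anchored at the cutoff
bin, α = 1.61 — from any user-supplied structure set. The η prefactor
defaults to 1.0 and is a free scale; parity with any particular published
scoring program is not claimed, so published per-complex energies serve
as calibration references rather than exact targets.

Thermodynamic conversion uses ΔG = RT·ln(Kd) with R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default (1 µM ↦ −8.18 kcal/mol).

## Interface electrostatics

Formal charges: Asp/Glu −1 at the carboxylate-oxygen centroid, Lys +1 at
NZ, Arg +1 at CZ, His neutral by default (+1 at the imidazole-nitrogen
centroid when enabled), termini uncharged. Missing side-chain atoms fall
back to CB then CA, with the fallback recorded.

The field is a uniform-dielectric screened Coulomb potential,
φ(x) = Σ qᵢ·exp(−κrᵢ)/(ε·rᵢ), defaults ε = 80 and κ = 0.124 Å⁻¹
(≈150 mM ionic strength at 298 K), with r clamped at 0.1 Å. This
closed-form model deliberately replaces a finite-difference
Poisson–Boltzmann solver: it is linear in the charges, exact to evaluate,
and preserves the structure of the similarity analysis at desk scale; it
ignores dielectric boundaries and solvent-accessibility weighting, so
absolute potentials are not physical — only comparisons on a shared grid
are used.

Fields are sampled on a regular grid skin 3–7 Å above the groove plane
(1 Å spacing). Comparing complexes requires a common frame: each complex
is mapped to a canonical groove frame (plane → z = 0 with the TR side at
+z, projected peptide axis → +x, plane centroid → origin) before
sampling, so all fields share one grid. Similarity uses the Hodgkin
index; an all-zero field has no defined similarity and its pairs are
flagged rather than scored. Distances √(2 − 2·SI) feed average-linkage
(UPGMA) clustering; the tree records ultrametric node heights (half the
cophenetic distance, so a leaf sits `height` below its merge node) and
exports to Newick with `id|allele|tr_type|species` leaf labels.

## Docking angle

The angle-measurement protocol formalises a manual drawing procedure:

1. peptide axis — total-least-squares (SVD) line through the peptide Cα
   atoms, oriented N→C;
2. groove plane — least-squares plane through the pMHC-unit Cα atoms,
   normal oriented toward the TR side;
3. ring — a groove charge joins iff its residue is in the epitope and at
   least one opposite-sign TR charge sits on a contact-partner residue
   within the pairing radius (default = contact cutoff, 5 Å); charges
   failing the cross-verification are omitted;
4. ellipse — the ring's groove-plane projections are decomposed by 2-D
   PCA; "the diagonal across the ellipse" is interpreted as the major
   axis (the leading component);
5. θ — the signed in-plane angle from the projected peptide direction to
   the major axis, reduced modulo 180°.

θ therefore lives in [0°, 180°) and is *not* folded at 90°: receptors
tilted the opposite way across the peptide read as obtuse angles (e.g.
112°), which the folded convention would alias to 68°. The plane-normal
orientation (toward the TR) fixes the handedness, making θ invariant
under rigid motions and mapping mirror reflections to 180° − θ. Rings
with fewer than 4 verified charges are rejected (the ellipse is
underdetermined); near-isotropic rings (major/minor < 1.05) return θ
flagged low-confidence. Ring ordering (clockwise about the centroid) is
cosmetic — PCA is order-free — but kept for reporting. Charge anchors,
not Cα positions, are projected, since the rings are defined by displayed
side-chain charges.

## Agonist statistics

Cutoffs use the sample (n−1) standard deviation — the population/sample
choice is unstated in the conventions this follows, and sample SD is the
safer default at n ≈ 10–50. Weak is strictly above mean + sd, strong
strictly below mean − sd, boundaries belong to moderate. Percentages are
rounded half-up to integers. The BE–θ correlation reports Pearson r, r²,
and the least-squares line of BE on θ, both with and without a
user-supplied exclusion list (reproducing manual outlier removal), plus
an automatic flag at |internally studentized residual| > 2 — flagged
records are reported, never silently dropped.

## Synthetic complexes

The generator builds geometric cartoons of the TR/pMHC interface with
known truth, not physical proteins:

* a peptide of Gly residues, extended at 3.5 Å Cα spacing along +x in the
  groove plane, N-terminus at −x;
* two ideal-helix walls (1.5 Å rise, 100°/residue, 2.3 Å radius) at
  y = ±9 Å, on one MHC chain (class I) or two (class II);
* n ≥ 4 charged residues whose side-chain anchors are planted exactly on
  an ellipse (semi-minor 0.8 × groove half-width, aspect 1.75) whose
  major axis makes the requested θ_true with the peptide axis — placing
  the ring points at uniform parameter angles makes the PCA axes coincide
  exactly with the ellipse axes, so the noise-free measurement is exact;
* negative charges on the N-terminal half and positive on the C-terminal
  half (the "flipped" pattern inverts every charge, emulating the rarer
  predominantly-inverted interfaces and giving SI ≈ −1 against standard
  ones);
* TR partner charges of opposite sign 4 Å above each ring anchor, split
  into Vα/Vβ pseudo-domains on either side of the major axis, plus
  neutral framework residues; two partner-less distractor charges sit at
  the helix ends to exercise the cross-verification filter;
* optional isotropic Gaussian coordinate noise; one RNG stream per spec
  seed, and identical seeds produce byte-identical PDB output.

Datasets draw θ_true uniformly and plant BE = a + b·θ + N(0, σ). Study
defaults — 50 complexes, θ on [20°, 110°] (spanning the characteristic
acute-to-obtuse range of observed dockings), coordinate noise 0.3 Å,
a = −22 kcal/mol, b = +0.12 kcal/mol/deg, σ = 1 kcal/mol — give a strong
but noisy linear law (r ≈ 0.94) comparable to reported BE–θ
correlations. Passing tests on these toys demonstrates that the
*machinery* (matching, projection, PCA, regression, clustering) recovers
planted truth under moderate noise; it says nothing about crystallographic
disorder, missing side chains, non-elliptical rings or charge patterns
real MHC helices display, which the cartoons do not emulate.

## Numerical choices and degeneracies

* Contact and pairing searches use KD-trees; ties in altloc occupancy,
  polar ring ordering and eigen-decomposition are all resolved
  deterministically, so identical configs give bit-identical outputs.
* Lines need ≥3 Cα, planes ≥10 Cα and a non-collinear spread; violations
  raise degenerate-geometry errors rather than returning junk.
* The in-plane basis seeds from the global axis least aligned with the
  normal; θ compares two in-plane directions, so the arbitrary seed
  cancels.
* Zero-variance energy sets (sd = 0) refuse to define cutoffs; zero
  variance in either regression variable refuses to define r.
* Distance-matrix clustering asserts symmetry and rejects flagged (NaN)
  entries instead of guessing.

## Problem sizes

The shipped studies use 50-complex cohorts (~140 atoms each) for angle
and correlation recovery, 12 complexes for clustering, and ≤200-atom
toys for the brute-force energy cross-check; these sizes give stable
statistics (binomial/regression standard errors well inside the asserted
tolerances) while keeping the whole suite and the acceptance script fast
to re-run.

## Known limitations

* No mmCIF input, structure repair, symmetry expansion or automatic MHC
  class detection from sequence.
* The statistical potential's absolute scale is table-dependent; computed
  toy energies are not kcal-accurate free energies.
* Electrostatics is uniform-dielectric screened Coulomb; no
  Poisson–Boltzmann, partial charges or buried-surface weighting.
* Conservation requires a user-supplied common numbering; the package
  does not compute IMGT numbering.
* The V-domain mass-centre "diagonal" angle convention from the
  literature is a different quantity from θ and is deliberately out of
  scope.
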