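# trpmhc

Structural analysis of T-cell-receptor recognition of peptide–MHC
(TR/pMHC) complexes: statistical-potential binding energies, interface
electrostatics, charge-ring docking angles, paratope/epitope conservation
and agonist-strength statistics — with a synthetic toy-complex generator
that provides ground truth for every stage.

## The problem

When an αβ T-cell receptor docks onto a peptide–MHC complex it does so at
a characteristic angle to the bound peptide, and the strength of the
interaction decides whether the peptide acts as a weak, moderate or strong
agonist of T-cell activation. This package implements a reproducible
pipeline for dissecting that interaction from crystal structures (or
synthetic stand-ins):

* **Binding energy (BE).** A rigid-body knowledge-based estimate
  ΔG_bind = G(AB) − G(A) − G(B), where G sums atom–atom potentials of mean
  force ū(tᵢ, tⱼ, r) over pairs not in the same residue. Because the units
  are rigid, intra-unit pairs cancel and the BE reduces to the sum of ū
  over cross-unit atom pairs within the table cutoff. Tables are
  exchangeable inputs: a packaged residue-typed toy table drives the
  synthetic studies, and a DFIRE-form trainer
  (ū = −η·RT·ln[N(i,j,r) / ((r/r_c)^α (Δr/Δr_c) N(i,j,r_c))], α = 1.61)
  can derive one from any structure set. Kd ↔ ΔG conversion uses
  ΔG = RT·ln(Kd).
* **Agonist classes.** Per MHC class, weak/moderate/strong cutoffs at
  mean ± one sample SD of the analysed energies; boundary values are
  moderate, and a positive energy is weak (non-binding).
* **Interface electrostatics.** Unit formal charges on Asp/Glu (−1) and
  Lys/Arg (+1) side chains generate a screened-Coulomb (Debye–Hückel)
  potential φ(x) = Σ qᵢ e^(−κr)/(εr) on a grid skin above the groove
  plane; interfaces are compared with the Hodgkin similarity index
  SI = 2⟨φₐ,φᵦ⟩/(⟨φₐ,φₐ⟩+⟨φᵦ,φᵦ⟩), converted to electrostatic distances
  √(2 − 2·SI) and clustered with UPGMA.
* **Docking angle θ.** Groove charges that belong to the epitope and have
  an opposite-sign TR partner among their contacts form a ring; projected
  into the groove plane the ring is elliptical, and θ is the in-plane
  angle between the ellipse's major axis (2-D PCA) and the peptide's
  N→C backbone axis, reported in [0°, 180°) without folding at 90°.
* **Conservation.** Paratope (TR side) and epitope (pMHC side) residues
  from 5 Å heavy-atom contacts, profiled across structures over a
  user-supplied common numbering (IMGT-style map).

## Worked example

```python
from trpmhc import *
from trpmhc.synth import ToyComplexSpec, generate_toy_complex

spec = ToyComplexSpec(theta_true=72.0, n_ring_pairs=8, seed=3)
structure, truth = generate_toy_complex(spec)
pmhc, tr = truncate_complex(structure)

cm = compute_contacts(pmhc, tr, cutoff=5.0)
plane = groove_plane(pmhc, tr)
ring = match_complementary_charges(
    assign_formal_charges(pmhc), assign_formal_charges(tr), cm, plane
)
theta = docking_angle(ring, peptide_axis(pmhc), plane)
be = binding_energy(pmhc, tr, load_default_table())
print(len(cm), ring.n_points, round(theta.theta, 2), round(be.be, 1))
```

prints `24 8 72.0 -78.5`: 24 residue–residue contacts across the
interface, all 8 planted charge pairs survive complementarity matching
(the 2 partner-less distractor charges are rejected), the docking angle
comes back at the planted 72.0°, and the toy potential scores the
interface at −78.5 kcal/mol (toy-table scale; more negative = stronger).

The same stages run from the shell:

```bash
trpmhc simulate --out demo --n 10 --seed 7     # PDBs + truth + config
trpmhc run --config demo/config.yaml --out demo/results
trpmhc config-schema                            # documented defaults
```

`demo/results/` then holds the per-structure TSV (BE, agonist class, θ,
contact counts, cluster id), the global JSON blocks (cutoffs,
classification summary, BE–θ correlation) and the annotated Newick tree.

## The analysis

`analysis/` contains the numbered study scripts, each a thin driver over
the package (run them in order from the repository root):

1. `01_simulate.py` — generate the 50-complex cohort (θ uniform on
   20–110°, coordinate noise 0.3 Å, planted BE = −22 + 0.12·θ + N(0,1))
   and a 12-complex cohort with 40% charge-flipped interfaces.
2. `02_interface_contacts.py` — contacts, paratope/epitope sets and
   conservation profiles across the cohort.
3. `03_binding_energy.py` — statistical-potential energies, cutoffs and
   weak/moderate/strong classification.
4. `04_docking_angles.py` — θ recovery against the planted angles,
   including obtuse (>90°) dockings.
5. `05_correlation.py` — regression of BE on measured θ with outlier
   flagging and exclusion.
6. `06_electrostatic_clustering.py` — Hodgkin similarity, UPGMA tree and
   recovery of the planted two-group split.

Tables land under `results/`; bulky regenerable artefacts (the PDB files)
under `scratch/`.

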