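# mcligand

Multiconformer ligand modeling into crystallographic and cryo-EM density.

Ligands bound to proteins are rarely frozen in a single pose: the density in
a well-measured map is a population average, and a flexible ligand often
needs two or three discrete conformers with fractional occupancies to
explain it. Building those alternate conformers by hand is slow and biased.
`mcligand` automates it: given a protein–ligand structure with a
single-conformer ligand, a density map, and a SMILES template for the
ligand's chemistry, it samples thousands of binding-site-compatible
conformers, fits their occupancies against the observed density, and returns
a parsimonious 1–3 conformer model embedded back into the untouched parent
structure. It is aimed at structural biologists and structure-based drug
designers who want occupancy-aware ligand models from X-ray maps, PanDDA
event maps, or high-resolution cryo-EM reconstructions.

## Method

1. **Biased conformer generation.** A distance-geometry embedding engine
   (RDKit's ETKDG with MMFF94 cleanup, behind a pluggable interface)
   generates 5,000 conformers for ligands under 25 heavy atoms and 7,000
   otherwise, split evenly across the applicable search strategies:
   *unconstrained*, *fixed terminal atoms* (terminal pair distances pinned),
   *blob* (poses confined to the input ligand's bounding sphere),
   *branching* (core fixed, side chains of ≥4 atoms move), *long chain*
   (side chains of >30 atoms fixed, core moves), and an optional
   *180° flip* search. Redundant conformers (RMSD < 0.2 Å) are pruned.
2. **Occupancy fitting.** Each conformer's density is transcribed onto the
   map grid; occupancies ω solve the convex program

       min_ω ‖ρ_c ω − ρ_o‖²   s.t.  0 ≤ ω_i ≤ 1,  Σ ω_i ≤ 1

   over the footprint mask. Survivors are enriched with rigid-body
   perturbations (±5/10/15° rotations, ±0.3 Å translations) and refit.
3. **Parsimonious selection.** A mixed-integer QP with indicator variables
   z_i ∈ {0,1}, z_i·t_min ≤ ω_i ≤ z_i, Σz_i ≤ 3 (2 for cryo-EM) and
   t_min = 0.20 picks the final set exactly (exhaustive support
   enumeration). Conformers below 0.1 occupancy are culled; survivors get
   altlocs A/B/C in descending occupancy.
4. **Validation.** RSCC (Pearson correlation of observed vs calculated
   density over the shared mask), per-atom EDIA and ligand EDIAm (capped
   density z-scores with distance weighting and grid-point ownership), and
   coordinate RMSD. Torsion strain is exposed as a pluggable interface.

A synthetic benchmark module generates two-conformer ground-truth models
(ring flip, rigid displacement, torsional shift, macrocycle branch rotation)
at occupancy splits 0.50/0.50 … 0.10/0.90 and simulates maps at 0.8–2.5 Å
with resolution-ramped B-factors and resolution-proportional noise — 360
cases used to characterize the method's detection limits.

## Worked example

Fit a simulated noise-free 0.50/0.50 two-conformer map, starting from the
"A" conformer alone (the snippet writes the example inputs itself):

```python
import numpy as np
from mcligand.benchmark import (build_true_model, ramp_bfactors, simulate_map,
                                single_conformer_input)
from mcligand.ligand import assign_bond_orders
from mcligand.model import MultiConformerLigandModel

true_model, bonded, cell = build_true_model("torsional_shift", (0.5, 0.5))
true_model = ramp_bfactors(true_model, 1.0)
grid = simulate_map(true_model, cell, 1.0, seed=1, noise_scale=0.0, ramp=False)
ligand = single_conformer_input(true_model)

problem = MultiConformerLigandModel(assign_bond_orders(ligand, "c1ccccc1CCCCO"),
                                    grid)
results = problem.fit(seed=1, n_conformers=400)
print(results.summary())
```

```
Multiconformer ligand fit
==========================================================
ligand            LIG A 401  (11 heavy atoms)
map resolution    1.00 Å
cardinality       3   t_min 0.20   seed 1
----------------------------------------------------------
altloc   occupancy
A             0.50
B             0.50
----------------------------------------------------------
RSCC              0.9997
generated              400
pruned                  11
qp1_support              5
perturbed               80
qp2_support              7
miqp_support             2
final                    2
```

The fit recovers both conformers at their true occupancies (0.50/0.50) and
the calculated density of the two-conformer model correlates with the map
at RSCC 0.9997; the stage counts show the pool shrinking from 400 generated
conformers to the final pair. The same run from the shell:

```sh
mcligand example.ccp4 example_input.pdb A,401 -sm 'c1ccccc1CCCCO' \
         -r 1.0 -nc 400 -s 1 -o example_out.pdb
```

prints `conformers: 2  occupancies: A=0.50, B=0.50` and writes the
multiconformer model with altloc records. MTZ map coefficients are accepted
in place of a gridded map (`-l 2FOFCWT,PH2FOFCWT`), `--cryo_em_ligand` caps
the output at two conformers, and `--BDC x` rescales occupancies by
(1 − BDC) for PanDDA event maps.

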