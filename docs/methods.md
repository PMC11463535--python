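# Methods

This note records the model behind `mcligand`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## The model

A ligand observed in an averaged density map is treated as a small discrete
mixture: conformers c₁…c_K with occupancies ω ∈ [0,1]^K, Σω ≤ 1. The map
region attributed to the ligand (the footprint mask) is a linear function of
the mixture, so the occupancies of a candidate pool solve the convex
quadratic program

    min_ω ‖ρ_c ω − ρ_o‖²,  0 ≤ ω_i ≤ 1,  Σ ω_i ≤ 1,

where the rows of ρ_c are per-conformer calculated densities at unit
occupancy and ρ_o is the observed density over the same mask. Parsimony is
imposed afterwards by a mixed-integer version of the same objective with
indicators z_i ∈ {0,1}, z_i·t_min ≤ ω_i ≤ z_i and Σ z_i ≤ cardinality. The
total occupancy is allowed to remain below 1 (partial-occupancy binding is
real); no renormalization to Σω = 1 is performed, and occupancies below 0.1
in the final selection are culled (an optional flag proportionally
redistributes culled weight, off by default because that step belongs to an
external refinement loop).

Assumptions: heavy atoms only (hydrogens contribute too little density at
the targeted resolutions and are ignored throughout); isotropic B-factors;
one ligand residue per run with connected covalent graph (salts and
multi-component ligands are rejected); the binding-site frame is the
deposited frame (no re-origin).

## Conformer sampling

Embedding is delegated to a pluggable engine; the default wraps RDKit's
ETKDG and then applies MMFF94 minimization (200 iterations). The
minimization step matters: without it, embedded torsions are spread broadly
and the pool rarely contains a conformer close enough to a genuine
alternate minimum for the density fit to reward it.

Strategy constraints are enforced in two ways. Fixed-atom strategies
(branching, long-chain) are honored by passing the fixed coordinates to the
engine, rigidly aligning each output onto the input over the fixed set, and
snapping fixed atoms to their exact input coordinates (the engine preserves
the pinned set's internal geometry to ~0.04 Å, so the snap is a negligible
correction). Distance pins (all terminal-atom pairs, at their input
distances) are written into the distance-bounds matrix and then enforced by
rejection at a 0.1 Å tolerance; the blob sphere (centroid-centered, radius
= the input ligand's maximal centroid–atom distance, +0.1 Å slack) is
enforced purely by rejection. Rejection-filtered strategies oversample 3×
and truncate back to budget. Every emitted conformer is re-checked by an
independent verifier (plain distance arithmetic, a separate code path from
the generator), including a bond-length check at ±15% of the input model's
bond lengths.

Conformers generated without fixed atoms are placed into the site by
least-squares superposition onto the input ligand over all heavy atoms; the
placement rule is a package choice — some placement is required before any
density comparison is meaningful.

Budgets: 5,000 conformers below 25 heavy atoms, 7,000 at or above, counted
as requested from the engine (pruning then reduces the pool); an even split
across applicable strategies with the remainder distributed one conformer
at a time from the first strategy on. Redundancy pruning removes one member
of each pair under 0.2 Å RMSD (no superposition), choosing the victim
uniformly at random under the run seed. After the first occupancy fit, the
strongest survivors (at most 80, matching the observed 1–80 support sizes)
are enriched with rigid perturbations — rotations of ±5/10/15° about each
principal axis through the centroid and single-axis translations of ±0.3 Å
(25 members per parent; axis moves are deliberately not composed, keeping
the pool linear in the parent count) — and re-pruned with a deterministic
keep-the-parent rule so a perturbed copy can never displace an exact fit.
The optional flip search emits the three 180° principal-axis flips plus
±10° refinements in 2° steps about each flip's own axis (33 rigid members);
the refinement-axis convention is a package choice, as is excluding the 0°
member already present.

Parallel generation partitions each strategy's request into fixed chunks
with per-chunk derived seeds, so results are independent of the worker
count.

## Density

Observed maps are read from CCP4/MRC files (canonicalized to a full-cell
[u,v,w] layout) or Fourier-synthesized from user-named MTZ amplitude/phase
columns on a grid sampled at resolution/3 per axis.

Calculated conformer density supports two transcription models. The default
for orthogonal cells is reciprocal-space: per conformer, structure factors
are summed directly from 4-Gaussian element scattering factors with
isotropic B, truncated at the map's resolution limit, and synthesized on
the observed grid. This reproduces the band-limited character of
crystallographic maps (including truncation ripple) and keeps fitted
occupancies on an absolute scale; on the noise-free benchmark it recovers a
0.50/0.50 split exactly, where a real-space Gaussian blur model deflates
total occupancy by ~25% through shape mismatch. The real-space model
(element Gaussians broadened by B plus a resolution blur with FWHM ≈ d) is
retained for non-orthogonal cells and as an always-nonnegative option.

The footprint mask is the union of voxels within 0.5 Å + resolution/3 of
any atom of the conformer ensemble, with periodic wrapping; the same mask
must be reused when comparing models on one map. Event maps are consumed as
ordinary grids at the user-supplied resolution, with output occupancies
scaled by (1 − BDC) when a background correction fraction is given; cryo-EM
maps go through the identical pipeline with cardinality 2.

## Solvers

The QP is solved exactly: the Gram matrix of conformer-density rows is
Cholesky-factorized (ridge ε = 10⁻¹⁰ with a warning if singular) and the
problem reduced to nonnegative least squares — the upper bounds ω ≤ 1 are
implied by ω ≥ 0 and Σω ≤ 1 — with the sum constraint enforced by bisection
on its Lagrange multiplier, along which the constrained sum is monotone.
Active-set NNLS cost tracks the (small) support, so pools of thousands are
cheap. Weights below 10⁻⁶ are treated as zero.

The MIQP is solved by exhaustive support enumeration (the pool entering it
is capped at 200): for each support of size ≤ cardinality, the bounded
least-squares subproblem is solved in closed form by enumerating the faces
of its feasible polytope (each weight free / at t_min / at 1; sum
constraint active or not) with batched KKT solves; the best feasible face
minimizer is exact for a convex objective. t_min applies only at this final
stage, not during the intermediate QPs.

## Validation metrics

RSCC is the Pearson correlation of observed and occupancy-weighted
calculated density over the shared mask. RMSD is coordinate-frame (no
superposition), heavy atoms, identical ordering.

EDIA follows the published formula — capped normalized density z(p) ∈
[0, ζ], ζ = 1.2, with μ the map mean and σ the map root-mean-square —
but the distance weighting w(p,a), ownership o(p,a), and atom radii are
unprinted there and are implemented here in simplified form: w = 1 − t²
inside the atom radius, a shallow negative lobe (−0.2 peak) on t ∈ (1, 1.3]
penalizing unattributed excess density, zero beyond; grid points inside
several atoms' radii are shared equally, points inside none belong to their
nearest atom; the atom radius is derived from the package's own density
model as the radius where the element's calculated density falls to 10% of
its central value at a resolution-typical B-factor. Atom scores are clamped
to [0, ζ]. EDIAm aggregates per-atom scores with a power mean of exponent
−2 (+0.1 shift guarding the pole), so weakly supported atoms dominate.
These simplified forms are a conformance caveat: orderings and qualitative
behavior track the published method, absolute values need not. EDIA refuses
maps worse than 2 Å, where the spherical-atom assumption fails. Torsion
strain is an interface only (conformer → kcal/mol); no implementation is
bundled because strain libraries are external services.

## Synthetic benchmark

Four archetypes emulate the disorder classes the method must detect: a
cyclohexane ring flip (mirror of the ring pucker, relaxed), a rigid 1.0 Å
displacement of a linear ligand, a 120° side-chain torsional shift, and a
90° branch rotation on a 14-membered macrocycle. Ligand identity is not
meant to match any particular compound — only the disorder class matters.
Base geometries are embedded and MMFF-minimized at a fixed internal seed;
alternate conformers are built by the stated transform and then relaxed
into the nearest force-field minimum with the untouched atoms pinned
(emulating the regularization a hand-built conformer receives), falling
back to the opposite rotation sense if the relaxation collapses below
0.2 Å from the base.

Cases live in orthorhombic P1 boxes with ≥6 Å padding. B-factors ramp as
B = 10 + 10·(resolution − 0.8) Å² — the schedule is configuration, chosen
to span typical ligand B values over 0.8–2.5 Å. Maps are simulated by
direct structure-factor summation to the resolution limit and Fourier
synthesis; Gaussian noise with s.d. 0.1·σ_map·(resolution/1 Å) is added
(the proportionality constant is configuration; the form is fixed). A flat
binary-mask bulk-solvent term (k_sol = 0.4, b_sol = 45 Å²) is implemented
but off by default: under the zero-F000 map convention this crude mask
model leaves a ligand-shaped depression that deflates fitted occupancies
by ~0.12 — an artifact of the simplified solvent model, not a property of
the fitting algorithm, so the operational-bounds runs use solvent-free
maps.

What passing the benchmark shows: on band-limited, moderately noisy maps
whose atom shapes follow this package's own scattering model, the pipeline
recovers a planted alternate conformer's geometry and occupancy down to
~0.2 minor occupancy at 1.0 Å, and degrades at 0.1. What it does not show:
performance against real maps with protein context, bulk solvent,
anisotropy, radiation damage, or model-phase bias — none of which the
simulator emulates.

## Problem sizes and determinism

Test and acceptance runs use a scaled sampling budget of 150–400 conformers
on the torsional-shift archetype (the localized-disorder class); the
5,000/7,000 defaults remain the library defaults and are asserted directly.
The pruned pool for an 11-heavy-atom ligand is small regardless of budget
because MMFF minimization funnels embeddings into a modest set of torsional
minima. All randomness flows from a single integer seed (per-strategy and
per-chunk seeds are derived), and two runs with the same configuration and
seed produce byte-identical output models. Map synthesis goes through
single-precision FFTs, so map-level identities hold to ~10⁻⁶ of the map
scale, not machine epsilon.

## Known limitations

- Occupancy scale depends on the observed map being on an absolute-ish
  scale consistent with the scattering model; maps with arbitrary scale
  still yield correct conformer selection and RSCC, but raw ω values then
  absorb the scale.
- Reciprocal-space transcription requires orthogonal cells; non-orthogonal
  cells fall back to the real-space model, whose shape mismatch against
  sharp maps biases occupancies downward.
- The MIQP enumeration cap (200 candidates) is generous for observed
  support sizes but is a hard limit.
- EDIA's weighting/ownership are simplified reconstructions (see above).
- Protein alternate conformations, waters, and joint protein–ligand
  occupancy refinement are out of scope.
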