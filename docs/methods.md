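# Methods

## The problem

Boronic-acid warheads bind serine hydrolases covalently: the boron switches
from trigonal sp² to tetrahedral sp³ as the serine Oγ attacks, producing an
adduct whose boron center and B–O linkage have no parameters in the standard
small-molecule (GAFF) or protein (ff14SB) force fields. Simulating such
adducts classically therefore requires a purpose-built bonded-parameter set.
`boronfit` packages such a set for four representative warhead chemistries —
phenyl-, benzyl-, benzylamino- and methylamino-boronates — together with the
machinery to fit torsion parameters against quantum energies and to validate
a parameter set by conformer-population and torsional-basin analysis.

## Parameter model

Parameters are stored per atom-type key (2 labels for bonds, 3 for angles, 4
for torsions) in kcal/mol, Å and degrees; angle force constants are per
radian², matching the published table headers. Lookup is symmetric under key
reversal for bonds, angles and proper torsions; improper keys are
directional with the central (trigonal) atom third, AMBER-style. Wildcards
(`X`) are supported at the outer positions of four-label keys, and exact
(or reversed) matches always shadow wildcard matches.

Duplicate policy: re-adding an identical entry is a no-op; adding a
*different* entry under an existing proper key appends an additive Fourier
term. This matches the AMBER multi-term torsion convention and preserves the
two distinct published rows that share the key `oh-b-c3-h1`. Whether those
two rows were intended as an additive series or reflect two compounds'
contexts cannot be decided from the published table alone; storing both as
additive terms is the documented default, and the `strict` frcmod dialect
writes them as a standard continuation series.

### Literal periodicities and their seam

Several fitted periodicities are non-integer or negative (−1.001, 0.129,
2.385, −0.101, …). They are stored and evaluated literally in
`(V/divider)(1 + cos(n·φ − γ))`: reinterpreting a negative `n` as the frcmod
continuation flag, or rounding to integers, would change the energy model
the values were fitted for. Two consequences are worth knowing:

* the sign of `n` matters whenever γ ≠ 0 (mod 180°), since
  cos(−nφ − γ) = cos(nφ + γ);
* for non-integer `n` the term is **not single-valued on the circle**: with
  φ reported in (−180°, 180°], the energy jumps at the ±180° seam
  (cos(n·180 − γ) ≠ cos(−n·180 − γ)). This discontinuity is inherent to the
  published functional values, not to the implementation. Geometries whose
  torsions sit exactly on the seam are numerically fragile there; the
  shipped fixtures deliberately avoid placing any non-integer-`n` torsion at
  ±180°.

The frcmod `literal` dialect writes `n` as stored (4 decimals for V and γ, 3
for n) and flags nonstandard rows in a comment; `strict` rounds |n| to the
nearest nonzero integer for stock AMBER tools and warns when the rounding
moves |n| by more than 0.5.

## Energy evaluation

Bonded terms follow the harmonic + Fourier form above, with Δθ converted to
radians at evaluation. Term enumeration takes angles as all length-2 bond
paths and propers as all length-3 paths, once per orientation; impropers are
emitted only where an explicit improper key matches an atom with exactly
three neighbors (no automatic planarity detection), with outer atoms
assigned in lowest-index order. Optional nonbonded terms use gas-phase
Coulomb (332.0522173 kcal·Å·mol⁻¹·e⁻²) and 12-6 Lennard-Jones with
Lorentz–Berthelot combination, 1-2/1-3 exclusion and 1-4 scaling (1/1.2
electrostatic, 1/2.0 LJ), no cutoff — the targets are single covalent-adduct
molecules. The shipped LJ table uses GAFF-like values for the organic types;
boron (R\* = 2.0 Å, ε = 0.05 kcal/mol) is this package's own choice of a
shallow, slightly large well for an anionic tetrahedral boronate and only
affects the optional nonbonded mode. Whether nonbonded terms belong inside
E_MM during fitting is left to the caller: both modes are exposed (`nb=None`
is bonded-only) and recorded in CLI logs, since either convention is
defensible when the reference energies are relative.

## Torsion fitting

The objective is `f = Σᵢ (E_MM,i − E_QM,i + K)²` over the N structures of a
set. For fixed model parameters the optimal offset has the closed form
`K* = mean(E_QM − E_MM)`; K is therefore profiled out of the optimization
entirely. The barrier heights `V_n` enter the model linearly, so they are
profiled as well — at each evaluation the best (V, K) follow from one linear
least-squares solve — leaving only the genuinely nonlinear (γ, n) to a
bounded trust-region optimizer (`scipy.optimize.least_squares`, ftol 1e−10)
with multistart (default 8 starts: the current parameter values plus seeded
uniform draws; γ unconstrained and wrapped to [0, 360) on output, |n| ≤ 6,
|V| ≤ 50 kcal/mol). Without the linear profile, 8 random starts over the
full (V, γ, n) space were observed to miss the global minimum on some seeds;
with it, noiseless recovery is exact for every seed tried. Ties between
numerically equal minima are broken toward the smallest Σ|V_n| (parsimony),
and the diagnostics record the best-so-far objective trace, per-start
objectives and rank checks.

The cosine form has exact symmetries — (V, γ, n) ≡ (V, −γ, −n), and flipping
the sign of V shifts the energy by a constant that K absorbs — so two
equally perfect fits can report different raw parameters and K values.
`canonical_term` maps any term to the representative with V ≥ 0, n ≥ 0,
γ ∈ [0, 360°) for comparisons.

Periodicity floats by default (`fit_n_continuous=True`), reflecting the
non-integer values of the shipped library; disabling it holds every `n` at
its starting value.

## Synthetic data and fixtures

The synthetic-energy oracle emits `E = E_MM(true parameters) + offset +
N(0, σ²)` per structure, seeded. It emulates what a quantum single-point
scan provides — an energy per geometry on an arbitrary absolute scale — and
nothing else: no electronic effects absent from the MM form, no geometry
relaxation, no correlated errors. Passing recovery tests therefore
demonstrates the estimator machinery (identifiability, offset handling,
noise propagation), not that the MM form can represent any particular real
quantum surface.

Structure sets come from rigid torsion scans: the atoms on the far side of
an acyclic bond rotate right-handedly about the j→k axis, so frame m has the
scanned torsion at original + m·step and every other internal coordinate
exactly preserved. The default study conditions for recovery experiments are
36 frames at 10° (full single-torsion coverage); the noise level σ = 0.1
kcal/mol represents a tight quantum-vs-model residual. The coverage check
bins each fitted torsion into twelve 30° bins and warns below 50% coverage.

The four fixtures are reduced ≤25-atom analogs of the warhead chemistries
(not the full published compounds, whose coordinates are not part of the
library): a tetrahedral boron carrying the characteristic oxygen arms — a
serine stub `cx–2c–oh–B` where the chemistry calls for it (the `2c`/`cx`
labels are the ff14SB serine side-chain types) — plus the phenyl, benzyl,
α-aminobenzyl or (methylamino)methyl carbon substituent. Geometries are
grown by natural-extension placement at the equilibrium bond lengths and
angles of the parameter set with staggered torsion choices, so bond strain
is zero by construction and angle strain vanishes wherever the printed
equilibria are mutually consistent. Two documented exceptions: ring ipso
carbons (the 120.97° B-ring angle cannot coexist with a 120° hexagon;
≈0.07 kcal/mol residual) and the benzylic `c2` center of the benzyl fixture,
whose published equilibria (109.5°, 120.97°, 123.3° across four
substituents) admit no strain-free embedding (≈11.5 kcal/mol constant
strain). A library audit reports which fitted torsion keys are realized in
at least one fixture; three keys (`b-o-c3-c3`, `2c-oh-b-o`, `2c-oh-b-c2`)
and the planar-CH₂ improper cannot occur at this fragment size and are
listed rather than silently skipped.

Fixture point charges are nominal per-type values, not derived charges; they
only exercise the optional nonbonded path.

## Analysis

Boltzmann populations use T = 298 K and R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹
exactly, re-referencing energies to their minimum; human-readable output
rounds to one decimal so table-level rounding is reproducible. Recomputing a
published 25-conformer population table from its 2-decimal ΔE inputs
reproduces every cell within ±0.13 percentage points; a handful of cells
differ in the last printed decimal purely from the rounding of the inputs.

Basin extraction segments the circular histogram (default 10° bins) into
maximal runs of contiguous occupied bins, circularly, so a well straddling
±180° is one basin; runs holding under the occupancy threshold (default 10%)
are discarded. Centers are circular means (atan2 of mean sine/cosine), which
maximize mean cosine alignment and agree with the squared-circular-distance
(Fréchet) minimizer in the concentrated limit. If no bin is empty the whole
circle is a single basin — its center is then poorly defined, as for any
near-uniform angular distribution. Segmentation by empty-bin separation
rather than clustering keeps the procedure deterministic with two
parameters.

Correspondence reports match each reference conformer's torsion angles to
the nearest basin center by minimal circular distance, flagging matches at a
configurable threshold (default 30°). A reference angle lying between two
basins simply reports its nearest center and distance; no averaging across
basins is attempted.

## Problem sizes

Tests and the acceptance script run on the toy fixtures (≤25 atoms,
36-frame scans, 50-seed Monte-Carlo for the noise study); these sizes fully
determine the one- and two-term fits exercised and keep the whole suite
under a minute. The Monte-Carlo noise study fits the serine-link torsion,
whose key matches a single quadruple in the fixture: keys matching several
symmetry-offset quadruples make the barrier height nearly degenerate with
(γ, n), which is an identifiability property of such fits generally, not an
implementation artifact.

## Known limitations

* No quantum chemistry, docking, MD, atom-type perception, charge
  derivation, geometry optimization, gradients/forces, or force-matching:
  the toolkit parameterizes and validates, upstream programs produce its
  inputs.
* Binary trajectory formats are out of scope; multi-frame XYZ/PDB (and mol2
  for topologies) only.
* The energy of literal non-integer periodicities is discontinuous at the
  torsion seam (above); strict-dialect exports are lossy by construction for
  such terms.
* Bond/angle parameters are treated as fixed literature data; only torsion
  parameters are fittable.
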