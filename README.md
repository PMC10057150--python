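# boronfit

A toolkit for AMBER-style force-field parameterization of boron-based
covalent ligands — boronic-acid "warheads" that react with the nucleophilic
serine of enzymes such as β-lactamases to form tetrahedral covalent adducts.
Standard parameter-assignment pipelines (GAFF + protein force fields) have no
parameters for the boron center or the ligand–enzyme covalent linkage;
`boronfit` carries a fitted bonded-parameter library for phenyl-, benzyl-,
benzylamino- and methylamino-boronate warheads and re-implements the
workflow used to produce and validate such libraries.

It is a Python library first (with an `examples/` directory of narrative
scripts) plus a thin `boronfit` command-line wrapper for the same steps.

## What it computes

**Energy model.** The additive AMBER functional form over a user-supplied
topology (atoms with force-field type labels and charges, plus a bond list):

```
E_MM = Σ K_r (r − r_eq)²  +  Σ K_θ (θ − θ_eq)²
     + Σ (V_n / divider) (1 + cos(n·φ − γ))     (propers and impropers)
     [ + Coulomb + 12-6 LJ, 1-4 scaled by 1/1.2 and 1/2.0 ]
```

Fitted torsion periodicities `n` may be negative or non-integer and are
evaluated literally (the shipped library contains e.g. `n = −1.001` and
`n = 0.129`); the `frcmod` writer offers a `literal` dialect that round-trips
these values exactly and a `strict` dialect that rounds to stock-AMBER
integer periodicities (with a lossy-export warning).

**Torsion fitting.** Given a structure set spanning a torsion and one quantum
single-point energy per structure, the fitter minimizes

```
f(K) = Σᵢ (E_MM,i − E_QM,i + K)²
```

over the floating Fourier parameters `(V_n, γ, n)`. The molecule-dependent
scale constant `K` has the closed form `K* = mean(E_QM − E_MM)` and is
profiled out analytically, as are the linearly-entering barrier heights; a
bounded multistart trust-region optimizer searches the remaining `(γ, n)`
landscape. The fit reports `K`, the objective `f`, `R²` and per-structure
residuals.

**Validation analytics.** Boltzmann equilibrium populations
`pᵢ = 100·exp(−ΔEᵢ/RT)/Σⱼexp(−ΔEⱼ/RT)` at 298 K
(R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹); circular-statistics segmentation of
torsion trajectories into basins (10° histogram, contiguous occupied bins,
>10% occupancy, circular-mean centers); and matching of reference
(quantum-optimized) torsion angles to the nearest simulated basin.

**Synthetic structure sets.** Rigid torsion scans, a 30°-bin coverage audit,
four deterministic ≤25-atom toy boronate fixtures exercising the library
keys, and a synthetic QM-energy oracle (known MM surface + offset + Gaussian
noise) so the whole pipeline is testable without any quantum chemistry.

## Worked example

Recover a torsion parameter from synthetic quantum energies
(`examples/03_fit_torsion.py`):

```text
structure set: 36 frames, torsion-space coverage 1.00
true   : V_n =   2.2276  gamma =  180.000  n =  2.156
fitted : V_n =   2.2276  gamma =  180.000  n =  2.156
K = 7.3000 kcal/mol (the constant aligning the two energy scales; equals the applied offset)
f = 1.27e-27 kcal^2/mol^2, R^2 = 1.0000000000
```

The 36-frame 10° scan of the O–B–C–N torsion of the methylamino fixture is
fitted starting from deliberately wrong values (V=1.0, γ=90°, n=1.5); the
noiseless fit reproduces the generating parameters to machine precision and
`K` equals the 7.3 kcal/mol offset that was added to the target energies.

Conformer populations (`examples/04_conformer_populations.py`):

```text
conf   dE (kcal/mol)   population (%)
2A           0.00           96.5
2B           2.16            2.5
2C           2.97            0.6
2D           3.54            0.2
2E           4.10            0.1
```

A 2.16 kcal/mol gap to the second conformer leaves ~96% of the
room-temperature population in the global minimum.

The same steps from the shell:

```bash
boronfit params --export boronate.frcmod
boronfit fixture --kind methylamino --out-prefix ma
boronfit scan --top ma.top --coords ma.mol2 --torsion "tau2:2,1,5,18" --out scan.xyz
boronfit fit --top ma.top --coords scan.xyz --qm qm.dat --units kcal/mol \
             --fit oh-b-c3-n3 --out fitted.frcmod
boronfit populations --energies deltaE.tsv --out pops.tsv
boronfit torsions --traj traj.xyz --defs taus.defs --reference minima.tsv --out basins.tsv
```

## Scope

The toolkit consumes quantum energies and optimized geometries; it does not
run quantum chemistry, docking or molecular dynamics, and it does not
perceive atom types from chemical structure. See `docs/methods.md` for the
model details, numerical choices and known limitations.
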