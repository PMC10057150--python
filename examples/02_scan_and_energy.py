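"""Build a toy boronate, scan a torsion rigidly and evaluate MM energies.

The scan isolates one rotatable bond at boron: every other internal
coordinate is untouched, so the energy profile along the scan is the torsion
potential of the bonds sharing that axis (plus any nonbonded change).
"""

import boronfit as bf

top, conformer, taus = bf.toy_boronate_fixture("methylamino")
print(f"methylamino fixture: {top.n_atoms} atoms, {len(top.bonds)} bonds")

pset = bf.fixture_params()  # built-in library + shipped GAFF-like fallback
tau2 = taus[1]              # O1-B-C7-N: serine-O/boron/carbon/amine torsion
frames = bf.scan_torsion(top, conformer, tau2, step=30.0)
print(f"scan of {tau2.label} ({tau2.atom_names}): {len(frames)} frames")

print("  phi (deg)   E_bonded (kcal/mol)")
e0 = bf.bonded_energy(top, pset, frames[0]).total
for frame in frames:
    phi = bf.measure_torsion(frame.coords, *tau2.indices)
    e = bf.bonded_energy(top, pset, frame).total
    print(f"  {phi:8.1f}   {e - e0:12.4f}")
print("energies are relative to the first frame; the profile is periodic in "
      "the scanned torsion because all other internal coordinates are rigid")
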