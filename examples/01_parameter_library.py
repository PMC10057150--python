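"""Inspect the built-in boronate parameter library and export it as frcmod.

The library carries the bonded parameters of tetrahedral boronate warheads
(boron bound to a serine-like oxygen, hydroxyls and a carbon substituent):
fitted torsion Fourier terms plus literature bond/angle constants.
"""

import boronfit as bf

pset = bf.builtin_boronate_params()
n_bonds, n_angles, n_proper, n_improper = pset.n_entries()
print(f"library: {n_bonds} bonds, {n_angles} angles, "
      f"{n_proper} proper torsion terms on {len(pset.propers)} keys, "
      f"{n_improper} improper")

# a one-term torsion and the two-term additive series
for labels in (("oh", "b", "ca", "ca"), ("oh", "b", "c3", "h1")):
    terms = pset.lookup_dihedral(bf.key(*labels))
    print(f"{'-'.join(labels)}:")
    for t in terms:
        print(f"   V_n = {t.v_n:9.4f} kcal/mol   gamma = {t.gamma:8.3f} deg"
              f"   n = {t.n:7.3f}")
# non-integer and negative n are literal fitted values: the energy term is
# (V_n/divider)(1 + cos(n*phi - gamma)) evaluated with n as printed

# lookup is symmetric under key reversal
assert pset.lookup_dihedral(bf.key("ca", "ca", "b", "oh")) == \
    pset.lookup_dihedral(bf.key("oh", "b", "ca", "ca"))

bf.write_frcmod(pset, "boronate.frcmod")
print("wrote boronate.frcmod (literal dialect; use dialect='strict' for "
      "stock AMBER tools, integer-rounded periodicities)")
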