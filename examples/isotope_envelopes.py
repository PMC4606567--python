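"""Isotope envelopes and ion m/z for lipid-sized molecules.

Builds elemental formulas for a few reference lipids, prints their
monoisotopic masses, adduct m/z values and M+0..M+3 isotope envelopes.
The monoisotopic fraction p0 is what the type II de-isotoping correction
divides by; note how it shrinks as the carbon count grows.
"""

from lipidshot import (
    ADDUCTS,
    adduct_mz,
    build_default_registry,
    isotope_distribution,
    monoisotopic_mass,
    parse_formula,
    parse_species_name,
    species_formula,
)

registry = build_default_registry()

for name, adduct in [("PC 34:1", "plus-OAc"), ("Chol", "plus-NH4"),
                     ("TAG 52:2", "plus-NH4"), ("LPC 12:0", "plus-OAc")]:
    f = species_formula(parse_species_name(name), registry)
    env = isotope_distribution(f, 4)
    print(f"{name:10s} {str(f):14s} M = {monoisotopic_mass(f):10.4f} Da  "
          f"m/z({adduct}) = {adduct_mz(f, ADDUCTS[adduct]):10.4f}")
    print(f"{'':10s} envelope M+0..M+3 = "
          + ", ".join(f"{p:.4f}" for p in env))

# The deuterated cholesterol standard: six mass units up, still one envelope
d6 = parse_formula("C27H40D6O")
print(f"\nChol D6    {d6}  M = {monoisotopic_mass(d6):.4f} Da "
      f"(+{monoisotopic_mass(d6) - monoisotopic_mass(parse_formula('C27H46O')):.4f} vs Chol)")
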