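"""Exact [M+H]+ masses and mamu errors for known compound ions.

Parses printed ion compositions, computes their monoisotopic m/z
(electron mass subtracted) and the signed observed-minus-calculated
error in mamu (mDa) — the arithmetic behind every dereplication call.
"""

from halonet import IonSpecies, mass_error_mamu, mz_of_ion, parse_formula

OBSERVED = [
    ("jamaicamide D", "C27H38BrN2O4", 533.1983),
    ("jamaicamide E", "C27H39N2O4", 455.2877),
    ("hectoramide", "C22H36N3O5", 422.2648),
    ("jamaicamide F", "C27H37O4ClIN2", 615.1471),
]

print(f"{'compound':<16}{'ion formula':<18}{'calc m/z':>10}{'obs m/z':>10}{'err mamu':>9}")
for name, formula, obs in OBSERVED:
    calc = mz_of_ion(IonSpecies(parse_formula(formula), 1))
    err = mass_error_mamu(obs, calc)
    print(f"{name:<16}{formula:<18}{calc:>10.4f}{obs:>10.4f}{err:>+9.1f}")

print("\nErrors within ~3 mamu support the proposed elemental composition;")
print("larger errors reject it.")
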