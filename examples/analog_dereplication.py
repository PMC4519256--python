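"""Analog hypothesis generation and exact-mass matching.

Starting from the dichlorinated parent compound, enumerates one- and
two-step transformation products, then matches their predicted masses
against observed cluster ions — reproducing how deacyl-, dechloro- and
methyl-analogs (and a halogen-swapped species) are called from a
network before any isolation work.
"""

from halonet import (
    BUILTIN_TRANSFORMATIONS,
    KnownCompound,
    Node,
    apply_transformation,
    enumerate_hypotheses,
    match_hypotheses,
    parse_formula,
)

hecto = KnownCompound(
    "hectochlorin",
    apply_transformation(parse_formula("C28H37O9Cl2N2S2"), "-CH2"),
    rt=23.8,
)
print(f"parent: {hecto.name}, ion {hecto.ion_formula.format()}, "
      f"m/z {hecto.mz:.4f} (nominal {round(hecto.mz)})")

hypotheses = enumerate_hypotheses(hecto, BUILTIN_TRANSFORMATIONS, max_steps=1)
print(f"\n{len(hypotheses)} one-step hypotheses; the analog family:")
for h in hypotheses:
    if h.chain[0] in ("deacylation", "dechlorination", "methylation"):
        print(f"  {h.chain[0]:<15} -> {h.formula.format():<18} "
              f"m/z {h.mz:.4f} (nominal {round(h.mz)})")

# Observed cluster masses (monoisotopic nodes of the analog ladders).
cluster = [
    Node("node_623", 623.1050, rt=20.3),
    Node("node_631", 631.1545, rt=22.6),
    Node("node_679", 679.1306, rt=25.8),
]
matched = [h for h in match_hypotheses(hypotheses, cluster, tol_mamu=5.0) if h.matched]
print("\nmatched against observed cluster nodes:")
for h in matched:
    print(f"  {'+'.join(h.chain):<15} predicted {h.mz:.4f} ~ {h.node_id} "
          f"({h.node_mz:.4f}), error {h.error_mamu:+.1f} mamu")
print("\nEach surviving hypothesis names a putative analog worth isolating.")
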