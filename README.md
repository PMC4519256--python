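# halonet

MS² molecular networking and halogen-aware analog dereplication for
natural-product extracts.

Crude extracts of secondary-metabolite producers — here modeled on
halogenated lipopeptide producers such as the marine cyanobacterium
*Moorea producens* — contain families of structurally related compounds:
a major metabolite plus minor analogs made by the same biosynthetic
machinery (missing an acyl group, carrying one chlorine fewer, an extra
methyl, or a swapped halogen). `halonet` finds these families from
LC-MS/MS data alone and proposes elemental compositions for the analogs
before any isolation work, for researchers doing mass-spectrometry-based
dereplication of microbial or environmental extracts.

## The method

1. **Spectral vectors.** Each MS² spectrum with ≥ 6 fragment peaks
   becomes a unit vector: intensities are square-root scaled, then
   divided by the Euclidean norm.
2. **Modified cosine.** Two spectra are compared by pairing peaks within
   a fragment tolerance (default 0.3 Da) either directly or offset by
   the precursor mass difference Δ = m_A − m_B, each peak used once, and
   summing the intensity products:
   `cos(A, B) = Σ_matched aᵢ·bⱼ` over unit-norm vectors, so
   `cos ∈ [0, 1]`. The precursor-shifted window is what lets a fragment
   that *retains* the modified or halogenated substructure — and
   therefore moves in lock-step with the parent mass — still count as
   shared.
3. **Network.** Nodes are spectra (labeled by nominal parent mass);
   edges connect pairs with cosine ≥ 0.7 and ≥ 6 matched peaks.
   Connected components are compound-family clusters, exportable as
   TSV/GraphML for Cytoscape.
4. **Isotopologue ladders.** Cl and Br each have two abundant isotopes
   ~2 Da apart (³⁵Cl/³⁷Cl = 75.8/24.2, ⁷⁹Br/⁸¹Br = 50.7/49.3), so a
   halogenated compound appears as a ladder of precursor ions spaced
   1.997 Da. The A/A+2/A+4 intensity triple is fit by cosine against
   per-class templates (Cl₁, Cl₂, Br₁, Br₁Cl₁, halogen-free) to read
   the halogenation state straight off the network.
5. **Analog hypotheses.** From a known compound's [M+H]⁺ composition,
   element-count transformations (deacylation −C₂H₂O, dechlorination
   −Cl+H, methylation +CH₂, Br→I, …) are applied in chains of ≤ 2;
   each predicted exact mass (monoisotopic sum − mₑ for +1 ions) is
   matched against cluster nodes within a tolerance in mamu (mDa,
   default 5). Matches are cross-checked against the node's isotope
   halogen class and retention time (a co-eluting match is flagged as a
   likely in-source fragment).

A seeded simulator (`halonet.simulate`) generates crude-extract-like
MS² datasets with known ground truth — compound families with shared
and shifting fragments, isotopologue sampling, lognormal intensity
noise, spurious peaks, decoys — so the whole pipeline is testable
end to end without instrument data.

## Worked example

```sh
python examples/analog_dereplication.py
```

```
parent: hectochlorin, ion C27H35Cl2N2O9S2, m/z 665.1156 (nominal 665)

6 one-step hypotheses; the analog family:
  deacylation     -> C25H33Cl2N2O8S2    m/z 623.1050 (nominal 623)
  dechlorination  -> C27H36ClN2O9S2     m/z 631.1545 (nominal 631)
  methylation     -> C28H37Cl2N2O9S2    m/z 679.1312 (nominal 679)

matched against observed cluster nodes:
  deacylation     predicted 623.1050 ~ node_623 (623.1050), error +0.0 mamu
  dechlorination  predicted 631.1545 ~ node_631 (631.1545), error -0.0 mamu
  methylation     predicted 679.1312 ~ node_679 (679.1306), error -0.6 mamu
```

Each line proposes an analog of the dichlorinated parent: the predicted
ion composition, its calculated exact m/z, the observed network node it
explains, and the signed mass error in mamu — sub-mamu errors mean the
composition accounts for the observed mass to instrument accuracy.
Other examples: `exact_masses.py` (mass/error arithmetic),
`isotope_envelopes.py` (the 665/667/669 chlorine ladder and its
classification), `network_simulated_extract.py` (full pipeline on a
simulated extract, scored against ground truth).

There is also a CLI with subcommands `mass`, `isotopes`, `network`,
`analogs`, `simulate` and `run` (full pipeline); `halonet run --mgf
extract.mgf --known known.tsv --out-dir out` writes `nodes.tsv`,
`edges.tsv` and `analog_report.tsv` plus a JSON run log.

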