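# Methods

## Mass arithmetic

All compositions are *ion* compositions: for protonated species the
extra proton is already in the element counts, following the
"calculated for \<formula\>" convention of compound characterization
data. The m/z of an ion is

    (Σ count_e · monoisotopic_mass_e − z · m_e) / |z|

with the IUPAC monoisotopic masses embedded as constants (C 12 exact,
H 1.00782503, N 14.00307400, O 15.99491462, S 31.97207117,
Cl 34.96885268, Br 78.91833760, I 126.90447190, plus P and F) and the
electron mass m_e = 0.000548579909 Da subtracted per positive charge.
The electron correction matters: omitting it shifts +1 ions by
+0.55 mamu, which is visible at the 0.1-mamu reporting precision used
for dereplication. Mass errors are reported as
(observed − calculated) × 1000 in mamu (mDa), rounded to 0.1.

Formula strings are parsed with the grammar `(Element Count?)+`,
arbitrary element order, implicit count 1, and tolerance for whitespace
and underscore markup. Unknown element symbols are rejected rather than
silently dropped. Transformations are signed element-count deltas
(e.g. dechlorination = −Cl+H); applying one is element-wise addition,
so predicted masses are exactly additive, and any delta that would
drive a count negative raises an infeasibility error.

## Isotope envelopes

Envelopes are computed by exact multinomial convolution over *all*
elements' isotopes, not just the halogens: two sulfur atoms contribute
~9% at A+2 and 27 carbons ~4% (¹³C₂), which is material both for
classification and for deciding which isotopologues an instrument
would sample. Per element, isotope occupancies are enumerated with
their multinomial weights (branches below 1e-15 pruned); element
distributions are convolved pairwise and peaks within 0.0005 Da
aggregated (fine structure below 0.01 Da is out of scope). The
un-pruned envelope sums to 1 within 1e-9; the default `prune_below` of
1e-4 only removes entries, never renormalizes.

`IsotopePattern.halogen_ladder()` aggregates the envelope into bins at
even nominal offsets (A, A+2, A+4, …) spaced by the ³⁷Cl−³⁵Cl mass
difference 1.99705 Da. The odd-offset ¹³C satellites (A+1, A+3) are
excluded: they are real ions, but they are not part of the ~2 Da
halogen ladder a network displays, and by raw abundance the A+1 peak of
a 27-carbon compound (0.29 relative) would otherwise outrank the ³⁷Cl₂
A+4 peak (0.17).

### Halogen classification

An observed A/A+2/A+4 triple is compared by cosine similarity against
one template per class (halogen-free, Cl₁, Cl₂, Br₁, Br₁Cl₁). Each
template is the binomial halogen ratio *plus a generic organic-skeleton
background* of 0.08 at A+2 (propagated to A+4): with halogen-only
templates, a halogen-free two-sulfur compound (A+2 ≈ 0.16) scores
marginally better on the Cl₁ template than on the halogen-free one.
With the background term, a grid of 162 compositions (C 10–35, O 0–10,
S 0–2, all six classes) classifies without error at a worst-case margin
of 0.006. Ties break toward fewer halogen atoms (parsimony). Iodine is
monoisotopic and therefore invisible to the envelope: an iodinated
species classifies as halogen-free, and the consistency check treats
those two classes as equivalent. The fit score is surfaced; no hard
score threshold is imposed, since the acceptable threshold depends on
MS¹ intensity quality and is left to the caller (`HalogenCall.score`).

Isotopologue ladders among observed precursors are chained greedily in
ascending m/z at spacing 1.99705 Da (tolerance 0.02 Da for
high-resolution precursors; one missing rung — an unsampled A+2 — can
be bridged at twice the spacing). Each precursor joins at most one
ladder.

## Spectral similarity and networking

Fragment vectors use square-root intensity scaling followed by unit
L2 normalization. Square-root scaling is the convention of the
spectral-networking lineage (it damps base-peak dominance); raw scaling
is available as a mode (`scaling="raw"`), and the raw mode is what an
external modified-cosine implementation (matchms) reproduces exactly in
the cross-check test.

The modified cosine pairs peaks within `frag_tol` either directly or
offset by the precursor mass difference, each peak used at most once
across both windows combined. Matching is greedy over candidate pairs
sorted by descending intensity product, ties broken by smaller |Δm/z|
then lower m/z (the m/z tie key is symmetric in the two spectra, so the
score is exactly symmetric under argument swap). On centroided spectra,
whose peaks are farther apart than the tolerance window, the greedy
matcher provably equals the exhaustive optimum; the test suite verifies
equality against an independent maximum-weight-assignment oracle on
1000 random pairs and never-exceeding it on adversarial ones.
`frag_tol` defaults to 0.3 Da, sized for low-resolution ion-trap MS²
scans; tighten it for high-resolution fragment data. `allow_shift`
defaults to true because isotopologue and analog spectra share
*shifted* fragments — plain cosine systematically under-scores exactly
the pairs this workflow exists to find — and plain cosine remains a
mode.

Network edges require cosine ≥ `cos_min` (default 0.7) and
≥ `min_matched` matched peaks (default 6, mirroring the six-peak vector
minimum; no per-edge floor is published, so it is a config knob). No
top-K neighbor pruning is applied by default. Consensus-merging of
near-duplicate spectra is deliberately absent: one compound yielding
multiple nodes (isotopologues, adducts, source fragments) is a feature
of these networks that the downstream ladder logic consumes. Cluster
lookup by seed mass takes the connected component of the node nearest
the seed (ties: smaller m/z).

## Analog dereplication

Hypotheses are chains of ≤ 2 built-in transformations (deacylation
−C₂H₂O, de/chlorination ∓Cl±H, de/bromination, de/methylation ∓CH₂,
Br→I) applied to a known [M+H]⁺ composition. Deacylation is modeled as
loss of C₂H₂O (acetyl leaving as ketene), which is what the
deacyl-analog's composition implies. Chains with net-zero element delta
predict the parent itself and are dropped; duplicate predicted formulas
collapse to the shortest chain. Depth 2 is the default because known
two-step analogs (dechlorination + debromination) require it, while
deeper chains explode combinatorially and add little at 5-mamu
matching; deeper search is opt-in.

Matching keeps a hypothesis when some cluster node lies within
`tol_mamu` (default 5.0 — the largest credible composition error at
m/z ~600, comfortably above the ≤ 3-mamu errors of well-calibrated
FT instruments). Several hypotheses may claim one node; the ambiguity
is flagged, never resolved, because resolving it requires orthogonal
data (NMR, MS³). Two recorded-but-non-fatal checks: the predicted
composition's halogen class must equal the node's envelope class, and
the node's retention time should differ from the parent's by more than
`rt_tol` (default 0.5 min) — a co-eluting match is likely an in-source
fragment of the parent, not a separate compound.

## The simulator

`simulate_dataset` emulates the data structure the analysis assumes,
not an instrument. Each family is a scaffold (lipopeptide-sized
C₂₂–₃₂ core, 8–12 fragment peaks, halogen sites per class) plus
analogs generated by feasible transformation chains. Fragments carry a
`shifts` flag: flagged fragments (≥ 2 when halogenated, ~40% of the
ladder) move with every precursor mass delta — isotopologue or
transformation — while the rest are shared unchanged, reproducing the
shared/shifted fragment split that makes the modified cosine work.
When isotopologue sampling is on, each ~2 Da ladder member above 5%
relative envelope abundance yields its own spectrum (three for Cl₂,
two for Br₁), mirroring which ladder members appear as network nodes.

Noise defaults are the validated study conditions: lognormal
multiplicative intensity noise σ = 0.3, Gaussian fragment m/z jitter
0.05 Da (low-resolution ion trap), Gaussian *precursor* jitter 0.001 Da
(precursor masses come from a high-resolution survey scan; a 0.05-Da
precursor error would make milli-Da analog matching meaningless, which
is not how these experiments are run), 2 spurious peaks per spectrum on
average, 5 singleton decoy compounds. Retention times of analogs are
displaced ≥ 1 min from the parent (they are genuinely different
compounds). Everything derives from one integer seed and the output is
byte-deterministic.

What the simulator does **not** model: chromatographic peak shapes,
MS¹ centroiding, adduct series, in-source fragmentation, dynamic-range
compression, co-isolation chimeras, or real ion-trap noise statistics.
Passing recovery tests therefore show the *pipeline logic* is sound
under the stated statistical structure — fragment sharing, isotope
envelopes, mass additivity, calibrated noise — not that any particular
instrument's raw data will behave as cleanly.

Recovery scoring: purity is the majority-family fraction per
truth-containing component (averaged over components); completeness the
largest single-component fraction per family; transformation
recall/precision compare matched hypotheses (parent + chain multiset)
against planted analogs. At the default conditions over seeds 1–10 the
pipeline attains purity and recall 1.0; the test suite asserts the
0.9 floors.

## Problem sizes and numerical choices

Test and validation runs use 5 families × (1 + 3 compounds) ×
2–3 isotopologues plus 5 decoys (≈ 55–60 spectra, ~1600 spectrum
pairs), 10 seeds for the recovery benchmark, and 1000 random pairs for
the matcher-oracle equivalence — sizes at which every result above is
exact or tightly converged. Envelope convolution prunes below 1e-15
per branch and merges within 0.0005 Da; peak lists merge within
0.01 Da on load; all tolerances are surfaced as parameters. Degenerate
inputs (empty formula, zero charge, all-zero intensities, < 6 peaks,
empty dataset, seed mass far from all nodes) raise typed errors or
return empty results as documented rather than guessing.

## Known limitations

- Only +1 ions are treated throughout; multiply-charged species and
  non-protonated adducts are out of scope.
- Halogen classification reads the A/A+2/A+4 triple only; it cannot
  distinguish iodinated from halogen-free species, nor resolve classes
  beyond the five templates (e.g. Cl₃).
- Formula *generation* from mass alone is out of scope; only
  verification against candidate compositions is provided.
- The greedy matcher can in principle differ from the exhaustive
  optimum on spectra with many peaks inside one tolerance window
  (merged on load in practice); it never overscores.
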