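"""Seeded simulator of crude-extract-like MS2 datasets with ground truth.

The generator emulates the statistical structure molecular networking
relies on: a handful of compound *families*, each a scaffold plus a few
transformed analogs that share the scaffold's fragment ladder —
fragments retaining the modified/halogenated part of the molecule shift
in lock-step with the precursor mass, the rest are shared unchanged.
When isotopologue sampling is on, every isotopologue above 5% relative
envelope abundance yields its own spectrum (the instrument picks the
most intense MS1 ions), so dichlorinated compounds appear as ~2 Da
precursor triples and brominated ones as doublets.

Noise model: lognormal multiplicative intensity noise, Gaussian m/z
jitter (wide on fragments, emulating a low-resolution ion trap; narrow
on precursors, emulating a high-resolution MS1 survey scan), Poisson
spurious peaks, and unrelated singleton decoy compounds.  Everything is
driven by one integer seed and is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analogs import BUILTIN_TRANSFORMATIONS, AnalogHypothesis, Transformation
from .formula import (
    FormulaError,
    IonSpecies,
    MolecularFormula,
    apply_transformation,
    mz_of_ion,
)
from .isotopes import HalogenClass, simulate_envelope
from .network import SpectralNetwork
from .spectra import Dataset, Peak, Spectrum

__all__ = [
    "FragmentSpec",
    "ScaffoldSpec",
    "SimulationConfig",
    "make_scaffold",
    "simulate_dataset",
    "score_recovery",
    "RecoveryMetrics",
]

#: Isotopologues below this abundance relative to the envelope base
#: peak are not sampled (the instrument never selects them).
ISO_SAMPLING_CUT: float = 0.05

_HALOGEN_SITES = {
    HalogenClass.NONE: {},
    HalogenClass.CL1: {"Cl": 1},
    HalogenClass.CL2: {"Cl": 2},
    HalogenClass.BR1: {"Br": 1},
    HalogenClass.BR1CL1: {"Cl": 1, "Br": 1},
    HalogenClass.I1: {"I": 1},
}


@dataclass(frozen=True)
class FragmentSpec:
    """One scaffold fragment: m/z, base intensity, and whether it moves
    with precursor mass deltas (i.e. retains the halogen/modified part)."""

    mz: float
    intensity: float
    shifts: bool


@dataclass(frozen=True)
class ScaffoldSpec:
    """A simulated compound scaffold with a fixed fragment ladder."""

    name: str
    ion_formula: MolecularFormula
    fragments: tuple[FragmentSpec, ...]
    rt: float
    halogen_class: HalogenClass

    @property
    def mz(self) -> float:
        return mz_of_ion(IonSpecies(self.ion_formula, 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated extract.

    Defaults are the conditions the pipeline is validated under:
    5 families of a scaffold plus 3 analogs each, isotopologue sampling
    on, lognormal intensity sigma 0.3, fragment m/z jitter 0.05 Da
    (precursors 0.001 Da — survey scans are high-resolution), 2 spurious
    peaks per spectrum on average, 5 singleton decoys.
    """

    n_families: int = 5
    analogs_per_family: int = 3
    isotopologues: bool = True
    intensity_sigma: float = 0.3
    mz_jitter_sd: float = 0.05
    precursor_jitter_sd: float = 0.001
    spurious_rate: float = 2.0
    n_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "intensity_sigma", "mz_jitter_sd", "precursor_jitter_sd",
            "spurious_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_families < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")

    def noise_free(self) -> "SimulationConfig":
        from dataclasses import replace

        return replace(
            self,
            intensity_sigma=0.0,
            mz_jitter_sd=0.0,
            precursor_jitter_sd=0.0,
            spurious_rate=0.0,
        )


def make_scaffold(
    seed: int,
    halogen_class: HalogenClass = HalogenClass.CL2,
    name: str | None = None,
) -> ScaffoldSpec:
    """A seed-deterministic plausible scaffold.

    The composition is a lipopeptide-sized CxHyNnOoSs core plus the
    requested halogen sites; the fragment ladder has 8–12 peaks spread
    over the precursor mass, at least two of which retain the halogens
    (and therefore shift with isotopologue/transformation deltas) when
    the scaffold is halogenated.
    """
    rng = np.random.default_rng(seed)
    n_c = int(rng.integers(22, 33))
    counts = {
        "C": n_c,
        "H": int(round(n_c * 1.35)) + int(rng.integers(0, 6)),
        "N": int(rng.integers(2, 4)),
        "O": int(rng.integers(4, 10)),
        "S": int(rng.integers(0, 3)),
    }
    for el, n in _HALOGEN_SITES[halogen_class].items():
        counts[el] = n
    formula = MolecularFormula(counts)
    prec = mz_of_ion(IonSpecies(formula, 1))

    n_frag = int(rng.integers(8, 13))
    mzs: list[float] = []
    while len(mzs) < n_frag:
        cand = float(rng.uniform(0.15, 0.92)) * prec
        if all(abs(cand - m) > 2.0 for m in mzs):
            mzs.append(cand)
    mzs.sort()
    intensities = rng.uniform(20.0, 100.0, size=n_frag)

    halogenated = halogen_class is not HalogenClass.NONE
    if halogenated:
        n_shift = max(2, int(round(0.4 * n_frag)))
        shift_idx = set(rng.choice(n_frag, size=n_shift, replace=False).tolist())
    else:
        shift_idx = set()
    fragments = tuple(
        FragmentSpec(mz=m, intensity=float(i), shifts=(k in shift_idx))
        for k, (m, i) in enumerate(zip(mzs, intensities))
    )
    rt = float(rng.uniform(15.0, 35.0))
    return ScaffoldSpec(
        name=name or f"scaffold{seed}",
        ion_formula=formula,
        fragments=fragments,
        rt=rt,
        halogen_class=halogen_class,
    )


def _pick_chains(
    scaffold: ScaffoldSpec,
    n: int,
    rng: np.random.Generator,
    transformations: Sequence[Transformation] = BUILTIN_TRANSFORMATIONS,
) -> list[tuple[tuple[str, ...], MolecularFormula]]:
    """Feasible, mass-distinct transformation chains for a scaffold."""
    if n <= 0:
        return []
    candidates: list[tuple[tuple[str, ...], MolecularFormula]] = []
    pool = list(transformations)
    singles = [(t,) for t in pool]
    pairs = [
        (a, b) for i, a in enumerate(pool) for b in pool[i:]
    ]
    for combo in singles + pairs:
        f = scaffold.ion_formula
        try:
            for t in combo:
                f = apply_transformation(f, t.delta)
        except FormulaError:
            continue
        if f == scaffold.ion_formula:
            continue
        candidates.append((tuple(t.name for t in combo), f))
    # unique formulas, prefer short chains, deterministic order
    chosen: list[tuple[tuple[str, ...], MolecularFormula]] = []
    seen_masses: list[float] = [scaffold.mz]
    order = rng.permutation(len(candidates))
    for idx in sorted(order, key=lambda i: (len(candidates[i][0]), order.tolist().index(i))):
        chain, f = candidates[idx]
        m = mz_of_ion(IonSpecies(f, 1))
        if any(abs(m - s) < 0.05 for s in seen_masses):
            continue
        if any(f == g for _, g in chosen):
            continue
        chosen.append((chain, f))
        seen_masses.append(m)
        if len(chosen) == n:
            break
    return chosen


def _compound_spectra(
    comp_name: str,
    family: str,
    chain: tuple[str, ...],
    formula: MolecularFormula,
    scaffold: ScaffoldSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    truth_rows: list[dict],
) -> list[Spectrum]:
    """Spectra of one compound: one per sampled isotopologue."""
    mono_mz = mz_of_ion(IonSpecies(formula, 1))
    analog_delta = mono_mz - scaffold.mz
    if cfg.isotopologues:
        env = simulate_envelope(IonSpecies(formula, 1), prune_below=1e-4).normalized()
        isotopologues = [
            (mz, ab) for mz, ab in env.entries
            if ab >= ISO_SAMPLING_CUT
            # only whole ~2 Da ladder members, not A+1 fine structure
            and abs((mz - env.entries[0][0]) / 1.99705
                    - round((mz - env.entries[0][0]) / 1.99705)) < 0.1
        ]
    else:
        isotopologues = [(mono_mz, 1.0)]
    base_level = float(rng.uniform(5e4, 5e5))
    spectra: list[Spectrum] = []
    for k, (iso_mz, iso_ab) in enumerate(isotopologues):
        iso_delta = iso_mz - isotopologues[0][0]
        total_delta = analog_delta + iso_delta
        peaks: list[Peak] = []
        for frag in scaffold.fragments:
            mz = frag.mz + (total_delta if frag.shifts else 0.0)
            mz += float(rng.normal(0.0, cfg.mz_jitter_sd)) if cfg.mz_jitter_sd else 0.0
            inten = frag.intensity * (
                float(np.exp(rng.normal(0.0, cfg.intensity_sigma)))
                if cfg.intensity_sigma
                else 1.0
            )
            if mz > 0:
                peaks.append(Peak(mz, inten))
        n_spur = int(rng.poisson(cfg.spurious_rate)) if cfg.spurious_rate else 0
        for _ in range(n_spur):
            peaks.append(
                Peak(float(rng.uniform(50.0, mono_mz)), float(rng.uniform(1.0, 20.0)))
            )
        prec_mz = iso_mz + (
            float(rng.normal(0.0, cfg.precursor_jitter_sd))
            if cfg.precursor_jitter_sd
            else 0.0
        )
        prec_int = base_level * iso_ab * (
            float(np.exp(rng.normal(0.0, cfg.intensity_sigma)))
            if cfg.intensity_sigma
            else 1.0
        )
        sid = f"{comp_name}_iso{k}"
        spectra.append(
            Spectrum(
                id=sid,
                precursor_mz=prec_mz,
                charge=1,
                rt=scaffold.rt if not chain else None,  # set by caller
                peaks=tuple(peaks),
                precursor_intensity=prec_int,
            )
        )
        truth_rows.append(
            {
                "spectrum_id": sid,
                "family": family,
                "compound": comp_name,
                "chain": "+".join(chain),
                "isotopologue": f"A+{round(iso_delta / 1.99705) * 2}" if k else "A",
                "true_precursor_mz": iso_mz,
                "ion_formula": formula.format(),
            }
        )
    return spectra


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a crude-extract-like MS2 dataset plus its ground truth.

    Returns the dataset and a truth table with one row per non-decoy
    spectrum (family, compound, transformation chain, isotopologue,
    true precursor m/z).  Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    class_cycle = [
        HalogenClass.CL2,
        HalogenClass.BR1,
        HalogenClass.CL1,
        HalogenClass.BR1CL1,
        HalogenClass.NONE,
    ]
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    for fi in range(cfg.n_families):
        fam = f"F{fi + 1}"
        cls = class_cycle[fi % len(class_cycle)]
        scaffold = make_scaffold(
            seed=int(rng.integers(0, 2**31 - 1)), halogen_class=cls, name=fam
        )
        chains = _pick_chains(scaffold, cfg.analogs_per_family, rng)
        compounds: list[tuple[str, tuple[str, ...], MolecularFormula, float]] = [
            (f"{fam}_parent", (), scaffold.ion_formula, scaffold.rt)
        ]
        for ci, (chain, f) in enumerate(chains):
            # distinct retention times: analogs are not source fragments
            rt = scaffold.rt + float(rng.uniform(1.0, 4.0)) * (
                1 if rng.random() < 0.5 else -1
            )
            compounds.append((f"{fam}_analog{ci + 1}", chain, f, rt))
        for comp_name, chain, f, rt in compounds:
            comp_spectra = _compound_spectra(
                comp_name, fam, chain, f, scaffold, cfg, rng, truth_rows
            )
            for s in comp_spectra:
                spectra.append(
                    Spectrum(
                        id=s.id,
                        precursor_mz=s.precursor_mz,
                        charge=s.charge,
                        rt=rt,
                        peaks=s.peaks,
                        precursor_intensity=s.precursor_intensity,
                    )
                )
    for di in range(cfg.n_decoys):
        decoy = make_scaffold(
            seed=int(rng.integers(0, 2**31 - 1)),
            halogen_class=HalogenClass.NONE,
            name=f"D{di + 1}",
        )
        peaks = [
            Peak(
                fr.mz + (float(rng.normal(0.0, cfg.mz_jitter_sd)) if cfg.mz_jitter_sd else 0.0),
                fr.intensity,
            )
            for fr in decoy.fragments
        ]
        spectra.append(
            Spectrum(
                id=f"D{di + 1}",
                precursor_mz=decoy.mz,
                charge=1,
                rt=decoy.rt,
                peaks=tuple(peaks),
                precursor_intensity=float(rng.uniform(1e4, 1e5)),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "spectrum_id", "family", "compound", "chain",
            "isotopologue", "true_precursor_mz", "ion_formula",
        ],
    )
    return Dataset(spectra, source=f"simulated(seed={cfg.seed})"), truth


def known_compounds_from_truth(truth: pd.DataFrame, dataset: Dataset):
    """Family parent compounds as dereplication seeds.

    One :class:`~halonet.analogs.KnownCompound` per family, named after
    the family, from the parent rows of the ground-truth table.
    """
    from .analogs import KnownCompound
    from .formula import parse_formula

    rt_by_id = {s.id: s.rt for s in dataset}
    knowns = []
    parents = truth[truth["chain"] == ""].drop_duplicates("family")
    for _, row in parents.iterrows():
        knowns.append(
            KnownCompound(
                name=row["family"],
                ion_formula=parse_formula(row["ion_formula"]),
                rt=rt_by_id.get(row["spectrum_id"]),
            )
        )
    return knowns


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the pipeline recovered the planted structure."""

    family_purity: float
    family_completeness: float
    transformation_precision: float
    transformation_recall: float
    n_components: int


def score_recovery(
    net: SpectralNetwork,
    report: Sequence[AnalogHypothesis],
    truth: pd.DataFrame,
) -> RecoveryMetrics:
    """Clustering purity/completeness and planted-chain precision/recall.

    Purity: per component containing truth spectra, the fraction
    belonging to its majority family, averaged over those components.
    Completeness: per family, the largest fraction of its spectra found
    in a single component, averaged over families.  Transformation
    recall: fraction of planted (family, chain) analogs for which a
    matched hypothesis with the same parent and chain multiset hit a
    spectrum of that compound; precision: fraction of matched
    hypotheses that are such true recoveries.
    """
    truth_by_id = truth.set_index("spectrum_id")
    known_ids = set(truth_by_id.index)
    net_ids = {n.id for n in net.nodes}
    missing = known_ids - net_ids
    if truth.shape[0] and not net_ids & known_ids and net.nodes:
        raise ValueError(f"truth/net spectrum ids do not overlap: {sorted(missing)[:3]}...")

    purities: list[float] = []
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(net.components):
        fams = [
            truth_by_id.loc[n.id, "family"] for n in comp if n.id in known_ids
        ]
        for n in comp:
            comp_of[n.id] = ci
        if fams:
            counts = pd.Series(fams).value_counts()
            purities.append(counts.iloc[0] / len(fams))
    purity = float(np.mean(purities)) if purities else 1.0

    completenesses: list[float] = []
    for fam, group in truth.groupby("family"):
        comps = [comp_of[sid] for sid in group["spectrum_id"] if sid in comp_of]
        if not comps:
            completenesses.append(0.0)
            continue
        counts = pd.Series(comps).value_counts()
        completenesses.append(counts.iloc[0] / len(group))
    completeness = float(np.mean(completenesses)) if completenesses else 1.0

    planted = {
        (row["family"], frozenset_multiset(row["chain"]))
        for _, row in truth.iterrows()
        if row["chain"]
    }
    recovered: set[tuple[str, tuple]] = set()
    n_matched = 0
    n_correct = 0
    for h in report:
        if not h.matched:
            continue
        n_matched += 1
        if h.node_id in known_ids:
            row = truth_by_id.loc[h.node_id]
            if (
                row["family"] == h.parent
                and row["chain"]
                and frozenset_multiset(row["chain"]) == frozenset_multiset("+".join(h.chain))
            ):
                n_correct += 1
                recovered.add((row["family"], frozenset_multiset(row["chain"])))
    recall = len(recovered) / len(planted) if planted else 1.0
    precision = n_correct / n_matched if n_matched else 1.0
    return RecoveryMetrics(
        family_purity=purity,
        family_completeness=completeness,
        transformation_precision=precision,
        transformation_recall=recall,
        n_components=len(net.components),
    )


def frozenset_multiset(chain_str: str) -> tuple:
    """Canonical (sorted) form of a '+'-joined transformation chain."""
    parts = [p for p in chain_str.split("+") if p]
    return tuple(sorted(parts))
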