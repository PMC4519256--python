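"""End-to-end orchestration: read → filter → network → annotate → report.

One :class:`PipelineConfig` carries every stage parameter (defaults are
the workflow's published settings where stated: cosine floor 0.7,
six-peak vector minimum).  :func:`run_pipeline` executes the stages in
order, writes Cytoscape-importable node/edge tables plus the analog
report, and returns a run log with the counts at each stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .analogs import (
    BUILTIN_TRANSFORMATIONS,
    TOL_MAMU,
    RT_TOL_MIN,
    AnalogHypothesis,
    KnownCompound,
    Transformation,
    consistency_check,
    enumerate_hypotheses,
    hypotheses_table_rows,
    match_hypotheses,
)
from .formula import parse_delta, parse_formula
from .isotopes import (
    HalogenClass,
    classify_halogenation,
    find_isotopologue_ladders,
    ladder_pattern,
)
from .network import COS_MIN, SpectralNetwork, build_network, export_network, find_cluster
from .similarity import FRAG_TOL
from .spectra import MIN_PEAKS, Dataset, read_mgf

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "annotate_halogen_classes",
           "read_known_compounds", "read_transformations", "analog_report"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    mgf: str | Path = ""
    known: str | Path | None = None
    transforms: str | Path | None = None
    out_dir: str | Path = "."
    cos_min: float = COS_MIN
    min_peaks: int = MIN_PEAKS
    min_matched: int = MIN_PEAKS
    frag_tol: float = FRAG_TOL
    allow_shift: bool = True
    scaling: Literal["sqrt", "raw"] = "sqrt"
    tol_mamu: float = TOL_MAMU
    rt_tol: float = RT_TOL_MIN
    max_steps: int = 2
    cluster_seed_tol: float = 0.5
    ladder_tol: float = 0.02
    seed: int = 0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mgf"] = str(d["mgf"])
        d["out_dir"] = str(d["out_dir"])
        for key in ("known", "transforms"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def read_known_compounds(path: str | Path) -> list[KnownCompound]:
    """Load a known-compound TSV: columns name, ion_formula, rt_min."""
    df = pd.read_csv(path, sep="\t")
    knowns = []
    for _, row in df.iterrows():
        rt = row.get("rt_min")
        knowns.append(
            KnownCompound(
                name=str(row["name"]),
                ion_formula=parse_formula(str(row["ion_formula"])),
                rt=None if pd.isna(rt) else float(rt),
            )
        )
    return knowns


def read_transformations(path: str | Path) -> list[Transformation]:
    """Load a transformation TSV: columns name, delta (e.g. "-Cl+H")."""
    df = pd.read_csv(path, sep="\t")
    return [
        Transformation(str(row["name"]), parse_delta(str(row["delta"])))
        for _, row in df.iterrows()
    ]


def annotate_halogen_classes(
    net: SpectralNetwork,
    dataset: Dataset,
    ladder_tol: float = 0.02,
) -> dict[str, HalogenClass]:
    """Per-node halogen class from isotopologue ladders.

    Within each connected component, precursor ions are grouped into
    ~2 Da ladders using their MS1 intensities; each ladder's A/A+2/A+4
    triple is classified, and every member node inherits the call.
    """
    inten = {
        s.id: (s.precursor_intensity if s.precursor_intensity is not None else 1.0)
        for s in dataset
    }
    classes: dict[str, HalogenClass] = {}
    for comp in net.components:
        precursors = [(n.precursor_mz, inten.get(n.id, 1.0)) for n in comp]
        ladders = find_isotopologue_ladders(precursors, spacing_tol=ladder_tol)
        for ladder in ladders:
            call = classify_halogenation(ladder_pattern(precursors, ladder))
            for i in ladder:
                classes[comp[i].id] = call.cls
    return classes


def analog_report(
    net: SpectralNetwork,
    dataset: Dataset,
    knowns: Sequence[KnownCompound],
    transformations: Sequence[Transformation] = BUILTIN_TRANSFORMATIONS,
    tol_mamu: float = TOL_MAMU,
    rt_tol: float = RT_TOL_MIN,
    max_steps: int = 2,
    cluster_seed_tol: float = 0.5,
    ladder_tol: float = 0.02,
) -> list[AnalogHypothesis]:
    """Analog hypotheses for each known compound against its cluster."""
    classes = annotate_halogen_classes(net, dataset, ladder_tol)
    rt_by_id = {s.id: s.rt for s in dataset}
    out: list[AnalogHypothesis] = []
    for k in knowns:
        cluster = find_cluster(net, k.mz, tol=cluster_seed_tol)
        if not cluster:
            continue
        hyps = enumerate_hypotheses(k, transformations, max_steps=max_steps)
        matched = match_hypotheses(hyps, cluster, tol_mamu=tol_mamu)
        for h in matched:
            if h.matched:
                h = consistency_check(
                    h,
                    classes.get(h.node_id),
                    rt_by_id.get(h.node_id),
                    k.rt,
                    rt_tol=rt_tol,
                )
            out.append(h)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow and write nodes/edges/analog-report TSVs.

    Returns the run log: the resolved configuration plus spectrum,
    edge, cluster, hypothesis and match counts per stage.  Outputs are
    deterministic for a fixed configuration; on a stage failure a
    :class:`PipelineError` naming the stage is raised and partial
    outputs are removed.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "nodes": out_dir / "nodes.tsv",
        "edges": out_dir / "edges.tsv",
        "report": out_dir / "analog_report.tsv",
    }
    log: dict = {"config": cfg.as_dict()}
    try:
        try:
            dataset = read_mgf(cfg.mgf)
        except Exception as exc:
            raise PipelineError(f"read stage failed: {exc}") from exc
        log["spectra_read"] = len(dataset)

        retained = dataset.filtered(cfg.min_peaks)
        log["spectra_retained"] = len(retained)
        log["spectra_rejected_min_peaks"] = len(dataset) - len(retained)

        try:
            net = build_network(
                retained,
                cos_min=cfg.cos_min,
                min_matched=cfg.min_matched,
                frag_tol=cfg.frag_tol,
                allow_shift=cfg.allow_shift,
                scaling=cfg.scaling,
                min_peaks=cfg.min_peaks,
            )
        except Exception as exc:
            raise PipelineError(f"network stage failed: {exc}") from exc
        log["edges"] = len(net.edges)
        log["clusters"] = len(net.components)

        knowns = read_known_compounds(cfg.known) if cfg.known else []
        transformations = (
            read_transformations(cfg.transforms)
            if cfg.transforms
            else list(BUILTIN_TRANSFORMATIONS)
        )
        try:
            report = analog_report(
                net,
                dataset,
                knowns,
                transformations,
                tol_mamu=cfg.tol_mamu,
                rt_tol=cfg.rt_tol,
                max_steps=cfg.max_steps,
                cluster_seed_tol=cfg.cluster_seed_tol,
                ladder_tol=cfg.ladder_tol,
            )
        except Exception as exc:
            raise PipelineError(f"analog stage failed: {exc}") from exc
        log["hypotheses"] = len(report)
        log["hypothesis_matches"] = sum(1 for h in report if h.matched)

        export_network(net, outputs["nodes"], "nodes-tsv")
        export_network(net, outputs["edges"], "edges-tsv")
        pd.DataFrame(hypotheses_table_rows(report)).to_csv(
            outputs["report"], sep="\t", index=False
        )
        log["outputs"] = {k: str(v) for k, v in outputs.items()}
        return log
    except PipelineError:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise
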