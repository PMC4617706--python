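"""End-to-end pipeline orchestration with provenance.

Runs the full analysis in the canonical order — presence filter,
cumulative profiles, consensus construction, EPD scoring, threshold
calibration (or a fixed threshold), assignment, replicate QC — and
optionally writes the outputs plus a machine-readable provenance record
(config hash, seed, library versions, per-stage protein counts) so any
output file is reproducible from the record alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import (
    Assignment,
    EPDTable,
    ThresholdSearchResult,
    assign_modules,
    build_consensus,
    epd_table,
    threshold_search,
)
from .containers import ElutionProfileSet, IntensityMatrix
from .io import (
    read_intensity_table,
    read_modules,
    write_assignment,
    write_profiles,
)
from .profiles import build_profiles, presence_filter
from .qc import ReplicateQC, replicate_qc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Inputs may be given as paths (``intensity_path``, ``modules_path``)
    or as in-memory objects (``matrix``, ``modules``); exactly one form
    per input.  ``threshold`` (fixed) and ``auto_threshold`` are
    mutually exclusive.
    """

    intensity_path: str | None = None
    modules_path: str | None = None
    matrix: IntensityMatrix | None = None
    modules: dict[str, list[str]] | None = None
    min_fraction: float = 4 / 7
    epd_normalized: bool = False  # plain L2 by default
    consensus_leave_one_out: bool = False
    n_steps: int = 1000  # threshold-search grid size
    threshold: float | None = None
    auto_threshold: bool = True
    seed: int = 0
    out_dir: str | None = None
    run_qc: bool = True

    def validate(self) -> None:
        if (self.intensity_path is None) == (self.matrix is None):
            raise ValueError("provide exactly one of intensity_path or matrix")
        if (self.modules_path is None) == (self.modules is None):
            raise ValueError("provide exactly one of modules_path or modules")
        if self.threshold is not None and self.auto_threshold:
            raise ValueError("fixed threshold and auto_threshold are mutually exclusive")
        if self.threshold is None and not self.auto_threshold:
            raise ValueError("either a fixed threshold or auto_threshold is required")

    def content_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # the hash pins the computation, not its destination
        # in-memory inputs are hashed by value so the record pins them
        if self.matrix is not None:
            d["matrix"] = hashlib.sha256(
                self.matrix.values.to_csv().encode()
            ).hexdigest()
        if self.modules is not None:
            d["modules"] = {k: list(v) for k, v in sorted(self.modules.items())}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """All intermediate and final products of one run."""

    matrix: IntensityMatrix
    filtered: IntensityMatrix
    profiles: ElutionProfileSet
    epd: EPDTable
    search: ThresholdSearchResult | None
    assignment: Assignment
    qc: ReplicateQC | None
    provenance: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute filter -> profiles -> consensus -> EPD -> threshold -> assignment -> QC."""
    cfg.validate()
    counts: dict[str, int] = {}

    with _stage("load"):
        matrix = cfg.matrix if cfg.matrix is not None else read_intensity_table(cfg.intensity_path)
        modules_def = cfg.modules if cfg.modules is not None else read_modules(cfg.modules_path)
        counts["input_proteins"] = len(matrix.proteins)

    with _stage("presence_filter"):
        filtered = presence_filter(matrix, cfg.min_fraction)
        counts["after_presence_filter"] = len(filtered.proteins)
        logger.info(
            "presence filter: %d -> %d proteins",
            counts["input_proteins"], counts["after_presence_filter"],
        )

    with _stage("profiles"):
        profiles = build_profiles(filtered)
        counts["profiles"] = len(profiles)

    with _stage("consensus"):
        modules = [
            build_consensus(profiles, members, name)
            for name, members in sorted(modules_def.items())
        ]
        for m in modules:
            if m.missing_members:
                logger.warning(
                    "module %s: %d curated members lack profiles: %s",
                    m.name, len(m.missing_members), m.missing_members,
                )

    with _stage("epd"):
        table = epd_table(
            profiles,
            modules,
            normalized=cfg.epd_normalized,
            leave_one_out=cfg.consensus_leave_one_out,
        )

    search = None
    with _stage("threshold"):
        if cfg.auto_threshold:
            search = threshold_search(table, modules, n_steps=cfg.n_steps)
            threshold = search.selected_threshold
        else:
            threshold = float(cfg.threshold)

    with _stage("assignment"):
        assignment = assign_modules(table, modules, threshold)
        counts["reference_proteins"] = assignment.n_reference
        counts["candidate_proteins"] = assignment.n_candidates

    qc = None
    if cfg.run_qc:
        with _stage("qc"):
            qc = replicate_qc(filtered)

    provenance = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "threshold": threshold,
        "threshold_mode": "auto" if cfg.auto_threshold else "fixed",
        "versions": {
            "epasis": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
    }

    if cfg.out_dir is not None:
        with _stage("write"):
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_profiles(profiles, out / "profiles.tsv")
            write_assignment(assignment, out / "assignment.tsv")
            table.epd.rename_axis("accession").to_csv(out / "epd.tsv", sep="\t")
            if search is not None:
                pd.DataFrame(
                    {
                        "threshold": search.grid,
                        "sensitivity": search.sensitivity,
                        "specificity": search.specificity,
                    }
                ).to_csv(out / "threshold_search.tsv", sep="\t", index=False)
            if qc is not None:
                qc.replicate_pairs.to_csv(out / "qc_replicates.tsv", sep="\t", index=False)
                qc.step_spearman.rename_axis("step").to_csv(out / "qc_steps.tsv", sep="\t")
            (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return PipelineResult(
        matrix=matrix,
        filtered=filtered,
        profiles=profiles,
        epd=table,
        search=search,
        assignment=assignment,
        qc=qc,
        provenance=provenance,
    )
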