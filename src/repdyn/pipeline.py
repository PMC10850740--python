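"""Study-shaped orchestration: one config in, a directory of tables out.

A run config names the sample manifest (patient x timepoint x compartment
clone tables), the ordered comparisons to call expansions on, thresholds, the
tracking anchor and optional marker inputs.  ``run_pipeline`` executes
diversity -> overlap -> expansion -> tracking -> markers, writes TSV/CSV
outputs plus a JSON report, and is idempotent: re-running with identical
inputs rewrites identical content (the report's timestamp aside).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .clone_io import (
    CANONICAL_TIMEPOINTS,
    CloneTable,
    SampleSeries,
    read_clone_table,
)
from .expansion import call_expansions, calls_to_frame, track_expanded
from .longitudinal_markers import (
    AnalyteMatrix,
    cohort_mean_logfc,
    log_fold_change,
    paired_t,
)
from .repertoire_stats import diversity_result, overlap_matrix

__all__ = ["RunConfig", "RunReport", "PipelineError", "load_config", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending sample."""


@dataclass
class SampleEntry:
    patient: str
    timepoint: str
    compartment: str
    path: str


@dataclass
class RunConfig:
    """Parsed and path-resolved run configuration."""

    samples: list[SampleEntry]
    outdir: Path
    seed: int = 0
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: [("Pre", "PC")])
    fold_threshold: float = 2.0
    alpha: float = 0.05
    bh: bool = False
    track_anchor: tuple[str, str] = ("Pre", "PC")
    dialect: dict[str, str] = field(default_factory=dict)
    marker_csv: Path | None = None
    marker_baseline: str = "Pre"
    marker_log_base: float = 10
    llod_csv: Path | None = None


@dataclass
class RunReport:
    """Machine-readable record sufficient to reproduce the run."""

    version: str
    seed: int
    parameters: dict[str, Any]
    stages: dict[str, dict[str, Any]]
    qc: list[dict[str, Any]]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "parameters": self.parameters,
                "stages": self.stages,
                "qc": self.qc,
                "timestamp": self.timestamp,
            },
            indent=2,
            sort_keys=True,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; relative paths resolve against the config dir."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config document must be a mapping")
    base = path.parent

    def _resolve(p: str | None) -> Path | None:
        return (base / p) if p else None

    samples = [
        SampleEntry(
            patient=str(s["patient"]),
            timepoint=str(s["timepoint"]),
            compartment=str(s.get("compartment", "blood")),
            path=str(_resolve(s["path"])),
        )
        for s in doc.get("samples", [])
    ]
    thresholds = doc.get("thresholds", {})
    track = doc.get("track", {})
    markers = doc.get("markers", {})
    return RunConfig(
        samples=samples,
        outdir=Path(_resolve(doc.get("outdir", "out"))),
        seed=int(doc.get("seed", 0)),
        comparisons=[tuple(c) for c in doc.get("comparisons", [["Pre", "PC"]])],
        fold_threshold=float(thresholds.get("fold", 2.0)),
        alpha=float(thresholds.get("alpha", 0.05)),
        bh=bool(thresholds.get("bh", False)),
        track_anchor=(
            str(track.get("anchor_ref", "Pre")),
            str(track.get("anchor_cmp", "PC")),
        ),
        dialect=dict(doc.get("io", {}).get("dialect", {})),
        marker_csv=_resolve(markers.get("path")),
        marker_baseline=str(markers.get("baseline", "Pre")),
        marker_log_base=float(markers.get("base", 10)),
        llod_csv=_resolve(markers.get("llod")),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Static checks; an empty list means the config is runnable."""
    problems: list[str] = []
    if not config.samples:
        problems.append("manifest lists no samples")
    labels = {s.timepoint for s in config.samples}
    for entry in config.samples:
        if not Path(entry.path).exists():
            problems.append(f"sample file not found: {entry.path}")
    for ref, cmp_ in config.comparisons:
        for lab in (ref, cmp_):
            if lab not in labels:
                problems.append(f"comparison label {lab!r} not in manifest timepoints")
    if config.fold_threshold <= 0:
        problems.append(f"fold threshold must be > 0, got {config.fold_threshold}")
    if not 0 < config.alpha < 1:
        problems.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.marker_log_base not in (2, 10):
        problems.append(f"marker log base must be 2 or 10, got {config.marker_log_base}")
    if config.marker_csv is not None and not config.marker_csv.exists():
        problems.append(f"marker file not found: {config.marker_csv}")
    if config.llod_csv is not None and not config.llod_csv.exists():
        problems.append(f"LLOD file not found: {config.llod_csv}")
    return problems


def _load_samples(config: RunConfig) -> list[CloneTable]:
    tables = []
    for entry in config.samples:
        try:
            tables.append(
                read_clone_table(
                    entry.path,
                    dialect=config.dialect or None,
                    sample_id=f"{entry.patient}_{entry.timepoint}_{entry.compartment}",
                    patient_id=entry.patient,
                    timepoint=entry.timepoint,
                    compartment=entry.compartment,
                )
            )
        except Exception as exc:
            raise PipelineError(f"stage=ingest sample={entry.path}: {exc}") from exc
    return tables


def _fmt(x: float) -> str:
    return repr(float(x))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write outputs under ``config.outdir``."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("stage=validate: " + "; ".join(problems))
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, Any]] = {}

    tables = _load_samples(config)
    qc = [
        {
            "sample_id": t.sample_id,
            "patient": t.patient_id,
            "timepoint": t.timepoint,
            "compartment": t.compartment,
            "n_clones": t.n_clones,
            "total_templates": t.total_count,
            "discarded_rows": t.n_discarded,
        }
        for t in tables
    ]

    # --- diversity ------------------------------------------------------
    try:
        rows = []
        for t in tables:
            d = diversity_result(t)
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "patient": t.patient_id,
                    "timepoint": t.timepoint,
                    "compartment": t.compartment,
                    "n_clones": d.n_clones,
                    "total_templates": t.total_count,
                    "simpson": _fmt(d.simpson),
                    **{f"top{k}_fraction": _fmt(v) for k, v in d.top_k_fractions.items()},
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        stages["diversity"] = {"status": "ok", "output": "diversity.tsv", "n_samples": len(tables)}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage=diversity: {exc}") from exc

    # --- overlap --------------------------------------------------------
    if len(tables) >= 2:
        try:
            matrix = overlap_matrix(tables)
            matrix.to_csv(outdir / "overlap_matrix.tsv", sep="\t")
            pairs = []
            ids = list(matrix.index)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    pairs.append({"sample_a": a, "sample_b": b, "morisita": _fmt(matrix.loc[a, b])})
            pd.DataFrame(pairs).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
            stages["overlap"] = {
                "status": "ok",
                "output": ["overlap.tsv", "overlap_matrix.tsv"],
            }
        except Exception as exc:
            raise PipelineError(f"stage=overlap: {exc}") from exc
    else:
        stages["overlap"] = {"status": "skipped", "reason": "fewer than 2 samples"}

    # --- expansion + tracking (blood series per patient) ----------------
    by_patient: dict[str, list[CloneTable]] = {}
    for t in tables:
        if t.compartment == "blood":
            by_patient.setdefault(t.patient_id, []).append(t)

    expansion_outputs = []
    expansion_counts: dict[str, int] = {}
    tracked_rows = []
    any_comparison = False
    for patient in sorted(by_patient):
        series = SampleSeries.from_tables(by_patient[patient])
        for ref, cmp_ in config.comparisons:
            if ref not in series or cmp_ not in series:
                continue
            any_comparison = True
            try:
                calls = call_expansions(
                    series[ref], series[cmp_],
                    fold_threshold=config.fold_threshold,
                    alpha=config.alpha, bh=config.bh,
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage=expansion sample={patient}:{ref}->{cmp_}: {exc}"
                ) from exc
            name = f"calls_{patient}_{ref}_vs_{cmp_}.tsv"
            calls_to_frame(calls).to_csv(outdir / name, sep="\t", index=False)
            expansion_outputs.append(name)
            expansion_counts[f"{patient}:{ref}->{cmp_}"] = sum(c.expanded for c in calls)
        anchor_ref, anchor_cmp = config.track_anchor
        if anchor_ref in series and anchor_cmp in series:
            tracked = track_expanded(
                series, anchor_ref, anchor_cmp,
                fold_threshold=config.fold_threshold, alpha=config.alpha, bh=config.bh,
            )
            for label in series.labels:
                tracked_rows.append(
                    {
                        "patient": patient,
                        "timepoint": label,
                        "anchor": f"{anchor_ref}->{anchor_cmp}",
                        "n_members": len(tracked.members),
                        "aggregate_frequency": _fmt(tracked.aggregate_frequency[label]),
                    }
                )
    if any_comparison:
        stages["expansion"] = {
            "status": "ok",
            "outputs": expansion_outputs,
            "expanded_counts": expansion_counts,
        }
    else:
        stages["expansion"] = {
            "status": "skipped",
            "reason": "no patient has both labels of any comparison",
        }
    if tracked_rows:
        pd.DataFrame(tracked_rows).to_csv(outdir / "tracked.tsv", sep="\t", index=False)
        stages["tracking"] = {"status": "ok", "output": "tracked.tsv"}
    else:
        stages["tracking"] = {"status": "skipped", "reason": "anchor labels absent"}

    # --- markers --------------------------------------------------------
    if config.marker_csv is not None:
        try:
            long = pd.read_csv(config.marker_csv)
            llod = {}
            if config.llod_csv is not None:
                llod_df = pd.read_csv(config.llod_csv)
                llod = dict(zip(llod_df.iloc[:, 0], llod_df.iloc[:, 1].astype(float)))
            matrix = AnalyteMatrix.from_long(long, llod=llod)
            logfc, n_floored = log_fold_change(
                matrix, baseline=config.marker_baseline, base=config.marker_log_base
            )
            logfc.to_long().to_csv(outdir / "logfc.csv", index=False)
            means, ns = cohort_mean_logfc(logfc)
            means.to_csv(outdir / "logfc_means.csv")
            ns.to_csv(outdir / "logfc_n.csv")
            trows = []
            for ref, cmp_ in config.comparisons:
                if ref in matrix.timepoints and cmp_ in matrix.timepoints:
                    tt = paired_t(matrix, cmp_, ref).reset_index()
                    tt.insert(0, "comparison", f"{ref}->{cmp_}")
                    trows.append(tt)
            if trows:
                pd.concat(trows, ignore_index=True).to_csv(outdir / "ttests.csv", index=False)
            stages["markers"] = {
                "status": "ok",
                "outputs": ["logfc.csv", "logfc_means.csv", "logfc_n.csv"]
                + (["ttests.csv"] if trows else []),
                "n_floored": n_floored,
            }
        except Exception as exc:
            raise PipelineError(f"stage=markers sample={config.marker_csv}: {exc}") from exc
    else:
        stages["markers"] = {"status": "skipped", "reason": "no marker input configured"}

    report = RunReport(
        version=__version__,
        seed=config.seed,
        parameters={
            "comparisons": [list(c) for c in config.comparisons],
            "fold_threshold": config.fold_threshold,
            "alpha": config.alpha,
            "bh": config.bh,
            "track_anchor": list(config.track_anchor),
            "marker_baseline": config.marker_baseline,
            "marker_log_base": config.marker_log_base,
            "table_construction": "(clone count, all-other-template count) per sample",
            "timepoint_order": list(CANONICAL_TIMEPOINTS),
        },
        stages=stages,
        qc=qc,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
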