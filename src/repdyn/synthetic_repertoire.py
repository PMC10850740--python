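"""Seeded synthetic longitudinal repertoires and analyte matrices.

The generator emulates the processed clone-abundance tables the analysis
consumes, with known ground truth at every stage:

* a heavy-tailed true clone-frequency vector (Zipf by default — repertoires
  are dominated by a few large clones over a long singleton tail);
* per-timepoint biological expansions injected on the *true* frequencies
  (selected clones multiplied by a fold, then renormalized) before any
  sampling, so recovery tests compare caller output against real signal;
* observed tables as multinomial draws of a given template depth from the
  timepoint's true frequencies — the sampling noise the expansion caller must
  see through;
* tissue compartments sharing a configurable fraction of clone identities
  with blood, with independently perturbed frequencies and shallower
  (survey-resolution) depth;
* analyte panels with lognormal between-subject baselines, multiplicative
  per-timepoint effects and lognormal measurement noise.

Everything is driven by one integer seed; the same config and seed give
byte-identical emitted tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clone_io import (
    CANONICAL_TIMEPOINTS,
    CloneTable,
    SampleSeries,
    write_clone_table,
)

__all__ = [
    "ExpansionEvent",
    "CompartmentSpec",
    "AnalyteSpec",
    "SimulationConfig",
    "GroundTruth",
    "CompartmentTruth",
    "simulate_series",
    "simulate_analytes",
    "downsample",
    "write_fixtures",
    "int_to_cdr3",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def int_to_cdr3(i: int, prefix: str = "CAS") -> str:
    """Deterministic valid CDR3-like label for an integer (handy in tests)."""
    if i < 0:
        raise ValueError("index must be non-negative")
    digits = []
    i += 1
    while i:
        i, r = divmod(i, 20)
        digits.append(_AA[r])
    return prefix + "".join(digits) + "F"


def _random_cdr3s(rng: np.random.Generator, n: int, taken: set[str] | None = None) -> list[str]:
    """n unique CDR3-like strings: 'C' + 8..16 residues + 'F'."""
    taken = set(taken or ())
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 17))
        s = "C" + "".join(rng.choice(_AA, size=length)) + "F"
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


@dataclass(frozen=True)
class ExpansionEvent:
    """Inject ``n_clones`` expansions of ``fold`` at ``timepoint``.

    Clones are drawn from the baseline-frequency stratum
    ``stratum[0] <= p < stratum[1]``.
    """

    timepoint: str
    n_clones: int
    fold: float
    stratum: tuple[float, float] = (1e-3, 1e-2)


@dataclass(frozen=True)
class CompartmentSpec:
    """A tissue compartment sharing ``s_share`` of clone identities with blood.

    Shared clones keep their blood baseline frequency up to lognormal
    perturbation of log-sd ``perturb_sigma``; the rest are novel identities.
    Default depth is survey resolution (an order of magnitude below blood).
    """

    s_share: float = 0.2
    depth: int = 10_000
    perturb_sigma: float = 0.5
    timepoints: tuple[str, ...] = ("Pre", "PC")


@dataclass(frozen=True)
class AnalyteSpec:
    """Lognormal baseline and per-timepoint multiplicative effects (log10 scale)."""

    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 0.3
    effects: Mapping[str, float] = field(default_factory=dict)  # timepoint -> fold
    noise_log10_sd: float = 0.1
    llod: float | None = None


def _default_expansions() -> list[ExpansionEvent]:
    # One large-clone event (drives clonality up at PC) plus a cohort of
    # mid-frequency expansions (what the caller is asked to recover).
    return [
        ExpansionEvent("PC", 2, 4.0, (0.05, 1.0)),
        ExpansionEvent("PC", 20, 4.0, (1e-3, 1e-2)),
    ]


@dataclass
class SimulationConfig:
    """Full, seeded parameterization of one synthetic study."""

    seed: int
    n_clones: int = 5000
    abundance: tuple = ("zipf", 1.2)  # or ("lognormal", mu, sigma)
    timepoints: tuple[str, ...] = CANONICAL_TIMEPOINTS
    depth: int | Mapping[str, int] = 100_000
    expansions: list[ExpansionEvent] = field(default_factory=_default_expansions)
    compartments: dict[str, CompartmentSpec] = field(default_factory=dict)
    patient_id: str = "SIM01"
    n_subjects: int = 10
    analytes: dict[str, AnalyteSpec] = field(default_factory=dict)

    def depth_at(self, timepoint: str) -> int:
        if isinstance(self.depth, Mapping):
            return int(self.depth[timepoint])
        return int(self.depth)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for tp in self.timepoints:
            if self.depth_at(tp) < 1:
                raise ValueError(f"depth at {tp} must be >= 1")
        for ev in self.expansions:
            if ev.fold <= 0:
                raise ValueError(f"expansion fold must be > 0, got {ev.fold}")
            if ev.timepoint not in self.timepoints:
                raise ValueError(f"expansion timepoint {ev.timepoint!r} not simulated")
            if ev.n_clones > self.n_clones:
                raise ValueError("more expanded clones than clones")
        for name, spec in self.compartments.items():
            if not 0.0 <= spec.s_share <= 1.0:
                raise ValueError(f"{name}: s_share must be in [0, 1]")
            if spec.depth < 1:
                raise ValueError(f"{name}: depth must be >= 1")
        for name, spec in self.analytes.items():
            if spec.baseline_log10_sd < 0 or spec.noise_log10_sd < 0:
                raise ValueError(f"{name}: non-negative sds required")


@dataclass
class CompartmentTruth:
    """True clone identities and per-timepoint frequency vectors."""

    clones: list[str]
    freqs: dict[str, np.ndarray]  # timepoint -> vector aligned with clones


@dataclass
class GroundTruth:
    compartments: dict[str, CompartmentTruth]
    expanded: dict[str, list[str]]           # blood timepoint -> injected clone ids
    analyte_effects: dict[str, dict[str, float]]

    def frequency(self, compartment: str, timepoint: str, cdr3aa: str) -> float:
        truth = self.compartments[compartment]
        try:
            idx = truth.clones.index(cdr3aa)
        except ValueError:
            return 0.0
        return float(truth.freqs[timepoint][idx])


def _baseline_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.abundance[0]
    n = config.n_clones
    if kind == "zipf":
        s = float(config.abundance[1])
        w = np.arange(1, n + 1, dtype=float) ** (-s)
    elif kind == "lognormal":
        mu, sigma = float(config.abundance[1]), float(config.abundance[2])
        w = np.sort(rng.lognormal(mu, sigma, size=n))[::-1]
    else:
        raise ValueError(f"unknown abundance model {kind!r}")
    return w / w.sum()


def _inject(
    base: np.ndarray,
    events: list[ExpansionEvent],
    timepoint: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """True frequencies at a timepoint: fold-multiplied selections, renormalized."""
    mult = np.ones_like(base)
    chosen: list[int] = []
    taken: set[int] = set()
    for ev in events:
        if ev.timepoint != timepoint:
            continue
        lo, hi = ev.stratum
        eligible = np.flatnonzero((base >= lo) & (base < hi))
        eligible = np.array([i for i in eligible if i not in taken])
        if len(eligible) < ev.n_clones:
            raise ValueError(
                f"stratum [{lo}, {hi}) at {timepoint} has {len(eligible)} eligible "
                f"clones, {ev.n_clones} requested"
            )
        sel = rng.choice(eligible, size=ev.n_clones, replace=False)
        mult[sel] = ev.fold
        chosen.extend(int(i) for i in sel)
        taken.update(int(i) for i in sel)
    freqs = base * mult
    return freqs / freqs.sum(), sorted(chosen)


def _sample_table(
    clones: list[str],
    freqs: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    *,
    sample_id: str,
    patient_id: str,
    timepoint: str,
    compartment: str,
) -> CloneTable:
    counts = rng.multinomial(depth, freqs)
    nz = np.flatnonzero(counts)
    return CloneTable.from_counts(
        {clones[i]: int(counts[i]) for i in nz},
        sample_id=sample_id,
        patient_id=patient_id,
        timepoint=timepoint,
        compartment=compartment,
    )


def simulate_series(config: SimulationConfig) -> tuple[dict[str, SampleSeries], GroundTruth]:
    """Simulate the blood series plus any tissue compartments.

    Returns ``(series_by_compartment, ground_truth)``; the blood compartment
    is always present under the key ``"blood"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    base = _baseline_frequencies(config, rng)
    clones = _random_cdr3s(rng, config.n_clones)

    truths: dict[str, CompartmentTruth] = {}
    expanded: dict[str, list[str]] = {}
    blood_freqs: dict[str, np.ndarray] = {}
    for tp in config.timepoints:
        freqs, chosen = _inject(base, config.expansions, tp, rng)
        blood_freqs[tp] = freqs
        expanded[tp] = [clones[i] for i in chosen]
    truths["blood"] = CompartmentTruth(clones=clones, freqs=blood_freqs)

    series: dict[str, SampleSeries] = {}
    blood_tables = []
    for tp in config.timepoints:
        blood_tables.append(
            _sample_table(
                clones, blood_freqs[tp], config.depth_at(tp), rng,
                sample_id=f"{config.patient_id}_{tp}_blood",
                patient_id=config.patient_id, timepoint=tp, compartment="blood",
            )
        )
    series["blood"] = SampleSeries.from_tables(blood_tables)

    for name, spec in config.compartments.items():
        n = config.n_clones
        n_shared = int(round(spec.s_share * n))
        shared_idx = np.sort(rng.choice(n, size=n_shared, replace=False))
        novel = _random_cdr3s(rng, n - n_shared, taken=set(clones))
        comp_clones = list(clones)
        novel_iter = iter(novel)
        shared_mask = np.zeros(n, dtype=bool)
        shared_mask[shared_idx] = True
        for i in range(n):
            if not shared_mask[i]:
                comp_clones[i] = next(novel_iter)
        if spec.perturb_sigma > 0:
            noise = rng.lognormal(0.0, spec.perturb_sigma, size=n)
        else:
            noise = np.ones(n)
        w = base * noise
        comp_freqs = w / w.sum()
        truths[name] = CompartmentTruth(
            clones=comp_clones,
            freqs={tp: comp_freqs for tp in spec.timepoints},
        )
        tables = [
            _sample_table(
                comp_clones, comp_freqs, spec.depth, rng,
                sample_id=f"{config.patient_id}_{tp}_{name}",
                patient_id=config.patient_id, timepoint=tp, compartment=name,
            )
            for tp in spec.timepoints
        ]
        series[name] = SampleSeries.from_tables(tables)

    truth = GroundTruth(
        compartments=truths,
        expanded=expanded,
        analyte_effects={a: dict(s.effects) for a, s in config.analytes.items()},
    )
    return series, truth


def simulate_analytes(config: SimulationConfig):
    """Simulate the subject x analyte x timepoint matrix for the config's panel.

    Value = lognormal subject baseline x per-timepoint true effect x lognormal
    noise; with zero noise the log10 FC of each timepoint is exactly the log10
    of the true effect.  Returns ``(AnalyteMatrix, GroundTruth)`` (repertoire
    fields empty).
    """
    config.validate()
    if not config.analytes:
        raise ValueError("config has no analyte specs")
    from .longitudinal_markers import AnalyteMatrix

    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    rows = []
    for analyte, spec in sorted(config.analytes.items()):
        baseline = 10.0 ** rng.normal(
            spec.baseline_log10_mean, spec.baseline_log10_sd, size=config.n_subjects
        )
        for tp in config.timepoints:
            effect = float(spec.effects.get(tp, 1.0))
            if spec.noise_log10_sd > 0:
                noise = 10.0 ** rng.normal(0.0, spec.noise_log10_sd, size=config.n_subjects)
            else:
                noise = np.ones(config.n_subjects)
            values = baseline * effect * noise
            rows.extend(
                (subjects[i], analyte, tp, float(values[i]))
                for i in range(config.n_subjects)
            )
    long = pd.DataFrame(rows, columns=["subject", "analyte", "timepoint", "value"])
    llod = {a: s.llod for a, s in config.analytes.items() if s.llod is not None}
    matrix = AnalyteMatrix.from_long(long, llod=llod)
    truth = GroundTruth(
        compartments={},
        expanded={},
        analyte_effects={a: dict(s.effects) for a, s in config.analytes.items()},
    )
    return matrix, truth


def downsample(
    table: CloneTable, depth: int, seed: int, with_replacement: bool = False
) -> CloneTable:
    """Subsample a clone table to ``depth`` templates.

    Default is the without-replacement (multivariate hypergeometric) variant,
    under which ``depth == total_count`` returns the identical table; the
    multinomial with-replacement variant is selectable.  Deterministic per
    seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > table.total_count:
        raise ValueError(
            f"depth {depth} exceeds table total {table.total_count}"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(table.records)
    counts = np.array([table.records[k].count for k in keys])
    if with_replacement:
        new = rng.multinomial(depth, counts / counts.sum())
    else:
        new = rng.multivariate_hypergeometric(counts, depth)
    nz = np.flatnonzero(new)
    return CloneTable.from_counts(
        {keys[i]: int(new[i]) for i in nz},
        sample_id=table.sample_id,
        patient_id=table.patient_id,
        timepoint=table.timepoint,
        compartment=table.compartment,
    )


def write_fixtures(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit clone-table TSVs, an analyte CSV and ground_truth.json.

    Files are named ``<patient>_<timepoint>_<compartment>.tsv``.  Returns a
    manifest dict (also embedded in ground_truth.json) naming every file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = simulate_series(config)
    manifest = {"patient_id": config.patient_id, "samples": []}
    for comp, s in series.items():
        for label in s.labels:
            t = s[label]
            name = f"{config.patient_id}_{label}_{comp}.tsv"
            write_clone_table(t, outdir / name)
            manifest["samples"].append(
                {
                    "patient": config.patient_id,
                    "timepoint": label,
                    "compartment": comp,
                    "path": name,
                }
            )
    if config.analytes:
        matrix, _ = simulate_analytes(config)
        matrix.to_long().to_csv(outdir / "analytes.csv", index=False)
        manifest["analytes"] = "analytes.csv"
    gt = {
        "seed": config.seed,
        "expanded": truth.expanded,
        "analyte_effects": truth.analyte_effects,
        "true_frequencies": {
            comp: {
                "clones": ct.clones,
                "freqs": {tp: v.tolist() for tp, v in ct.freqs.items()},
            }
            for comp, ct in truth.compartments.items()
        },
        "manifest": manifest,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    return manifest
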