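"""Baseline-relative kinetics of flow-cytometry populations and serum cytokines.

Inputs are already-derived quantities: gated population frequencies (percent
of parent) or analyte concentrations in pg/ml, one value per subject x
analyte x timepoint on the canonical blood-draw schedule (Pre, PI, PC, PS).
The effect of therapy on each marker is described as the log fold change
relative to the subject's own baseline, which removes between-subject
baseline variability; cohort summaries average that log FC per analyte and
timepoint.  Derived cell ratios (e.g. effector CD8 over regulatory
Foxp3+CD4+, or CD8 over the immunosuppressive CD4+PD-1hi subset) and paired t
tests between two timepoints complete the stage.

Values below a declared lower limit of detection (LLOD) are floored at the
LLOD before any log transform, and the number of floored values is surfaced;
with no declared LLOD a zero yields a missing log FC rather than -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .clone_io import CANONICAL_TIMEPOINTS

__all__ = [
    "AnalyteMatrix",
    "RatioTable",
    "log_fold_change",
    "cohort_mean_logfc",
    "cell_ratio",
    "paired_t",
]


@dataclass
class AnalyteMatrix:
    """Subject x analyte x timepoint grid of non-negative values.

    ``values`` is a DataFrame indexed by subject with a 2-level column index
    (analyte, timepoint); missing measurements are NaN.  ``llod`` maps an
    analyte to its lower limit of detection where one is declared.
    """

    values: pd.DataFrame
    llod: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex) or self.values.columns.nlevels != 2:
            raise ValueError("values needs (analyte, timepoint) MultiIndex columns")
        bad_tp = set(self.values.columns.get_level_values(1)) - set(CANONICAL_TIMEPOINTS)
        if bad_tp:
            raise ValueError(
                f"unknown timepoint labels {sorted(bad_tp)}; expected {CANONICAL_TIMEPOINTS}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("analyte values must be >= 0 or missing")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        *,
        subject: str = "subject",
        analyte: str = "analyte",
        timepoint: str = "timepoint",
        value: str = "value",
        llod: Mapping[str, float] | None = None,
    ) -> "AnalyteMatrix":
        """Build from a long table with subject/analyte/timepoint/value columns."""
        wide = df.pivot_table(
            index=subject, columns=[analyte, timepoint], values=value, aggfunc="first"
        )
        wide.index.name = "subject"
        wide.columns.names = ["analyte", "timepoint"]
        return cls(values=wide, llod=dict(llod or {}))

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def timepoints(self) -> list[str]:
        present = set(self.values.columns.get_level_values(1))
        return [t for t in CANONICAL_TIMEPOINTS if t in present]

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack(["analyte", "timepoint"], future_stack=True)
        long = long.rename("value").reset_index()
        return long.dropna(subset=["value"]).reset_index(drop=True)


def _floored(matrix: AnalyteMatrix) -> tuple[pd.DataFrame, int]:
    """Apply LLOD floors; returns (floored values, number of floored cells)."""
    vals = matrix.values.copy()
    n_floored = 0
    for analyte, limit in matrix.llod.items():
        if analyte not in vals.columns.get_level_values(0):
            continue
        block = vals.loc[:, analyte]
        below = (block < limit) & block.notna()
        n_floored += int(below.to_numpy().sum())
        vals.loc[:, analyte] = block.where(~below, other=limit).to_numpy()
    return vals, n_floored


def log_fold_change(
    matrix: AnalyteMatrix, baseline: str = "Pre", base: float = 10
) -> tuple[AnalyteMatrix, int]:
    """Per subject/analyte/timepoint log fold change relative to baseline.

    Returns ``(logfc, n_floored)`` where ``n_floored`` counts values raised to
    their analyte's LLOD before the transform.  The baseline column is 0 by
    construction; a zero value with no declared LLOD, or a missing baseline,
    propagates as missing.  Base 10 is the convention for marker heatmaps and
    base 2 for clone fold changes.
    """
    if base not in (2, 10):
        raise ValueError("log base must be 2 or 10")
    if baseline not in matrix.timepoints:
        raise ValueError(f"baseline {baseline!r} not among timepoints {matrix.timepoints}")
    vals, n_floored = _floored(matrix)
    out = {}
    for analyte in matrix.analytes:
        block = vals.loc[:, analyte]
        if baseline not in block.columns:
            continue
        base_col = block[baseline]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = block.div(base_col, axis=0).to_numpy(dtype=float)
            lfc = np.log(ratio) / np.log(base)
        lfc[~np.isfinite(lfc)] = np.nan
        for j, tp in enumerate(block.columns):
            out[(analyte, tp)] = lfc[:, j]
    frame = pd.DataFrame(out, index=matrix.values.index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["analyte", "timepoint"])
    # log FC is signed; bypass the >=0 check by constructing around __post_init__
    result = object.__new__(AnalyteMatrix)
    result.values = frame
    result.llod = {}
    return result, n_floored


def cohort_mean_logfc(logfc: AnalyteMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average log FC over subjects, per analyte and timepoint.

    Returns ``(means, n)``: two analyte x timepoint frames, the second giving
    the number of non-missing subjects behind each mean (0 => missing mean).
    Suitable for heatmap export.
    """
    stacked = logfc.values
    means = stacked.mean(axis=0, skipna=True).unstack("timepoint")
    ns = stacked.notna().sum(axis=0).unstack("timepoint")
    order = [t for t in CANONICAL_TIMEPOINTS if t in means.columns]
    return means[order], ns[order]


@dataclass
class RatioTable:
    """Per-subject, per-timepoint ratio of two analytes (e.g. Teff/Treg)."""

    numerator: str
    denominator: str
    values: pd.DataFrame  # subject x timepoint; NaN where undefined


def cell_ratio(matrix: AnalyteMatrix, numerator: str, denominator: str) -> RatioTable:
    """Elementwise ratio of two analytes per subject and timepoint.

    A zero or missing denominator yields a missing ratio, never infinity.
    """
    for name in (numerator, denominator):
        if name not in matrix.analytes:
            raise KeyError(f"analyte {name!r} not in matrix ({matrix.analytes})")
    num = matrix.values.loc[:, numerator]
    den = matrix.values.loc[:, denominator]
    den = den.where(den > 0)
    ratio = num.div(den)
    order = [t for t in CANONICAL_TIMEPOINTS if t in ratio.columns]
    return RatioTable(numerator=numerator, denominator=denominator, values=ratio[order])


def paired_t(matrix: AnalyteMatrix, label_a: str, label_b: str) -> pd.DataFrame:
    """Classical paired t test between two timepoints, one row per analyte.

    Subjects missing either member of the pair are excluded pairwise.  Columns
    ``t``, ``p``, ``n``, ``degenerate``: with fewer than 2 complete pairs both
    statistics are missing; with zero-variance nonzero differences the test is
    flagged degenerate (p is not fabricated as 0); identical columns give
    t = 0, p = 1.
    """
    rows = []
    for analyte in matrix.analytes:
        block = matrix.values.loc[:, analyte]
        if label_a not in block.columns or label_b not in block.columns:
            rows.append((analyte, np.nan, np.nan, 0, False))
            continue
        pair = block[[label_a, label_b]].dropna()
        n = len(pair)
        if n < 2:
            rows.append((analyte, np.nan, np.nan, n, False))
            continue
        diff = pair[label_a].to_numpy() - pair[label_b].to_numpy()
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.all(diff == 0):
                rows.append((analyte, 0.0, 1.0, n, False))
            else:
                rows.append((analyte, np.nan, np.nan, n, True))
            continue
        t = diff.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        rows.append((analyte, float(t), float(p), n, False))
    return pd.DataFrame(
        rows, columns=["analyte", "t", "p", "n", "degenerate"]
    ).set_index("analyte")
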