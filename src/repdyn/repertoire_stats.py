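"""Per-sample diversity and between-sample overlap of TCR repertoires.

Clonality is quantified with the Simpson index, Sigma p_i^2 over normalized
clone frequencies: the probability that two TCR templates sampled at random
from the repertoire belong to the same clone.  It is 1 for a monoclonal
sample, 1/K for a uniform K-clone sample, and grows as the repertoire
concentrates in few clones (more clonal = less diverse).

Similarity between two samples uses the Morisita(-Horn) overlap,

    M(x, y) = 2 * Sigma_i x_i * y_i / (Sigma_i x_i^2 + Sigma_i y_i^2),

over the union of clones (frequency 0 where a clone is absent).  M is 0 when
no clone is shared and exactly 1 for identical frequency vectors, and is
dominated by the large clones: perturbing the small-clone tail barely moves
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clone_io import CloneTable, EmptySampleError

__all__ = [
    "DiversityResult",
    "simpson_index",
    "simpson_from_counts",
    "rank_frequency",
    "morisita_overlap",
    "overlap_matrix",
    "diversity_result",
]


def simpson_from_counts(counts: Sequence[float] | np.ndarray, unbiased: bool = False) -> float:
    """Simpson index from a vector of clone counts (or frequencies).

    With ``unbiased=True`` the without-replacement estimator
    Sigma n_i (n_i - 1) / (N (N - 1)) is used instead of Sigma p_i^2; the
    default is the plug-in form the frequency-based definition prescribes.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise EmptySampleError("empty count vector")
    if unbiased:
        n = c.sum()
        if n < 2:
            raise ValueError("unbiased Simpson needs at least 2 templates")
        return float(np.sum(c * (c - 1.0)) / (n * (n - 1.0)))
    p = c / c.sum()
    return float(np.sum(p * p))


def simpson_index(table: CloneTable, unbiased: bool = False) -> float:
    """Simpson clonality index of one sample (Sigma p_i^2)."""
    return simpson_from_counts(
        [r.count for r in table.records.values()], unbiased=unbiased
    )


def rank_frequency(table: CloneTable, top_n: int) -> tuple[list[tuple[str, float]], float]:
    """Clones sorted by descending frequency; returns (top entries, remainder).

    Ties are broken lexicographically on the CDR3 so the order is
    deterministic.  The remainder aggregates every clone below ``top_n`` so
    the entries plus remainder sum to 1.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not table.records:
        raise EmptySampleError(f"{table.sample_id}: empty table")
    ranked = sorted(table.records.values(), key=lambda r: (-r.frequency, r.cdr3aa))
    top = [(r.cdr3aa, r.frequency) for r in ranked[:top_n]]
    remainder = sum(r.count for r in ranked[top_n:]) / table.total_count
    return top, remainder


@dataclass
class DiversityResult:
    """Per-sample diversity summary used by the pipeline's diversity stage."""

    sample_id: str
    simpson: float
    n_clones: int
    top_k_fractions: dict[int, float]


def diversity_result(table: CloneTable, ks: Sequence[int] = (1, 5, 10, 25, 100)) -> DiversityResult:
    """Simpson index plus cumulative frequency of the k most abundant clones."""
    ranked = sorted(table.records.values(), key=lambda r: (-r.frequency, r.cdr3aa))
    cum = np.cumsum([r.frequency for r in ranked])
    top_k = {
        int(k): float(cum[min(int(k), len(ranked)) - 1]) for k in ks if k >= 1
    }
    return DiversityResult(
        sample_id=table.sample_id,
        simpson=simpson_index(table),
        n_clones=table.n_clones,
        top_k_fractions=top_k,
    )


def morisita_overlap(a: CloneTable, b: CloneTable) -> float:
    """Morisita-Horn overlap of two samples over the union of their clones."""
    if not a.records or not b.records:
        raise EmptySampleError("overlap of an empty table is undefined")
    # one pass over the sorted union with identical accumulation order for the
    # cross term and both Simpson terms, so identical samples score exactly 1
    # and disjoint samples exactly 0
    cross = sa = sb = 0.0
    for key in sorted(set(a.records) | set(b.records)):
        x = a.frequency(key)
        y = b.frequency(key)
        cross += x * y
        sa += x * x
        sb += y * y
    return 2.0 * cross / (sa + sb)


def overlap_matrix(tables: Iterable[CloneTable]) -> pd.DataFrame:
    """Symmetric pairwise Morisita overlap with a unit diagonal.

    Returns a square DataFrame indexed by sample id in input order.
    """
    tabs = list(tables)
    if len(tabs) < 2:
        raise ValueError("overlap matrix needs at least 2 tables")
    ids = [t.sample_id for t in tabs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in {ids}")
    n = len(tabs)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = morisita_overlap(tabs[i], tabs[j])
    return pd.DataFrame(m, index=ids, columns=ids)
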