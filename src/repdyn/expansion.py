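"""Clone expansion calling between two samples and longitudinal clone tracking.

A clone is called *expanded* from a reference sample to a comparison sample
when both of the following hold:

* its frequency increases by more than ``fold_threshold`` (default 2-fold), and
* the two-sided Fisher exact p-value of the 2x2 table
  ``(count_ref, total_ref - count_ref; count_cmp, total_cmp - count_cmp)``
  is below ``alpha`` (default 0.05).

The conjunction filters the large relative fluctuations that sampling noise
produces in small clones: a 3-fold jump of a 1-in-100,000 clone is not
significant, while the same fold on an abundant clone is.  Clones absent from
the reference but present in the comparison have infinite fold change and are
eligible for expansion solely on the Fisher criterion; clones absent from the
comparison are never expanded.

``fisher_exact_p`` sums hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed that of the observed table
(the classical two-sided exact test).  For grand totals up to 2000 the
inclusion rule is decided in exact integer arithmetic; above that (repertoire
depths of 1e4-1e6 templates) a log-gamma evaluation with a 1e-7 relative tie
guard is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .clone_io import CloneTable, EmptySampleError, SampleSeries

__all__ = [
    "ExpansionCall",
    "TrackedCloneSet",
    "fisher_exact_p",
    "call_expansions",
    "volcano_data",
    "track_expanded",
    "calls_to_frame",
]

# grand total up to which the two-sided inclusion set is decided with exact
# integer combinatorics; beyond it log-gamma is used
_EXACT_TOTAL_LIMIT = 2000
# relative tie guard for the log-gamma path (same rule scipy and R use)
_LOG_TIE_EPS = math.log1p(1e-7)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table ``[[a, b], [c, d]]``.

    Rows are the two samples: ``(clone count, all-other-template count)``.
    Both row totals must be positive.  Deterministic and exact: the p-value is
    the hypergeometric probability mass of all tables with the observed
    margins that are at most as probable as the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"cell counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be positive")
    K = a + c          # total clone templates across both samples
    N = n1 + n2
    if K == 0 or K == N:
        return 1.0
    lo = max(0, K - n2)
    hi = min(K, n1)
    if N <= _EXACT_TOTAL_LIMIT:
        # integer weights w(x) = C(K, x) * C(N-K, n1-x); p = sum(included)/sum(all)
        weights = [math.comb(K, x) * math.comb(N - K, n1 - x) for x in range(lo, hi + 1)]
        w_obs = weights[a - lo]
        included = sum(w for w in weights if w <= w_obs)
        return included / sum(weights)
    support = np.arange(lo, hi + 1)
    logw = (
        gammaln(K + 1)
        - gammaln(support + 1)
        - gammaln(K - support + 1)
        + gammaln(N - K + 1)
        - gammaln(n1 - support + 1)
        - gammaln(N - K - n1 + support + 1)
    )
    log_obs = logw[a - lo]
    mask = logw <= log_obs + _LOG_TIE_EPS
    p = math.exp(logsumexp(logw[mask]) - logsumexp(logw))
    return min(1.0, p)


@dataclass(frozen=True)
class ExpansionCall:
    """Per-clone two-sample comparison result."""

    cdr3aa: str
    count_ref: int
    count_cmp: int
    total_ref: int
    total_cmp: int
    fold_change: float      # freq_cmp / freq_ref; inf when freq_ref == 0
    log2_fc: float          # nan when either frequency is 0
    p_value: float
    expanded: bool


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="fdr_bh")[1]


def call_expansions(
    ref: CloneTable,
    cmp: CloneTable,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[ExpansionCall]:
    """Call expansions for every clone in the union of two samples.

    ``fold_threshold`` and ``alpha`` must be positive.  With ``bh=True`` the
    significance half of the criterion uses Benjamini-Hochberg adjusted
    p-values; the reported ``p_value`` stays raw either way.  Output is sorted
    by CDR3 so identical inputs give identical call tables.
    """
    if not ref.records or not cmp.records:
        raise EmptySampleError("expansion calling needs two non-empty tables")
    if fold_threshold <= 0 or alpha <= 0:
        raise ValueError("fold_threshold and alpha must be positive")
    t_ref, t_cmp = ref.total_count, cmp.total_count
    union = sorted(set(ref.records) | set(cmp.records))

    pcache: dict[tuple[int, int], float] = {}
    raw_p = np.empty(len(union))
    folds = np.empty(len(union))
    counts = []
    for idx, key in enumerate(union):
        cr, cc = ref.count(key), cmp.count(key)
        counts.append((cr, cc))
        pk = (cr, cc)
        p = pcache.get(pk)
        if p is None:
            p = fisher_exact_p(cr, t_ref - cr, cc, t_cmp - cc)
            pcache[pk] = p
        raw_p[idx] = p
        fr, fc = cr / t_ref, cc / t_cmp
        folds[idx] = fc / fr if fr > 0 else math.inf

    sig_p = _bh_adjust(raw_p) if bh else raw_p
    calls = []
    for idx, key in enumerate(union):
        cr, cc = counts[idx]
        fold = folds[idx]
        log2fc = math.log2(fold) if 0 < fold < math.inf else math.nan
        expanded = bool(fold > fold_threshold and sig_p[idx] < alpha)
        calls.append(
            ExpansionCall(
                cdr3aa=key,
                count_ref=cr,
                count_cmp=cc,
                total_ref=t_ref,
                total_cmp=t_cmp,
                fold_change=fold,
                log2_fc=log2fc,
                p_value=float(raw_p[idx]),
                expanded=expanded,
            )
        )
    return calls


def volcano_data(
    calls: Sequence[ExpansionCall], neg_log10_cap: float = 300.0
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Volcano-plot table (log2 FC vs -log10 p) plus a sidecar of edge cases.

    Clones with zero or infinite fold change cannot sit on the log2 axis; they
    are returned in the second frame with their p-values instead of being
    silently dropped.  ``-log10(p)`` is capped at ``neg_log10_cap`` for
    plotting.
    """
    import pandas as pd

    if not calls:
        raise ValueError("no calls supplied")
    main_rows, side_rows = [], []
    for call in calls:
        if math.isfinite(call.log2_fc):
            neg = min(-math.log10(call.p_value) if call.p_value > 0 else neg_log10_cap,
                      neg_log10_cap)
            main_rows.append((call.cdr3aa, call.log2_fc, neg, call.expanded))
        else:
            side_rows.append((call.cdr3aa, call.fold_change, call.p_value, call.expanded))
    main = pd.DataFrame(main_rows, columns=["cdr3aa", "log2_fc", "neg_log10_p", "expanded"])
    side = pd.DataFrame(side_rows, columns=["cdr3aa", "fold_change", "p_value", "expanded"])
    return main, side


@dataclass
class TrackedCloneSet:
    """Clones expanded in an anchor comparison, followed across a series.

    ``aggregate_frequency[label]`` is the summed frequency of the member
    clones in the table at ``label`` (0 where a member is absent).
    """

    anchor_comparison: tuple[str, str]
    members: list[str]
    aggregate_frequency: dict[str, float]


def track_expanded(
    series: SampleSeries,
    anchor_ref: str,
    anchor_cmp: str,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    bh: bool = False,
) -> TrackedCloneSet:
    """Track across a series the clones expanded in one anchor comparison.

    E.g. anchor ``Pre -> PC`` selects the clones that expanded by the
    post-cryoablation draw; their aggregate frequency is then reported at
    every timepoint of the series.
    """
    for label in (anchor_ref, anchor_cmp):
        if label not in series:
            raise KeyError(
                f"anchor label {label!r} not in series ({', '.join(series.labels)})"
            )
    calls = call_expansions(
        series[anchor_ref], series[anchor_cmp],
        fold_threshold=fold_threshold, alpha=alpha, bh=bh,
    )
    members = [c.cdr3aa for c in calls if c.expanded]
    aggregate = {
        label: float(sum(series[label].frequency(m) for m in members))
        for label in series.labels
    }
    return TrackedCloneSet(
        anchor_comparison=(anchor_ref, anchor_cmp),
        members=members,
        aggregate_frequency=aggregate,
    )


def calls_to_frame(calls: Sequence[ExpansionCall]) -> "pd.DataFrame":
    """Expansion calls as a DataFrame in the call-table column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            (c.cdr3aa, c.count_ref, c.count_cmp, c.total_ref, c.total_cmp,
             c.fold_change, c.log2_fc, c.p_value, c.expanded)
            for c in calls
        ],
        columns=[
            "cdr3aa", "count_ref", "count_cmp", "total_ref", "total_cmp",
            "fold_change", "log2_fc", "p_value", "expanded",
        ],
    )
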