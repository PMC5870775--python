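"""Sequential Causal Analysis of Networks (SCAN).

A hypothesis that genuinely drives the observed signature should explain
genes at several path-length horizons, not just at one.  SCAN re-ranks
all hypotheses at each delta of a user-supplied increasing sequence and
keeps only the hypotheses common to every per-delta top list, which
suppresses single-horizon false positives.

The "top list" at a delta is score-based, not row-count based: it
contains every hypothesis whose score is at least the score at rank
``top_n``, so boundary ties are all included and the consensus does not
depend on tie ordering.  The atomic unit throughout is the *signed*
hypothesis -- the two opposite-signed hypotheses of one node are
distinct SCAN candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .experiment import MappedSignature
from .graph_io import CCG
from .scoring import (
    Hypothesis,
    HypothesisResult,
    SignificanceMethod,
    rank_hypotheses,
)

__all__ = ["ScanResult", "run_scan", "scan_table", "DEFAULT_DELTAS", "DEFAULT_TOP_N"]

DEFAULT_DELTAS: tuple[int, ...] = (1, 2, 3)
DEFAULT_TOP_N: int = 100


@dataclass(frozen=True)
class ScanResult:
    """Per-delta top lists and their intersection.

    ``consensus`` holds the hypotheses present in every per-delta top
    list, ordered by their rank at the largest delta.  ``per_delta_results``
    keeps the full ranking rows for reporting.
    """

    deltas: tuple[int, ...]
    top_n: int
    per_delta_top: Mapping[int, tuple[Hypothesis, ...]]
    per_delta_results: Mapping[int, tuple[HypothesisResult, ...]]
    consensus: tuple[Hypothesis, ...]


def _top_by_score(results: Sequence[HypothesisResult], top_n: int) -> list[HypothesisResult]:
    """All rows whose score reaches the score at rank ``top_n`` (ties included)."""
    if not results:
        return []
    cutoff_idx = min(top_n, len(results)) - 1
    cutoff_score = results[cutoff_idx].score
    return [r for r in results if r.score >= cutoff_score]


def run_scan(
    ccg: CCG,
    msig: MappedSignature,
    deltas: Sequence[int] = DEFAULT_DELTAS,
    top_n: int = DEFAULT_TOP_N,
    significance: SignificanceMethod = "none",
    n_perm: int = 10_000,
    seed: int = 0,
) -> ScanResult:
    """Rank hypotheses at every delta and intersect the top lists.

    ``deltas`` must be non-empty and strictly increasing; ``top_n >= 1``.
    Significance defaults to ``'none'`` here because consensus membership
    depends only on scores; pass ``'exact'``/``'montecarlo'``/``'auto'``
    to also populate p-values in the retained ranking rows.
    """
    deltas = tuple(deltas)
    if not deltas:
        raise ValueError("deltas must be a non-empty sequence")
    if any(d < 1 for d in deltas) or any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError(f"deltas must be strictly increasing positive integers, got {deltas}")
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")

    per_delta_results: dict[int, tuple[HypothesisResult, ...]] = {}
    per_delta_top: dict[int, tuple[Hypothesis, ...]] = {}
    for delta in deltas:
        results = rank_hypotheses(
            ccg, msig, delta, significance=significance, n_perm=n_perm, seed=seed
        )
        per_delta_results[delta] = tuple(results)
        per_delta_top[delta] = tuple(
            r.hypothesis for r in _top_by_score(results, top_n)
        )

    consensus_set = set(per_delta_top[deltas[0]])
    for delta in deltas[1:]:
        consensus_set &= set(per_delta_top[delta])
    # order by rank at the largest delta
    consensus = tuple(
        h for h in per_delta_top[deltas[-1]] if h in consensus_set
    )
    return ScanResult(
        deltas=deltas,
        top_n=top_n,
        per_delta_top=per_delta_top,
        per_delta_results=per_delta_results,
        consensus=consensus,
    )


def scan_table(scan: ScanResult) -> pd.DataFrame:
    """Consensus hypotheses with their score and rank at every delta."""
    by_delta: dict[int, dict[Hypothesis, HypothesisResult]] = {
        d: {r.hypothesis: r for r in rows} for d, rows in scan.per_delta_results.items()
    }
    data: dict[str, list] = {
        "NodeName": [h.node for h in scan.consensus],
        "Regulation": [h.sign for h in scan.consensus],
    }
    for d in scan.deltas:
        data[f"Score_delta{d}"] = [by_delta[d][h].score for h in scan.consensus]
        data[f"Rank_delta{d}"] = [by_delta[d][h].rank for h in scan.consensus]
    return pd.DataFrame(data)
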