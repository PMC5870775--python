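"""Hypothesis scoring and ranking on the computational causal graph.

A *hypothesis* is a signed statement "entity X is up- (or down-)
regulated" placed at the root of the cascade.  Propagating it through
the CCG for at most ``delta`` edges predicts a regulation direction for
every entity reachable within that horizon; the prediction is compared
gene-by-gene with the mapped experimental signature and summarised as

    score = correct - incorrect

where a gene is *correct* when its predicted and observed signs agree,
*incorrect* when they contradict, and *ambiguous* (contributing nothing)
when both signs are reachable within delta.  Every signed hypothesis of
every network entity is scored and the table ranked, yielding candidate
upstream regulators of the observed signature.

Significance machinery
----------------------
Two per-hypothesis quantities accompany the score:

* ``p_value`` -- probability of a score at least as large when the
  observed multiset of +1/0/-1 values is reassigned uniformly at random
  to the signature genes with the predictions held fixed.  Computed
  exactly by summing multivariate-hypergeometric weights over the
  (prediction class x observation class) contingency tables, or
  estimated by seeded Monte Carlo shuffles with the add-one estimator
  ``(k+1)/(n_perm+1)``.
* ``enrichment_p`` -- a sign-blind one-sided hypergeometric tail for the
  overlap between predicted and observed-nonzero genes, flagging
  hypotheses that merely touch many measured genes.

Neither quantity is corrected for multiple testing across hypotheses;
that is deliberately left to the caller.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .experiment import MappedSignature
from .graph_io import CCG

__all__ = [
    "Hypothesis",
    "PredictionMap",
    "ScoreBreakdown",
    "HypothesisResult",
    "predict_regulation",
    "score_hypothesis",
    "score_significance",
    "enrichment_significance",
    "rank_hypotheses",
    "ranking_table",
]

#: Above this many contingency tables the exact null switches to Monte Carlo.
DEFAULT_EXACT_TABLE_BUDGET = 10_000_000

SignificanceMethod = Literal["auto", "exact", "montecarlo", "none"]


@dataclass(frozen=True, order=True)
class Hypothesis:
    """A signed candidate regulator: ``node`` driven in direction ``sign``."""

    node: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"hypothesis sign must be +1 or -1, got {self.sign!r}")

    def __str__(self) -> str:
        return f"{self.node}{'+' if self.sign > 0 else '-'}"


@dataclass(frozen=True)
class PredictionMap:
    """Predicted regulation per entity within ``delta`` edges of a hypothesis.

    ``predictions[e]`` is +1 or -1 when exactly one sign copy of ``e`` is
    reachable, and 0 (ambiguous) when both are.  Entities with neither
    copy reachable are absent.  The hypothesis node itself is present at
    distance 0 with its hypothesised sign, unless a cycle of length
    <= delta reaches its opposite copy, in which case it is ambiguous.
    """

    hypothesis: Hypothesis
    delta: int
    predictions: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.predictions)

    def get(self, entity: str, default=None):
        return self.predictions.get(entity, default)


class ScoreBreakdown(tuple):
    """(score, correct, incorrect, ambiguous) with named access."""

    __slots__ = ()

    def __new__(cls, score: int, correct: int, incorrect: int, ambiguous: int):
        return super().__new__(cls, (score, correct, incorrect, ambiguous))

    score = property(lambda self: self[0])
    correct = property(lambda self: self[1])
    incorrect = property(lambda self: self[2])
    ambiguous = property(lambda self: self[3])


@dataclass(frozen=True)
class HypothesisResult:
    """One row of the ranking table."""

    hypothesis: Hypothesis
    score: int
    correct: int
    incorrect: int
    ambiguous: int
    p_value: float
    enrichment_p: float
    rank: int = 0


def predict_regulation(ccg: CCG, hyp: Hypothesis, delta: int) -> PredictionMap:
    """Breadth-first sign propagation from a hypothesis to depth ``delta``.

    BFS runs over the CCG arcs from the node copy ``(hyp.node, hyp.sign)``;
    an entity reached only through its +1 copy is predicted up, only
    through its -1 copy down, and through both copies ambiguous (0).
    ``delta`` counts edges and is inclusive.
    """
    if delta < 1:
        raise ValueError(f"delta must be a positive integer, got {delta}")
    if hyp.node not in ccg.entities:
        raise KeyError(f"hypothesis node {hyp.node!r} is not in the causal network")
    reached = nx.single_source_shortest_path_length(
        ccg.graph, (hyp.node, hyp.sign), cutoff=delta
    )
    predictions: dict[str, int] = {}
    for entity, _copy_sign in reached:
        if entity in predictions:
            continue
        plus = (entity, +1) in reached
        minus = (entity, -1) in reached
        predictions[entity] = 0 if (plus and minus) else (+1 if plus else -1)
    return PredictionMap(hypothesis=hyp, delta=delta, predictions=predictions)


def score_hypothesis(pred: PredictionMap, msig: MappedSignature) -> ScoreBreakdown:
    """Count correct/incorrect/ambiguous genes and form score = correct - incorrect.

    Only genes present in both the prediction map and the mapped
    signature are counted; genes observed 0 or not predicted contribute
    to no counter.
    """
    correct = incorrect = ambiguous = 0
    for gene, obs in msig.mapped.items():
        p = pred.predictions.get(gene)
        if p is None or obs == 0:
            continue
        if p == 0:
            ambiguous += 1
        elif p == obs:
            correct += 1
        else:
            incorrect += 1
    return ScoreBreakdown(correct - incorrect, correct, incorrect, ambiguous)


def _null_class_counts(
    pred: PredictionMap, msig: MappedSignature
) -> tuple[int, int, int]:
    """Numbers of mapped genes predicted +1, -1, and 0-or-absent."""
    n_plus = n_minus = n_null = 0
    for gene in msig.mapped:
        p = pred.predictions.get(gene)
        if p == +1:
            n_plus += 1
        elif p == -1:
            n_minus += 1
        else:
            n_null += 1
    return n_plus, n_minus, n_null


def _exact_table_count(n_plus: int, n_minus: int, q_plus: int, q_minus: int) -> int:
    return (
        (min(n_plus, q_plus) + 1)
        * (min(n_plus, q_minus) + 1)
        * (min(n_minus, q_plus) + 1)
        * (min(n_minus, q_minus) + 1)
    )


def _exact_p_value(
    n_plus: int, n_minus: int, n_null: int, q_plus: int, q_minus: int, q_zero: int,
    observed_score: int,
) -> Fraction:
    """P(score >= observed) under uniform reassignment of the observation multiset.

    Sums, over all contingency tables of (prediction class x observation
    class) with the given margins, the number of gene labelings realising
    the table; a table's score depends only on its four signed cells.
    """
    n = n_plus + n_minus + n_null
    total = Fraction(math.factorial(n), math.factorial(q_plus) * math.factorial(q_minus) * math.factorial(q_zero))
    favourable = 0
    for u_plus in range(min(n_plus, q_plus) + 1):
        for u_minus in range(min(n_plus - u_plus, q_minus) + 1):
            ways_plus_bin = (
                math.comb(n_plus, u_plus) * math.comb(n_plus - u_plus, u_minus)
            )
            for v_plus in range(min(n_minus, q_plus - u_plus) + 1):
                for v_minus in range(min(n_minus - v_plus, q_minus - u_minus) + 1):
                    w_plus = q_plus - u_plus - v_plus
                    w_minus = q_minus - u_minus - v_minus
                    if w_plus + w_minus > n_null:
                        continue
                    score = (u_plus - u_minus) - (v_plus - v_minus)
                    if score < observed_score:
                        continue
                    ways = (
                        ways_plus_bin
                        * math.comb(n_minus, v_plus)
                        * math.comb(n_minus - v_plus, v_minus)
                        * math.comb(n_null, w_plus)
                        * math.comb(n_null - w_plus, w_minus)
                    )
                    favourable += ways
    return Fraction(favourable) / total


def _derive_seed(seed: int, *tokens: object) -> int:
    """Stable per-hypothesis sub-seed, independent of evaluation order."""
    digest = hashlib.sha256(repr((seed, *tokens)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _montecarlo_p_value(
    pred_vec: np.ndarray, obs_vec: np.ndarray, observed_score: int,
    n_perm: int, seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    obs = obs_vec.copy()
    for _ in range(n_perm):
        rng.shuffle(obs)
        if int(pred_vec @ obs) >= observed_score:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def score_significance(
    pred: PredictionMap,
    msig: MappedSignature,
    method: SignificanceMethod = "auto",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    exact_table_budget: int = DEFAULT_EXACT_TABLE_BUDGET,
) -> float:
    """P(score >= observed) when observations are shuffled across genes.

    ``method='exact'`` enumerates contingency tables with multivariate-
    hypergeometric weights; ``'montecarlo'`` uses ``n_perm`` seeded
    shuffles and the add-one estimator.  ``'auto'`` picks exact unless
    the margin-bounded table count exceeds ``exact_table_budget``.  With
    no signature genes the p-value is 1 by convention.
    """
    if len(msig.mapped) == 0:
        return 1.0
    breakdown = score_hypothesis(pred, msig)
    n_plus, n_minus, n_null = _null_class_counts(pred, msig)
    if method == "auto":
        tables = _exact_table_count(n_plus, n_minus, msig.q_plus, msig.q_minus)
        method = "exact" if tables <= exact_table_budget else "montecarlo"
    if method == "exact":
        p = _exact_p_value(
            n_plus, n_minus, n_null, msig.q_plus, msig.q_minus, msig.q_zero,
            breakdown.score,
        )
        return float(p)
    if method == "montecarlo":
        if seed is None:
            raise ValueError("montecarlo significance requires a seed")
        genes = list(msig.mapped)
        pred_vec = np.array(
            [pred.predictions.get(g) or 0 for g in genes], dtype=np.int64
        )
        obs_vec = np.array([msig.mapped[g] for g in genes], dtype=np.int64)
        return _montecarlo_p_value(pred_vec, obs_vec, breakdown.score, n_perm, seed)
    raise ValueError(f"unknown significance method {method!r}")


def enrichment_significance(
    pred: PredictionMap, msig: MappedSignature, universe_size: Optional[int] = None
) -> float:
    """One-sided hypergeometric tail for predicted/observed-nonzero overlap.

    The overlap counts signature genes that are both predicted (with any
    value, ambiguous included) and observed nonzero; the predicted margin
    likewise counts only signature genes, so the universe defaults to the
    mapped signature.  Degenerate margins (no predictions, or no nonzero
    observations) give 1.
    """
    n_observed = msig.q_plus + msig.q_minus
    n_predicted = sum(1 for gene in msig.mapped if gene in pred.predictions)
    if universe_size is None:
        universe_size = len(msig.mapped)
    if universe_size < len(msig.mapped):
        raise ValueError(
            f"universe_size {universe_size} smaller than signature ({len(msig.mapped)})"
        )
    if n_predicted == 0 or n_observed == 0:
        return 1.0
    overlap = sum(
        1
        for gene, obs in msig.mapped.items()
        if obs != 0 and gene in pred.predictions
    )
    return float(hypergeom.sf(overlap - 1, universe_size, n_predicted, n_observed))


def _sort_key(result: HypothesisResult):
    return (
        -result.score,
        result.p_value,
        result.enrichment_p,
        result.hypothesis.node,
        -result.hypothesis.sign,
    )


def rank_hypotheses(
    ccg: CCG,
    msig: MappedSignature,
    delta: int,
    significance: SignificanceMethod = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
    universe_size: Optional[int] = None,
    nodes: Optional[Iterable[str]] = None,
) -> list[HypothesisResult]:
    """Score and rank every signed hypothesis of the network.

    Both signs of every entity are scored (2N rows), sorted by score
    descending with the deterministic tie-break chain (p-value, then
    enrichment p, then node name, then +1 before -1) and assigned ranks
    1..2N.  Scoring of distinct hypotheses is independent -- each row is
    a pure function of (CCG, signature, hypothesis, delta, seed) -- so
    any concurrent schedule reproduces the sequential table.

    ``significance='none'`` sets all p-values to 1 (useful when only the
    score ordering matters, e.g. inside SCAN).  ``nodes`` optionally
    restricts ranking to a subset of entities.
    """
    if universe_size is None:
        universe_size = len(msig.mapped)
    if nodes is None:
        candidates = sorted(ccg.entities)
    else:
        candidates = sorted(set(nodes))
        missing = [n for n in candidates if n not in ccg.entities]
        if missing:
            raise KeyError(f"nodes not in the causal network: {missing}")
    results: list[HypothesisResult] = []
    for node in candidates:
        for sign in (+1, -1):
            hyp = Hypothesis(node, sign)
            pred = predict_regulation(ccg, hyp, delta)
            breakdown = score_hypothesis(pred, msig)
            if significance == "none":
                p_value = 1.0
            else:
                p_value = score_significance(
                    pred,
                    msig,
                    method=significance,
                    n_perm=n_perm,
                    seed=_derive_seed(seed, node, sign),
                )
            enr = enrichment_significance(pred, msig, universe_size)
            results.append(
                HypothesisResult(
                    hypothesis=hyp,
                    score=breakdown.score,
                    correct=breakdown.correct,
                    incorrect=breakdown.incorrect,
                    ambiguous=breakdown.ambiguous,
                    p_value=p_value,
                    enrichment_p=enr,
                )
            )
    results.sort(key=_sort_key)
    return [
        HypothesisResult(
            hypothesis=r.hypothesis,
            score=r.score,
            correct=r.correct,
            incorrect=r.incorrect,
            ambiguous=r.ambiguous,
            p_value=r.p_value,
            enrichment_p=r.enrichment_p,
            rank=i,
        )
        for i, r in enumerate(results, start=1)
    ]


def ranking_table(results: Sequence[HypothesisResult]) -> pd.DataFrame:
    """Ranking results as the canonical TSV-ready table."""
    return pd.DataFrame(
        {
            "NodeName": [r.hypothesis.node for r in results],
            "Regulation": [r.hypothesis.sign for r in results],
            "Score": [r.score for r in results],
            "Correct": [r.correct for r in results],
            "Incorrect": [r.incorrect for r in results],
            "Ambiguous": [r.ambiguous for r in results],
            "PValue": [r.p_value for r in results],
            "EnrichmentPValue": [r.enrichment_p for r in results],
            "Rank": [r.rank for r in results],
        }
    )
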