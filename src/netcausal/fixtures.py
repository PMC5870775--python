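"""Synthetic signed networks, planted-regulator signatures and test oracles.

Everything here is reproducible from an integer seed with integer-only
randomness, so fixtures are bit-identical across platforms.  The random
graph model is deliberately simple -- uniform over distinct ordered node
pairs, no self-loops, independent edge signs -- and makes no attempt to
mimic the degree distributions or motif content of curated interactomes.

Signatures are generated by propagating a chosen ("planted") regulator
hypothesis through the network at a generation delta and observing the
predicted signs, optionally corrupted by noise: with the stated per-gene
probability the value is either sign-flipped or zeroed (equal odds),
exercising both the mismatch and the dropout paths of the scorer.

:func:`oracle_predict` is the deliberately slow reference for sign
propagation: it enumerates every walk of bounded length explicitly and
classifies entities by the set of achievable edge-sign products.  It is
guarded to small instances and exists to check the BFS implementation,
never to replace it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .graph_io import CCG, SignedEdge
from .experiment import Signature
from .scoring import Hypothesis, PredictionMap, predict_regulation

__all__ = ["FixtureSpec", "generate_network", "generate_signature", "oracle_predict"]

_SIGN_BITS = 30  # resolution of the integer Bernoulli draws


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic network + signature instance.

    Defaults describe a mid-sized, moderately dense toy regulatory network:
    30 entities with 90 edges (mean out-degree 3, enough for multi-step
    cascades), three quarters of edges activating (curated signalling
    networks skew toward activation), a noise-free fully observed
    signature generated two steps from the planted regulator.
    """

    n_nodes: int = 30
    n_edges: int = 90
    activation_fraction: float = 0.75
    hypothesis: Hypothesis = field(default_factory=lambda: Hypothesis("G000", +1))
    delta: int = 2
    noise: float = 0.0
    coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.n_edges <= self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"n_edges must be within [0, n_nodes*(n_nodes-1)] = "
                f"[0, {self.n_nodes * (self.n_nodes - 1)}], got {self.n_edges}"
            )
        for name in ("activation_fraction", "noise", "coverage"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")

    def with_(self, **changes) -> "FixtureSpec":
        return replace(self, **changes)


def node_name(i: int) -> str:
    return f"G{i:03d}"


def _bernoulli(rng: random.Random, probability: float) -> bool:
    # integer comparison keeps generation decisions float-free
    threshold = round(probability * (1 << _SIGN_BITS))
    return rng.getrandbits(_SIGN_BITS) < threshold


def generate_network(spec: FixtureSpec) -> list[SignedEdge]:
    """Sample a seeded random signed digraph with exactly ``n_edges`` edges.

    Ordered node pairs are drawn uniformly without replacement (so no
    duplicate pairs and no self-loops); each edge activates with
    probability ``activation_fraction``, independently.
    """
    rng = random.Random(spec.seed)
    n = spec.n_nodes
    pair_indices = rng.sample(range(n * (n - 1)), spec.n_edges)
    edges: list[SignedEdge] = []
    for idx in pair_indices:
        i, j0 = divmod(idx, n - 1)
        j = j0 if j0 < i else j0 + 1
        sign = +1 if _bernoulli(rng, spec.activation_fraction) else -1
        edges.append(SignedEdge(node_name(i), sign, node_name(j)))
    return edges


def generate_signature(ccg: CCG, spec: FixtureSpec) -> Signature:
    """Propagate the planted hypothesis and observe it with noise and dropout.

    The planted hypothesis is propagated at ``spec.delta``; a seeded
    sample of ``coverage`` of the predicted entities enters the
    signature with its predicted sign (ambiguous entities as 0).  Each
    value is then independently corrupted with probability ``noise``:
    half the corruptions flip the sign, half zero the value.
    """
    if spec.hypothesis.node not in ccg.entities:
        raise KeyError(
            f"planted hypothesis node {spec.hypothesis.node!r} is not in the network"
        )
    pred = predict_regulation(ccg, spec.hypothesis, spec.delta)
    rng = random.Random(spec.seed + 0x5EED)
    genes = sorted(pred.predictions)
    n_keep = round(spec.coverage * len(genes))
    kept = sorted(rng.sample(genes, n_keep))
    values: dict[str, int] = {}
    for gene in kept:
        value = pred.predictions[gene]
        if _bernoulli(rng, spec.noise):
            if rng.getrandbits(1):
                value = -value  # a zero stays zero under a sign flip
            else:
                value = 0
        values[gene] = value
    return Signature(values=values, name=f"planted:{spec.hypothesis}")


_ORACLE_MAX_NODES = 12
_ORACLE_MAX_DELTA = 4


def oracle_predict(ccg: CCG, hyp: Hypothesis, delta: int) -> PredictionMap:
    """Reference sign propagation by exhaustive walk enumeration.

    Every directed walk of length <= delta starting at the hypothesis
    node is enumerated over the substrate edges; each reached entity is
    classified by the set of achievable edge-sign products multiplied by
    the hypothesis sign.  Guarded to <= 12 entities and delta <= 4
    because the enumeration is intentionally brute-force.
    """
    if ccg.n_entities > _ORACLE_MAX_NODES or delta > _ORACLE_MAX_DELTA:
        raise ValueError(
            f"oracle limited to <= {_ORACLE_MAX_NODES} nodes and "
            f"delta <= {_ORACLE_MAX_DELTA} (got {ccg.n_entities} nodes, delta {delta})"
        )
    if hyp.node not in ccg.entities:
        raise KeyError(f"hypothesis node {hyp.node!r} is not in the causal network")
    out_edges: dict[str, list[tuple[str, int]]] = {}
    for edge in ccg.edges:
        out_edges.setdefault(edge.source, []).append((edge.target, edge.sign))

    achievable: dict[str, set[int]] = {}

    def walk(entity: str, product: int, remaining: int) -> None:
        achievable.setdefault(entity, set()).add(product)
        if remaining == 0:
            return
        for target, sign in out_edges.get(entity, ()):
            walk(target, product * sign, remaining - 1)

    walk(hyp.node, +1, delta)
    predictions = {
        entity: (0 if len(products) == 2 else hyp.sign * next(iter(products)))
        for entity, products in achievable.items()
    }
    return PredictionMap(hypothesis=hyp, delta=delta, predictions=predictions)
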