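"""Signed causal networks: SIF parsing and the computational causal graph.

A causal network is a directed graph whose edges assert that the source
entity *activates* (sign +1) or *inhibits* (sign -1) the target entity.
Networks are exchanged in the simple interaction format (SIF): three
whitespace-separated columns ``source  relation  target``, one edge per
line, the dialect Cytoscape reads and writes.

The computational causal graph (CCG) doubles every entity into an
up-copy ``(e, +1)`` and a down-copy ``(e, -1)``.  An input edge
``(a, s, b)`` contributes the two arcs ``(a,+1) -> (b, s)`` and
``(a,-1) -> (b,-s)``, so that reaching copy ``(e, q)`` from copy
``(h, p)`` certifies a directed path from ``h`` to ``e`` whose edge-sign
product is ``p*q``.  Plain reachability queries on the doubled graph
therefore answer signed-regulation questions on the original network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Canonical relation tokens of the SIF dialect this package speaks.
ACTIVATES = "Activates"
INHIBITS = "Inhibits"

_RELATION_SIGNS = {"activates": +1, "inhibits": -1}
_SIGN_RELATIONS = {+1: ACTIVATES, -1: INHIBITS}


class SifParseError(ValueError):
    """A SIF line could not be interpreted as a signed causal edge."""


@dataclass(frozen=True, order=True)
class SignedEdge:
    """One causal assertion: ``source`` drives ``target`` with ``sign``.

    ``sign`` is +1 for activation and -1 for inhibition.  Identifiers are
    taken verbatim (case-sensitive, no symbol harmonisation) and must be
    non-empty and tab-free so the edge can round-trip through SIF.
    """

    source: str
    sign: int
    target: str

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        for field_name, value in (("source", self.source), ("target", self.target)):
            if not isinstance(value, str) or not value or "\t" in value:
                raise ValueError(
                    f"{field_name} must be a non-empty, tab-free string, got {value!r}"
                )

    @property
    def relation(self) -> str:
        """The SIF relation token encoding this edge's sign."""
        return _SIGN_RELATIONS[self.sign]

    def to_sif_line(self) -> str:
        return f"{self.source}\t{self.relation}\t{self.target}"


class CCG:
    """Computational causal graph: the signed network with doubled nodes.

    Parameters
    ----------
    edges:
        Signed edges of the substrate network.  Duplicates are harmless
        (the arc set is a set); contradictory duplicates -- the same
        ordered pair asserted with both signs -- are both retained and
        simply render the target ambiguous downstream of the source.
    """

    def __init__(self, edges: Iterable[SignedEdge]):
        self.edges: tuple[SignedEdge, ...] = tuple(dict.fromkeys(edges))
        graph = nx.DiGraph()
        entities: set[str] = set()
        for edge in self.edges:
            entities.add(edge.source)
            entities.add(edge.target)
            graph.add_edge((edge.source, +1), (edge.target, edge.sign))
            graph.add_edge((edge.source, -1), (edge.target, -edge.sign))
        # isolated copies cannot arise from edges, but both copies of every
        # entity must exist so reachability queries are well-posed
        for entity in entities:
            graph.add_node((entity, +1))
            graph.add_node((entity, -1))
        self.graph: nx.DiGraph = graph
        self.entities: frozenset[str] = frozenset(entities)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def edge_count(self) -> int:
        """Number of distinct input edges retained."""
        return len(self.edges)

    def __contains__(self, entity: str) -> bool:
        return entity in self.entities

    def __repr__(self) -> str:
        return f"CCG({self.n_entities} entities, {self.edge_count} edges)"


def parse_sif(path: PathLike, strict: bool = True) -> list[SignedEdge]:
    """Read signed edges from a SIF file.

    Lines are split on any run of whitespace; blank lines and lines whose
    first non-space character is ``#`` are skipped.  Relation tokens are
    matched case-insensitively against ``Activates``/``Inhibits``.  Exact
    duplicate edges collapse to one, keeping first-appearance order.

    Parameters
    ----------
    path:
        SIF file to read (UTF-8).
    strict:
        If true (default), an unknown relation token raises
        :class:`SifParseError`; otherwise the line is skipped with a
        logged warning.  Malformed lines (not exactly three fields) are
        always errors.
    """
    seen: dict[SignedEdge, None] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise SifParseError(
                f"{path}: line {lineno}: expected 3 fields, found {len(fields)}"
            )
        source, relation, target = fields
        sign = _RELATION_SIGNS.get(relation.lower())
        if sign is None:
            message = (
                f"{path}: line {lineno}: unknown relation token {relation!r} "
                f"(expected {ACTIVATES!r} or {INHIBITS!r})"
            )
            if strict:
                raise SifParseError(message)
            logger.warning("%s -- line skipped", message)
            continue
        seen.setdefault(SignedEdge(source, sign, target))
    return list(seen)


def write_sif(edges: Sequence[SignedEdge], path: PathLike) -> None:
    """Write edges to ``path`` in the same SIF dialect :func:`parse_sif` reads."""
    lines = [edge.to_sif_line() for edge in dict.fromkeys(edges)]
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def build_ccg(edges: Iterable[SignedEdge]) -> CCG:
    """Build the computational causal graph for a list of signed edges.

    The entity set is the union of all sources and targets; every input
    edge ``(a, s, b)`` yields the arcs ``(a,+1)->(b,s)`` and
    ``(a,-1)->(b,-s)``.  The arc set is consequently symmetric under a
    global sign flip of all node copies.
    """
    return CCG(edges)
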