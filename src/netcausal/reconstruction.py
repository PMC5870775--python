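"""Explained-subnetwork reconstruction and Cytoscape export.

Given a regulator hypothesis, the *explained* nodes are the measured
genes whose predicted regulation (within delta edges) equals their
observed regulation.  The reconstructed network retains, for every
explained node, **all shortest sign-consistent paths** from the
hypothesis to that node in the CCG, projected back to signed edges of
the substrate network.  This keeps the output deterministic and
size-bounded while still showing redundant parallel branches.

Cascade members that lie on retained paths without being explained
themselves are *intermediate* ("grey") nodes: predicted parts of the
signalling cascade that were unchanged or unmeasured in the experiment.
They are annotated 0 in the companion node-attribute table, which
Cytoscape can load directly alongside the SIF file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import networkx as nx

from .experiment import MappedSignature
from .graph_io import CCG, SignedEdge, write_sif
from .scan import ScanResult
from .scoring import Hypothesis, predict_regulation

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "ExplainedNetwork",
    "explained_nodes",
    "reconstruct",
    "write_explained_sif",
    "write_all_scan_networks",
]


@dataclass(frozen=True)
class ExplainedNetwork:
    """Subnetwork of predictive paths from a hypothesis to its explained nodes."""

    hypothesis: Hypothesis
    delta: int
    explained: frozenset[str]
    intermediates: frozenset[str]
    edges: frozenset[SignedEdge]
    annotations: Mapping[str, int]

    @property
    def nodes(self) -> frozenset[str]:
        return (
            self.explained
            | self.intermediates
            | {self.hypothesis.node}
            | {e.source for e in self.edges}
            | {e.target for e in self.edges}
        )


def explained_nodes(
    ccg: CCG, msig: MappedSignature, hyp: Hypothesis, delta: int
) -> set[str]:
    """Entities whose nonzero prediction equals their nonzero observation.

    Ambiguous entities (prediction 0) and contradicted entities are never
    explained.
    """
    pred = predict_regulation(ccg, hyp, delta)
    return {
        gene
        for gene, obs in msig.mapped.items()
        if obs != 0 and pred.predictions.get(gene) == obs
    }


def reconstruct(
    ccg: CCG, msig: MappedSignature, hyp: Hypothesis, delta: int
) -> ExplainedNetwork:
    """Retain all shortest sign-consistent paths to every explained node.

    For an explained node ``g`` observed with sign ``q``, every shortest
    path in the CCG from copy ``(hyp.node, hyp.sign)`` to copy ``(g, q)``
    is retained (its length is <= delta because ``g`` was predicted
    within delta).  CCG arcs on retained paths are projected back to
    signed edges: the arc ``(a,p) -> (b,q)`` came from the edge
    ``(a, p*q, b)``.  An empty explained set yields a hypothesis-only
    network with zero edges (a logged notice, not an error).
    """
    explained = explained_nodes(ccg, msig, hyp, delta)
    edges: set[SignedEdge] = set()
    path_entities: set[str] = set()
    source_copy = (hyp.node, hyp.sign)
    for gene in sorted(explained):
        target_copy = (gene, msig.mapped[gene])
        for path in nx.all_shortest_paths(ccg.graph, source_copy, target_copy):
            for (a, p), (b, q) in zip(path, path[1:]):
                edges.add(SignedEdge(a, p * q, b))
            path_entities.update(entity for entity, _ in path)
    if not explained:
        logger.info(
            "hypothesis %s explains no nodes at delta %d; writing hypothesis-only network",
            hyp,
            delta,
        )
    intermediates = path_entities - explained - {hyp.node}
    all_nodes = path_entities | {hyp.node}
    annotations = {node: msig.mapped.get(node, 0) for node in sorted(all_nodes)}
    return ExplainedNetwork(
        hypothesis=hyp,
        delta=delta,
        explained=frozenset(explained),
        intermediates=frozenset(intermediates),
        edges=frozenset(edges),
        annotations=annotations,
    )


def write_explained_sif(
    net: ExplainedNetwork, sif_path: PathLike, annot_path: PathLike
) -> None:
    """Write a network as a Cytoscape-ready SIF plus node-annotation TSV.

    SIF lines are deduplicated and sorted lexicographically; the
    annotation table has the header ``NodeName<TAB>Regulation`` and
    covers every node of the SIF (the hypothesis node included even when
    the edge set is empty).
    """
    try:
        write_sif(sorted(net.edges), sif_path)
        nodes = sorted(net.nodes)
        lines = ["NodeName\tRegulation"]
        lines += [f"{node}\t{net.annotations.get(node, 0)}" for node in nodes]
        Path(annot_path).write_text(
            "".join(line + "\n" for line in lines), encoding="utf-8"
        )
    except OSError as exc:
        raise OSError(
            f"failed writing explained network to {sif_path} / {annot_path}: {exc}"
        ) from exc


_UNSAFE_CHARS = re.compile(r"[^A-Za-z0-9._-]")


def _safe_stem(hyp: Hypothesis) -> str:
    node = _UNSAFE_CHARS.sub("_", hyp.node)
    return f"{node}{'+' if hyp.sign > 0 else '-'}"


def write_all_scan_networks(
    ccg: CCG,
    msig: MappedSignature,
    scan: ScanResult,
    delta: int,
    out_dir: PathLike,
) -> list[tuple[Path, Path]]:
    """Write one (SIF, annotation) file pair per SCAN consensus hypothesis.

    Filenames encode the node name and hypothesis sign (``NODE+.sif`` /
    ``NODE-.sif`` with filesystem-unsafe characters replaced by ``_``);
    name collisions after escaping get a deterministic numeric suffix.
    Returns the written path pairs in consensus order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not scan.consensus:
        logger.info("SCAN consensus is empty; no networks written")
        return []
    written: list[tuple[Path, Path]] = []
    used_stems: dict[str, int] = {}
    for hyp in scan.consensus:
        stem = _safe_stem(hyp)
        count = used_stems.get(stem, 0)
        used_stems[stem] = count + 1
        if count:
            stem = f"{stem}.{count}"
        net = reconstruct(ccg, msig, hyp, delta)
        sif_path = out_dir / f"{stem}.sif"
        annot_path = out_dir / f"{stem}_annotations.txt"
        write_explained_sif(net, sif_path, annot_path)
        written.append((sif_path, annot_path))
    return written
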