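"""Shared fixtures: small hand-built graphs and random-instance helpers."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netcausal import (
    CCG,
    FixtureSpec,
    Hypothesis,
    MappedSignature,
    Signature,
    SignedEdge,
    build_ccg,
    generate_network,
    map_signature,
)


@pytest.fixture
def chain_ccg() -> CCG:
    """A -Activates-> B -Inhibits-> C."""
    return build_ccg([SignedEdge("A", +1, "B"), SignedEdge("B", -1, "C")])


@pytest.fixture
def diamond_ccg() -> CCG:
    """A activates D through both B and C (two parallel length-2 paths)."""
    return build_ccg(
        [
            SignedEdge("A", +1, "B"),
            SignedEdge("A", +1, "C"),
            SignedEdge("B", +1, "D"),
            SignedEdge("C", +1, "D"),
        ]
    )


def mapped(ccg: CCG, values: dict[str, int]) -> MappedSignature:
    return map_signature(Signature(values), ccg)


def random_small_spec(seed: int, max_nodes: int = 12) -> FixtureSpec:
    """A random graph spec small enough for the exhaustive-walk oracle."""
    rng = random.Random(seed)
    n = rng.randint(3, max_nodes)
    n_edges = rng.randint(0, min(3 * n, n * (n - 1)))
    return FixtureSpec(
        n_nodes=n,
        n_edges=n_edges,
        activation_fraction=rng.choice([0.25, 0.5, 0.75]),
        seed=seed,
    )


def random_small_ccg(seed: int, max_nodes: int = 12) -> CCG:
    return build_ccg(generate_network(random_small_spec(seed, max_nodes)))


def random_observations(ccg: CCG, seed: int, n_genes: int) -> MappedSignature:
    """A random ternary signature over a sample of network entities."""
    rng = random.Random(seed)
    entities = sorted(ccg.entities)
    genes = rng.sample(entities, min(n_genes, len(entities)))
    values = {g: rng.choice([-1, 0, 1]) for g in genes}
    return mapped(ccg, values)


def planted_spec(seed: int, rng_range=(20, 50), delta: int = 2, noise: float = 0.0) -> FixtureSpec:
    """A planted-regulator fixture whose hypothesis node is the max-out-degree node."""
    rng = random.Random(seed)
    n = rng.randint(*rng_range)
    spec = FixtureSpec(n_nodes=n, n_edges=3 * n, delta=delta, noise=noise, seed=seed)
    edges = generate_network(spec)
    out_degree: dict[str, int] = {}
    for e in edges:
        out_degree[e.source] = out_degree.get(e.source, 0) + 1
    planted = max(sorted(out_degree), key=out_degree.get)
    return spec.with_(hypothesis=Hypothesis(planted, +1))
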