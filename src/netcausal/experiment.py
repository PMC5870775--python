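"""Ternary experimental signatures and their projection onto a network.

A signature summarises a differential experiment (usually a case/control
transcriptomics contrast) as one value per gene: ``+1`` up-regulated,
``0`` unchanged, ``-1`` down-regulated.  Only the direction of change is
used downstream; discretising fold changes into this ternary form is the
caller's job.

Mapping a signature onto a CCG restricts it to genes the causal network
actually contains, and reports how many genes were lost: with public
causal interaction data still sparse, substantial unmapped fractions are
normal and are surfaced as a warning, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from .graph_io import CCG

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_ALLOWED_VALUES = (-1, 0, 1)
# dashes that occur in the wild (and in typeset tables): U+2212 minus,
# en dash, em dash -- normalised to ASCII '-' before integer parsing
_DASH_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})


class SignatureParseError(ValueError):
    """A signature file line could not be interpreted."""


@dataclass(frozen=True)
class Signature:
    """Mapping from gene identifier to observed regulation in {+1, 0, -1}."""

    values: Mapping[str, int]
    name: str = ""

    def __post_init__(self) -> None:
        for gene, value in self.values.items():
            if value not in _ALLOWED_VALUES:
                raise ValueError(
                    f"regulation value for {gene!r} must be -1, 0 or 1, got {value!r}"
                )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MappedSignature:
    """A signature restricted to the entities of a causal network.

    ``q_plus``, ``q_minus`` and ``q_zero`` count the mapped genes observed
    up, down and unchanged; they always sum to ``len(mapped)``.  Genes
    observed as 0 are retained: they contribute no score but occupy cells
    of the significance null's contingency table.
    """

    mapped: Mapping[str, int]
    unmapped_count: int
    name: str = ""
    q_plus: int = field(init=False)
    q_minus: int = field(init=False)
    q_zero: int = field(init=False)

    def __post_init__(self) -> None:
        vals = list(self.mapped.values())
        object.__setattr__(self, "q_plus", vals.count(+1))
        object.__setattr__(self, "q_minus", vals.count(-1))
        object.__setattr__(self, "q_zero", vals.count(0))

    def __len__(self) -> int:
        return len(self.mapped)


def _parse_value(token: str) -> int:
    return int(token.translate(_DASH_TRANSLATION))


def read_signature(path: PathLike) -> Signature:
    """Read a two-column gene/regulation table.

    Columns are separated by any run of whitespace.  Values must be -1, 0
    or 1 (a Unicode minus sign is accepted).  If the first line's second
    field is non-numeric it is treated as a header and skipped.  A gene
    repeated with the same value collapses with a warning; repeated with
    conflicting values it is an error.
    """
    path = Path(path)
    values: dict[str, int] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    start = 0
    if lines:
        first_fields = lines[0].strip().split()
        if len(first_fields) >= 2:
            try:
                _parse_value(first_fields[1])
            except ValueError:
                logger.info("%s: first line treated as header: %r", path, lines[0])
                start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise SignatureParseError(
                f"{path}: line {lineno}: expected 2 fields, found {len(fields)}"
            )
        gene, token = fields
        try:
            value = _parse_value(token)
        except ValueError:
            raise SignatureParseError(
                f"{path}: line {lineno}: regulation value {token!r} is not an integer"
            ) from None
        if value not in _ALLOWED_VALUES:
            raise SignatureParseError(
                f"{path}: line {lineno}: regulation value {value} outside {{-1, 0, 1}}"
            )
        if gene in values:
            if values[gene] != value:
                raise SignatureParseError(
                    f"{path}: line {lineno}: gene {gene!r} repeated with "
                    f"conflicting values {values[gene]} and {value}"
                )
            logger.warning(
                "%s: line %d: duplicate entry for %r collapsed", path, lineno, gene
            )
            continue
        values[gene] = value
    return Signature(values=values, name=path.name)


def write_signature(sig: Signature, path: PathLike) -> None:
    """Write a signature in the same two-column dialect :func:`read_signature` reads."""
    Path(path).write_text(
        "".join(f"{gene}\t{value}\n" for gene, value in sig.values.items()),
        encoding="utf-8",
    )


def map_signature(sig: Signature, ccg: CCG) -> MappedSignature:
    """Restrict ``sig`` to the entities of ``ccg`` and report coverage.

    When any gene is lost a warning is logged in the form
    ``"N of M signature genes (P%) not present in causal network"``.
    An entirely unmapped signature is legal; downstream scoring of it
    simply yields empty evidence.
    """
    mapped = {g: v for g, v in sig.values.items() if g in ccg.entities}
    unmapped = len(sig.values) - len(mapped)
    if unmapped > 0:
        pct = 100.0 * unmapped / len(sig.values)
        logger.warning(
            "%d of %d signature genes (%.1f%%) not present in causal network",
            unmapped,
            len(sig.values),
            pct,
        )
    return MappedSignature(mapped=mapped, unmapped_count=unmapped, name=sig.name)
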