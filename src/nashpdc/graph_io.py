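"""Readers and writers for PPI networks and protein-complex membership files.

Networks are plain-text edge lists (two-column TSV, or SIF where the middle
token names the interaction type and is ignored).  Complex files hold one
complex per line with whitespace-separated member identifiers -- the format
emitted by most complex-detection tools and used by yeast gold standards.

Node identifiers are opaque, case-sensitive strings; no integer mapping is
ever exposed, because protein identifiers differ in convention across
DIP/MIPS/Gavin-style exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import TYPE_CHECKING, Iterable, Union

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .game import CoverSet

logger = logging.getLogger("nashpdc")

PathType = Union[str, PathLike]


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


@dataclass
class ComplexSet:
    """An ordered collection of protein complexes (node-id sets).

    Reference complex sets may overlap; predicted cover sets exported by the
    game engine are disjoint.  Empty member sets are rejected.
    """

    complexes: list[set]
    name: str = ""

    def __post_init__(self) -> None:
        self.complexes = [set(c) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("a complex must have at least one member")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)


def _data_lines(path: PathType) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: PathType, dialect: str = "tsv") -> nx.Graph:
    """Read an undirected, unweighted PPI network from an edge-list file.

    Parameters
    ----------
    path
        Text file with one interaction per line.
    dialect
        ``"tsv"``: columns 1-2 are the endpoints.  ``"sif"``: columns 1 and 3
        are the endpoints, column 2 (interaction type) is ignored.

    Self-loops are dropped (with a logged count) and duplicate edges are
    collapsed, so the result is always a simple graph.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")
    need = 2 if dialect == "tsv" else 3
    g = nx.Graph()
    n_lines = 0
    n_loops = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < need:
            raise ParseError(
                f"{path}: line {lineno}: expected at least {need} columns "
                f"for dialect {dialect!r}, got {len(tokens)}"
            )
        u = tokens[0]
        v = tokens[1] if dialect == "tsv" else tokens[2]
        n_lines += 1
        if u == v:
            n_loops += 1
            g.add_node(u)
            continue
        g.add_edge(u, v)
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found (file empty or comments only)")
    if n_loops:
        logger.info("dropped %d self-loop(s) while reading %s", n_loops, path)
    return g


def read_complexes(path: PathType, name: str = "") -> ComplexSet:
    """Read a one-complex-per-line membership file.

    Members are whitespace/tab separated; duplicates within a line collapse;
    blank lines and '#' comments are skipped.  An empty file is an error.
    """
    complexes = [set(line.split()) for _, line in _data_lines(path)]
    if not complexes:
        raise ParseError(f"{path}: no complexes found (file empty or comments only)")
    return ComplexSet(complexes, name=name or str(path))


def write_cover_set(
    cover: "CoverSet", path: PathType, include_singletons: bool = False
) -> None:
    """Write a detected cover set, one coalition per line, members tab-separated.

    Coalitions appear in detection order with members sorted lexicographically
    so output is deterministic and diffable.  Residual singletons are appended
    one per line only when ``include_singletons`` is set.
    """
    with open(path, "w") as fh:
        for coalition in cover.coalitions:
            fh.write("\t".join(sorted(coalition.members, key=str)) + "\n")
        if include_singletons:
            for v in sorted(cover.residual, key=str):
                fh.write(f"{v}\n")
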