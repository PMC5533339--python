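"""Readers and writers for PPI networks and the annotation tables around them.

All formats are plain UTF-8 text with ``#`` comment lines:

* network — two-column (whitespace- or tab-separated) edge list;
* essential proteins — one ID per line;
* complexes — ``complexID<TAB>member1,member2,...``;
* orthology — ``proteinID<TAB>organismID`` rows;
* localization — ``proteinID<TAB>location`` rows.

Networks are normalized to undirected simple :class:`networkx.Graph` objects:
self-loops are dropped (with a logged count) and duplicate or reversed
duplicate edges collapse to a single undirected edge. Protein ID matching is
case-sensitive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ComplexCatalog",
    "OrthologyTable",
    "LocalizationTable",
    "read_network",
    "write_network",
    "read_essential_list",
    "write_essential_list",
    "read_complexes",
    "write_complexes",
    "read_orthology",
    "write_orthology",
    "read_localization",
    "write_localization",
    "essential_count",
    "read_scores",
    "write_scores",
]


class ParseError(ValueError):
    """Malformed line in an input file; message carries the 1-based line number."""


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


@dataclass
class ComplexCatalog:
    """Catalog of protein complexes: (complex ID, member set) pairs.

    A protein may belong to any number of complexes; membership multiplicity
    is preserved across complexes.
    """

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def complex_set(self, protein: str) -> list[str]:
        """IDs of the complexes containing *protein*."""
        return [cid for cid, members in self.complexes if protein in members]


@dataclass
class OrthologyTable:
    """Presence of proteins across a panel of reference organisms."""

    organisms: list[str] = field(default_factory=list)
    presence: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_organisms(self) -> int:
        return len(self.organisms)

    def score(self, protein: str) -> int:
        """Number of reference organisms in which *protein* appears."""
        return sum(1 for org in self.organisms if protein in self.presence.get(org, ()))


@dataclass
class LocalizationTable:
    """Subcellular locations and their protein membership sets."""

    locations: list[str] = field(default_factory=list)
    membership: dict[str, set[str]] = field(default_factory=dict)

    @property
    def total_proteins(self) -> int:
        """Number of distinct proteins recorded anywhere in the table (``a``)."""
        seen: set[str] = set()
        for members in self.membership.values():
            seen |= members
        return len(seen)

    def location_size(self, location: str) -> int:
        """``a_l`` — proteins recorded in *location*."""
        return len(self.membership.get(location, ()))

    def locations_of(self, protein: str) -> list[str]:
        return [l for l in self.locations if protein in self.membership.get(l, ())]


def read_network(path: str | Path) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Each non-comment line must have at least two whitespace-separated tokens;
    the first two are the edge endpoints (any further tokens, e.g. confidence
    columns, are ignored). Self-loops and duplicate/reversed edges are
    normalized away and the counts logged. An empty file yields an empty graph.
    """
    graph = nx.Graph()
    self_loops = 0
    duplicates = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected two protein IDs, got {line!r}")
        u, v = tokens[0], tokens[1]
        if u == v:
            self_loops += 1
            graph.add_node(u)
            continue
        if graph.has_edge(u, v):
            duplicates += 1
            continue
        graph.add_edge(u, v)
    if self_loops or duplicates:
        logger.info(
            "read_network(%s): dropped %d self-loop line(s) and %d duplicate edge line(s)",
            path, self_loops, duplicates,
        )
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a canonical edge list: endpoints sorted within each edge, edges sorted."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    isolated = sorted(v for v in graph.nodes() if graph.degree(v) == 0)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
        # an isolated node has no edge to carry it; a self-referential line
        # round-trips to the bare node because read_network drops the loop
        for v in isolated:
            fh.write(f"{v}\t{v}\n")


def read_essential_list(path: str | Path) -> set[str]:
    """Read one protein ID per line; duplicates collapse."""
    ids: set[str] = set()
    for _, line in _data_lines(path):
        ids.add(line.split()[0])
    return ids


def write_essential_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(set(ids)):
            fh.write(pid + "\n")


def essential_count(essential: set[str], graph: nx.Graph) -> int:
    """``P`` — number of essential proteins present in the network."""
    return sum(1 for v in graph.nodes() if v in essential)


def read_complexes(path: str | Path) -> ComplexCatalog:
    """Read ``complexID<TAB>member1,member2,...`` lines."""
    complexes: list[tuple[str, frozenset[str]]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise ParseError(f"{path}:{lineno}: complex line needs an ID and members")
        members = frozenset(m for m in parts[1].split(",") if m)
        if not members:
            raise ParseError(f"{path}:{lineno}: complex {parts[0]!r} has no members")
        complexes.append((parts[0], members))
    return ComplexCatalog(complexes)


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, members in catalog.complexes:
            fh.write(f"{cid}\t{','.join(sorted(members))}\n")


def _read_two_column(path: str | Path) -> list[tuple[str, str]]:
    rows = []
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
        rows.append((tokens[0], tokens[1]))
    return rows


def read_orthology(path: str | Path) -> OrthologyTable:
    """Read ``proteinID<TAB>organismID`` rows into an orthology-presence table."""
    presence: dict[str, set[str]] = {}
    for protein, organism in _read_two_column(path):
        presence.setdefault(organism, set()).add(protein)
    return OrthologyTable(organisms=sorted(presence), presence=presence)


def write_orthology(table: OrthologyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for org in table.organisms:
            for protein in sorted(table.presence.get(org, ())):
                fh.write(f"{protein}\t{org}\n")


def read_localization(path: str | Path) -> LocalizationTable:
    """Read ``proteinID<TAB>location`` rows into a localization table."""
    membership: dict[str, set[str]] = {}
    for protein, location in _read_two_column(path):
        membership.setdefault(location, set()).add(protein)
    return LocalizationTable(locations=sorted(membership), membership=membership)


def write_localization(table: LocalizationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for loc in table.locations:
            for protein in sorted(table.membership.get(loc, ())):
                fh.write(f"{protein}\t{loc}\n")


def read_scores(path: str | Path) -> dict[str, float]:
    return {p: float(s) for p, s in _read_two_column(path)}


def write_scores(scores: dict[str, float], path: str | Path, name: str = "score") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# protein\t{name}\n")
        for protein in sorted(scores):
            fh.write(f"{protein}\t{scores[protein]:.10g}\n")
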