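"""Domain types and readers/writers for ortholog-clustering output.

The central objects are ortholog groups — clusters of genes across species
descended from a single ancestral gene, as emitted by MCL-style clustering of
reciprocal-best-BLAST-hit (RBBH) pairs — plus the species table that assigns
each genome a clade and quality flag, and the RBBH gene–gene graph used to
screen weakly connected contaminating members.

File dialects:

* groups file: one group per line, ``GROUPID: sp|gene sp|gene ...``
  (whitespace-separated members, ``#`` comments allowed);
* species table: 5-column TSV ``code name clade is_metazoan well_sequenced``;
* RBBH edges: 2-column TSV of serialized gene ids.

Writers emit canonical forms (groups sorted by id, members sorted
lexicographically; edges sorted) so that parse ∘ write is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneID",
    "SpeciesRecord",
    "OrthologGroup",
    "GroupCollection",
    "RBBHGraph",
    "parse_species_table",
    "write_species_table",
    "parse_groups",
    "write_groups",
    "parse_rbbh",
    "write_rbbh",
]

COMMENT_CHAR = "#"

_TRUE_LITERALS = {"true", "1", "yes", "t"}
_FALSE_LITERALS = {"false", "0", "no", "f"}


class ParseError(ValueError):
    """Malformed input file."""


def _parse_bool(token: str, *, context: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_LITERALS:
        return True
    if low in _FALSE_LITERALS:
        return False
    raise ParseError(f"unknown boolean literal {token!r} ({context})")


@dataclass(frozen=True, order=True)
class GeneID:
    """A gene, addressed as ``species_code|local_id``.

    The species code may not contain whitespace or ``|``; the local id is an
    opaque token (compared case-sensitively) that may itself contain ``|`` —
    parsing splits on the first separator only, so serialization round-trips.
    """

    species_code: str
    local_id: str

    def __post_init__(self) -> None:
        for name, tok in (("species_code", self.species_code), ("local_id", self.local_id)):
            if not tok:
                raise ValueError(f"GeneID.{name} must be non-empty")
            if any(c.isspace() for c in tok):
                raise ValueError(f"GeneID.{name} may not contain whitespace: {tok!r}")
        if "|" in self.species_code:
            raise ValueError(f"species_code may not contain '|': {self.species_code!r}")

    @classmethod
    def parse(cls, text: str) -> "GeneID":
        code, sep, local = text.partition("|")
        if not sep:
            raise ParseError(f"gene identifier lacks '|' separator: {text!r}")
        return cls(code, local)

    def __str__(self) -> str:
        return f"{self.species_code}|{self.local_id}"


@dataclass(frozen=True)
class SpeciesRecord:
    """One genome in the analysis: code, display name, clade and flags."""

    code: str
    name: str
    clade: str
    is_metazoan: bool
    well_sequenced: bool

    def __post_init__(self) -> None:
        if not self.code or "|" in self.code or any(c.isspace() for c in self.code):
            raise ValueError(f"species code must be a non-empty token without whitespace or '|': {self.code!r}")
        if not self.clade:
            raise ValueError(f"species {self.code!r} has an empty clade")


@dataclass(frozen=True)
class OrthologGroup:
    """One ortholog cluster: an id plus its member genes.

    A species may contribute several members (paralogs arising from lineage-
    specific duplication); species-level presence is therefore derived, not
    stored.
    """

    group_id: str
    members: frozenset[GeneID]

    def __post_init__(self) -> None:
        if not self.group_id:
            raise ValueError("group_id must be non-empty")
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(m.species_code for m in self.members)

    def members_of(self, species_code: str) -> frozenset[GeneID]:
        return frozenset(m for m in self.members if m.species_code == species_code)

    def __len__(self) -> int:
        return len(self.members)


class GroupCollection:
    """Ordered set of ortholog groups with a species → group-id index."""

    def __init__(self, groups: Iterable[OrthologGroup]):
        self._groups: tuple[OrthologGroup, ...] = tuple(groups)
        self._by_id: dict[str, OrthologGroup] = {}
        index: dict[str, set[str]] = {}
        for g in self._groups:
            if g.group_id in self._by_id:
                raise ValueError(f"duplicate group id {g.group_id!r}")
            self._by_id[g.group_id] = g
            for sp in g.species_present:
                index.setdefault(sp, set()).add(g.group_id)
        self._species_index = index

    @property
    def groups(self) -> tuple[OrthologGroup, ...]:
        return self._groups

    @property
    def species_index(self) -> Mapping[str, set[str]]:
        return self._species_index

    def groups_with_species(self, species_code: str) -> frozenset[str]:
        return frozenset(self._species_index.get(species_code, set()))

    def __getitem__(self, group_id: str) -> OrthologGroup:
        return self._by_id[group_id]

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._by_id

    def __iter__(self) -> Iterator[OrthologGroup]:
        return iter(self._groups)

    def __len__(self) -> int:
        return len(self._groups)


class RBBHGraph:
    """Undirected gene–gene reciprocal-best-hit graph.

    Self-edges are rejected; repeated and reversed edges collapse. The one
    query the classifier needs is the degree of a gene restricted to a subset
    of endpoints (how many links a suspect foreign member has to the metazoan
    members of its group).
    """

    def __init__(self, edges: Iterable[tuple[GeneID, GeneID]] = ()):
        self._g: nx.Graph = nx.Graph()
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: GeneID, b: GeneID) -> None:
        if a == b:
            raise ValueError(f"self-edge rejected: {a}")
        self._g.add_edge(a, b)

    @property
    def edges(self) -> frozenset[frozenset[GeneID]]:
        return frozenset(frozenset(e) for e in self._g.edges())

    def neighbors(self, gene: GeneID) -> frozenset[GeneID]:
        if gene not in self._g:
            return frozenset()
        return frozenset(self._g[gene])

    def degree_to_subset(self, gene: GeneID, subset: Iterable[GeneID]) -> int:
        """Number of edges from *gene* whose other endpoint lies in *subset*."""
        if gene not in self._g:
            return 0
        target = set(subset)
        return sum(1 for nb in self._g[gene] if nb in target)

    def __len__(self) -> int:
        return self._g.number_of_edges()


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(stream: TextIO) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(COMMENT_CHAR):
            continue
        yield lineno, line


_SPECIES_COLUMNS = ("code", "name", "clade", "is_metazoan", "well_sequenced")


def parse_species_table(stream: TextIO) -> list[SpeciesRecord]:
    """Parse the 5-column species TSV (header required, order preserved)."""
    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    header_done = False
    for lineno, line in _data_lines(stream):
        fields = line.split("\t")
        if not header_done:
            got = tuple(f.strip() for f in fields)
            if got != _SPECIES_COLUMNS:
                raise ParseError(
                    f"species table header must be {_SPECIES_COLUMNS}, got {got} (line {lineno})"
                )
            header_done = True
            continue
        if len(fields) != 5:
            raise ParseError(f"species table line {lineno} has {len(fields)} columns, expected 5")
        code, name, clade = (f.strip() for f in fields[:3])
        if code in seen:
            raise ParseError(f"duplicate species code {code!r} (line {lineno})")
        seen.add(code)
        records.append(
            SpeciesRecord(
                code=code,
                name=name,
                clade=clade,
                is_metazoan=_parse_bool(fields[3], context=f"species {code}, line {lineno}"),
                well_sequenced=_parse_bool(fields[4], context=f"species {code}, line {lineno}"),
            )
        )
    if not header_done:
        raise ParseError("species table is empty (missing header)")
    return records


def write_species_table(records: Sequence[SpeciesRecord], stream: TextIO) -> None:
    stream.write("\t".join(_SPECIES_COLUMNS) + "\n")
    for r in records:
        stream.write(
            f"{r.code}\t{r.name}\t{r.clade}\t{str(r.is_metazoan).lower()}\t{str(r.well_sequenced).lower()}\n"
        )


def parse_groups(stream: TextIO) -> GroupCollection:
    """Parse the OrthoMCL-style groups file ``GROUPID: sp|gene sp|gene ...``.

    Duplicate members within a line are deduplicated with a logged warning;
    a member without ``|`` or a duplicate group id is a hard error.
    """
    groups: list[OrthologGroup] = []
    for lineno, line in _data_lines(stream):
        gid, sep, rest = line.partition(":")
        if not sep:
            raise ParseError(f"groups line {lineno} lacks ':' after the group id")
        gid = gid.strip()
        if not gid:
            raise ParseError(f"groups line {lineno} has an empty group id")
        tokens = rest.split()
        if not tokens:
            raise ParseError(f"group {gid!r} (line {lineno}) has no members")
        members: list[GeneID] = []
        seen: set[GeneID] = set()
        for tok in tokens:
            try:
                gene = GeneID.parse(tok)
            except ParseError as exc:
                raise ParseError(f"group {gid!r} (line {lineno}): {exc}") from None
            if gene in seen:
                logger.warning("group %s: duplicate member %s deduplicated", gid, gene)
                continue
            seen.add(gene)
            members.append(gene)
        groups.append(OrthologGroup(group_id=gid, members=frozenset(members)))
    return GroupCollection(groups)


def write_groups(collection: GroupCollection, stream: TextIO) -> None:
    for g in sorted(collection, key=lambda g: g.group_id):
        members = " ".join(sorted(str(m) for m in g.members))
        stream.write(f"{g.group_id}: {members}\n")


def parse_rbbh(stream: TextIO) -> RBBHGraph:
    """Parse the 2-column RBBH edge TSV into an undirected graph."""
    graph = RBBHGraph()
    for lineno, line in _data_lines(stream):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"RBBH line {lineno} has {len(fields)} columns, expected 2")
        try:
            a = GeneID.parse(fields[0].strip())
            b = GeneID.parse(fields[1].strip())
        except ParseError as exc:
            raise ParseError(f"RBBH line {lineno}: {exc}") from None
        if a == b:
            raise ParseError(f"RBBH line {lineno}: self-edge {a}")
        graph.add_edge(a, b)
    return graph


def write_rbbh(graph: RBBHGraph, stream: TextIO) -> None:
    lines = sorted(tuple(sorted((str(a), str(b)))) for a, b in (tuple(e) for e in graph.edges))
    for a, b in lines:
        stream.write(f"{a}\t{b}\n")
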