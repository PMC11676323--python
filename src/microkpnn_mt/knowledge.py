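"""Prior-knowledge parsing and construction of the MaskedLinear connectivity.

Three knowledge sources wire species (input nodes) to named hidden nodes:

* a metabolic producer/consumer edge list (NJS16-style): each metabolite
  contributes a *production* node connected to its producer species and a
  *consumption* node connected to its consumer species;
* a species -> genus map derived from the NCBI taxonomy: one hidden node per
  genus, connected to its member species;
* a species -> community membership map (e.g. Leiden communities of a
  co-occurrence network): one hidden node per community.

Species not covered by a source are collected in a per-source catch-all
("unknown") node so that every input species keeps at least one connection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Role",
    "MetabolicEdge",
    "HiddenNode",
    "HiddenSchema",
    "MaskMatrix",
    "parse_metabolic_edges",
    "parse_taxonomy_map",
    "parse_communities",
    "build_hidden_schema",
    "build_mask",
]


class Role(str, Enum):
    PRODUCER = "producer"
    CONSUMER = "consumer"


@dataclass(frozen=True)
class MetabolicEdge:
    """One species--metabolite relation with a production/consumption role."""

    species_id: str
    metabolite_id: str
    role: Role


class KnowledgeParseError(ValueError):
    """Raised for malformed knowledge files; message names the offending line."""


NODE_GROUPS = (
    "metabolite_production",
    "metabolite_consumption",
    "genus",
    "community",
    "unknown_metabolite",
    "unknown_genus",
    "unknown_community",
)


@dataclass(frozen=True)
class HiddenNode:
    name: str
    group: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.group not in NODE_GROUPS:
            raise ValueError(f"unknown hidden-node group {self.group!r}")


@dataclass(frozen=True)
class HiddenSchema:
    """Ordered, named hidden nodes of the MaskedLinear layer."""

    nodes: tuple[HiddenNode, ...]
    species: tuple[str, ...]

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def groups(self) -> list[str]:
        return [n.group for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class MaskMatrix:
    """Immutable binary species x hidden-node connectivity matrix."""

    values: np.ndarray  # (n_species, n_hidden), dtype float64, entries in {0, 1}
    species: tuple[str, ...]
    node_names: tuple[str, ...]
    node_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# -- file parsing -------------------------------------------------------------

_HEADER_FIRST_CELLS = {"species", "species_id", "#species", "#species_id"}


def _read_rows(path: str | Path, n_cols: int) -> list[tuple[int, list[str]]]:
    """Read a delimited text file into (line_number, fields) pairs.

    Tabs are the primary delimiter; commas are accepted as a fallback for
    single-field rows.  A header row is skipped when its first cell is a
    recognised column name.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1 and "," in line:
                fields = next(csv.reader([line]))
            fields = [f.strip() for f in fields]
            if lineno == 1 and fields[0].lower() in _HEADER_FIRST_CELLS:
                continue
            if len(fields) != n_cols:
                raise KnowledgeParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            if any(f == "" for f in fields):
                raise KnowledgeParseError(f"{path}: line {lineno}: empty field")
            rows.append((lineno, fields))
    return rows


def parse_metabolic_edges(path: str | Path) -> set[MetabolicEdge]:
    """Parse a 3-column (species, metabolite, role) edge list.

    Duplicate triples collapse to one edge; a role outside
    {producer, consumer} is rejected with the line number.
    """
    edges: set[MetabolicEdge] = set()
    for lineno, (sp, met, role) in _read_rows(path, 3):
        try:
            role_enum = Role(role.lower())
        except ValueError:
            raise KnowledgeParseError(
                f"{path}: line {lineno}: unknown role {role!r} "
                f"(expected 'producer' or 'consumer')"
            ) from None
        edges.add(MetabolicEdge(sp, met, role_enum))
    return edges


def parse_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Parse a 2-column species -> genus map; conflicting rows are an error."""
    mapping: dict[str, str] = {}
    for lineno, (sp, genus) in _read_rows(path, 2):
        if sp in mapping and mapping[sp] != genus:
            raise KnowledgeParseError(
                f"{path}: line {lineno}: species {sp!r} mapped to both "
                f"{mapping[sp]!r} and {genus!r}"
            )
        mapping[sp] = genus
    return mapping


def parse_communities(path: str | Path) -> dict[str, set[str]]:
    """Parse a 2-column species -> community table; memberships may overlap."""
    mapping: dict[str, set[str]] = {}
    for _, (sp, comm) in _read_rows(path, 2):
        mapping.setdefault(sp, set()).add(comm)
    return mapping


# -- schema + mask construction -----------------------------------------------


def build_hidden_schema(
    species: Sequence[str],
    edges: Iterable[MetabolicEdge],
    taxmap: Mapping[str, str],
    commmap: Mapping[str, set[str]],
) -> HiddenSchema:
    """Construct the named hidden-layer schema from the three knowledge sources.

    Node order is deterministic: metabolite nodes sorted by metabolite id with
    production before consumption, then genera (sorted), then communities
    (sorted), then the nonempty catch-all nodes.  Memberships are restricted
    to the input species; nodes that end up with no member are omitted.
    """
    species = list(species)
    if not species:
        raise ValueError("species list must be non-empty")
    if len(set(species)) != len(species):
        raise ValueError("species list contains duplicates")
    in_species = set(species)

    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for e in edges:
        if e.species_id not in in_species:
            continue
        target = producers if e.role is Role.PRODUCER else consumers
        target.setdefault(e.metabolite_id, set()).add(e.species_id)

    nodes: list[HiddenNode] = []
    for met in sorted(set(producers) | set(consumers)):
        if producers.get(met):
            nodes.append(
                HiddenNode(f"{met}_production", "metabolite_production", frozenset(producers[met]))
            )
        if consumers.get(met):
            nodes.append(
                HiddenNode(f"{met}_consumption", "metabolite_consumption", frozenset(consumers[met]))
            )

    genus_members: dict[str, set[str]] = {}
    for sp in species:
        if sp in taxmap:
            genus_members.setdefault(taxmap[sp], set()).add(sp)
    for genus in sorted(genus_members):
        nodes.append(HiddenNode(f"genus_{genus}", "genus", frozenset(genus_members[genus])))

    comm_members: dict[str, set[str]] = {}
    for sp in species:
        for comm in commmap.get(sp, ()):
            comm_members.setdefault(comm, set()).add(sp)
    for comm in sorted(comm_members):
        nodes.append(HiddenNode(f"community_{comm}", "community", frozenset(comm_members[comm])))

    in_metabolic = set().union(*producers.values(), *consumers.values()) if (producers or consumers) else set()
    unknowns = [
        ("unknown_metabolite", in_metabolic),
        ("unknown_genus", set(taxmap) & in_species),
        ("unknown_community", set(commmap) & in_species),
    ]
    for name, covered in unknowns:
        members = frozenset(sp for sp in species if sp not in covered)
        if members:
            nodes.append(HiddenNode(name, name, members))

    names = [n.name for n in nodes]
    if len(set(names)) != len(names):
        raise ValueError("hidden-node names collide; check knowledge-file identifiers")
    return HiddenSchema(nodes=tuple(nodes), species=tuple(species))


def build_mask(schema: HiddenSchema, species: Sequence[str]) -> MaskMatrix:
    """Build the binary species x hidden-node mask from a schema.

    Row order follows ``species`` (which must match the list the schema was
    built from); column order follows the schema.  The returned matrix is
    read-only.
    """
    if tuple(species) != schema.species:
        raise ValueError("species list does not match the list the schema was built from")
    mask = np.zeros((len(species), len(schema)), dtype=np.float64)
    index = {sp: i for i, sp in enumerate(species)}
    for j, node in enumerate(schema.nodes):
        for sp in node.members:
            mask[index[sp], j] = 1.0
    if not (mask.sum(axis=1) >= 1).all():
        raise AssertionError("every species must connect to at least one hidden node")
    if not (mask.sum(axis=0) >= 1).all():
        raise AssertionError("every hidden node must have at least one member")
    return MaskMatrix(
        values=mask,
        species=tuple(species),
        node_names=tuple(schema.names),
        node_groups=tuple(schema.groups),
    )
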