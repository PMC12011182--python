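"""Pathway collections, the merged interactome, and genecentric pathway extraction.

A pathway collection is a set of named directed edge lists with typed
interactions.  Merging the collection on shared gene products yields a single
interactome graph; a genecentric pathway is then the first-order interaction
neighborhood of one central gene product in that graph, with the typed edges
linking each member to the central node retained for downstream role
annotation.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionType",
    "NodeClass",
    "Edge",
    "PathwayCollection",
    "InteractomeGraph",
    "GenecentricPathway",
    "LoadReport",
    "load_pathway_collection",
    "merge_to_interactome",
    "extract_genecentric",
    "pathway_overlap",
]


class InteractionType(str, enum.Enum):
    """The nine pairwise molecular interaction types of the interactome model."""

    ACTIVATION = "activation"
    COUPLING = "coupling"
    INHIBITION = "inhibition"
    PHOSPHORYLATION = "phosphorylation"
    DISSOCIATION = "dissociation"
    REPRESSION = "repression"
    DEPHOSPHORYLATION = "dephosphorylation"
    BINDING_ASSOCIATION = "binding/association"
    UBIQUITINATION = "ubiquitination"

    @classmethod
    def parse(cls, label: str) -> "InteractionType":
        """Parse a label case-insensitively; ``binding_association`` is accepted
        as an alias for ``binding/association``."""
        key = label.strip().lower().replace("binding_association", "binding/association")
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown interaction type: {label!r}") from None


class NodeClass(str, enum.Enum):
    GENE = "gene"
    METABOLITE = "metabolite"


@dataclass(frozen=True)
class Edge:
    """A directed typed interaction between two molecular players."""

    source: str
    target: str
    type: InteractionType


@dataclass
class PathwayCollection:
    """Named directed edge lists; the raw material of the interactome.

    Self-loops are dropped and duplicate (source, target, type) triples within
    one pathway are deduplicated at construction.
    """

    pathways: dict[str, list[Edge]]
    node_classes: dict[str, NodeClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, edges in self.pathways.items():
            seen: set[Edge] = set()
            clean: list[Edge] = []
            for e in edges:
                if e.source == e.target:
                    continue
                if e not in seen:
                    seen.add(e)
                    clean.append(e)
            self.pathways[pid] = clean

    def node_class(self, node: str) -> NodeClass:
        return self.node_classes.get(node, NodeClass.GENE)

    @property
    def nodes(self) -> set[str]:
        return {n for edges in self.pathways.values() for e in edges for n in (e.source, e.target)}

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class ConnectivityReport:
    n_components: int
    largest_component_size: int
    component_sizes: list[int]

    @property
    def is_connected(self) -> bool:
        return self.n_components <= 1


@dataclass
class InteractomeGraph:
    """Merged directed multigraph over all pathways of a collection.

    Parallel edges of different types between the same ordered pair are kept;
    the node and edge sets are exact unions over the collection.
    """

    graph: nx.MultiDiGraph
    connectivity: ConnectivityReport

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {Edge(u, v, t) for u, v, t in self.graph.edges(keys=True)}

    def node_class(self, node: str) -> NodeClass:
        return self.graph.nodes[node].get("node_class", NodeClass.GENE)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass
class GenecentricPathway:
    """A central gene product plus all members with first-order interactions
    with it, and the typed edges connecting them to the central node."""

    central: str
    members: set[str]
    edges: list[Edge]
    node_classes: dict[str, NodeClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.central not in self.members:
            raise ValueError("central node must be a member of its own pathway")

    def node_class(self, node: str) -> NodeClass:
        return self.node_classes.get(node, NodeClass.GENE)

    def gene_members(self) -> set[str]:
        return {m for m in self.members if self.node_class(m) is NodeClass.GENE}

    def edges_touching(self, member: str) -> list[Edge]:
        return [e for e in self.edges if member in (e.source, e.target)]

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self, arr: Mapping[str, float] | None = None) -> pd.DataFrame:
        """Tabular export: one row per member with edge counts and types."""
        rows = []
        for m in sorted(self.members):
            touching = self.edges_touching(m) if m != self.central else []
            rows.append(
                {
                    "member": m,
                    "arr": arr.get(m) if arr is not None else None,
                    "n_edges_to_central": len(touching),
                    "edge_types": ";".join(sorted(e.type.value for e in touching)),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class LoadReport:
    n_rows: int
    n_accepted: int
    rejected_rows: list[tuple[int, str]]  # (row index, reason)


class FormatError(ValueError):
    pass


class EmptyCollectionError(ValueError):
    pass


def load_pathway_collection(
    path: str | Path,
    dialect: str = "single-file-with-id-column",
    node_class_path: str | Path | None = None,
    pathway_id: str | None = None,
) -> tuple[PathwayCollection, LoadReport]:
    """Load a pathway collection from a TSV edge list.

    Two dialects are supported: ``single-file-with-id-column`` expects columns
    ``pathway_id, source, target, interaction_type``; ``per-pathway-files``
    expects ``source, target, interaction_type`` and a ``pathway_id`` argument
    (default: the file stem).  Rows whose interaction type is outside the nine
    recognised labels are rejected individually and listed in the load report;
    the load itself succeeds on the remaining rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise EmptyCollectionError(f"{path}: no data rows")
    required = {"source", "target", "interaction_type"}
    if dialect == "single-file-with-id-column":
        required = required | {"pathway_id"}
    elif dialect != "per-pathway-files":
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    pathways: dict[str, list[Edge]] = {}
    rejected: list[tuple[int, str]] = []
    default_pid = pathway_id if pathway_id is not None else path.stem
    for i, row in df.iterrows():
        try:
            itype = InteractionType.parse(row["interaction_type"])
        except ValueError as exc:
            rejected.append((int(i), str(exc)))
            continue
        pid = row["pathway_id"] if "pathway_id" in df.columns else default_pid
        pathways.setdefault(pid, []).append(Edge(row["source"], row["target"], itype))

    node_classes: dict[str, NodeClass] = {}
    if node_class_path is not None:
        sidecar = pd.read_csv(node_class_path, sep="\t", dtype=str, header=None, names=["node_id", "class"])
        node_classes = {r["node_id"]: NodeClass(r["class"]) for _, r in sidecar.iterrows()}

    report = LoadReport(n_rows=len(df), n_accepted=len(df) - len(rejected), rejected_rows=rejected)
    return PathwayCollection(pathways, node_classes), report


def merge_to_interactome(collection: PathwayCollection) -> InteractomeGraph:
    """Merge all pathway graphs into one interactome on shared gene products.

    Node and edge sets are exact unions.  Weak connectivity is reported, not
    enforced: disconnected collections yield a multi-component report and
    downstream extraction proceeds on the full graph.
    """
    if len(collection) == 0:
        raise EmptyCollectionError("cannot merge an empty collection")
    g = nx.MultiDiGraph()
    for edges in collection.pathways.values():
        for e in edges:
            g.add_node(e.source, node_class=collection.node_class(e.source))
            g.add_node(e.target, node_class=collection.node_class(e.target))
            if not g.has_edge(e.source, e.target, key=e.type):
                g.add_edge(e.source, e.target, key=e.type)
    comps = sorted((len(c) for c in nx.weakly_connected_components(g)), reverse=True)
    report = ConnectivityReport(
        n_components=len(comps),
        largest_component_size=comps[0] if comps else 0,
        component_sizes=comps,
    )
    return InteractomeGraph(graph=g, connectivity=report)


def extract_genecentric(
    interactome: InteractomeGraph,
    central: str,
    allowed_types: Iterable[InteractionType] | None = None,
    depth: int = 1,
) -> GenecentricPathway:
    """Extract the genecentric pathway of ``central``: the central node plus
    every node with a first-order interaction to or from it (both directions),
    restricted to ``allowed_types`` (default: all nine).

    ``depth`` > 1 extends membership by breadth-first search over allowed
    edges; the induced edge list always contains the edges between members.
    """
    if central not in interactome:
        raise KeyError(f"central node {central!r} not present in the interactome")
    allowed = set(allowed_types) if allowed_types is not None else set(InteractionType)
    g = interactome.graph

    members = {central}
    frontier = {central}
    for _ in range(depth):
        nxt: set[str] = set()
        for node in frontier:
            for _, v, t in g.out_edges(node, keys=True):
                if t in allowed:
                    nxt.add(v)
            for u, _, t in g.in_edges(node, keys=True):
                if t in allowed:
                    nxt.add(u)
        frontier = nxt - members
        members |= nxt
        if not frontier:
            break

    edges = [
        Edge(u, v, t)
        for u, v, t in g.edges(keys=True)
        if t in allowed and u in members and v in members and central in (u, v)
    ]
    classes = {m: interactome.node_class(m) for m in members}
    return GenecentricPathway(central=central, members=members, edges=edges, node_classes=classes)


def pathway_overlap(
    p1: GenecentricPathway, p2: GenecentricPathway
) -> tuple[int, float, float]:
    """Shared member count and the percentage of each pathway it represents.

    Percentages are reported to one decimal, as conventional for pathway
    composition comparisons.
    """
    if not p1.members or not p2.members:
        raise ValueError("pathway overlap requires two non-empty pathways")
    shared = len(p1.members & p2.members)
    pct1 = round(100.0 * shared / len(p1.members), 1)
    pct2 = round(100.0 * shared / len(p2.members), 1)
    return shared, pct1, pct2
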