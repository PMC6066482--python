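"""The 24-node reward-network atlas.

Twelve reward-related regions per hemisphere form the network nodes.  The
prefrontal/insular regions (dlPFC, ACC, OFC, INS) constitute the
reward-control subnetwork; the remaining subcortical regions (VTA, VStr,
caudate, AMY, HIP, THA, putamen, pallidum) the reward-driving subnetwork.
Edges are the 276 unordered node pairs; each edge is classified as
``control`` (both endpoints control), ``driving`` (both driving) or ``btn``
(between-subnetwork).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

REGIONS: tuple[str, ...] = (
    "dlPFC", "ACC", "VTA", "OFC", "INS", "VStr",
    "caudate", "AMY", "HIP", "THA", "putamen", "pallidum",
)

CONTROL_REGIONS: frozenset[str] = frozenset({"dlPFC", "ACC", "OFC", "INS"})

HEMISPHERES: tuple[str, str] = ("L", "R")

EDGE_CLASSES: tuple[str, str, str] = ("control", "driving", "btn")


@dataclass(frozen=True)
class Node:
    """A single atlas node: an anatomical region in one hemisphere."""

    region: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")

    @property
    def label(self) -> str:
        return f"{self.region}_{self.hemisphere}"

    @property
    def subnetwork(self) -> str:
        return "control" if self.region in CONTROL_REGIONS else "driving"


@dataclass(frozen=True)
class NodeAtlas:
    """An ordered collection of the 24 reward-network nodes."""

    nodes: tuple[Node, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.nodes) != 24:
            raise ValueError(f"atlas must have 24 nodes, got {len(self.nodes)}")
        for hemi in HEMISPHERES:
            n = sum(1 for node in self.nodes if node.hemisphere == hemi)
            if n != 12:
                raise ValueError(f"expected 12 nodes in hemisphere {hemi}, got {n}")
        n_control = sum(1 for node in self.nodes if node.subnetwork == "control")
        if n_control != 8:
            raise ValueError(f"expected 8 control nodes, got {n_control}")
        labels = [node.label for node in self.nodes]
        if len(set(labels)) != 24:
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(labels)})

    @property
    def labels(self) -> list[str]:
        return [node.label for node in self.nodes]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"node {label!r} not in atlas") from None

    def node(self, label: str) -> Node:
        return self.nodes[self.index(label)]

    def edges(self) -> list[tuple[str, str]]:
        """All 276 unordered edges, endpoints in atlas order."""
        labs = self.labels
        return list(itertools.combinations(labs, 2))

    def canonical_edge(self, a: str, b: str) -> tuple[str, str]:
        """Order an edge's endpoints by atlas index; reject self-loops."""
        i, j = self.index(a), self.index(b)
        if i == j:
            raise ValueError(f"self-loop edge {a!r}")
        return (a, b) if i < j else (b, a)

    def edge_class(self, edge: tuple[str, str]) -> str:
        sub_a = self.node(edge[0]).subnetwork
        sub_b = self.node(edge[1]).subnetwork
        if sub_a == sub_b:
            return sub_a
        return "btn"

    def edges_of_class(self, edge_class: str) -> list[tuple[str, str]]:
        if edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {edge_class!r}")
        return [e for e in self.edges() if self.edge_class(e) == edge_class]


def default_atlas() -> NodeAtlas:
    """The standard 24-node atlas: each region in L then R hemisphere."""
    nodes = tuple(
        Node(region=r, hemisphere=h) for h in HEMISPHERES for r in REGIONS
    )
    return NodeAtlas(nodes=nodes)


def edge_label(edge: tuple[str, str]) -> str:
    """Stable string form of an edge, used in file outputs."""
    return f"{edge[0]}--{edge[1]}"


def parse_edge_label(label: str) -> tuple[str, str]:
    a, _, b = label.partition("--")
    if not b:
        raise ValueError(f"malformed edge label {label!r}")
    return (a, b)
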