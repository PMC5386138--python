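"""Styled ontology subgraphs and DOT serialization.

A plotted graph shows a *term set*, not the whole ontology: edges are the
transitive reduction (Hasse diagram) of the ancestor relation restricted to
the plotted terms, so scattered term sets stay connected through their
nearest in-set ancestors instead of falling apart into orphans.

Node width encodes information content when an IC table is supplied
(affine map, capped), and fill color encodes the membership pattern — which
annotated objects carry the term — with the all-objects pattern drawn in
light blue.  Terms whose children convey exactly the same annotation
information can be dropped beforehand with
:func:`remove_uninformative_terms` to declutter the picture.

Rendering and layout are left entirely to external DOT consumers
(``dot``, ``neato``, online viewers); this module only emits text.
"""

from __future__ import annotations

import re
import textwrap
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .annotations import AnnotationTable, ICTable
from .index import OntologyIndex

__all__ = [
    "OntoGraph",
    "build_graph",
    "remove_uninformative_terms",
    "to_dot",
    "to_graphml",
    "SHARED_COLOR",
    "PALETTE",
]

#: fill for terms annotated to every provided object
SHARED_COLOR = "lightblue"
#: deterministic palette cycled over the remaining membership patterns
PALETTE = (
    "palegreen",
    "plum",
    "lightsalmon",
    "khaki",
    "lightpink",
    "paleturquoise",
    "wheat",
    "thistle",
    "peachpuff",
    "lightgray",
)
DEFAULT_COLOR = "white"

_BASE_WIDTH = 0.3
_IC_WIDTH_SCALE = 0.25
_MAX_WIDTH = 2.5


@dataclass
class OntoGraph:
    """Nodes with display attributes plus child-to-parent edges."""

    nodes: list[tuple[str, str, float, str]] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)


def _node_width(ic_value: float) -> float:
    return min(_BASE_WIDTH + _IC_WIDTH_SCALE * ic_value, _MAX_WIDTH)


def build_graph(
    index: OntologyIndex,
    terms: Iterable[str],
    ic: ICTable | None = None,
    membership: Mapping[str, Iterable[str]] | None = None,
) -> OntoGraph:
    """Build a styled subgraph over *terms*.

    Parameters
    ----------
    index
        The indexed ontology.
    terms
        The term IDs to plot (resolved through the index).
    ic
        Optional IC table; when given, node width grows with IC.
    membership
        Optional map from object ID to that object's *propagated* term set;
        when given, nodes are colored by which objects carry the term.
    """
    nodes = sorted(index.resolve_all(terms))
    if not nodes:
        raise ValueError("cannot build a graph over an empty term set")
    node_set = set(nodes)

    relation = nx.DiGraph()
    relation.add_nodes_from(nodes)
    for t in nodes:
        for u in index.ancestors_of[t]:
            if u != t and u in node_set:
                relation.add_edge(t, u)
    reduced = nx.transitive_reduction(relation)

    patterns: dict[str, frozenset[str]] = {}
    colors: dict[frozenset[str], str] = {}
    if membership is not None:
        all_objects = frozenset(membership)
        for t in nodes:
            patterns[t] = frozenset(o for o, ts in membership.items() if t in set(ts))
        distinct = sorted(
            {p for p in patterns.values() if p != all_objects},
            key=lambda p: tuple(sorted(p)),
        )
        colors = {p: PALETTE[i % len(PALETTE)] for i, p in enumerate(distinct)}
        colors[all_objects] = SHARED_COLOR

    graph = OntoGraph()
    for t in nodes:
        label = textwrap.fill(index.names.get(t) or t, width=20)
        width = _node_width(ic.get(t, 0.0) or 0.0) if ic is not None else _BASE_WIDTH
        color = colors.get(patterns.get(t), DEFAULT_COLOR) if membership else DEFAULT_COLOR
        graph.nodes.append((t, label, width, color))
    graph.edges = sorted(reduced.edges())
    return graph


def remove_uninformative_terms(
    index: OntologyIndex, annotations: AnnotationTable, terms: Iterable[str]
) -> set[str]:
    """Drop terms whose annotation information is duplicated by a child.

    A term is uninformative when some child (in the full ontology, plotted
    or not) is annotated to exactly the same objects after propagation — it
    adds a node to the picture without separating any objects.

    Raises
    ------
    ValueError
        If *annotations* has not been propagated.
    """
    if not annotations.propagated:
        raise ValueError("remove_uninformative_terms requires a propagated table")
    resolved = index.resolve_all(terms)
    objects_with: dict[str, frozenset[str]] = {}

    def objs(t: str) -> frozenset[str]:
        if t not in objects_with:
            objects_with[t] = frozenset(
                o for o in annotations.objects if t in annotations.terms_of[o]
            )
        return objects_with[t]

    return {
        t for t in resolved if not any(objs(c) == objs(t) for c in index.children[t])
    }


def _sanitize_ids(ids: Iterable[str]) -> dict[str, str]:
    """Map term IDs to unique DOT-safe identifiers."""
    out: dict[str, str] = {}
    used: set[str] = set()
    for tid in ids:
        base = re.sub(r"[^0-9A-Za-z]", "_", tid) or "_"
        if base[0].isdigit():
            base = "_" + base
        candidate, k = base, 1
        while candidate in used:
            k += 1
            candidate = f"{base}_{k}"
        used.add(candidate)
        out[tid] = candidate
    return out


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n") + '"'


def to_dot(graph: OntoGraph) -> str:
    """Serialize an :class:`OntoGraph` to Graphviz DOT text.

    Output is byte-stable: nodes and edges are emitted in sorted order and
    identifiers are sanitized deterministically, with the original term ID
    kept in a ``tooltip`` attribute.
    """
    nodes = sorted(graph.nodes)
    ids = _sanitize_ids(tid for tid, *_ in nodes)
    lines = ["digraph ontology {"]
    for tid, label, width, color in nodes:
        attrs = ", ".join(
            [
                f"label={_quote(label)}",
                f"width={width:.3f}",
                f"fillcolor={_quote(color)}",
                "style=filled",
                "fixedsize=true",
                f"tooltip={_quote(tid)}",
            ]
        )
        lines.append(f"  {ids[tid]} [{attrs}];")
    for child, parent in sorted(graph.edges):
        lines.append(f"  {ids[child]} -> {ids[parent]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(graph: OntoGraph) -> str:
    """Serialize an :class:`OntoGraph` to GraphML with the same attributes."""
    g = nx.DiGraph()
    for tid, label, width, color in sorted(graph.nodes):
        g.add_node(tid, label=label, width=width, fillcolor=color)
    g.add_edges_from(sorted(graph.edges))
    return "\n".join(nx.generate_graphml(g)) + "\n"
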