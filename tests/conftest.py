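"""Shared fixtures: the 5-term diamond ontology and its 3-object corpus.

The diamond (T0 at the top; T1 and T2 below it; T3 below both; T4 below
T3) is small enough that every closure, information content and similarity
value can be derived by hand, yet it exercises multiple inheritance.
"""

from __future__ import annotations

import math

import pytest

import ontokit as ok

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: T:0000000
name: root

[Term]
id: T:0000001
name: left branch
is_a: T:0000000

[Term]
id: T:0000002
name: right branch
is_a: T:0000000

[Term]
id: T:0000003
name: junction
is_a: T:0000001
is_a: T:0000002

[Term]
id: T:0000004
name: leaf
is_a: T:0000003
"""

T0, T1, T2, T3, T4 = (f"T:000000{i}" for i in range(5))

DIAMOND_ANNOTATIONS = f"X\t{T3}\nY\t{T4}\nZ\t{T1}\n"

# hand-derived information content for the diamond corpus
IC_T2 = -math.log(2 / 3)  # also IC(T3)
IC_T4 = -math.log(1 / 3)


@pytest.fixture(scope="session")
def diamond_doc() -> ok.OboDocument:
    return ok.parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def diamond(diamond_doc) -> ok.OntologyIndex:
    return ok.build_index(diamond_doc)


@pytest.fixture(scope="session")
def diamond_table(diamond) -> ok.AnnotationTable:
    return ok.read_annotations(DIAMOND_ANNOTATIONS, diamond)


@pytest.fixture(scope="session")
def diamond_ic(diamond, diamond_table) -> ok.ICTable:
    return ok.information_content(diamond, diamond_table)


def bfs_reachable(edges: dict[str, set[str]], start: str) -> set[str]:
    """Independent reachability oracle: plain BFS over an adjacency map."""
    seen = {start}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for nxt in edges.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def doc_parent_edges(doc: ok.OboDocument) -> dict[str, set[str]]:
    return {t.id: set(t.is_a_parents) for t in doc.terms}


def doc_child_edges(doc: ok.OboDocument) -> dict[str, set[str]]:
    edges: dict[str, set[str]] = {t.id: set() for t in doc.terms}
    for t in doc.terms:
        for p in t.is_a_parents:
            edges[p].add(t.id)
    return edges
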