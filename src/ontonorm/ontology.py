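"""Concept graphs and ontology-aware semantic similarity.

An :class:`OntologyGraph` holds concepts connected by ``is_a`` edges (a DAG
with one or more roots).  Graphs are built either from an OBO 1.2 flat file
(:func:`parse_obo`) or from a flat dictionary of id/term/synonym entries
(:func:`dictionary_as_graph`), which is attached under a single virtual root
so that flat terminologies (MedDRA-style) run through the same pipeline.

Semantic similarity between two concepts is the Wang measure: each concept
contributes the set of its ancestors (including itself), every ancestor
weighted by ``s**d`` where ``d`` is the shortest-in-weight is_a path length
(the maximum of ``s**path_length`` over all paths) and ``s`` in (0, 1] is a
per-edge decay.  The similarity is the ratio of the summed weights of shared
ancestors (counted from both sides) to the total weight of both ancestor
sets; it is 1 exactly for identical concepts and symmetric by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Concept",
    "OntologyGraph",
    "AncestorWeights",
    "OntologyError",
    "parse_obo",
    "dictionary_as_graph",
    "ancestor_weights",
    "wang_similarity",
]

#: Default per-edge decay for ancestor weights, the value used by the
#: Bacteria Biotope normalization evaluation.
DEFAULT_DECAY = 0.65

#: Reserved id of the virtual root created by :func:`dictionary_as_graph`.
DICT_ROOT_ID = "ROOT:0000000"


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology input."""


@dataclass
class Concept:
    """A single ontology concept: an id, a preferred name, synonyms and
    ``is_a`` parents."""

    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    parent_ids: list[str] = field(default_factory=list)

    @property
    def surfaces(self) -> list[str]:
        """Preferred name followed by synonyms."""
        return [self.name, *self.synonyms]


class OntologyGraph:
    """A DAG of concepts over the ``is_a`` relation.

    Validates on construction: ids unique and non-empty, parents resolve,
    and the relation is acyclic.  Multiple roots are permitted.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if not c.id:
                raise OntologyError("concept with empty id")
            if c.id in self.concepts:
                raise OntologyError(f"duplicate concept id: {c.id}")
            self.concepts[c.id] = c
        for c in self.concepts.values():
            for p in c.parent_ids:
                if p not in self.concepts:
                    raise OntologyError(f"{c.id}: is_a target {p!r} not defined")
        cycle = self._find_cycle_member()
        if cycle is not None:
            raise OntologyError(f"is_a cycle detected involving {cycle!r}")
        self.root_ids: list[str] = sorted(
            cid for cid, c in self.concepts.items() if not c.parent_ids
        )
        if not self.root_ids:
            raise OntologyError("graph has no root concept")

    def _find_cycle_member(self) -> str | None:
        # iterative three-colour DFS over is_a edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {cid: WHITE for cid in self.concepts}
        for start in self.concepts:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, i = stack[-1]
                parents = self.concepts[node].parent_ids
                if i < len(parents):
                    stack[-1] = (node, i + 1)
                    nxt = parents[i]
                    if colour[nxt] == GREY:
                        return nxt
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK
                    stack.pop()
        return None

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __getitem__(self, cid: str) -> Concept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise OntologyError(f"unknown concept id: {cid}") from None

    @property
    def root_id(self) -> str:
        """The unique root, or the lexicographically smallest of several."""
        return self.root_ids[0]

    def to_obo(self) -> str:
        """Serialize as an OBO 1.2 flat file (id, name, synonym, is_a)."""
        out = ["format-version: 1.2", ""]
        for cid in sorted(self.concepts):
            c = self.concepts[cid]
            out.append("[Term]")
            out.append(f"id: {c.id}")
            out.append(f"name: {c.name}")
            for syn in c.synonyms:
                out.append(f'synonym: "{syn}" EXACT []')
            for p in c.parent_ids:
                out.append(f"is_a: {p} ! {self.concepts[p].name}")
            out.append("")
        return "\n".join(out)


@dataclass
class AncestorWeights:
    """Decay-weighted ancestor set of one concept.

    ``weights[a]`` is the S-value ``max over is_a paths of s**len(path)``;
    the concept itself is always present with weight 1.
    """

    concept_id: str
    weights: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.weights.values())


_SYNONYM_RE = re.compile(r'^"(.*)"')


def parse_obo(stream: Iterable[str]) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Only the ``[Term]`` stanzas and the keys id, name, synonym, is_a and
    is_obsolete are interpreted; obsolete terms are skipped.  Synonym lines
    keep the quoted string whatever the scope tag (EXACT, RELATED, ...).

    Raises :class:`OntologyError` on duplicate ids, is_a references to
    undefined ids, or an is_a cycle (naming one member of the cycle).
    """
    concepts: list[Concept] = []
    in_term = False
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        if not cur.get("obsolete"):
            if "id" not in cur:
                raise OntologyError("[Term] stanza without id")
            concepts.append(
                Concept(
                    id=cur["id"],
                    name=cur.get("name", cur["id"]),
                    synonyms=cur.get("synonyms", []),
                    parent_ids=cur.get("parents", []),
                )
            )
        cur = None

    for raw in stream:
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur = {} if in_term else None
            continue
        if not in_term or cur is None or not line or line.startswith("!"):
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        key = key.strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OntologyError(f"malformed synonym line: {line!r}")
            cur.setdefault("synonyms", []).append(m.group(1))
        elif key == "is_a":
            target = value.split("!")[0].strip()
            cur.setdefault("parents", []).append(target)
        elif key == "is_obsolete" and value.lower().startswith("true"):
            cur["obsolete"] = True
    flush()
    return OntologyGraph(concepts)


def dictionary_as_graph(
    entries: Iterable[tuple[str, str, list[str]]],
    root_id: str = DICT_ROOT_ID,
    root_name: str = "dictionary root",
) -> OntologyGraph:
    """Wrap a flat dictionary as a two-level graph under a virtual root.

    ``entries`` are ``(id, preferred_term, synonyms)`` triples; each becomes
    a child of the virtual root so that flat terminologies run through the
    same ranking and evaluation code as a real ontology.
    """
    concepts = [Concept(id=root_id, name=root_name)]
    for cid, term, synonyms in entries:
        if cid == root_id:
            raise OntologyError(f"entry id collides with reserved root id {root_id!r}")
        concepts.append(
            Concept(id=cid, name=term, synonyms=list(synonyms), parent_ids=[root_id])
        )
    return OntologyGraph(concepts)


def ancestor_weights(
    graph: OntologyGraph, concept_id: str, s: float = DEFAULT_DECAY
) -> AncestorWeights:
    """Decay-weighted ancestor closure of ``concept_id``.

    weight(a) = max over is_a paths from the concept to ``a`` of ``s**len``;
    the concept itself always has weight 1.  Computed by best-first
    propagation: weights only shrink along edges (s <= 1), so each node's
    weight is final once no larger candidate remains.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"decay s must be in (0, 1], got {s}")
    graph[concept_id]  # raises on unknown id
    weights: dict[str, float] = {concept_id: 1.0}
    frontier = [concept_id]
    while frontier:
        node = frontier.pop()
        w = weights[node]
        for parent in graph.concepts[node].parent_ids:
            cand = w * s
            if cand > weights.get(parent, 0.0):
                weights[parent] = cand
                frontier.append(parent)
    return AncestorWeights(concept_id=concept_id, weights=weights)


def wang_similarity(
    graph: OntologyGraph, c1: str, c2: str, s: float = DEFAULT_DECAY
) -> float:
    """Wang semantic similarity between two concepts.

    With T1, T2 the decay-weighted ancestor maps of c1 and c2::

        sim = sum_{a in T1 & T2} (w1(a) + w2(a)) / (sum(T1) + sum(T2))

    Symmetric; 1.0 iff the weighted ancestor sets coincide (in particular
    when ``c1 == c2``); strictly below 1 when they differ.
    """
    t1 = ancestor_weights(graph, c1, s)
    t2 = ancestor_weights(graph, c2, s)
    shared = t1.weights.keys() & t2.weights.keys()
    num = sum(t1.weights[a] + t2.weights[a] for a in shared)
    return num / (t1.total + t2.total)
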