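"""Deterministic synthetic ontologies, embeddings and corpora.

Every other module is testable offline against fixtures built here: a
complete ``is_a`` tree of concepts, a clustered toy embedding space in
which each concept owns a unit base vector and its surface tokens scatter
around it, and a mention corpus drawn from the concept surfaces with
controllable difficulty.

Difficulty knobs mirror the failure modes of real normalization corpora:

* ``noise_sd`` — at 0 every mention is the verbatim name or synonym of its
  gold concept (the easy, lexically-matched regime).  At larger values each
  mention token is realized as a mention-specific variant whose vector is
  the term token's vector plus fresh Gaussian noise, emulating the surface
  variety between free text and ontology terms that makes normalization
  hard; ranking accuracy degrades smoothly as the noise grows.
* ``paraphrase_rate`` — fraction of mentions rendered as a synonym rather
  than the preferred name.
* ``ppp_rate`` — fraction of mentions wrapped in an uninformative
  possessive construction ("X of the ...") with a matching NP-PP(of)-NP
  parse, exercising the possessive-PP stripping rule.
* ``oov_rate`` — fraction of mentions replaced by out-of-vocabulary
  gibberish, exercising the fallback paths.

All randomness flows from one integer seed; every artifact can be written
to disk in the real external formats (OBO, word2vec text, .a1/.a2, TSV) so
I/O and algorithms are tested together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import (
    Mention,
    NormalizationRecord,
    write_a1,
    write_a2,
    write_gold_tsv,
    write_mentions_tsv,
    write_parse_table,
)
from .embeddings import EmbeddingStore, default_stopwords, preprocess
from .ontology import Concept, OntologyGraph
from .syntax import ParseNode, serialize

__all__ = [
    "FixtureSpec",
    "make_toy_ontology",
    "make_toy_embeddings",
    "make_toy_corpus",
    "write_fixture",
]

_FILLERS = ["specimen", "sample", "region", "material", "area", "site"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study condition."""

    seed: int = 0
    n_levels: int = 2
    branching: int = 3
    dim: int = 16
    noise_sd: float = 0.0
    n_mentions: int = 200
    paraphrase_rate: float = 0.3
    oov_rate: float = 0.0
    ppp_rate: float = 0.0
    n_docs: int = 5

    def __post_init__(self) -> None:
        for name in ("paraphrase_rate", "oov_rate", "ppp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def make_toy_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Complete ``branching``-ary tree of depth ``n_levels``.

    Each concept's name carries a globally distinctive token (e.g.
    ``concept-v2x4`` has token ``v2x4``) and its 1-2 synonyms share that
    token, so surfaces of one concept cluster in embedding space.
    """
    rng = spec.rng(1)
    concepts: list[Concept] = []
    counter = 0
    prev_level: list[str] = []
    for level in range(spec.n_levels + 1):
        n_here = spec.branching**level
        this_level: list[str] = []
        for i in range(n_here):
            cid = f"TOY:{counter:07d}"
            counter += 1
            tok = f"v{level}x{i}"
            synonyms = [f"{tok} term"]
            if rng.random() < 0.5:
                synonyms.append(f"alternate {tok}")
            parents = [] if level == 0 else [prev_level[i // spec.branching]]
            concepts.append(
                Concept(
                    id=cid,
                    name=f"concept-{tok}",
                    synonyms=synonyms,
                    parent_ids=parents,
                )
            )
            this_level.append(cid)
        prev_level = this_level
    return OntologyGraph(concepts)


def make_toy_embeddings(graph: OntologyGraph, spec: FixtureSpec) -> EmbeddingStore:
    """Clustered toy vectors for every surface token plus distractors.

    Each concept gets a deterministic unit base vector; a token's vector is
    the mean of the bases of the concepts whose surfaces contain it, plus
    per-token Gaussian noise of scale ``noise_sd``.  A token unique to one
    concept therefore sits on that concept's base (exactly, at zero noise),
    while shared tokens land between their concepts.
    """
    rng = spec.rng(2)
    stop = default_stopwords()
    bases: dict[str, np.ndarray] = {}
    for cid in sorted(graph.concepts):
        v = rng.normal(size=spec.dim)
        bases[cid] = v / np.linalg.norm(v)
    token_concepts: dict[str, list[str]] = {}
    for cid in sorted(graph.concepts):
        for surface in graph.concepts[cid].surfaces:
            for tok in preprocess(surface, stop).tokens:
                token_concepts.setdefault(tok, []).append(cid)
    store = EmbeddingStore(dim=spec.dim)
    for tok in sorted(token_concepts):
        base = np.mean([bases[c] for c in token_concepts[tok]], axis=0)
        store.add(tok, base + rng.normal(0.0, spec.noise_sd, size=spec.dim))
    for word in _FILLERS + [f"distractor{i}" for i in range(20)]:
        v = rng.normal(size=spec.dim)
        store.add(word, v / np.linalg.norm(v))
    return store


def make_toy_corpus(
    graph: OntologyGraph, store: EmbeddingStore, spec: FixtureSpec
) -> tuple[list[Mention], list[NormalizationRecord], dict[str, ParseNode]]:
    """Draw ``n_mentions`` mentions with gold concepts and parses.

    At ``noise_sd == 0`` mention texts are verbatim concept surfaces; at
    positive noise each mention token becomes a mention-specific variant
    token (added to ``store``) whose vector is the term token's vector plus
    fresh noise, so the mention and the indexed term drift apart as the
    noise grows.  Parses are flat NPs, or the NP-PP(of)-NP shape for
    possessive-wrapped mentions.
    """
    rng = spec.rng(3)
    stop = default_stopwords()
    concept_ids = sorted(graph.concepts)
    mentions: list[Mention] = []
    gold: list[NormalizationRecord] = []
    parses: dict[str, ParseNode] = {}
    per_doc_count: dict[str, int] = {}
    per_doc_cursor: dict[str, int] = {}

    for j in range(spec.n_mentions):
        doc_id = f"doc{(j % spec.n_docs) + 1:02d}"
        per_doc_count[doc_id] = per_doc_count.get(doc_id, 0) + 1
        mid = f"T{per_doc_count[doc_id]}"
        cid = concept_ids[rng.integers(len(concept_ids))]
        concept = graph.concepts[cid]
        use_synonym = concept.synonyms and rng.random() < spec.paraphrase_rate
        surface = (
            concept.synonyms[rng.integers(len(concept.synonyms))]
            if use_synonym
            else concept.name
        )
        if rng.random() < spec.oov_rate:
            text = f"zzgib{j}a zzgib{j}b"
            tree = _flat_np(text.split())
        else:
            base_tokens = preprocess(surface, stop).tokens
            if spec.noise_sd > 0:
                tokens = []
                for t in base_tokens:
                    variant = f"{t}m{j}"
                    store.add(
                        variant,
                        store[t] + rng.normal(0.0, spec.noise_sd, size=spec.dim),
                    )
                    tokens.append(variant)
                text = " ".join(tokens)
            else:
                tokens = base_tokens
                text = surface
            if rng.random() < spec.ppp_rate:
                fillers = [
                    _FILLERS[rng.integers(len(_FILLERS))],
                    _FILLERS[rng.integers(len(_FILLERS))],
                ]
                text = f"{text} of the {' '.join(fillers)}"
                tree = ParseNode(
                    "NP",
                    children=[
                        _flat_np(tokens),
                        ParseNode(
                            "PP",
                            children=[
                                ParseNode("IN", token="of"),
                                ParseNode(
                                    "NP",
                                    children=[ParseNode("DT", token="the")]
                                    + [ParseNode("NN", token=f) for f in fillers],
                                ),
                            ],
                        ),
                    ],
                )
            else:
                tree = _flat_np(tokens)
        cursor = per_doc_cursor.get(doc_id, 0)
        mention = Mention(
            doc_id=doc_id,
            mention_id=mid,
            entity_type="Habitat",
            spans=[(cursor, cursor + len(text))],
            text=text,
        )
        per_doc_cursor[doc_id] = cursor + len(text) + 1
        mentions.append(mention)
        gold.append(
            NormalizationRecord(doc_id=doc_id, mention_id=mid, concept_ids=[cid])
        )
        parses[mention.key] = tree
    return mentions, gold, parses


def _flat_np(tokens: list[str]) -> ParseNode:
    return ParseNode("NP", children=[ParseNode("NN", token=t) for t in tokens])


def write_fixture(out_dir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Generate a full fixture and write it in the real external formats.

    Produces ``ontology.obo``, ``vectors.txt`` (word2vec text format, after
    corpus generation so mention-variant tokens are included),
    per-document ``.a1``/``.a2`` standoff files, ``parses.tsv``,
    ``mentions.tsv`` and ``gold.tsv``.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = make_toy_ontology(spec)
    store = make_toy_embeddings(graph, spec)
    mentions, gold, parses = make_toy_corpus(graph, store, spec)

    paths: dict[str, Path] = {}
    paths["ontology"] = out / "ontology.obo"
    paths["ontology"].write_text(graph.to_obo(), encoding="utf-8")
    paths["vectors"] = out / "vectors.txt"
    with paths["vectors"].open("w", encoding="utf-8") as fh:
        store.write_text(fh)
    doc_ids = sorted({m.doc_id for m in mentions})
    for doc_id in doc_ids:
        a1 = out / f"{doc_id}.a1"
        with a1.open("w", encoding="utf-8") as fh:
            write_a1([m for m in mentions if m.doc_id == doc_id], fh)
        a2 = out / f"{doc_id}.a2"
        with a2.open("w", encoding="utf-8") as fh:
            write_a2([g for g in gold if g.doc_id == doc_id], fh)
    paths["parses"] = out / "parses.tsv"
    with paths["parses"].open("w", encoding="utf-8") as fh:
        write_parse_table({k: serialize(t) for k, t in parses.items()}, fh)
    paths["mentions"] = out / "mentions.tsv"
    with paths["mentions"].open("w", encoding="utf-8") as fh:
        write_mentions_tsv(mentions, fh)
    paths["gold"] = out / "gold.tsv"
    texts = {m.key: m.text for m in mentions}
    with paths["gold"].open("w", encoding="utf-8") as fh:
        write_gold_tsv(gold, fh, texts=texts)
    paths["dir"] = out
    return paths
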