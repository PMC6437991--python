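"""Term indexing, semantic ranking and head-weighted re-ranking."""

import numpy as np
import pytest

from ontonorm.embeddings import (
    EmbeddingStore,
    PhraseVector,
    compose_vector,
    cosine_similarity,
    preprocess,
)
from ontonorm.linker import (
    LinkerConfig,
    LinkerError,
    build_term_index,
    link_mention,
    rank_candidates,
    rerank,
)
from ontonorm.ontology import Concept, OntologyGraph
from ontonorm.syntax import HeadResult, parse_bracketed


def small_graph():
    return OntologyGraph(
        [
            Concept("G:0", "root"),
            Concept("G:1", "medical center", ["clinic"], parent_ids=["G:0"]),
            Concept("G:2", "child", ["kid"], parent_ids=["G:0"]),
        ]
    )


def small_store():
    rng = np.random.default_rng(0)
    toks = ["root", "medical", "center", "clinic", "child", "kid"]
    return EmbeddingStore(dim=4, vectors={t: rng.normal(size=4) for t in toks})


class TestBuildTermIndex:
    def test_one_entry_per_surface(self):
        index = build_term_index(small_graph(), small_store())
        # root + (name+synonym) x 2 concepts
        assert len(index) == 5
        assert {(e.concept_id, e.surface) for e in index} == {
            ("G:0", "root"),
            ("G:1", "medical center"),
            ("G:1", "clinic"),
            ("G:2", "child"),
            ("G:2", "kid"),
        }

    def test_fully_oov_surface_dropped(self):
        store = small_store()
        del store.vectors["kid"]
        index = build_term_index(small_graph(), store)
        assert ("G:2", "kid") not in {(e.concept_id, e.surface) for e in index}

    def test_head_cached_on_entry(self):
        parses = {"medical center": parse_bracketed("(NP (JJ medical) (NN center))")}
        index = build_term_index(small_graph(), small_store(), parses=parses)
        entry = next(e for e in index if e.surface == "medical center")
        assert entry.head.token == "center"
        assert entry.head_vector == pytest.approx(small_store()["center"])

    def test_empty_index_is_an_error(self):
        empty_store = EmbeddingStore(dim=2, vectors={"unrelated": np.ones(2)})
        with pytest.raises(LinkerError, match="empty"):
            build_term_index(small_graph(), empty_store)


class TestRankCandidates:
    def test_exact_vector_ranks_first_with_cosine_one(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec = compose_vector(preprocess("medical center").tokens, store)
        ranked = rank_candidates(mvec, index, k=3)
        assert ranked.stage == "semantic"
        assert ranked.entries[0].concept_id == "G:1"
        assert ranked.entries[0].score == pytest.approx(1.0)

    def test_k_larger_than_concepts_returns_all_ordered(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec = compose_vector(["child"], store)
        ranked = rank_candidates(mvec, index, k=50)
        assert len(ranked.entries) == 3
        scores = [c.score for c in ranked.entries]
        assert scores == sorted(scores, reverse=True)

    def test_concepts_unique_within_list(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec = compose_vector(["clinic"], store)
        ids = rank_candidates(mvec, index, k=5).concept_ids()
        assert len(ids) == len(set(ids))

    def test_matches_full_sort_oracle_on_random_indexes(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_concepts = int(rng.integers(2, 20))
            dim = 5
            store = EmbeddingStore(dim=dim)
            concepts = [Concept("R", "shared root")]
            for i in range(n_concepts):
                toks = [f"w{i}a", f"w{i}b"][: int(rng.integers(1, 3))]
                for t in toks:
                    store.add(t, rng.normal(size=dim))
                concepts.append(
                    Concept(f"C{i:02d}", " ".join(toks), parent_ids=["R"])
                )
            store.add("shared", rng.normal(size=dim))
            store.add("root", rng.normal(size=dim))
            graph = OntologyGraph(concepts)
            index = build_term_index(graph, store)
            mvec = PhraseVector(vector=rng.normal(size=dim), contributing=1)
            k = int(rng.integers(1, 6))
            got = rank_candidates(mvec, index, k=k)
            # oracle: exhaustive per-concept max, then full stable sort
            best: dict[str, float] = {}
            for e in index:
                s = cosine_similarity(mvec.vector, e.phrase_vector.vector)
                best[e.concept_id] = max(s, best.get(e.concept_id, -2.0))
            expected = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
            assert got.concept_ids() == [cid for cid, _ in expected]
            for cand, (_, score) in zip(got.entries, expected):
                assert cand.score == pytest.approx(score)


class TestRerank:
    def _candidates(self, store, index, mention_tokens):
        mvec = compose_vector(mention_tokens, store)
        return mvec, rank_candidates(mvec, index, k=5)

    def test_w_zero_is_identity_on_scores(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec, sem = self._candidates(store, index, ["child"])
        rr = rerank(mvec, HeadResult("child", "parse"), sem, store, w=0.0, index=index)
        assert rr.stage == "reranked"
        assert [(c.concept_id, c.score) for c in rr.entries] == [
            (c.concept_id, pytest.approx(c.score)) for c in sem.entries
        ]

    def test_equation_arithmetic(self):
        # cos(heads) = 1 and semantic score 0.5 with w = 0.25 -> 0.625
        store = EmbeddingStore(
            dim=2, vectors={"h": np.array([1.0, 0.0]), "m": np.array([1.0, 1.0])}
        )
        graph = OntologyGraph([Concept("A", "h")])
        index = build_term_index(graph, store)
        mvec = PhraseVector(vector=np.array([np.sqrt(3) / 2, 0.5]), contributing=1)
        sem = rank_candidates(mvec, index, k=1)
        sem.entries[0].score = 0.5  # pin the semantic part of the formula
        rr = rerank(mvec, HeadResult("h", "parse"), sem, store, w=0.25, index=index)
        assert rr.entries[0].score == pytest.approx(0.25 * 1.0 + 0.75 * 0.5)

    def test_oov_head_keeps_semantic_score(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec, sem = self._candidates(store, index, ["child"])
        rr = rerank(
            mvec, HeadResult("unseen", "parse"), sem, store, w=0.25, index=index
        )
        for before, after in zip(sem.entries, rr.entries):
            assert after.score == pytest.approx(before.score)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(3)
        store = small_store()
        index = build_term_index(small_graph(), store)
        by_surface = {(e.concept_id, e.surface): e for e in index}
        for _ in range(50):
            mvec = PhraseVector(vector=rng.normal(size=4), contributing=1)
            sem = rank_candidates(mvec, index, k=3)
            w = float(rng.uniform(0, 1))
            head_tok = ["child", "center", "clinic"][int(rng.integers(3))]
            rr = rerank(mvec, HeadResult(head_tok, "parse"), sem, store, w=w, index=index)
            sem_scores = {c.concept_id: c.score for c in sem.entries}
            for cand in rr.entries:
                entry = by_surface[
                    (cand.concept_id, next(c.surface for c in sem.entries if c.concept_id == cand.concept_id))
                ]
                if entry.head_vector is None:
                    continue
                head_sim = cosine_similarity(store[head_tok], entry.head_vector)
                lo = min(sem_scores[cand.concept_id], head_sim) - 1e-9
                hi = max(sem_scores[cand.concept_id], head_sim) + 1e-9
                assert lo <= cand.score <= hi

    def test_w_one_orders_by_head_similarity_alone(self):
        store = small_store()
        index = build_term_index(small_graph(), store)
        mvec, sem = self._candidates(store, index, ["child", "clinic"])
        rr = rerank(mvec, HeadResult("child", "parse"), sem, store, w=1.0, index=index)
        head_sims = {}
        by_surface = {(e.concept_id, e.surface): e for e in index}
        for cand in sem.entries:
            entry = by_surface[(cand.concept_id, cand.surface)]
            head_sims[cand.concept_id] = cosine_similarity(
                store["child"], entry.head_vector
            )
        expected = sorted(head_sims.items(), key=lambda kv: (-kv[1], kv[0]))
        assert rr.concept_ids() == [cid for cid, _ in expected]


class TestLinkMention:
    def test_exact_name_links_with_score_one(self):
        graph, store = small_graph(), small_store()
        index = build_term_index(graph, store)
        cid, score, trace = link_mention(
            "medical center", None, graph, store, index, LinkerConfig(use_rerank=False)
        )
        assert cid == "G:1"
        assert score == pytest.approx(1.0)
        assert trace["fallback"] is None

    def test_head_dominated_rerank_flips_semantic_winner(self):
        """A mention whose phrase vector drifts toward the wrong concept is
        recovered by the head-word similarity during re-ranking."""
        vectors = {
            # phrase context pulls toward "center"-like tokens
            "children": np.array([1.0, 0.0, 0.0]),
            "attending": np.array([0.0, 1.0, 0.0]),
            "day": np.array([0.0, 1.0, 0.0]),
            "care": np.array([0.0, 1.0, 0.0]),
            "center": np.array([0.0, 1.0, 0.0]),
            "medical": np.array([0.0, 1.0, 0.0]),
            # "child" splits the difference: close to the mention head
            "child": np.array([0.5, np.sqrt(3) / 2, 0.0]),
            "root": np.array([0.0, 0.0, 1.0]),
        }
        store = EmbeddingStore(dim=3, vectors=vectors)
        graph = OntologyGraph(
            [
                Concept("G:0", "root"),
                Concept("G:1", "medical center", parent_ids=["G:0"]),
                Concept("G:2", "child", parent_ids=["G:0"]),
            ]
        )
        parses = {"medical center": parse_bracketed("(NP (JJ medical) (NN center))")}
        index = build_term_index(graph, store, parses=parses)
        mention = "children attending a day-care center"
        parse = parse_bracketed(
            "(NP (NP (NNS children)) (VP (VBG attending) "
            "(NP (DT a) (JJ day-care) (NN center))))"
        )
        no_rr, _, _ = link_mention(
            mention, parse, graph, store, index, LinkerConfig(use_rerank=False)
        )
        with_rr, _, trace = link_mention(
            mention, parse, graph, store, index, LinkerConfig(w=0.25)
        )
        assert no_rr == "G:1"  # semantic stage prefers "medical center"
        assert with_rr == "G:2"  # head similarity recovers "child"
        assert trace["head"] == "children"

    def test_ppp_strip_changes_composition(self):
        graph, store = small_graph(), small_store()
        index = build_term_index(graph, store)
        parse = parse_bracketed(
            "(NP (NP (NN clinic)) (PP (IN of) (NP (DT the) (NN child))))"
        )
        cid_strip, _, trace = link_mention(
            "clinic of the child", parse, graph, store, index, LinkerConfig()
        )
        assert trace["ppp_stripped"] is True
        assert cid_strip == "G:1"

    def test_all_oov_fallback_root(self):
        graph, store = small_graph(), small_store()
        index = build_term_index(graph, store)
        cid, score, trace = link_mention(
            "zzz qqq", None, graph, store, index, LinkerConfig(fallback="root")
        )
        assert cid == "G:0" and trace["fallback"] == "root"

    def test_all_oov_fallback_exact_match_first(self):
        graph, store = small_graph(), small_store()
        index = build_term_index(graph, store)
        del store.vectors["kid"]
        cid, _, trace = link_mention(
            "Kid", None, graph, store, index, LinkerConfig(fallback="exact_then_root")
        )
        assert cid == "G:2" and trace["fallback"] == "exact_match"

    def test_all_oov_abstain(self):
        graph, store = small_graph(), small_store()
        index = build_term_index(graph, store)
        cid, _, trace = link_mention(
            "zzz", None, graph, store, index, LinkerConfig(fallback="abstain")
        )
        assert cid is None and trace["fallback"] == "abstain"


class TestLinkerConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"k": 0}, {"w": 1.5}, {"metric": "euclid"}, {"fallback": "guess"}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LinkerConfig(**kwargs)
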