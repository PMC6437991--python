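"""Scoring predicted normalizations against gold annotations.

Two evaluation regimes:

* **Ontology-aware precision** (the Bacteria Biotope measure): each
  predicted concept is credited with its Wang similarity to the gold
  referent (the best one, if the mention has several), and precision is
  the mean credit over all predicted mentions.  A prediction equal to its
  gold concept scores 1; a wrong but nearby prediction scores partial
  credit that decays with ontological distance.

* **Exact micro/macro precision, recall and F-score** (the adverse-drug-
  reaction measure): per-document TP/FP/FN from exact concept-id matching,
  pooled over documents (micro) or averaged per document (macro); each
  F-score is the harmonic mean of the corresponding precision and recall.

Two reference baselines are provided: exact string match backed off to the
ontology root, and the trivial all-root assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import Mention, NormalizationRecord, Prediction
from .ontology import OntologyGraph, wang_similarity

__all__ = [
    "DocCounts",
    "EvalReport",
    "EvaluationError",
    "bb_precision",
    "exact_counts",
    "micro_scores",
    "macro_scores",
    "harmonic_mean",
    "baseline_exact_or_root",
    "baseline_all_root",
    "evaluate_exact",
]


class EvaluationError(ValueError):
    pass


@dataclass
class DocCounts:
    """Exact-match tallies for one document."""

    doc_id: str
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class EvalReport:
    """Micro and macro precision/recall/F plus the per-document table."""

    micro_precision: float
    micro_recall: float
    micro_fscore: float
    macro_precision: float
    macro_recall: float
    macro_fscore: float
    per_doc: list[DocCounts]
    n_docs: int

    def summary(self) -> str:
        lines = [
            f"{'':16s}{'precision':>10s}{'recall':>10s}{'f-score':>10s}",
            f"{'micro-average':16s}{self.micro_precision:10.3f}"
            f"{self.micro_recall:10.3f}{self.micro_fscore:10.3f}",
            f"{'macro-average':16s}{self.macro_precision:10.3f}"
            f"{self.macro_recall:10.3f}{self.macro_fscore:10.3f}",
            f"documents: {self.n_docs}",
        ]
        return "\n".join(lines)


def _gold_by_key(gold: Iterable[NormalizationRecord]) -> dict[str, NormalizationRecord]:
    return {rec.key: rec for rec in gold}


def bb_precision(
    predictions: Sequence[Prediction],
    gold: Sequence[NormalizationRecord],
    graph: OntologyGraph,
    s: float = 0.65,
) -> float:
    """Ontology-aware precision: mean Wang similarity of predictions.

    For each predicted mention the credit is the maximum Wang similarity
    (decay ``s``) between the predicted concept and any of the mention's
    gold referents; the score is the sum of credits divided by the number
    of predicted mentions.  Every predicted mention must appear in the
    gold (the task provides gold mention spans).
    """
    if not predictions:
        raise EvaluationError("no predictions to score")
    by_key = _gold_by_key(gold)
    total = 0.0
    for pred in predictions:
        key = f"{pred.doc_id}:{pred.mention_id}"
        if key not in by_key:
            raise EvaluationError(f"prediction for unknown mention {key}")
        total += max(
            wang_similarity(graph, pred.concept_id, g, s)
            for g in by_key[key].concept_ids
        )
    return total / len(predictions)


def exact_counts(
    predictions: Sequence[Prediction], gold: Sequence[NormalizationRecord]
) -> list[DocCounts]:
    """Per-document TP/FP/FN under exact concept-id matching.

    A prediction is a TP when its concept is one of the mention's gold
    concepts; a gold record with no correct prediction is an FN.
    """
    by_key = _gold_by_key(gold)
    doc_ids = sorted({p.doc_id for p in predictions} | {g.doc_id for g in gold})
    counts = {d: DocCounts(doc_id=d) for d in doc_ids}
    correct_keys: set[str] = set()
    for pred in predictions:
        rec = by_key.get(f"{pred.doc_id}:{pred.mention_id}")
        if rec is not None and pred.concept_id in rec.concept_ids:
            counts[pred.doc_id].tp += 1
            correct_keys.add(rec.key)
        else:
            counts[pred.doc_id].fp += 1
    for rec in gold:
        if rec.key not in correct_keys:
            counts[rec.doc_id].fn += 1
    return [counts[d] for d in doc_ids]


def harmonic_mean(p: float, r: float) -> float:
    """F-score from a precision and a recall; 0 when both are 0."""
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def micro_scores(counts: Sequence[DocCounts]) -> tuple[float, float, float]:
    """Pool TP/FP/FN over all documents, then compute P, R and F."""
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("micro scores over zero predictions or zero gold records")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, harmonic_mean(p, r)


def macro_scores(counts: Sequence[DocCounts]) -> tuple[float, float, float]:
    """Average per-document precision and recall; F is their harmonic mean.

    Documents with a zero denominator contribute 0 to the average and are
    still counted in the number of documents.
    """
    if not counts:
        warnings.warn("macro scores over zero documents")
        return 0.0, 0.0, 0.0
    ps = [c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0 for c in counts]
    rs = [c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0 for c in counts]
    p = sum(ps) / len(counts)
    r = sum(rs) / len(counts)
    return p, r, harmonic_mean(p, r)


def evaluate_exact(
    predictions: Sequence[Prediction], gold: Sequence[NormalizationRecord]
) -> EvalReport:
    """Full exact-match report (micro + macro + per-document table)."""
    counts = exact_counts(predictions, gold)
    mp, mr, mf = micro_scores(counts)
    Mp, Mr, Mf = macro_scores(counts)
    return EvalReport(
        micro_precision=mp,
        micro_recall=mr,
        micro_fscore=mf,
        macro_precision=Mp,
        macro_recall=Mr,
        macro_fscore=Mf,
        per_doc=counts,
        n_docs=len(counts),
    )


def baseline_exact_or_root(
    mentions: Sequence[Mention], graph: OntologyGraph
) -> list[Prediction]:
    """Exact-string baseline: case-insensitive match of the mention text
    against concept names and synonyms (ties to the smaller id), backing
    off to the root concept when no surface matches."""
    surface_map: dict[str, str] = {}
    for cid in sorted(graph.concepts, reverse=True):
        for surface in graph.concepts[cid].surfaces:
            surface_map[surface.strip().lower()] = cid  # smaller ids overwrite
    out = []
    for m in mentions:
        cid = surface_map.get(m.text.strip().lower(), graph.root_id)
        fallback = "" if cid != graph.root_id or _is_root_surface(m, graph) else "root"
        out.append(
            Prediction(
                doc_id=m.doc_id,
                mention_id=m.mention_id,
                mention_text=m.text,
                concept_id=cid,
                score=1.0 if not fallback else 0.0,
                fallback=fallback,
            )
        )
    return out


def _is_root_surface(m: Mention, graph: OntologyGraph) -> bool:
    root = graph.concepts[graph.root_id]
    return m.text.strip().lower() in (s.strip().lower() for s in root.surfaces)


def baseline_all_root(
    mentions: Sequence[Mention], graph: OntologyGraph
) -> list[Prediction]:
    """Trivial baseline: every mention is assigned the root concept."""
    return [
        Prediction(
            doc_id=m.doc_id,
            mention_id=m.mention_id,
            mention_text=m.text,
            concept_id=graph.root_id,
            score=0.0,
            fallback="root",
        )
        for m in mentions
    ]
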