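# ontonorm

Unsupervised normalization of biomedical entity mentions: given a mention
annotated in text (a bacteria habitat such as *"children attending a
day-care center"*, or an adverse drug reaction such as *"neuropathy"*) and
an ontology or flat dictionary (an OBO habitat ontology, a MedDRA-style
terminology), `ontonorm` links the mention to the concept identifier it
denotes. No labelled training data is required: the method relies on
pre-trained word embeddings for semantics and a constituency parse for
syntax.

It is aimed at biomedical text-mining practitioners who have named-entity
mentions (BioNLP-ST standoff `.a1` files or a plain TSV) and need concept
assignments that can be scored both exactly and with ontology-aware partial
credit.

## Method

Every mention *m* and every ontology surface form *c* (concept names and
synonyms) is embedded the same way: lowercase, strip non-ASCII characters,
split on non-alphanumeric characters, drop stop words, then average the
word vectors of the surviving in-vocabulary tokens. Concepts are ranked by
the cosine similarity S(m, c) of these phrase vectors (word mover's
distance is available as an alternative metric), and the top *k* candidates
are re-scored with the head-word weighted similarity

    S_RR(m, c) = w · S(m_head, c_head) + (1 − w) · S(m, c)

where the head of a phrase is the top-level rightmost noun of its
constituency parse (for *"children attending a day-care center"* the head
is *"children"*, which is what rescues the correct concept *child* from
center-like distractors). Defaults are k = 5 and w = 0.25. Mentions shaped
as possessive prepositional phrases (*"throats of two healthy children"*)
are stripped to their informative left NP (*"throats"*) before embedding.

Predictions are scored two ways:

* **Ontology-aware precision** — each prediction earns the Wang similarity
  between predicted and gold concept: with ancestor weights
  S(a) = s^d (d = is_a distance, decay s = 0.65),

      W(c1, c2) = Σ_{a ∈ T1 ∩ T2} (w1(a) + w2(a)) / (Σ T1 + Σ T2)

  and precision is the mean W over all predicted mentions.
* **Exact micro/macro precision, recall and F-score** — per-document
  TP/FP/FN pooled (micro) or averaged (macro); F is the harmonic mean of
  the corresponding precision and recall.

Two reference baselines are included: case-insensitive exact string match
backed off to the ontology root, and the trivial all-root assignment.

## Worked example

The package ships a deterministic fixture generator (a 13-concept ontology,
clustered toy embeddings, and a mention corpus with controllable surface
noise), so the whole pipeline runs without downloads:

```sh
ontonorm fixtures --seed 11 --n-mentions 40 --noise-sd 0.3 --ppp-rate 0.25 --out demo
ontonorm link --ontology demo/ontology.obo --embeddings demo/vectors.txt \
    --parses demo/parses.tsv --a1 demo/doc01.a1 --a1 demo/doc02.a1 \
    --a1 demo/doc03.a1 --a1 demo/doc04.a1 --a1 demo/doc05.a1 \
    --out demo/preds.tsv
ontonorm eval --mode bb --ontology demo/ontology.obo \
    --predictions demo/preds.tsv --a2 demo/doc01.a2 --a2 demo/doc02.a2 \
    --a2 demo/doc03.a2 --a2 demo/doc04.a2 --a2 demo/doc05.a2
ontonorm eval --mode exact --predictions demo/preds.tsv --gold-tsv demo/gold.tsv
```

prints

```
linked 40 mentions (0 fallbacks, 0 abstentions) -> demo/preds.tsv
ontology-aware precision: 0.962
                 precision    recall   f-score
micro-average        0.950     0.950     0.950
macro-average        0.950     0.950     0.950
documents: 5
```

38 of the 40 noisy mentions are linked to exactly the right concept
(micro precision 0.950); the two misses land on ontologically nearby
concepts, so the Wang-weighted precision (0.962) sits above the exact rate.
Each row of `preds.tsv` is
`doc_id  mention_id  mention_text  concept_id  score  fallback_flag`.

The same pipeline is available as a library (`ontonorm.link_mention`,
`ontonorm.build_term_index`, `ontonorm.wang_similarity`, ...); see
`docs/methods.md` for the model details and design choices.

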