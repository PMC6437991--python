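# Methods

## The normalization model

`ontonorm` treats entity normalization as nearest-concept search in a word
embedding space, corrected by syntax. The model has three stages.

**Phrase embedding.** A mention or ontology surface form is normalized by
lowercasing, stripping non-ASCII characters, splitting on every
non-alphanumeric character (so *"day-care"* yields *day* and *care*),
dropping empty tokens and stop words, and averaging the word vectors of the
tokens that are in vocabulary. Out-of-vocabulary tokens are skipped rather
than zero-filled; a phrase whose tokens are all out of vocabulary is routed
to a fallback (below). The packaged stop-word list is the classic 127-word
English list; any list can be substituted (one token per line). Splitting
happens before stop-word removal, but since stop words are single tokens
the order is immaterial.

**Semantic ranking.** Every concept contributes one index entry per surface
form (name and each synonym). A concept's score against a mention is the
maximum similarity over its entries, so a well-matching synonym is as good
as a well-matching name; the best surface is remembered for head
extraction. Ties are broken toward the smaller concept id so runs are
exactly reproducible. Cosine similarity is the default metric; word mover's
distance — the exact optimal-transport cost between the two uniform
token-vector distributions with Euclidean ground distance — is available as
an alternative and is solved exactly with a transportation LP (phrases have
a handful of tokens, so exactness is cheap). WMD ranks by ascending
distance; internally it is negated so one ordering rule serves both
metrics.

**Syntactic re-ranking.** The top k candidates are re-scored as

    S_RR(m, c) = w · cos(m_head, c_head) + (1 − w) · S(m, c),

a convex combination, so every re-ranked score lies between the phrase
similarity and the head similarity. The head of a phrase is the top-level
rightmost noun of its constituency parse: descend through unary wrappers to
the outermost NP; scan its immediate children right to left for a leaf
tagged NN/NNS/NNP/NNPS; otherwise recurse into the rightmost NP child;
otherwise take the NP's last token. Trees with no NP at all (e.g. a bare
adjective such as *"respiratory"*) fall back to the last token, and the
result is flagged so downstream code can tell. When either head is out of
vocabulary the candidate keeps its phrase score unchanged — a deliberately
conservative fallback that never punishes a candidate for a missing head
vector.

Parses are an input, not a dependency: they are supplied per mention in a
`doc_id:mention_id → bracketed parse` table (Penn Treebank notation, e.g.
from an off-the-shelf constituency parser). When a string has no parse, a
degenerate flat NP with every token tagged NN is synthesized, which makes
the head the last token — the correct answer for the right-headed compound
nouns that dominate this domain — and keeps the pipeline total.

**Possessive-PP stripping.** Mentions shaped `NP → [NP, PP(of, NP)]`
(punctuation ignored) carry their information in the left NP (*"throats of
two healthy children"* → *throats*); the rule fires before vector
composition, since it changes the tokens being embedded. It is applied only
at the top level of the parse: an *"of"* embedded deeper (e.g. *"children
less than 2 years of age"*) does not trigger it. The rule is idempotent and
never empties a mention.

**Fallbacks.** A mention that preprocesses to nothing or is entirely out of
vocabulary takes one of three configured routes: case-insensitive exact
string match against all surfaces and then the ontology root
(`exact_then_root`, the default), the root directly, or abstention. The
choice taken is recorded in the per-mention trace.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 5 | candidates kept for re-ranking |
| w | 0.25 | weight of the head-word similarity in S_RR |
| metric | cosine | semantic stage metric (cosine or wmd) |
| s | 0.65 | per-edge ancestor decay of the Wang similarity |

k = 5 and w = 0.25 are the values that performed best on the
bacteria-biotope development data and are kept as package defaults; both
are exposed in `LinkerConfig` and on the command line. The decay s = 0.65
is the value used by the official biotope-normalization evaluation.

## Wang similarity

Ancestor weights use the S-value with per-edge decay: weight(a) = max over
is_a paths of s^d, d the path length, so the concept itself has weight 1
and weights strictly decrease along a chain. The pairwise score is the
ratio of shared ancestor weights (counted from both sides) to the total
weight of both ancestor sets. This is the standard hierarchy-aware
formulation; the informal description of the evaluation measure as a
"Jaccard index with weight d^s" is read as this ratio, since a literal d^s
gives the concept itself weight 0 and does not decay with distance.
Multiple parents take the maximum over paths; multiple roots are allowed
(ancestor sets simply stop at parentless concepts).

## Evaluation

Ontology-aware precision is the mean, over predicted mentions, of the Wang
similarity between prediction and gold; a mention with several gold
referents is credited with the best-matching one. Exact scoring counts a
prediction correct when its concept id is in the mention's gold set; micro
scores pool TP/FP/FN over documents, macro scores average per-document
precision and recall, and every F-score is the harmonic mean of its
precision and recall (documents with zero denominators contribute 0 and
stay in the average). The harmonic-mean rule reproduces the published
macro P/R/F triples of the drug-reaction benchmark to their printed
rounding, which is how the aggregation choice was validated.

## The synthetic data generator

The fixture module emulates the structure of a normalization corpus, not
its language. A complete b-ary tree of concepts (default: branching 3,
depth 2, 13 concepts) gives every concept a name and 1–2 synonyms sharing
a distinctive token. Each concept owns a random unit base vector
(dimension 16 by default); a token's vector is the mean of the bases of
the concepts whose surfaces contain it, plus Gaussian noise of scale
`noise_sd`, so distinctive tokens sit on their concept's base and shared
tokens sit between concepts. Distractor vocabulary and filler words are
added so uninformative context has somewhere to point.

Mentions sample a concept and render one of its surfaces (a synonym with
probability `paraphrase_rate`). At `noise_sd = 0` the mention text is the
verbatim surface — the lexically easy regime in which the pipeline must be
perfect, and is (rank-1 accuracy and Wang precision both 1.0 on 200
mentions). At positive noise each mention token is realized as a
mention-specific variant whose vector is the term token's vector plus
fresh Gaussian noise: the corpus-side wording drifts away from the
ontology-side wording, which is precisely the surface-variety problem the
method exists to solve, and accuracy degrades smoothly and monotonically
with `noise_sd`. This is the one place the generator goes beyond verbatim
surfaces; without it, embedding noise would perturb mention and index
identically and ranking would stay trivially perfect at any noise level.
`ppp_rate` wraps mentions in an uninformative *"X of the ..."*
construction with a matching NP-PP(of)-NP parse; `oov_rate` replaces
mentions with out-of-vocabulary gibberish to exercise the fallbacks. All
randomness flows from one integer seed through independent named streams,
and every artifact can be written in the real external formats (OBO,
word2vec text, `.a1`/`.a2`, TSV) so parsers and algorithms are tested
together.

What passing on fixtures does *not* show: the toy embedding space is far
cleaner than distributional vectors trained on PubMed (real embeddings
conflate senses, and abbreviations or rare words are out of vocabulary in
systematic rather than random ways), ontology depth and fan-out are
uniform, and toy parses are flat except for the possessive construction.
Absolute fixture scores therefore say nothing about performance on real
corpora; the fixtures validate the machinery (ranking, re-ranking,
stripping, fallbacks, scoring), not the linguistic difficulty.

## Numerical and design notes

* Scores are compared as floats with exact sort order; determinism comes
  from the concept-id tie-break, not from tolerance fuzz. Two runs on the
  same inputs produce byte-identical prediction files.
* The transportation LP drops one redundant marginal constraint and runs
  the HiGHS solver; one-token sides short-circuit to a closed form.
* The word2vec binary reader follows the original little-endian float32
  layout, tolerating an optional newline between entries; duplicate tokens
  keep the last vector seen, in both text and binary formats.
* The OBO reader handles the `[Term]` stanza keys id, name, synonym
  (quoted part kept regardless of scope tag), is_a and is_obsolete;
  obsolete terms are dropped on load. Duplicate ids, dangling is_a targets
  and is_a cycles are load errors (cycles name a member). Other
  relationship types and OWL semantics are out of scope.
* Flat dictionaries are attached under a virtual root, which doubles as
  the fallback target and gives the Wang measure a well-defined (if
  shallow) hierarchy.
* Candidate lists keep one slot per concept (not per surface); the
  alternative — letting several surfaces of one concept occupy k slots —
  would waste re-ranking slots on duplicates.
* Problem sizes in the test suite and acceptance script (13–25 concept
  graphs, 200-mention corpora, 200-instance oracle sweeps) were chosen as
  the smallest sizes at which the checked properties are non-trivial and
  sampling noise is manageable.

## Known limitations

* No use of sentence context: identical mentions always link identically,
  so ambiguous abbreviations (e.g. *"ten"* for toxic epidermal necrolysis)
  cannot be disambiguated.
* Head extraction trusts the supplied parse; a wrong parse gives a wrong
  head, and the synthesized flat-NP fallback assumes right-headedness.
* The possessive-PP rule only fires on the exact top-level NP-PP(of)-NP
  shape; other uninformative modifiers are kept.
* Exact evaluation treats multi-referent gold mentions as satisfied by any
  one referent; the behaviour of official scorers on such mentions may
  differ.
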