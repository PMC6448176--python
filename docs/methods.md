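# Methods

This note records the model, the choices made where the design was open, and
what the synthetic experiments do and do not show.

## Model and procedure

A problem-list item is a pair (code, d): an optional ICD-10 code and a
free-text description of at most 50 characters.  Only the 3-character ICD-10
category (letter + two digits, e.g. `N17`) is ever used: topics are defined
at that level, codes with subcategories are truncated on load, and dialect
variation (dot or no dot, 0–2 subcategory characters) is accepted.

The pipeline is, per clustered group:

1. **Deduplication.**  Clustering operates on unique description strings
   (whitespace-trimmed, case-sensitive); each unique string is represented
   by its first item id and a multiplicity map re-expands clusters to items
   afterwards.  Identical entries therefore co-cluster by construction, and
   cut-off inference counts coded *items*, not unique strings, so duplicate
   coded entries contribute same-code pairs.
2. **Normalization.**  Tokenize on non-word characters → lowercase →
   stopword removal → Snowball German stemming → strip spans matching
   `[\d\.\,\_\:]+` (tokens fully consumed are dropped).  The strip step runs
   last so dates, dose numbers and similar context fragments vanish even
   when glued to words.  The stopword list is a small shipped German
   function-word list (one token per line, configurable); stemming uses the
   published Snowball German algorithm implemented in `problist.stemmer`
   (including the `niss` repair and the `syst`-protects-`em` exception),
   with umlauts preserved until the stemmer's own postlude removes the
   diacritics.
3. **Character 3-grams.**  Sliding windows inside tokens only — no
   cross-token grams, no boundary padding; tokens shorter than n are kept
   whole so clinically salient short forms ("CT", "Rez") survive.  n is
   configurable, default 3.
4. **tf-idf.**  Raw term frequency times smoothed idf
   ln((1+n)/(1+df)) + 1, columns L2-normalized (the scikit-learn
   `TfidfTransformer` convention).  Smoothing keeps idf positive for
   ubiquitous grams in tiny corpora; unit columns make cosine a dot
   product.  All-empty documents stay as zero columns (similarity 0 by
   convention) and are logged.
5. **Optional LSA.**  Full SVD, truncated to k = max(1, round(fraction ·
   min(m, n))) — the fraction is taken of the attainable rank, not of the
   vocabulary size.  Document representations are the columns of
   **S**ₖ**D**ᵀₖ, L2-normalized for cosine; zero singular values are
   trimmed.  Signs are fixed deterministically (largest-magnitude entry of
   each term vector made positive).  In reduced space cosine can leave
   [0, 1], so distances are clipped to [0, 1] to keep the UPGMA contract
   identical in both spaces.
6. **UPGMA** on cosine distances via `scipy.cluster.hierarchy.linkage
   (method="average")`.  Cutting at height h keeps merges with height ≤ h
   (closed boundary — stated explicitly because the grid lands exactly on
   two-decimal heights).
7. **Cut-off inference.**  Grid 0.00–1.00 inclusive, step 0.01
   (configurable); this two-decimal grid covers any two-decimal operating
   point exactly.  Score per height: pair-counting precision/recall/F over
   coded items (same category & co-clustered → TP, etc.), computed from the
   cluster × code contingency table.  Ties between equal-F heights break
   toward the smallest height — more, purer clusters, favoring precision
   over accidental merges.  Inference requires ≥ 2 coded items and at least
   one same-code pair (recall is undefined otherwise).  Pair counting is
   the label-free choice for "same code ⇒ same grouping"; a majority-map
   per-code F would be an alternative operationalization, and with the
   per-topic structure of the synthetic data the two coincide at the
   optimum.
8. **Post-coding.**  An uncoded item is coded iff its cluster contains a
   coded item; it inherits the category of its most similar coded neighbor
   *within the cluster* (the cluster-membership condition would be vacuous
   under global search).  Mixed-code clusters are resolved per item, not by
   majority.  Ties break toward the lexicographically smallest item id
   (logged at debug level — ties at similarity 1.0 are routine for
   duplicated strings).  Exactly one code per item; existing codes are
   never modified.
9. **Evaluation.**  Two protocols, kept apart: (a) *masked-code recovery* —
   per masked item TP/FP/FN/TN by comparing the assigned category with the
   hidden truth; (b) *pair-counting* cluster quality over all coded items.
   Compression rate = 1 − topics/items.  Per-patient rows are aggregated as
   unweighted means of two-decimal-rounded values (configurable via
   `summarize(round_to=...)`), mirroring how tabulated two-decimal values
   aggregate.  TN counts are computed but unused by precision/recall/F.
   The coded and clustered subset F values are reported separately; a
   combined figure, when needed, is the coded-fraction-weighted mean and is
   labeled as such.

Intra-patient mode clusters each patient independently; inter-patient mode
pools all items, then derives per-patient rows by restricting the pooled
partition and assignments to each patient's items (a patient's topic count
is the number of pooled clusters containing its items).

The Chernoff-bound sample size is n = ⌈(3/ε²)·ln(2/δ)⌉ with the natural
logarithm (ε = δ = 0.05 → 1200·ln 40 = 4426.67 → 4427); it is monotone
non-increasing in both parameters and independent of the pool size.

## Synthetic data: what it emulates, what it does not

The generator draws each item from one of 12 default 3-digit topics
(nephrology-flavored German phrases), picks one of ~3 surface variants per
topic (word reorderings, umlaut respellings like "Anämie"/"Anaemie",
deterministic short forms like "Chron.", "Rez."), optionally appends a
context fragment (dates, "Z.n.", episode markers — mostly consumed by the
strip pattern, as with real annotations), truncates to 50 characters, and
masks the code on 1 − coded_fraction of items (default 0.5).  Defaults are
5 patients × 200 items.  Random per-character typos and random word
truncation exist as operators (`NoiseConfig.heavy()`: typo 0.01/char,
abbreviation 0.05/item) but default to 0: a single typo in a short word can
erase most of its 3-grams, and the default conditions are chosen so that
topics remain *linearly separable* in gram space (every within-topic
distance below every between-topic distance).  `separability()` verifies
that gap explicitly; across seeds 0–39 it stays ≥ 0.07, comfortably above
the 0.01 grid step.

Under a positive gap, average linkage provably completes every topic before
any cross-topic merge, so some grid height reproduces the generating
partition exactly — this is what the parameter-recovery tests assert
(inferred pairwise F = 1.0, 100% masked-code recovery for items co-clustered
with a coded seed).  Passing them shows the chain is implemented correctly,
*not* that real problem lists are separable: real lists mix topics
lexically, contain wrong codes (the generator can inject these via
`wrong_code_rate`, default 0) and multi-topic expressions, and their
operating points are far from F = 1.  The `NoiseConfig.heavy()` preset is
the built-in way to study graceful degradation.

All randomness flows from one seed; per-patient substreams come from
`SeedSequence.spawn`, so enlarging the corpus never perturbs earlier
patients.

## Numerical choices and degenerate inputs

- Distance matrices are symmetrized ((D + Dᵀ)/2), clipped to [0, 1], zero
  diagonal; UPGMA validates symmetry (1e-10), non-negativity and the zero
  diagonal, and logs (never repairs) non-monotone merge sequences.
- Nearest-neighbor ties in post-coding use a 1e-12 similarity tolerance.
- Full-rank LSA reproduces vector-space similarities to 1e-8 (asserted in
  tests); the Eckart–Young tail bound is used as the SVD oracle.
- Rows without a description are rejected at load — they cannot be
  vectorized.  Descriptions over 50 characters are an error in strict mode
  and truncated (with a warning) in permissive mode.
- A clustered group needs ≥ 2 unique strings; a corpus needs ≥ 1 item.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
5 × 200-item synthetic corpus (≈ 300 unique strings pooled), 200 random
UPGMA oracle comparisons at n ≤ 12 and 200 pair-counting oracle comparisons
at n ≤ 30; the whole suite completes in a few seconds on one CPU.

## Known limitations

- One code per item; multi-topic expressions ("Akutes Nierenversagen mit
  Hyperkaliämie") are out of scope.
- No correction of wrong visible codes; post-coding trusts coded seeds.
- The stemmer implements the published Snowball German algorithm; any
  residual divergence from other Snowball ports is confined to the frozen
  fixtures in `tests/test_stemmer.py`.
- No unsupervised cut-off selection (Elbow/Silhouette); inference requires
  partial codes.
- German-only normalization; other languages would need their own stemmer
  and stopword list.
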