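# Methods

## The problem

Primary-care electronic health records attach free text to coded clinical
events. The codes are cheap to query but incomplete: a result or diagnosis
is often present only in the text (typed notes, scanned letters), and the
code attached to such a text may be non-specific. Manually reviewing tens
of thousands of texts to find, say, coronary angiogram results is
expensive. `textscm` learns, from *code-derived* labels only, a sparse set
of word-combination rules that flag the relevant texts — accepting that
the code-derived "positive" training set is noisy (a substantial fraction
of texts carrying the target code contain nothing of interest).

## Model

Every text is reduced to a set of lower-cased word stems; case,
punctuation, word order and repetition are discarded. A **feature** is a
non-empty set of stems; a text matches a feature iff it contains every
stem of it. Explicit feature vectors over all word subsets would be
exponentially large, so features exist only as containment queries.

Training data are three disjoint record sets: positives **P** (texts
carrying a target diagnostic code), negatives **N** (texts from control
patients or an external collection), and the unlabelled pool **U**
(remaining case-side texts). Manual-review labels, where present, are used
for evaluation only; the training path masks them.

**Candidate features** are all word combinations shared by at least two
positive texts, found by intersecting text pairs and enumerating subsets
of each intersection (up to `s_cap` stems, default 4 — enumeration is
otherwise exponential in the intersection size, and pairs whose
intersection exceeds `pair_intersection_limit` = 20 stems raise an error
when no cap is set).

**The set covering machine** greedily selects features by the penalized
score

    score(h) = |P_h| − p·|N_h| − q·|U_h|

where X_h is the set of *active* records of X matching h. Selecting h
deactivates the positive and unlabelled records it covers; negatives stay
active, so every later candidate keeps paying its full negative penalty
(removing them would progressively erase the penalty; a
`remove_matched_negatives` switch exposes the alternative reading).
Selection stops when no positive remains active, `M` rules have been
accepted, or the best score fails to exceed `min_score` (default 0,
strict). With q = 0 and U empty this is the classic fully supervised
objective. The learned classifier is a **disjunction** of the selected
rules, each rule a conjunction of stems: a record is positive iff at least
one selected word combination is contained in it.

Ties are broken deterministically: higher score, then fewer stems, then
more covered positives, then lexicographic canonical key — preferring
simpler, more general rules and making training reproducible byte for
byte.

**Semi-supervised bootstrap.** For T iterations (default 4): mine common
word sets over the current positive pool (labelled positives plus all
pseudo-positives so far) and append new ones to a cumulative candidate
pool; set the unlabelled penalty to the scale-free linear schedule

    q_t = q0 · (1 + q_growth · n_pseudo / |P|);

fit the machine on (P ∪ pseudo-positives, N, U \ pseudo-positives); then
promote every remaining unlabelled record the model classifies positive
into the pseudo-positive pool. Promotions are irrevocable. The growing
penalty counteracts the growing risk of false promotions as covering the
unlabelled pool gets easier. The returned model is the final iteration's
fit; unlabelled records are labelled positive iff promoted (or classified
positive by that final model).

### Parameters

| name | default | meaning |
|------|---------|---------|
| `p` | 1.0 | penalty weight per covered negative |
| `q0` | 0.2 | base penalty weight per covered unlabelled record |
| `q_growth` | 1.0 | linear growth of q per pseudo-positive, normalized by |P| |
| `M` | 50 | maximum rules per fit |
| `T` | 4 | bootstrap iterations (0 = supervised fit) |
| `s_cap` | 4 | maximum stems per mined feature |
| `min_score` | 0.0 | rules must score strictly above this |

`p`, `q0` and `q_growth` are dimensionless weights trading one covered
record of N or U against one covered positive. The defaults were
calibrated once on the synthetic corpus described below (the exact values
used in the motivating study are not recoverable): `q0` must be small
enough that a genuine general rule (which necessarily matches its
unlabelled true positives, pre-promotion) is not outscored by over-specific
combinations of the same signal stem with background stems, which match
almost no unlabelled records and thereby dodge the penalty; `q0 = 0.2`
with `q_growth = 1.0` achieves that on the fixture while still suppressing
indiscriminate promotion. The q-schedule's normalization by |P| makes the
escalation independent of corpus size. T = 4 follows the study's reported
setting; in the synthetic experiments promotions saturate by iteration 2–3.

### Numerical and algorithmic notes

- Greedy selection is exact at every step. Per-candidate counts are
  maintained incrementally — deactivating a record touches only the
  candidates matching it — and updated candidates re-enter a heap with a
  version stamp. A lazy-reevaluation heap is *not* sound here: scores are
  not monotone across steps, because covering unlabelled records shrinks
  the q-penalty of the features they share (that relief is exactly how
  promoted texts make letter-specific features attractive).
- Candidate match sets are computed once per run by posting-list
  intersection over the fixed record collection and reused across
  bootstrap iterations; mining is incremental (only new-by-old text pairs
  are intersected when the positive pool grows).
- Degenerate inputs: empty P refuses with a diagnostic; an empty candidate
  pool yields an empty model with a warning (an empty model predicts
  negative for everything); undefined evaluation ratios are reported as
  missing, never as 0 or 100.

## Preprocessing

Tokens are maximal `[a-z0-9]+` runs of the lower-cased text (numeric
tokens are kept — angiogram texts carry vessel counts), stemmed with a
Porter stemmer implemented in `textscm.stemming`. One extension to the
classic algorithm: the adjectival suffix `-ian` reduces to `-i` (measure
condition m > 1), so *ovarian*, *ovary* and *ovaries* all map to `ovari`;
plain Porter merges only the latter two. Stemming and an optional
stop-list are switchable. Deduplication on load keys on the
post-preprocessing token set within the same patient; whether real
extracts deduplicate across patients is unknowable from our side, and
within-patient is the conservative choice.

## Evaluation

Precision = positive predictive value, recall = sensitivity, both against
manual-review gold labels and reported as percentages rounded
half-away-from-zero to one decimal; F is the harmonic mean computed from
the unrounded ratios (2TP/(2TP+FP+FN)). Confidence intervals are 95%
Wilson score intervals (well-behaved at extreme proportions; computed via
statsmodels and cross-checked against the closed form in the tests).

The **leave-one-out** adaptation for semi-supervised learning demotes each
labelled positive to unlabelled in turn, retrains end to end, and counts
the held-out text as an error if its final label is not positive.

**Patient-level** detection calls a patient algorithm-detected iff any of
their records is predicted positive, code-detected iff any record carries
a positive code; earliest detection dates per method are the minimum event
date over qualifying records. Undated records count for detection but are
excluded from timing with a warning.

## Synthetic corpus

The generator emulates the structure — not the language — of code-labelled
primary-care text:

- **Background**: each text draws ~Poisson(11) tokens from a shifted-Zipf
  distribution over 600 pronounceable nonsense stems (clinical vocabulary
  is long-tailed). The stems are filtered to be stemmer-stable and
  disjoint from all signal stems, so ground truth is exact by
  construction.
- **Planted rules**: true-positive texts carry one core rule (a stem set,
  sampled by weight), plus a second with probability 0.35. The default
  angiogram task uses eight fragmented core rules (vessel, stent, graft,
  lad, coronari+arteri, occlud, stenosi, angiogram).
- **Label noise**: of the 199 code-labelled positives, exactly
  round(0.603·199) = 120 are true; the rest are decoys built from
  background plus 2–3 stems from a small administrative pool ("hospit",
  "admiss", "letter", …) that also seasons 8% of all background texts —
  so realistic decoy common sets exist and are penalized by N.
- **Hidden vocabulary**: latent rules occur only among unlabelled true
  positives — hospital-letter jargon that never reaches the code-labelled
  set. Their weight is a per-text prevalence (default: `cathet` at 0.9,
  `angioplasti` at 0.3), and 25% of unlabelled true positives are
  latent-only (no core rule at all). This makes the bootstrap's value
  measurable: the supervised learner structurally cannot reach latent-only
  texts, while after one round of promotion the high-prevalence marker
  becomes a high-support positive feature and is selected. A low-support
  hidden rule would never be selected, because each pseudo-positive is
  covered by the re-selected rule that promoted it before a weak feature
  gets a turn — prevalence, not mere presence, is what the covering order
  rewards.
- Patients, event dates and a designated positive code are generated so
  the patient-level and earliest-detection paths are exercisable; every
  case patient has at least one text.

What passing tests on this corpus do **not** show: robustness to negation,
misspellings, abbreviation ambiguity, or distribution shift between
labelled and unlabelled vocabulary beyond the planted structure. The
generator's separability also makes precision near-perfect, which real
text would not; the tested claims are therefore the structural ones
(oracle equivalence, recovery, the recall *ordering* between the
semi-supervised and supervised learners, determinism), not absolute
performance levels.

## Problem sizes used in the checks

Metric arithmetic and interval checks run on the published-scale counts
directly. The recall-gain experiment uses the full training-set shape
(|P| = 199, |U| = 1673, |N| = 3539) over 10 seeds; rule recovery uses
noise-free corpora of 240 positives / 300 unlabelled / 800 negatives over
10 seeds; the oracle-equivalence suites use hundreds of random instances
with vocabularies of ≤ 12 stems, where exhaustive enumeration is exact.

## Known limitations

- The bootstrap can entrench an early false promotion (promotions are
  irrevocable by design).
- Rules are pure conjunctions over stems; no negation, windows, or term
  weights.
- The q-schedule's exact published form is unavailable; the normalized
  linear form here is one reasonable reading and is exposed via
  `q_growth`.
- The LOO-CV retrains the full bootstrap per fold: O(|P|) full fits —
  usable for parameter tuning at hundreds of positives, not thousands.
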