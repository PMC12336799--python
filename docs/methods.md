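# Methods

## The harmonization problem

A radiotherapy structure set stores one free-text name per delineated
structure. Across clinics the same organ-at-risk appears under translations
(`Niere` for kidney), abbreviations (`li`, `re`, `bds`), locality notation
variants (`CervMyelum` vs `SpinalCord_Cerv`), plurality variants, and
misspellings. TG-263 defines a closed, case-sensitive target vocabulary.
Harmonization is therefore a classification task: map each observed raw
name either to exactly one standard name or to an explicit *no match*.

Two accuracies summarize performance. With distinct raw names
$u_1,\dots,u_m$ carrying multiplicities $w_i$ (occurrence counts in the
full dataset) and correctness indicators $c_i \in \{0,1\}$:

* unique accuracy $= \frac{1}{m}\sum_i c_i$
* overall accuracy $= \frac{\sum_i w_i c_i}{\sum_i w_i}$

Correctness is exact trimmed, case-sensitive string equality; the no-match
sentinel equals only itself. Case sensitivity is an interpretation — TG-263
prescribes exact capitalization, and a correctly capitalized but reordered
name (`Lacrimal_Gland_L`) still counts as an error — and is applied
consistently in scoring, deduplication, and label counting.

## Lexicon model

Each lexicon entry decomposes a standard name into a *concept* (shared by
all variants of one organ: `Kidney`, `Kidney_L`, `Kidney_R`, `Kidneys` are
one concept), a laterality (left/right/bilateral/none), an optional spatial
qualifier (`Cerv`, `Sup`, ...), a plurality, and per-language synonyms.
Loading validates uniqueness of standard names, unambiguity of synonyms
(each maps to exactly one concept), and left/right sibling pairing.

Concept resolution for arbitrary strings proceeds through exact membership,
a normalized form (umlaut transliteration, camel-case splitting, lowercase,
punctuation/digit stripping), the marker-stripped concept phrase, the
synonym table, token-order-insensitive and space-free variants, and
singular/plural spelling variants of the final word. Names that survive
none of these are *unresolvable* — a distinct outcome, not an error.

## Error taxonomy

Misassignments are classified by a deterministic first-match cascade:

1. prediction equals truth → no error;
2. prediction is the no-match sentinel → **no match**;
3. same concept but laterality or spatial qualifier differs →
   **laterality/locality** (left-vs-right and regional designations are one
   merged category, since both are spatial designation errors);
4. same concept but plurality differs → **plurality**;
5. same concept otherwise → **misspelling** (any same-concept,
   non-exact spelling, with no edit-distance bound);
6. otherwise (different concept or unresolvable prediction) → **wrong OAR**.

Two deliberate choices: the cascade order (locality before plurality before
misspelling) resolves compound errors consistently where human judgment
would be case-by-case; and bilateral laterality collapses to "unsided"
before comparison, so `Kidney` vs `Kidneys` is a plurality error (the
composite plural differs from the unsided singular only in number) while
`Lung_L` vs `Lungs` remains a laterality difference. Automating what is
otherwise a manual classification is itself a documented deviation: the
cascade makes the precedence explicit and reproducible.

## Mock backend

The default backend is a deterministic multilingual fuzzy matcher:
normalize → expand clinical abbreviations (data-driven table) → detect
laterality/bilateral/qualifier markers → score every lexicon concept
against the residual phrase → compose the standard name matching the
detected markers. Keys per concept are the normalized standard names
(markers stripped), their abbreviation-expanded variants, and all
synonyms. Key similarity is the maximum of whole-phrase normalized edit
similarity (via edlib) and a greedy token-overlap score (exact token 1.0,
prefix 0.9, edit similarity ≥ 0.8 accepted). The acceptance threshold
defaults to 0.75, chosen so every clean synthetic surface form clears it
while random strings do not; it is a constructor parameter, not a
hard-coded constant. Confidence is high for exact key hits, medium for
comfortable fuzzy hits (≥ threshold + 0.10), low near the threshold, and
predictions below threshold become no-match.

At temperature 0 the mock is a pure function of its input. At temperature
T > 0 it samples among above-threshold concepts with weight
$\propto e^{s/T}$ truncated to the smallest candidate prefix of cumulative
probability ≥ top-p; as top-p → 0 this reduces to the deterministic argmax.
Sampling is a pure function of (seed, input name, call index), so repeated
runs with one seed reproduce sample lists exactly.

## Uncertainty estimation

Self-reported confidence is coded low/medium (and missing, conservatively:
an unparseable reply should be reviewed) as 1, high as 0; errors as 1,
correct as 0; association is the phi coefficient, computed from the 2×2
table as $(ad-bc)/\sqrt{(a{+}b)(c{+}d)(a{+}c)(b{+}d)}$, which equals the
Pearson correlation of the 0/1 vectors. Any zero margin makes phi
undefined; it is reported as NaN with a degenerate flag rather than 0.

Monte-Carlo uncertainty repeats inference k = 10 times per structure at
temperature 1 with top-p 0.95 and computes the Shannon entropy
$H = -\sum_i p_i \ln p_i$ over the relative frequencies of distinct
sampled labels (whitespace-trimmed, case-sensitive, no-match being a legal
label). Entropy is reported in nats; the base is a convention the H > 0
flag does not depend on. Numerically, H is evaluated in the counts form
$\ln k - \frac{1}{k}\sum_i c_i \ln c_i$ with the single-label case returned
as exactly 0.0, making the boundary cases (H = 0, H = ln n for uniform
samples) exact in floating point. The uncertainty flag is implemented as
"≥ 2 distinct labels", which is equivalent to H > 0 without a floating
tolerance.

The entropy flag is then scored as a binary classifier of errors: condition
positive = the *temperature-0* prediction is incorrect (the deterministic
run is taken as the reference, not the majority sampled label); test
positive = H > 0. Sensitivity is computed over incorrect records,
specificity over correct ones, and phi on the indicator pair. Incomplete
sample sets (backend failures) are excluded and reported rather than
imputed.

## Synthetic data generator

The generator emulates the statistical structure of a multi-center
clinical corpus: per distinct name it draws a language (defaults en 0.2,
de 0.4, nl 0.4 — German and Dutch dominate a central-European multi-center
pool), a corruption operator (defaults: translate 0.25, abbreviate 0.20,
laterality notation 0.15, plurality notation 0.10, misspell 0.10,
case/separator 0.10, no-op 0.10), a compatible lexicon entry, and a
multiplicity from a Zipf(1.8) distribution truncated at 200, so a few
frequent names dominate the full dataset and frequent-name failures
visibly separate overall from unique accuracy. Centers follow language
(German → C, Dutch → A/B, English → any), mimicking center-specific
conventions. Operators change notation, never meaning: every record keeps
its true TG-263 label and its operator trace. All randomness flows through
one seeded generator per corpus.

The operators are intentionally the inverses of the mock backend's
normalization steps: a no-op corpus is recovered perfectly, while raising
the misspelling rate sweeps accuracy downward — a controlled difficulty
dial for tests. What the generator does **not** emulate: genuinely
ambiguous clinical names, organ names absent from the lexicon,
free-text comments, and center-specific abbreviation inventories beyond
the bundled illustrative table. Passing tests therefore demonstrate the
pipeline's correctness and calibration machinery, not clinical-grade
renaming accuracy on real structure sets.

The simulated backend is the measurement double: per item its
temperature-0 answer is wrong with programmed probability ε, wrong answers
are constructed from lexicon structure to belong to a configured taxonomy
category (sided names get their mirrored sibling, plurals their singular
sibling or a textual plural of the concept token, misspellings a
case-mangled form, and so on), and in sampling mode each inference deviates
from the modal answer with probability `variability_wrong` or
`variability_correct` (defaults 0.5 / 0.0 — two rates, so sampling
variability can be confined to erroneous items, which is what makes exact
specificity checks possible). Everything is a pure function of (seed, item
name, sample index).

## Problem sizes and numerical choices

The test suite and the acceptance script use corpora of 300–3,000 records,
2,000-item error-recovery cohorts, a 30-item (15 correct + 15 incorrect)
entropy cohort with k = 10, and 10,000-draw frequency checks — sizes at
which binomial three-standard-error bands are tight enough to detect real
miscalibration while the whole suite runs in seconds. Exclusion-rule
regexes are case-insensitive and first-match-wins; deduplication sorts by
descending multiplicity then name for stable output; report files contain
no timestamps, so seeded runs are byte-identical.

## Known limitations

* The bundled lexicon is a curated subset (~100 entries); real deployments
  should load the full TG-263 list in the documented TSV format.
* The plurality heuristic for names outside the lexicon relies on terminal
  "s" with a Latin-term exception list; exotic plural forms may classify as
  misspellings.
* The mock backend resolves only what the lexicon's synonym and
  abbreviation tables cover; it is a testable stand-in with the same
  interface as an LLM backend, not a clinical renaming model.
* The remote chat backend is exercised against an injected transport in
  tests; live endpoint behavior (rate limits, streaming) is untested here.
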