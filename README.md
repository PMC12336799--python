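# tg263harm

Radiotherapy structure sets name the same organ-at-risk (OAR) in wildly
different ways across clinics — `Niere bds`, `CervMyelum`, `Traenendruese
li.` — while the AAPM TG-263 report prescribes one standardized spelling for
each structure (`Kidneys`, `SpinalCord_Cerv`, `Glnd_Lacrimal_L`).
**tg263harm** is a library and CLI for harmonizing such center-specific,
multilingual (English/German/Dutch) OAR names to TG-263 via a pluggable
renaming backend, and for rigorously evaluating how well any backend does
it. It is aimed at medical-physics and radiation-oncology informatics groups
curating multi-institutional datasets.

## What it does

* **Nomenclature model** — a validated TG-263 lexicon (a curated ~100-entry
  subset ships with the package; the format is a plain TSV so the complete
  list can be dropped in) with per-entry concept identity, laterality,
  spatial qualifier, plurality, and multilingual synonyms.
* **Ingest** — ROI-name extraction from DICOM RT Structure Sets (metadata
  only, no contours), transparent pattern-based exclusion of target volumes
  and auxiliary planning structures, and deduplication into a unique-name
  view with multiplicities.
* **Harmonization** — a five-part renaming prompt (task instructions,
  language/abbreviation rules with a "no match" escape, output-format and
  confidence rules, few-shot examples, the TG-263 name list plus one input
  name), dispatched to a backend. A deterministic multilingual
  fuzzy-matching **mock backend** is the offline default; a chat-completion
  HTTP backend connects to locally hosted LLMs. Replies follow the grammar
  `name: <X> | confidence: <low|medium|high>`; chain-of-thought preamble is
  stripped by taking the last well-formed block.
* **Evaluation** — *unique accuracy* (fraction of distinct names renamed
  exactly) and *overall accuracy* (multiplicity-weighted), per center and
  pooled, plus a deterministic five-category error taxonomy: wrong OAR,
  laterality/locality, plurality, misspelling, no-match.
* **Uncertainty** — phi (binary Pearson) correlation between low
  self-reported confidence and errors, and Monte-Carlo sampling
  uncertainty: k repeated inferences at temperature 1 / top-p 0.95, Shannon
  entropy H = −Σ pᵢ ln pᵢ of the predicted-label distribution, and the
  H > 0 flag evaluated as an error classifier (phi, sensitivity,
  specificity).
* **Synthetic data** — a seeded generator that corrupts TG-263 names by
  translation, abbreviation, laterality-notation change, plurality change,
  misspelling, and casing drift, with heavy-tailed duplication, so the whole
  stack is testable without clinical data; plus a simulated backend with
  programmed error rate, error-category mix, and sampling variability.

## Worked example

```bash
tg263harm simulate --out sim --size 300 --seed 5
# 300 records over 60 unique names
tg263harm rename --names sim/unique.tsv --out ren --backend mock
# 60 predictions written (0 resumed)
tg263harm evaluate --names sim/unique.tsv --predictions ren/predictions.tsv --out ev
# unique accuracy 1.000, overall accuracy 1.000
tg263harm uncertainty --names sim/unique.tsv --out unc --backend simulated --k 10 --seed 3
# uncertainty written for 60 structures
```

The simulated corpus of 300 name instances collapses to 60 distinct names;
the mock backend inverts every corruption in this run, so both accuracies
are 1.000 (`ev/report.json` also carries the per-center breakdown and the
error histogram, empty here). The uncertainty run (`unc/metrics.json`)
reports the entropy flag's phi = 1.0, sensitivity = 1.0, specificity = 1.0
on this seed: the simulated backend was configured so only erroneous items
vary across samples, and the entropy flag finds exactly those.

From Python:

```python
from tg263harm import load_bundled_lexicon, MockBackend, BackendConfig

lexicon = load_bundled_lexicon()
backend = MockBackend(lexicon)
backend.predict("Niere bds", BackendConfig()).predicted_name   # 'Kidneys'
backend.predict("CervMyelum", BackendConfig()).predicted_name  # 'SpinalCord_Cerv'
```

## Scope notes

The package renames OARs only: target volumes and planning structures are
excluded at ingest, DICOM files are never written back, and no anatomical
ontology reasoning is performed — concept identity is lexicon-declared.
Actual LLM weights, quantization, and inference engines are out of scope;
any backend speaking the chat-completion protocol and reply grammar can be
plugged in.
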