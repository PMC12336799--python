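"""Synthetic multilingual structure-name corpora and simulated backends.

Real clinical structure sets contain center-specific names in English,
German, and Dutch that diverge from TG-263 by translation, abbreviation,
laterality-notation changes, plurality changes, misspellings, and casing or
separator drift, and the same name recurs across many patients with a
heavy-tailed frequency distribution (a corpus of tens of thousands of
instances collapsing to roughly a thousand distinct names). This module
emulates that structure from the lexicon itself, labeling every generated
record with its true TG-263 name and the corruption-operator sequence that
produced it — so every pipeline stage can be tested, end to end, without
clinical data.

The corruption operators are deliberately the inverse of the mock backend's
normalization steps: a no-op corpus is perfectly recoverable, while raising
misspelling rates sweeps accuracy downward in a controlled way.

:class:`SimulatedBackend` is a seeded test double for an LLM backend with a
programmed per-item error rate, error-category mix, and sampling
variability; it is what makes error-rate recovery and the Monte-Carlo
entropy experiment exactly checkable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .harmonize import BackendConfig, Confidence, Prediction, render_response
from .ingest import RawStructure
from .nomenclature import (
    NO_MATCH,
    Laterality,
    Lexicon,
    Plurality,
    TG263Entry,
)

__all__ = [
    "CorruptionConfig",
    "SimulatedBackendConfig",
    "generate_corpus",
    "apply_operator",
    "SimulatedBackend",
    "OPERATORS",
]

OPERATORS = (
    "noop",
    "translate",
    "abbreviate",
    "laterality",
    "plurality",
    "misspell",
    "case",
)

_LAT_WORDS = {
    "left": {"en": "left", "de": "links", "nl": "links"},
    "right": {"en": "right", "de": "rechts", "nl": "rechts"},
    "bilateral": {"en": "both", "de": "beidseits", "nl": "beide"},
}
_REVERSE_ABBREV = {
    "links": "li.",
    "rechts": "re.",
    "left": "lt",
    "right": "rt",
    "beidseits": "bds",
    "both": "bds",
    "beide": "bds",
}
_LAT_NOTATIONS = {
    "en": {"left": [" left", " L", "-L", " lt"], "right": [" right", " R", "-R", " rt"]},
    "de": {"left": [" links", " li", " li."], "right": [" rechts", " re", " re."]},
    "nl": {"left": [" links", " li", " li."], "right": [" rechts", " re", " re."]},
}
_CENTERS_BY_LANG = {"de": ("C",), "nl": ("A", "B"), "en": ("A", "B", "C")}


def _normalize_probs(mix: dict, what: str) -> dict:
    total = sum(mix.values())
    if total <= 0 or any(v < 0 for v in mix.values()):
        raise ConfigurationError(f"{what} probabilities must be non-negative with positive sum")
    return {k: v / total for k, v in mix.items()}


@dataclass(frozen=True)
class CorruptionConfig:
    """How the generator corrupts TG-263 names into center-specific forms.

    ``language_mix`` weights en/de/nl; ``operator_rates`` weights the
    corruption operators (one primary operator is drawn per distinct name);
    multiplicities are drawn from a truncated Zipf so a few names dominate
    the full dataset, as in real structure-set collections.
    """

    language_mix: dict = field(
        default_factory=lambda: {"en": 0.2, "de": 0.4, "nl": 0.4}
    )
    operator_rates: dict = field(
        default_factory=lambda: {
            "noop": 0.10,
            "translate": 0.25,
            "abbreviate": 0.20,
            "laterality": 0.15,
            "plurality": 0.10,
            "misspell": 0.10,
            "case": 0.10,
        }
    )
    mult_kind: str = "zipf"  # "zipf" or "fixed"
    mult_a: float = 1.8
    mult_max: int = 200
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "language_mix", _normalize_probs(dict(self.language_mix), "language_mix")
        )
        rates = dict(self.operator_rates)
        unknown = set(rates) - set(OPERATORS)
        if unknown:
            raise ConfigurationError(f"unknown operators: {sorted(unknown)}")
        object.__setattr__(
            self, "operator_rates", _normalize_probs(rates, "operator_rates")
        )


# -- operator implementations ----------------------------------------------


def _concept_base_synonyms(entry: TG263Entry, lexicon: Lexicon, lang: str) -> list[str]:
    """Singular-form synonyms of the entry's concept in *lang*."""
    pool = []
    for sibling in lexicon.concept_entries(entry.concept_id):
        if sibling.plurality is Plurality.SINGULAR:
            pool.extend(sibling.synonyms_for(lang))
    return pool


def _translate_phrase(
    entry: TG263Entry, lexicon: Lexicon, lang: str, rng: np.random.Generator
) -> str:
    """Common-language surface form of *entry*, markers included."""
    own = entry.synonyms_for(lang)
    if own:
        phrase = own[int(rng.integers(len(own)))]
        needs_qualifier = False
        needs_plural_marker = False
    else:
        pool = _concept_base_synonyms(entry, lexicon, lang)
        if not pool:
            raise ConfigurationError(
                f"lexicon has no {lang!r} synonyms for concept {entry.concept_id!r}"
            )
        phrase = pool[int(rng.integers(len(pool)))]
        needs_qualifier = entry.spatial_qualifier is not None
        needs_plural_marker = entry.plurality is Plurality.PLURAL
    parts = [phrase]
    if needs_qualifier:
        parts.append(entry.spatial_qualifier.lower())
    if entry.laterality is Laterality.LEFT:
        parts.append(_LAT_WORDS["left"][lang])
    elif entry.laterality is Laterality.RIGHT:
        parts.append(_LAT_WORDS["right"][lang])
    elif needs_plural_marker or entry.laterality is Laterality.BILATERAL:
        parts.append(_LAT_WORDS["bilateral"][lang])
    text = " ".join(parts)
    return text[0].upper() + text[1:]


def _misspell(text: str, rng: np.random.Generator) -> tuple[str, int]:
    n_edits = 1 + int(rng.random() < 0.3)
    chars = list(text)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(n_edits):
        positions = [i for i, ch in enumerate(chars) if ch.isalpha()]
        if not positions:
            break
        i = positions[int(rng.integers(len(positions)))]
        op = int(rng.integers(3))
        if op == 0:  # substitute
            chars[i] = alphabet[int(rng.integers(26))]
        elif op == 1:  # delete
            del chars[i]
        else:  # insert
            chars.insert(i, alphabet[int(rng.integers(26))])
    return "".join(chars), n_edits


def apply_operator(
    entry: TG263Entry,
    operator: str,
    lang: str,
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> tuple[str, tuple[str, ...]]:
    """Produce a corrupted surface form of *entry* and its operator trace.

    The true label is always ``entry.standard_name``: operators change
    notation, never meaning.
    """
    name = entry.standard_name
    if operator == "noop":
        return name, ("noop",)
    if operator == "case":
        variants = [name.lower(), name.upper(), name.replace("_", " "), name.replace("_", " ").lower()]
        return variants[int(rng.integers(len(variants)))], ("case",)
    if operator == "translate":
        return _translate_phrase(entry, lexicon, lang, rng), ("translate", f"lang:{lang}")
    if operator == "abbreviate":
        text = _translate_phrase(entry, lexicon, lang, rng)
        tokens = [
            _REVERSE_ABBREV.get(tok.lower(), tok) for tok in text.split()
        ]
        return " ".join(tokens), ("abbreviate", f"lang:{lang}")
    if operator == "laterality":
        if entry.laterality not in (Laterality.LEFT, Laterality.RIGHT):
            raise ConfigurationError(f"{name!r} has no left/right laterality token")
        side = "left" if entry.laterality is Laterality.LEFT else "right"
        notations = _LAT_NOTATIONS[lang][side]
        suffix = notations[int(rng.integers(len(notations)))]
        return name[:-2] + suffix, ("laterality", f"lang:{lang}")
    if operator == "plurality":
        if entry.plurality is not Plurality.PLURAL:
            raise ConfigurationError(f"{name!r} is not a plural entry")
        pool = _concept_base_synonyms(entry, lexicon, lang)
        if not pool:
            raise ConfigurationError(
                f"lexicon has no singular {lang!r} synonym for {entry.concept_id!r}"
            )
        phrase = pool[int(rng.integers(len(pool)))]
        marker_full = _LAT_WORDS["bilateral"][lang]
        marker = marker_full if rng.random() < 0.5 else _REVERSE_ABBREV[marker_full]
        text = f"{phrase} {marker}"
        return text[0].upper() + text[1:], ("plurality", f"lang:{lang}")
    if operator == "misspell":
        text = _translate_phrase(entry, lexicon, lang, rng)
        corrupted, n_edits = _misspell(text, rng)
        return corrupted, ("misspell", f"lang:{lang}", f"edits:{n_edits}")
    raise ConfigurationError(f"unknown operator {operator!r}")


def _compatible(entry: TG263Entry, operator: str, lang: str, lexicon: Lexicon) -> bool:
    if operator in ("noop", "case"):
        return True
    if operator == "laterality":
        return entry.laterality in (Laterality.LEFT, Laterality.RIGHT)
    if operator == "plurality":
        return entry.plurality is Plurality.PLURAL and bool(
            _concept_base_synonyms(entry, lexicon, lang)
        )
    # translate / abbreviate / misspell need a surface form in *lang*
    return bool(entry.synonyms_for(lang)) or bool(
        _concept_base_synonyms(entry, lexicon, lang)
    )


# -- corpus generation ------------------------------------------------------


def generate_corpus(
    lexicon: Lexicon,
    size: int,
    config: Optional[CorruptionConfig] = None,
) -> list[RawStructure]:
    """Generate *size* labeled records emulating a multi-center corpus.

    Each distinct generated name carries its true TG-263 label and operator
    provenance and is duplicated according to the configured multiplicity
    distribution; the output is fully determined by ``config.seed``.
    """
    if config is None:
        config = CorruptionConfig()
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    langs = sorted(config.language_mix)
    lang_p = np.array([config.language_mix[l] for l in langs])
    ops = sorted(config.operator_rates)
    op_p = np.array([config.operator_rates[o] for o in ops])

    compat_cache: dict[tuple[str, str], list[TG263Entry]] = {}

    def compatible_entries(operator: str, lang: str) -> list[TG263Entry]:
        key = (operator, lang)
        if key not in compat_cache:
            compat_cache[key] = [
                e for e in lexicon.entries if _compatible(e, operator, lang, lexicon)
            ]
        return compat_cache[key]

    for lang in langs:
        if config.language_mix[lang] > 0 and not compatible_entries("translate", lang):
            raise ConfigurationError(f"lexicon has no synonyms for language {lang!r}")

    records: list[RawStructure] = []
    while len(records) < size:
        lang = langs[int(rng.choice(len(langs), p=lang_p))]
        operator = ops[int(rng.choice(len(ops), p=op_p))]
        candidates = compatible_entries(operator, lang)
        if not candidates:
            continue
        entry = candidates[int(rng.integers(len(candidates)))]
        raw_name, trace = apply_operator(entry, operator, lang, lexicon, rng)
        if config.mult_kind == "fixed":
            mult = 1
        else:
            mult = min(int(rng.zipf(config.mult_a)), config.mult_max)
        mult = min(mult, size - len(records))
        centers = _CENTERS_BY_LANG[lang]
        center = centers[int(rng.integers(len(centers)))]
        record = RawStructure(
            raw_name=raw_name,
            center_id=center,
            language_hint=lang,
            ground_truth=entry.standard_name,
            operators=trace,
        )
        records.extend([record] * mult)
    return records


# -- simulated backend ------------------------------------------------------


@dataclass(frozen=True)
class SimulatedBackendConfig:
    """Programmed behavior of the simulated renaming backend.

    ``error_rate`` is the probability that an item's modal (temperature-0)
    answer is wrong; ``category_mix`` chooses which error taxonomy class a
    wrong answer belongs to. In sampling mode each inference independently
    deviates from the modal answer with probability ``variability_wrong``
    (items whose modal answer is wrong) or ``variability_correct`` (items
    whose modal answer is right); the split exists so that sampling
    variability can be confined to erroneous items.
    """

    error_rate: float = 0.1
    category_mix: dict = field(
        default_factory=lambda: {
            "wrong_oar": 0.2,
            "laterality_or_locality": 0.2,
            "plurality": 0.2,
            "misspelling": 0.2,
            "no_match": 0.2,
        }
    )
    variability_wrong: float = 0.5
    variability_correct: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.error_rate <= 1):
            raise ConfigurationError("error_rate must lie in [0, 1]")
        for rate in (self.variability_wrong, self.variability_correct):
            if not (0 <= rate <= 1):
                raise ConfigurationError("variability rates must lie in [0, 1]")
        object.__setattr__(
            self, "category_mix", _normalize_probs(dict(self.category_mix), "category_mix")
        )


class SimulatedBackend:
    """Seeded test double conforming to the backend contract.

    At temperature 0 each item deterministically gets its modal answer: the
    ground truth with probability 1 - error_rate, otherwise a wrong answer
    constructed from the lexicon to belong to the configured error category.
    At temperature > 0 each inference independently deviates from the modal
    answer with the configured variability rate. All behavior is a pure
    function of (config seed, raw name, sample index).
    """

    backend_id = "simulated"

    def __init__(
        self,
        ground_truth: dict[str, str],
        lexicon: Lexicon,
        config: Optional[SimulatedBackendConfig] = None,
    ):
        self.ground_truth = dict(ground_truth)
        self.lexicon = lexicon
        self.config = config if config is not None else SimulatedBackendConfig()
        self._calls: dict[str, int] = {}
        self._categories = sorted(self.config.category_mix)
        self._category_p = np.array(
            [self.config.category_mix[c] for c in self._categories]
        )

    def _item_rng(self, name: str, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.config.seed & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8")), stream]
        )

    def modal_answer(self, name: str) -> tuple[str, Confidence]:
        gt = self.ground_truth[name]
        rng = self._item_rng(name, 0)
        if rng.random() < self.config.error_rate:
            category = self._categories[
                int(rng.choice(len(self._categories), p=self._category_p))
            ]
            label = self._wrong_label(gt, category, rng)
            confidence = _draw_confidence(rng, [0.5, 0.35, 0.15])  # low/med/high
        else:
            label = gt
            confidence = _draw_confidence(rng, [0.02, 0.13, 0.85])
        return label, confidence

    def _wrong_label(self, gt: str, category: str, rng: np.random.Generator) -> str:
        entry = self.lexicon.get(gt)
        if category == "no_match" or entry is None:
            return NO_MATCH
        if category == "wrong_oar":
            others = [
                n
                for n in self.lexicon.standard_names
                if self.lexicon.get(n).concept_id != entry.concept_id
            ]
            return others[int(rng.integers(len(others)))]
        siblings = [
            s
            for s in self.lexicon.concept_entries(entry.concept_id)
            if s.standard_name != gt
        ]
        if category == "laterality_or_locality":
            if entry.laterality is Laterality.LEFT:
                return gt[:-2] + "_R"
            if entry.laterality is Laterality.RIGHT:
                return gt[:-2] + "_L"
            for s in siblings:
                if (
                    s.spatial_qualifier != entry.spatial_qualifier
                    and s.plurality is entry.plurality
                    and _collapse(s.laterality) is _collapse(entry.laterality)
                ):
                    return s.standard_name
            return gt + "_Sup"
        if category == "plurality":
            for s in siblings:
                if (
                    s.plurality is not entry.plurality
                    and _collapse(s.laterality) is _collapse(entry.laterality)
                    and s.spatial_qualifier == entry.spatial_qualifier
                ):
                    return s.standard_name
            if entry.plurality is Plurality.PLURAL:
                return gt[:-1] if gt.endswith("s") else gt
            return _pluralize_name(gt, self.lexicon)
        # misspelling: correct concept, wrong TG-263 spelling
        return gt.lower() if gt.lower() != gt else gt.upper()

    def _deviation(self, name: str, modal: str, rng: np.random.Generator) -> str:
        gt = self.ground_truth[name]
        names = self.lexicon.standard_names
        pool = [NO_MATCH, gt] + [
            names[int(rng.integers(len(names)))] for _ in range(3)
        ]
        pool = [p for p in pool if p != modal]
        return pool[int(rng.integers(len(pool)))]

    def predict(self, name: str, config: BackendConfig) -> Prediction:
        name = name.strip()
        if name not in self.ground_truth:
            raise ConfigurationError(f"simulated backend has no ground truth for {name!r}")
        modal, confidence = self.modal_answer(name)
        label = modal
        if config.temperature > 0:
            index = self._calls.get(name, 0)
            self._calls[name] = index + 1
            rng = self._item_rng(name, 1 + index)
            gt = self.ground_truth[name]
            rate = (
                self.config.variability_wrong
                if modal != gt
                else self.config.variability_correct
            )
            if rng.random() < rate:
                label = self._deviation(name, modal, rng)
        return Prediction(
            predicted_name=label,
            confidence=confidence,
            raw_response=render_response(label, confidence),
            backend_id=self.backend_id,
        )


def _collapse(lat: Laterality) -> Laterality:
    return Laterality.NONE if lat is Laterality.BILATERAL else lat


def _pluralize_name(name: str, lexicon: Lexicon) -> str:
    """Pluralize the final concept token, leaving laterality/qualifier
    suffix tokens (``_L``, ``_Cerv``) in place."""
    tokens = name.split("_")
    qualifiers = lexicon.qualifier_tokens()
    idx = len(tokens) - 1
    while idx > 0 and (tokens[idx].lower() in {"l", "r"} or tokens[idx].lower() in qualifiers):
        idx -= 1
    tok = tokens[idx]
    tokens[idx] = tok + ("es" if tok.lower().endswith("s") else "s")
    return "_".join(tokens)


def _draw_confidence(rng: np.random.Generator, probs: Sequence[float]) -> Confidence:
    levels = (Confidence.LOW, Confidence.MEDIUM, Confidence.HIGH)
    return levels[int(rng.choice(3, p=np.array(probs) / sum(probs)))]
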