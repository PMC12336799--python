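"""Prompt construction, backend dispatch, and reply parsing.

The renaming task is phrased as a five-part prompt: (1) general task
instructions, (2) language/abbreviation/locality rules including the
"no match" escape, (3) output-format and confidence-level rules, (4) few-shot
input/output examples, and (5) the list of allowed TG-263 names together with
exactly one input structure name. Backends are pluggable: a deterministic
multilingual fuzzy-matching mock (the offline default) and a remote
chat-completion endpoint share one contract, so the evaluation and
uncertainty stages are backend-agnostic.

Backend replies follow a machine-parseable grammar::

    name: <TG-263 name or "No match"> | confidence: <low|medium|high>

Reasoning backends may emit chain-of-thought text first; the parser takes the
last well-formed structured block.
"""

from __future__ import annotations

import re
import string
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import BackendError, ConfigurationError, TemplateError
from .ingest import UniqueName
from .nomenclature import (
    BILATERAL_MARKERS,
    LEFT_MARKERS,
    NO_MATCH,
    RIGHT_MARKERS,
    Laterality,
    Lexicon,
    Plurality,
    canonical_label,
    normalize_text,
)

__all__ = [
    "Confidence",
    "Prediction",
    "BackendConfig",
    "PromptSpec",
    "Backend",
    "build_prompt",
    "parse_response",
    "render_response",
    "MockBackend",
    "RemoteChatBackend",
    "rename_batch",
    "load_default_template",
    "load_default_fewshot",
]


class Confidence(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    MISSING = "missing"


@dataclass(frozen=True)
class Prediction:
    """Structured backend output for one input name."""

    predicted_name: str  # a TG-263 name or the NO_MATCH sentinel
    confidence: Confidence
    raw_response: str
    backend_id: str
    parse_failed: bool = False
    error: Optional[str] = None

    def __post_init__(self):
        if self.predicted_name != NO_MATCH and not self.predicted_name.strip():
            raise ValueError("predicted_name must be NO_MATCH or non-empty")


@dataclass(frozen=True)
class BackendConfig:
    """Sampling and transport parameters shared by all backends.

    temperature 0 means fully deterministic output (greedy decoding for
    LLMs, argmax for the mock); temperature 1 with top_p 0.95 reproduces the
    Monte-Carlo sampling regime used for uncertainty estimation.
    """

    temperature: float = 0.0
    top_p: float = 0.95
    kind: str = "mock"
    endpoint: Optional[str] = None
    model: Optional[str] = None
    seed: int = 0
    timeout: float = 60.0
    max_retries: int = 2

    def __post_init__(self):
        if self.temperature < 0:
            raise ConfigurationError("temperature must be non-negative")
        if not (0 < self.top_p <= 1):
            raise ConfigurationError("top_p must lie in (0, 1]")


class Backend(Protocol):
    backend_id: str

    def predict(self, name: str, config: BackendConfig) -> Prediction: ...


# -- prompt ----------------------------------------------------------------

DEFAULT_INSTRUCTIONS = (
    "You harmonize radiotherapy structure names. Rename the given input "
    "structure name to the single best-matching standardized TG-263 "
    "structure name from the list below. The input is an organ-at-risk name "
    "as used clinically at one treatment center."
)
DEFAULT_LANGUAGE_RULES = (
    "Input names may be written in English, German, or Dutch, may use "
    "center-specific abbreviations (e.g. 'li'/'re' for links/rechts, 'bds' "
    "for beidseits/bilateral), and may carry anatomical locality indicators "
    "(left, right, superior, inferior, cervical). Resolve these before "
    "matching. If no suitable TG-263 structure name exists, reply with "
    "'no match'."
)
DEFAULT_OUTPUT_FORMAT_RULES = (
    "Answer with exactly one line of the form "
    "'name: <TG-263 name or No match> | confidence: <low|medium|high>'. "
    "The confidence level expresses how certain you are of the match."
)

_REQUIRED_PLACEHOLDERS = {
    "instructions",
    "language_rules",
    "output_format_rules",
    "fewshot_examples",
    "tg263_names",
    "input_name",
}


@dataclass(frozen=True)
class PromptSpec:
    """The five prompt parts plus the single input name they wrap."""

    instructions: str
    language_rules: str
    output_format_rules: str
    fewshot_examples: tuple[tuple[str, str], ...]
    tg263_names: tuple[str, ...]
    input_name: str

    def __post_init__(self):
        if not self.tg263_names:
            raise ConfigurationError("tg263_names must be non-empty")
        if not self.input_name.strip():
            raise ConfigurationError("input_name must be non-empty")


def load_default_template() -> str:
    return (resources.files("tg263harm.data") / "prompt_template.txt").read_text(
        encoding="utf-8"
    )


def load_default_fewshot() -> tuple[tuple[str, str], ...]:
    path = resources.files("tg263harm.data") / "fewshot_examples.tsv"
    frame = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    return tuple(zip(frame["input"], frame["expected"]))


def build_prompt(
    name: str,
    lexicon: Lexicon,
    template: Optional[str] = None,
    fewshot: Optional[Sequence[tuple[str, str]]] = None,
    instructions: str = DEFAULT_INSTRUCTIONS,
    language_rules: str = DEFAULT_LANGUAGE_RULES,
    output_format_rules: str = DEFAULT_OUTPUT_FORMAT_RULES,
) -> tuple[PromptSpec, str]:
    """Render the five-part renaming prompt for one input name.

    *template* is a ``str.format`` skeleton declaring placeholders for all
    five parts; a missing placeholder raises :class:`TemplateError` naming
    it. Identical inputs render byte-identical text.
    """
    if template is None:
        template = load_default_template()
    if fewshot is None:
        fewshot = load_default_fewshot()
    declared = {
        field_name
        for _, field_name, _, _ in string.Formatter().parse(template)
        if field_name
    }
    missing = _REQUIRED_PLACEHOLDERS - declared
    if missing:
        raise TemplateError(f"template is missing placeholder(s): {sorted(missing)}")

    spec = PromptSpec(
        instructions=instructions,
        language_rules=language_rules,
        output_format_rules=output_format_rules,
        fewshot_examples=tuple((str(a), str(b)) for a, b in fewshot),
        tg263_names=tuple(lexicon.standard_names),
        input_name=name.strip(),
    )
    fewshot_text = "\n".join(
        f"Input: {inp}\nOutput: {render_response(out, Confidence.HIGH)}"
        for inp, out in spec.fewshot_examples
    )
    rendered = template.format(
        instructions=spec.instructions,
        language_rules=spec.language_rules,
        output_format_rules=spec.output_format_rules,
        fewshot_examples=fewshot_text,
        tg263_names="\n".join(spec.tg263_names),
        input_name=spec.input_name,
    )
    return spec, rendered


# -- reply grammar ----------------------------------------------------------

_NAME_LINE_RE = re.compile(r"(?im)\bname\s*[:=]\s*(?P<name>[^|\n]+)")
_CONF_RE = re.compile(r"(?i)\bconfidence\s*[:=]\s*(?P<conf>low|medium|high)\b")


def render_response(predicted_name: str, confidence: Confidence) -> str:
    """Serialize a prediction into the documented reply grammar."""
    display = "No match" if predicted_name == NO_MATCH else predicted_name
    conf = "high" if confidence is Confidence.MISSING else confidence.value
    return f"name: {display} | confidence: {conf}"


def parse_response(raw: str, backend_id: str = "unknown") -> Prediction:
    """Parse a backend reply into a :class:`Prediction`.

    Takes the *last* well-formed ``name:`` field so chain-of-thought preamble
    is ignored; recognizes the no-match sentinel case-insensitively.
    Unparseable replies yield a parse-failure flag with confidence=missing
    instead of raising, so batch runs never abort.
    """
    matches = list(_NAME_LINE_RE.finditer(raw))
    if not matches:
        return Prediction(
            predicted_name=NO_MATCH,
            confidence=Confidence.MISSING,
            raw_response=raw,
            backend_id=backend_id,
            parse_failed=True,
        )
    match = matches[-1]
    name = canonical_label(match.group("name"))
    conf_match = _CONF_RE.search(raw, match.end()) or _CONF_RE.search(raw)
    confidence = (
        Confidence(conf_match.group("conf").lower()) if conf_match else Confidence.MISSING
    )
    if not name:
        return Prediction(
            predicted_name=NO_MATCH,
            confidence=Confidence.MISSING,
            raw_response=raw,
            backend_id=backend_id,
            parse_failed=True,
        )
    return Prediction(
        predicted_name=name,
        confidence=confidence,
        raw_response=raw,
        backend_id=backend_id,
    )


# -- mock backend -----------------------------------------------------------


def _load_default_abbreviations() -> dict[str, str]:
    path = resources.files("tg263harm.data") / "abbreviations.tsv"
    table = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        short, expansion = line.split("\t", 1)
        table[short.strip()] = expansion.strip()
    return table


def _edit_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _token_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if len(a) >= 3 and len(b) >= 3 and (a.startswith(b) or b.startswith(a)):
        return 0.9
    sim = _edit_similarity(a, b)
    return sim if sim >= 0.8 else 0.0


def _phrase_similarity(a: str, b: str) -> float:
    """Combined whole-phrase edit similarity and greedy token overlap."""
    if a == b:
        return 1.0
    ta, tb = a.split(), b.split()
    if frozenset(ta) == frozenset(tb):
        return 1.0
    overlap = sum(max((_token_similarity(x, y) for y in tb), default=0.0) for x in ta)
    token_score = overlap / max(len(ta), len(tb))
    return max(_edit_similarity(a, b), token_score)


class MockBackend:
    """Deterministic multilingual fuzzy-matching renaming backend.

    Pipeline: normalize (lowercase, strip punctuation/digits, camel-split,
    transliterate umlauts) -> expand abbreviations -> detect laterality /
    bilateral / qualifier markers -> score lexicon concepts against the
    residual phrase via multilingual synonym keys (exact, token-overlap, and
    bounded edit distance) -> compose the standard name matching the
    detected markers. Below-threshold best scores yield NO_MATCH.

    With temperature 0 the output is fully deterministic; with temperature
    > 0 the backend samples among above-threshold candidates with
    probability proportional to exp(score/T), restricted to the top_p mass,
    seeded from :class:`BackendConfig`.
    """

    backend_id = "mock"

    def __init__(
        self,
        lexicon: Lexicon,
        abbreviations: Optional[dict[str, str]] = None,
        threshold: float = 0.75,
    ):
        self.lexicon = lexicon
        self.abbreviations = (
            dict(abbreviations) if abbreviations is not None else _load_default_abbreviations()
        )
        self.threshold = threshold
        self.qualifiers = lexicon.qualifier_tokens()
        self._calls: dict[str, int] = {}
        # concept -> list of (key phrase, owner standard_name)
        self._keys: dict[str, list[tuple[str, str]]] = {}
        for entry in lexicon.entries:
            keys = self._keys.setdefault(entry.concept_id, [])
            phrase, _, _, _ = self._markers(normalize_text(entry.standard_name).split())
            for variant in {phrase, self._expand(phrase)}:
                if variant:
                    keys.append((variant, entry.standard_name))
            for _, term in entry.synonyms:
                norm = normalize_text(term)
                if norm:
                    keys.append((norm, entry.standard_name))
        for concept, keys in self._keys.items():
            seen = {}
            for key, owner in keys:
                seen.setdefault(key, owner)
            self._keys[concept] = sorted(seen.items())

    # -- normalization helpers

    def _expand(self, phrase: str) -> str:
        return " ".join(self.abbreviations.get(t, t) for t in phrase.split())

    def _markers(
        self, tokens: list[str]
    ) -> tuple[str, Laterality, Optional[str], bool]:
        """Split normalized tokens into (residual phrase, laterality,
        qualifier, plural-marker flag)."""
        laterality = Laterality.NONE
        plural_marker = False
        rest: list[str] = []
        for i, tok in enumerate(tokens):
            terminal = i == len(tokens) - 1
            if tok in BILATERAL_MARKERS:
                laterality = Laterality.BILATERAL
                plural_marker = True
            elif tok in LEFT_MARKERS and (terminal or len(tok) <= 2 or tok in {"links", "left"}):
                laterality = Laterality.LEFT
            elif tok in RIGHT_MARKERS and (terminal or len(tok) <= 2 or tok in {"rechts", "right"}):
                laterality = Laterality.RIGHT
            else:
                rest.append(tok)
        qualifier = None
        if len(rest) > 1:
            for i in range(len(rest) - 1, -1, -1):
                if rest[i] in self.qualifiers:
                    qualifier = rest[i]
                    rest = rest[:i] + rest[i + 1 :]
                    break
        return " ".join(rest), laterality, qualifier, plural_marker

    # -- scoring

    def _score_concepts(self, phrase: str) -> list[tuple[float, str, str]]:
        """(score, concept_id, owning standard_name of the best key), sorted
        by descending score then concept id."""
        scored = []
        for concept, keys in self._keys.items():
            best, owner = 0.0, keys[0][1]
            for key, key_owner in keys:
                sim = _phrase_similarity(phrase, key)
                if sim > best:
                    best, owner = sim, key_owner
            scored.append((best, concept, owner))
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored

    def _select_entry(
        self,
        concept: str,
        laterality: Laterality,
        qualifier: Optional[str],
        plural_marker: bool,
        owner: str,
    ) -> str:
        entries = self.lexicon.concept_entries(concept)
        want_qual = (qualifier or "").lower()

        def rank(entry):
            s = 0
            if entry.laterality is laterality:
                s += 4
            elif laterality is Laterality.BILATERAL and entry.plurality is Plurality.PLURAL:
                s += 3
            if plural_marker and entry.plurality is Plurality.PLURAL:
                s += 2
            if (entry.spatial_qualifier or "").lower() == want_qual:
                s += 3
            if entry.standard_name == owner:
                s += 2
            return (-s, entry.standard_name)

        return min(entries, key=rank).standard_name

    # -- prediction

    def predict(self, name: str, config: BackendConfig) -> Prediction:
        text = name.strip()
        entry = self.lexicon.get(text)
        if entry is not None:
            return self._emit(text, Confidence.HIGH)

        tokens = [self.abbreviations.get(t, t) for t in normalize_text(text).split()]
        phrase, laterality, qualifier, plural_marker = self._markers(tokens)
        if not phrase:
            return self._emit(NO_MATCH, Confidence.LOW)
        scored = self._score_concepts(phrase)
        candidates = [s for s in scored if s[0] >= self.threshold]
        if not candidates:
            return self._emit(NO_MATCH, Confidence.LOW)

        if config.temperature > 0 and len(candidates) > 1:
            chosen = self._sample(text, candidates, config)
        else:
            chosen = candidates[0]
        score, concept, owner = chosen
        predicted = self._select_entry(concept, laterality, qualifier, plural_marker, owner)
        if score >= 1.0:
            confidence = Confidence.HIGH
        elif score >= self.threshold + 0.1:
            confidence = Confidence.MEDIUM
        else:
            confidence = Confidence.LOW
        return self._emit(predicted, confidence)

    def _sample(self, text, candidates, config):
        index = self._calls.get(text, 0)
        self._calls[text] = index + 1
        rng = np.random.default_rng(
            [config.seed & 0x7FFFFFFF, zlib.crc32(text.encode("utf-8")), index]
        )
        scores = np.array([c[0] for c in candidates])
        weights = np.exp((scores - scores.max()) / config.temperature)
        probs = weights / weights.sum()
        cum = np.cumsum(probs)
        cutoff = int(np.searchsorted(cum, config.top_p)) + 1
        probs = probs[:cutoff] / probs[:cutoff].sum()
        return candidates[int(rng.choice(cutoff, p=probs))]

    def _emit(self, predicted: str, confidence: Confidence) -> Prediction:
        return Prediction(
            predicted_name=predicted,
            confidence=confidence,
            raw_response=render_response(predicted, confidence),
            backend_id=self.backend_id,
        )


# -- remote backend ---------------------------------------------------------


class RemoteChatBackend:
    """Chat-completion-style HTTP backend.

    Sends the rendered five-part prompt as a single user message; temperature
    and top_p are passed through verbatim from :class:`BackendConfig`. The
    transport is injectable for testing.
    """

    def __init__(
        self,
        lexicon: Lexicon,
        template: Optional[str] = None,
        fewshot: Optional[Sequence[tuple[str, str]]] = None,
        transport: Optional[Callable] = None,
        backend_id: str = "remote-chat",
    ):
        self.lexicon = lexicon
        self.template = template
        self.fewshot = fewshot
        self.backend_id = backend_id
        if transport is None:
            import requests

            transport = requests.post
        self._post = transport

    def predict(self, name: str, config: BackendConfig) -> Prediction:
        if not config.endpoint:
            raise ConfigurationError("remote backend requires config.endpoint")
        _, prompt = build_prompt(name, self.lexicon, self.template, self.fewshot)
        payload = {
            "model": config.model or "default",
            "messages": [{"role": "user", "content": prompt}],
            "temperature": config.temperature,
            "top_p": config.top_p,
        }
        try:
            response = self._post(config.endpoint, json=payload, timeout=config.timeout)
            response.raise_for_status()
            content = response.json()["choices"][0]["message"]["content"]
        except Exception as exc:  # transport failures become BackendError
            raise BackendError(f"remote backend failed for {name!r}: {exc}") from exc
        return parse_response(content, backend_id=self.backend_id)


# -- batch driver -----------------------------------------------------------


def rename_batch(
    names: Iterable[str | UniqueName],
    backend: Backend,
    config: BackendConfig,
) -> list[Prediction]:
    """Predict one TG-263 name per input, order-preserving.

    Backend failures are retried up to ``config.max_retries`` times and then
    recorded as failure-state predictions; a batch run never aborts on a
    single item.
    """
    predictions = []
    for item in names:
        raw_name = item.raw_name if isinstance(item, UniqueName) else str(item)
        last_error: Optional[Exception] = None
        prediction = None
        for _ in range(config.max_retries + 1):
            try:
                prediction = backend.predict(raw_name, config)
                break
            except BackendError as exc:
                last_error = exc
        if prediction is None:
            prediction = Prediction(
                predicted_name=NO_MATCH,
                confidence=Confidence.MISSING,
                raw_response="",
                backend_id=getattr(backend, "backend_id", "unknown"),
                parse_failed=True,
                error=str(last_error),
            )
        predictions.append(prediction)
    return predictions
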