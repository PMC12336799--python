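"""Model of the TG-263 structure-name vocabulary.

The AAPM TG-263 report defines a closed, case-sensitive nomenclature for
radiotherapy structures (``Glnd_Lacrimal_L``, ``SpinalCord_Cerv``, ...).
This module loads a lexicon file describing a curated subset of that
vocabulary, decomposes names into concept / laterality / spatial-qualifier /
plurality components, and answers the two questions every downstream stage
needs: *is this string an exact TG-263 name?* and *do these two names refer
to the same organ concept?*

A bundled lexicon (``data/tg263_lexicon.tsv``) ships with the package; users
can substitute the complete TG-263 list in the same tabular format (see
:func:`load_lexicon`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import InvalidNameError, LexiconError

__all__ = [
    "NO_MATCH",
    "is_no_match",
    "Laterality",
    "Plurality",
    "Category",
    "TG263Entry",
    "Lexicon",
    "NameComponents",
    "load_lexicon",
    "bundled_lexicon_path",
    "load_bundled_lexicon",
    "normalize_text",
    "parse_name",
    "compose_name",
    "same_concept",
    "is_valid_tg263",
    "DEFAULT_QUALIFIER_TOKENS",
]

#: Sentinel label for "no suitable TG-263 name found". Backends may reply
#: "no match" in any capitalization; :func:`is_no_match` canonicalizes.
NO_MATCH = "NO_MATCH"

_NO_MATCH_FORMS = {"no match", "no_match", "no-match", "nomatch"}


def is_no_match(label: str) -> bool:
    """True if *label* is any spelling of the no-match sentinel."""
    return label.strip().lower() in _NO_MATCH_FORMS


def canonical_label(label: str) -> str:
    """Trim a predicted/ground-truth label, mapping no-match spellings to NO_MATCH."""
    text = label.strip()
    return NO_MATCH if is_no_match(text) else text


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    BILATERAL = "bilateral"
    NONE = "none"


class Plurality(str, Enum):
    SINGULAR = "singular"
    PLURAL = "plural"


class Category(str, Enum):
    ORGAN = "organ"
    SUBSTRUCTURE = "substructure"
    COMPOSITE = "composite"


#: Spatial/locality qualifier tokens recognized when parsing names.
#: Covers the regional designations TG-263 appends (cervical, superior,
#: inferior, ...) in the abbreviated and spelled-out forms seen clinically.
DEFAULT_QUALIFIER_TOKENS = frozenset(
    {
        "cerv", "cervical", "zervikal",
        "sup", "superior", "inf", "inferior",
        "ant", "anterior", "post", "posterior",
        "prox", "proximal", "dist", "distal",
        "mid", "upper", "lower",
    }
)

#: Tokens that mark laterality when they terminate a name (``Kidney_L``) or,
#: for bilateral markers, appear anywhere (``Niere bds``).
LEFT_MARKERS = frozenset({"l", "li", "lt", "lft", "left", "links", "linker", "linksseitig", "sin", "sinister"})
RIGHT_MARKERS = frozenset({"r", "re", "rt", "rgt", "right", "rechts", "rechter", "rechtsseitig", "dex", "dexter"})
BILATERAL_MARKERS = frozenset({"bds", "bdz", "beidseits", "beiderseits", "bilateral", "bilat", "both", "beide"})

# Words whose terminal "s" is not an English plural (keeps the fallback
# plurality heuristic from misfiring on Latin anatomical terms).
_PLURAL_EXCEPTIONS = frozenset(
    {
        "pancreas", "uterus", "esophagus", "oesophagus", "anus", "atlas",
        "pelvis", "testis", "iris", "meatus", "ramus", "pons", "bronchus",
        "thymus", "hippocampus", "sinus", "plexus", "lens", "glottis",
        "epiglottis", "pubis", "constrict", "ves",
    }
)

_UMLAUTS = str.maketrans(
    {"ä": "ae", "ö": "oe", "ü": "ue", "ß": "ss", "Ä": "Ae", "Ö": "Oe", "Ü": "Ue", "é": "e", "è": "e", "ë": "e"}
)
_CAMEL_RE = re.compile(r"(?<=[a-z])(?=[A-Z])")
_NON_ALPHA_RE = re.compile(r"[^a-z]+")
_TOKEN_SPLIT_RE = re.compile(r"[_\s\-./\\]+")


def normalize_text(text: str) -> str:
    """Canonical lowercase form: umlauts transliterated, camel-case split,
    digits and punctuation collapsed to single spaces."""
    s = text.translate(_UMLAUTS)
    s = _CAMEL_RE.sub(" ", s)
    s = _NON_ALPHA_RE.sub(" ", s.lower())
    return " ".join(s.split())


@dataclass(frozen=True)
class TG263Entry:
    """One standardized TG-263 structure name and its decomposition.

    ``concept_id`` groups all variants of one organ-at-risk: ``Kidney``,
    ``Kidney_L``, ``Kidney_R`` and ``Kidneys`` share the concept ``kidney``.
    ``synonyms`` maps languages (en/de/nl/...) to common clinical names.
    """

    standard_name: str
    concept_id: str
    category: Category
    laterality: Laterality
    spatial_qualifier: Optional[str]
    plurality: Plurality
    synonyms: tuple[tuple[str, str], ...] = ()  # (language, term) pairs

    def synonyms_for(self, language: str) -> list[str]:
        return [term for lang, term in self.synonyms if lang == language]


@dataclass(frozen=True)
class NameComponents:
    """Deterministic decomposition of a structure name."""

    concept_tokens: tuple[str, ...]
    laterality: Laterality
    spatial_qualifier: Optional[str]
    plurality: Plurality


class Lexicon:
    """A validated collection of :class:`TG263Entry` rows.

    Maintains the lookup indices used for concept resolution: exact standard
    names, normalized standard names, concept phrases (the name minus
    laterality/qualifier tokens) and multilingual synonyms.
    """

    def __init__(self, entries: Iterable[TG263Entry], version_tag: str = "unversioned"):
        self.entries: list[TG263Entry] = list(entries)
        self.version_tag = version_tag
        self._by_name: dict[str, TG263Entry] = {}
        self._concepts: dict[str, list[TG263Entry]] = {}
        self._synonym_index: dict[str, str] = {}  # normalized term -> concept_id
        self._synonym_lang: dict[str, set[str]] = {}  # concept -> languages present
        self._phrase_index: dict[str, str] = {}  # normalized phrase -> concept_id
        self._sorted_phrase_index: dict[frozenset, str] = {}
        self._compact_index: dict[str, str] = {}  # phrase without spaces -> concept_id
        self._validate_and_index()

    # -- construction -----------------------------------------------------

    def _validate_and_index(self) -> None:
        for entry in self.entries:
            if entry.standard_name in self._by_name:
                raise LexiconError(f"duplicate standard_name: {entry.standard_name!r}")
            self._by_name[entry.standard_name] = entry
            self._concepts.setdefault(entry.concept_id, []).append(entry)
            for lang, term in entry.synonyms:
                norm = normalize_text(term)
                if not norm:
                    raise LexiconError(f"empty synonym on {entry.standard_name!r}")
                owner = self._synonym_index.get(norm)
                if owner is not None and owner != entry.concept_id:
                    raise LexiconError(
                        f"synonym {term!r} (row {entry.standard_name!r}) maps to two "
                        f"concepts: {owner!r} and {entry.concept_id!r}"
                    )
                self._synonym_index[norm] = entry.concept_id
                self._synonym_lang.setdefault(entry.concept_id, set()).add(lang)

        for entry in self.entries:
            if entry.laterality is Laterality.LEFT and not entry.standard_name.endswith("_L"):
                raise LexiconError(f"left entry {entry.standard_name!r} must end with '_L'")
            if entry.laterality is Laterality.RIGHT and not entry.standard_name.endswith("_R"):
                raise LexiconError(f"right entry {entry.standard_name!r} must end with '_R'")

        # laterality siblings differ only in the terminal token
        for concept, group in self._concepts.items():
            lefts = {e.standard_name[:-2] for e in group if e.laterality is Laterality.LEFT}
            rights = {e.standard_name[:-2] for e in group if e.laterality is Laterality.RIGHT}
            if lefts and rights and lefts != rights:
                raise LexiconError(
                    f"left/right names of concept {concept!r} do not pair up: {lefts ^ rights}"
                )

        for entry in self.entries:
            norm = normalize_text(entry.standard_name)
            self._claim_phrase(norm, entry.concept_id, entry.standard_name)
            comps = parse_name(entry.standard_name, lexicon=None)
            phrase = normalize_text(" ".join(comps.concept_tokens))
            if phrase:
                self._claim_phrase(phrase, entry.concept_id, entry.standard_name)
        for norm, concept in list(self._synonym_index.items()):
            self._claim_phrase(norm, concept, f"synonym {norm!r}")

    def _claim_phrase(self, phrase: str, concept_id: str, origin: str) -> None:
        owner = self._phrase_index.get(phrase)
        if owner is not None and owner != concept_id:
            raise LexiconError(
                f"phrase {phrase!r} ({origin}) is ambiguous between concepts "
                f"{owner!r} and {concept_id!r}"
            )
        self._phrase_index[phrase] = concept_id
        key = frozenset(phrase.split())
        if self._sorted_phrase_index.get(key, concept_id) == concept_id:
            self._sorted_phrase_index[key] = concept_id
        compact = phrase.replace(" ", "")
        if self._compact_index.get(compact, concept_id) == concept_id:
            self._compact_index[compact] = concept_id

    # -- basic access -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> Optional[TG263Entry]:
        return self._by_name.get(name)

    @property
    def standard_names(self) -> list[str]:
        return [e.standard_name for e in self.entries]

    def concept_entries(self, concept_id: str) -> list[TG263Entry]:
        return list(self._concepts.get(concept_id, []))

    @property
    def concept_ids(self) -> list[str]:
        return list(self._concepts)

    def languages(self, concept_id: str) -> set[str]:
        return set(self._synonym_lang.get(concept_id, set()))

    def qualifier_tokens(self) -> frozenset[str]:
        declared = {
            e.spatial_qualifier.lower() for e in self.entries if e.spatial_qualifier
        }
        return DEFAULT_QUALIFIER_TOKENS | frozenset(declared)

    # -- concept resolution ------------------------------------------------

    def resolve_concept(self, name: str) -> Optional[str]:
        """Map *name* to a concept_id via standard names, normalized forms,
        synonyms, token reordering, or singular/plural variants.

        Returns None when the name is unresolvable in this lexicon.
        """
        text = name.strip()
        if not text or is_no_match(text):
            return None
        entry = self._by_name.get(text)
        if entry is not None:
            return entry.concept_id
        norm = normalize_text(text)
        if norm in self._phrase_index:
            return self._phrase_index[norm]
        comps = parse_name(text, lexicon=None, qualifier_tokens=self.qualifier_tokens())
        phrase = normalize_text(" ".join(comps.concept_tokens))
        return self._lookup_phrase(phrase)

    def _lookup_phrase(self, phrase: str) -> Optional[str]:
        if not phrase:
            return None
        hit = self._phrase_index.get(phrase)
        if hit is not None:
            return hit
        hit = self._sorted_phrase_index.get(frozenset(phrase.split()))
        if hit is not None:
            return hit
        # lowercased camel-case ("spinalcord") loses the word boundary
        hit = self._compact_index.get(phrase.replace(" ", ""))
        if hit is not None:
            return hit
        # singular/plural spelling variants of the final word
        tokens = phrase.split()
        last = tokens[-1]
        variants = []
        if last.endswith("es"):
            variants.append(last[:-2])
        if last.endswith("s"):
            variants.append(last[:-1])
        variants.append(last + "s")
        for var in variants:
            alt = " ".join(tokens[:-1] + [var])
            hit = self._phrase_index.get(alt)
            if hit is not None:
                return hit
        return None


# -- file I/O ---------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "standard_name", "concept_id", "category", "laterality",
    "spatial_qualifier", "plurality", "synonyms",
]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a tab-delimited UTF-8 file.

    Columns: standard_name, concept_id, category (organ/substructure/
    composite), laterality (left/right/bilateral/none), spatial_qualifier
    (may be empty), plurality (singular/plural), synonyms (pipe-separated
    ``lang:term`` pairs). Lines starting with ``#`` are comments; a comment
    ``# version=...`` sets the lexicon version tag.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    version_tag = "unversioned"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "version=" in line:
                version_tag = line.split("version=", 1)[1].strip()
            elif not line.startswith("#"):
                break
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise LexiconError(f"lexicon {path} missing columns: {missing}")

    entries = []
    for idx, row in frame.iterrows():
        name = row["standard_name"].strip()
        if not name:
            raise LexiconError(f"{path} row {idx + 2}: empty standard_name")
        try:
            category = Category(row["category"].strip())
            laterality = Laterality(row["laterality"].strip())
            plurality = Plurality(row["plurality"].strip())
        except ValueError as exc:
            raise LexiconError(f"{path} row {idx + 2} ({name!r}): {exc}") from exc
        synonyms = []
        for chunk in filter(None, (p.strip() for p in row["synonyms"].split("|"))):
            if ":" not in chunk:
                raise LexiconError(
                    f"{path} row {idx + 2} ({name!r}): synonym {chunk!r} is not 'lang:term'"
                )
            lang, term = chunk.split(":", 1)
            synonyms.append((lang.strip(), term.strip()))
        entries.append(
            TG263Entry(
                standard_name=name,
                concept_id=row["concept_id"].strip(),
                category=category,
                laterality=laterality,
                spatial_qualifier=row["spatial_qualifier"].strip() or None,
                plurality=plurality,
                synonyms=tuple(synonyms),
            )
        )
    try:
        return Lexicon(entries, version_tag=version_tag)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


def bundled_lexicon_path() -> Path:
    """Path of the curated TG-263 subset shipped with the package."""
    return Path(resources.files("tg263harm.data") / "tg263_lexicon.tsv")


def load_bundled_lexicon() -> Lexicon:
    return load_lexicon(bundled_lexicon_path())


# -- parsing ---------------------------------------------------------------


def parse_name(
    name: str,
    lexicon: Optional[Lexicon] = None,
    qualifier_tokens: Optional[frozenset[str]] = None,
) -> NameComponents:
    """Decompose a structure name into concept tokens, laterality, spatial
    qualifier and plurality.

    Laterality is read from a terminal ``_L``/``_R``-style token and from
    bilateral markers anywhere in the name; the spatial qualifier from a
    configurable token list (cervical, superior, ...); the concept tokens are
    the residue. When *lexicon* is given and the name is an exact standard
    name, the entry's declared laterality/qualifier/plurality take precedence
    over the string heuristics.
    """
    text = name.strip()
    if not text:
        raise InvalidNameError("structure name is empty")
    if qualifier_tokens is None:
        qualifier_tokens = (
            lexicon.qualifier_tokens() if lexicon is not None else DEFAULT_QUALIFIER_TOKENS
        )

    tokens = [t for t in _TOKEN_SPLIT_RE.split(text) if t]
    laterality = Laterality.NONE
    if tokens and tokens[-1].lower() in LEFT_MARKERS:
        laterality = Laterality.LEFT
        tokens = tokens[:-1]
    elif tokens and tokens[-1].lower() in RIGHT_MARKERS:
        laterality = Laterality.RIGHT
        tokens = tokens[:-1]
    remaining = []
    for tok in tokens:
        if tok.lower() in BILATERAL_MARKERS:
            laterality = Laterality.BILATERAL
        else:
            remaining.append(tok)
    tokens = remaining

    qualifier = None
    for i in range(len(tokens) - 1, -1, -1):
        if tokens[i].lower() in qualifier_tokens and len(tokens) > 1:
            qualifier = tokens[i]
            tokens = tokens[:i] + tokens[i + 1 :]
            break

    plurality = _heuristic_plurality(tokens)

    if lexicon is not None:
        entry = lexicon.get(text)
        if entry is not None:
            laterality = entry.laterality
            qualifier = entry.spatial_qualifier
            plurality = entry.plurality

    return NameComponents(
        concept_tokens=tuple(tokens),
        laterality=laterality,
        spatial_qualifier=qualifier,
        plurality=plurality,
    )


def _heuristic_plurality(tokens: list[str]) -> Plurality:
    if not tokens:
        return Plurality.SINGULAR
    last = tokens[-1].lower()
    if (
        len(last) > 3
        and last.endswith("s")
        and not last.endswith("ss")
        and last not in _PLURAL_EXCEPTIONS
    ):
        return Plurality.PLURAL
    return Plurality.SINGULAR


def compose_name(components: NameComponents) -> str:
    """Recompose a TG-263-style name from components (inverse of
    :func:`parse_name` up to token spelling)."""
    tokens = list(components.concept_tokens)
    if components.spatial_qualifier:
        tokens.append(components.spatial_qualifier)
    if components.laterality is Laterality.LEFT:
        tokens.append("L")
    elif components.laterality is Laterality.RIGHT:
        tokens.append("R")
    return "_".join(tokens)


# -- comparisons ------------------------------------------------------------


def same_concept(a: str, b: str, lexicon: Lexicon) -> Optional[bool]:
    """True/False if both names resolve to concepts in *lexicon*; None if
    either is unresolvable. Symmetric, and reflexive for resolvable names."""
    ca = lexicon.resolve_concept(a)
    cb = lexicon.resolve_concept(b)
    if ca is None or cb is None:
        return None
    return ca == cb


def is_valid_tg263(name: str, lexicon: Lexicon) -> bool:
    """Exact (case-sensitive, whitespace-trimmed) membership in the lexicon."""
    return name.strip() in lexicon
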