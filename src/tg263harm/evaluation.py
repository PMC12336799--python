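"""Scoring of predictions against ground truth and error-taxonomy
classification.

Two accuracies are reported, mirroring how harmonization performance is
summarized clinically: *unique* accuracy over distinct raw names, and
*overall* accuracy weighting each distinct name by how often it occurs in
the full dataset (a frequent name that fails depresses overall accuracy far
below unique accuracy).

Misassignments fall into five categories: wrong OAR, laterality/locality
(left vs. right, or a regional designation such as cervical/superior),
plurality (singular vs. plural form), misspelling (correct organ, wrong
TG-263 spelling), and no-match. The classifier is a deterministic decision
cascade over the lexicon's concept/laterality/plurality decomposition;
where a human reviewer made these calls case by case, the cascade makes the
precedence explicit (locality before plurality before misspelling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, TG263HarmError
from .harmonize import Confidence, Prediction
from .nomenclature import (
    NO_MATCH,
    Laterality,
    Lexicon,
    canonical_label,
    is_valid_tg263,
    parse_name,
    same_concept,
)

__all__ = [
    "ErrorType",
    "EvaluationRecord",
    "AccuracyReport",
    "score",
    "classify_error",
    "accuracy_report",
    "evaluate",
    "write_evaluation_table",
]


class ErrorType(str, Enum):
    NONE = "none"
    WRONG_OAR = "wrong_oar"
    LATERALITY_OR_LOCALITY = "laterality_or_locality"
    PLURALITY = "plurality"
    MISSPELLING = "misspelling"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class EvaluationRecord:
    """One scored unique name: raw input, truth, prediction, verdict."""

    raw_name: str
    ground_truth: str
    prediction: Prediction
    correct: bool
    error_type: ErrorType
    multiplicity: int = 1
    center_id: str = "unknown"
    region: Optional[str] = None


@dataclass(frozen=True)
class AccuracyReport:
    unique_accuracy: float
    overall_accuracy: float
    n_unique: int
    n_total: int
    per_center: dict[str, tuple[float, float]]
    error_histogram: dict[ErrorType, int]


def _collapse(lat: Laterality) -> Laterality:
    """Bilateral composites (Kidneys, Lungs, ...) compare as unsided: their
    difference from the unsided singular is a plurality matter, while a
    sided name vs. anything unsided remains a laterality difference."""
    return Laterality.NONE if lat is Laterality.BILATERAL else lat


def classify_error(prediction: str, ground_truth: str, lexicon: Lexicon) -> ErrorType:
    """Assign the error category for one (prediction, ground-truth) pair.

    Decision cascade, first match wins: exact equality -> NONE; no-match
    sentinel -> NO_MATCH; same concept with differing laterality or spatial
    qualifier -> LATERALITY_OR_LOCALITY; same concept with differing
    plurality -> PLURALITY; same concept otherwise (wrong TG-263 spelling)
    -> MISSPELLING; everything else -> WRONG_OAR. Total and deterministic.
    """
    pred = canonical_label(prediction)
    truth = canonical_label(ground_truth)
    if truth != NO_MATCH and not is_valid_tg263(truth, lexicon):
        raise ConfigurationError(
            f"ground truth {ground_truth!r} is not in the lexicon; the lexicon "
            "must cover the ground-truth vocabulary"
        )
    if pred == truth:
        return ErrorType.NONE
    if pred == NO_MATCH:
        return ErrorType.NO_MATCH
    if truth == NO_MATCH:
        # predicted a name where none was expected
        return ErrorType.WRONG_OAR
    if same_concept(pred, truth, lexicon) is not True:
        return ErrorType.WRONG_OAR
    pc = parse_name(pred, lexicon)
    tc = parse_name(truth, lexicon)
    if _collapse(pc.laterality) is not _collapse(tc.laterality):
        return ErrorType.LATERALITY_OR_LOCALITY
    if (pc.spatial_qualifier or "").lower() != (tc.spatial_qualifier or "").lower():
        return ErrorType.LATERALITY_OR_LOCALITY
    if pc.plurality is not tc.plurality:
        return ErrorType.PLURALITY
    return ErrorType.MISSPELLING


def score(
    items: Sequence[tuple],
    lexicon: Lexicon,
) -> tuple[list[EvaluationRecord], list]:
    """Score (unique_name_like, prediction) pairs against their ground truth.

    *items* holds pairs whose first element provides ``raw_name``,
    ``ground_truth`` and optionally ``multiplicity``/``center_id`` attributes
    (:class:`~tg263harm.ingest.UniqueName` or
    :class:`~tg263harm.ingest.RawStructure`), and whose second is the
    :class:`~tg263harm.harmonize.Prediction`. Correctness is exact trimmed
    case-sensitive string equality, with the no-match sentinel equal only to
    itself. Items without ground truth are excluded and returned separately.
    """
    records: list[EvaluationRecord] = []
    excluded = []
    for source, prediction in items:
        truth = getattr(source, "ground_truth", None)
        if truth is None:
            excluded.append(source)
            continue
        truth = canonical_label(truth)
        pred = canonical_label(prediction.predicted_name)
        records.append(
            EvaluationRecord(
                raw_name=source.raw_name,
                ground_truth=truth,
                prediction=prediction,
                correct=pred == truth,
                error_type=classify_error(pred, truth, lexicon),
                multiplicity=getattr(source, "multiplicity", 1),
                center_id=_center_of(source),
            )
        )
    return records, excluded


def _center_of(source) -> str:
    centers = getattr(source, "source_centers", None)
    if centers:
        return sorted(centers)[0]
    return getattr(source, "center_id", "unknown")


def accuracy_report(records: Sequence[EvaluationRecord]) -> AccuracyReport:
    """Unique and multiplicity-weighted overall accuracy, with per-center
    breakdown and the error histogram over misassignments."""
    if not records:
        raise TG263HarmError("cannot build an accuracy report from zero records")

    def _acc(group: Sequence[EvaluationRecord]) -> tuple[float, float]:
        unique = sum(r.correct for r in group) / len(group)
        weight = sum(r.multiplicity for r in group)
        overall = sum(r.multiplicity * r.correct for r in group) / weight
        return unique, overall

    unique_acc, overall_acc = _acc(records)
    centers = sorted({r.center_id for r in records})
    per_center = {c: _acc([r for r in records if r.center_id == c]) for c in centers}
    histogram = Counter(r.error_type for r in records if not r.correct)
    return AccuracyReport(
        unique_accuracy=unique_acc,
        overall_accuracy=overall_acc,
        n_unique=len(records),
        n_total=sum(r.multiplicity for r in records),
        per_center=per_center,
        error_histogram=dict(histogram),
    )


def evaluate(
    uniques: Sequence,
    predictions: Sequence[Prediction],
    lexicon: Lexicon,
) -> tuple[list[EvaluationRecord], AccuracyReport]:
    """Convenience wrapper: pair inputs with predictions, score, and report."""
    if len(uniques) != len(predictions):
        raise TG263HarmError(
            f"{len(uniques)} names but {len(predictions)} predictions"
        )
    records, _ = score(list(zip(uniques, predictions)), lexicon)
    return records, accuracy_report(records)


def write_evaluation_table(records: Sequence[EvaluationRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "raw_name": [r.raw_name for r in records],
            "ground_truth": [r.ground_truth for r in records],
            "predicted_name": [r.prediction.predicted_name for r in records],
            "confidence": [r.prediction.confidence.value for r in records],
            "correct": [int(r.correct) for r in records],
            "error_type": [r.error_type.value for r in records],
            "multiplicity": [r.multiplicity for r in records],
            "center_id": [r.center_id for r in records],
            "needs_review": [
                int(r.prediction.predicted_name == NO_MATCH or r.prediction.parse_failed)
                for r in records
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
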