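"""Prediction-reliability estimation.

Two complementary signals are quantified:

* **Self-reported confidence.** Backends emit a low/medium/high confidence
  with each prediction; its usefulness as an error flag is measured by the
  phi coefficient (binary Pearson correlation) between a low-confidence
  indicator (low or medium = 1, high = 0) and an error indicator
  (wrong = 1, correct = 0).

* **Monte-Carlo sampling entropy.** Each structure is renamed k times
  (default 10) at temperature 1 with top-p sampling (0.95); the Shannon
  entropy H = -sum p_i ln p_i of the distribution of distinct predicted
  labels measures output variability. H > 0 (equivalently, at least two
  distinct labels) flags the structure as uncertain, and the flag is
  evaluated as a binary classifier of deterministic-run errors via phi,
  sensitivity, and specificity.

Entropy is reported in nats; the H > 0 flag and all derived classifier
metrics are invariant to the logarithm base.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InvalidNameError, TG263HarmError
from .harmonize import Backend, BackendConfig, Confidence
from .nomenclature import canonical_label

__all__ = [
    "UncertaintyResult",
    "BinaryAssociation",
    "EntropyErrorMetrics",
    "sample_predictions",
    "shannon_entropy",
    "phi_correlation",
    "entropy_error_metrics",
    "confidence_error_correlation",
    "uncertainty_for",
]


@dataclass(frozen=True)
class UncertaintyResult:
    """The k sampled labels for one structure and their entropy."""

    raw_name: str
    samples: tuple[str, ...]
    frequencies: tuple[float, ...]  # relative frequency of each distinct label
    entropy: float  # nats
    flagged: bool  # H > 0, i.e. >= 2 distinct labels
    complete: bool = True  # False if any sample failed

    @property
    def n_distinct(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class BinaryAssociation:
    """Phi coefficient with its 2x2 contingency table (a,b,c,d) =
    (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0). A zero margin makes phi
    undefined; it is then reported as NaN with ``degenerate`` set, so
    'undefined' can never be mistaken for 'no association'."""

    phi: float
    table: tuple[int, int, int, int]
    degenerate: bool = False

    @property
    def n(self) -> int:
        return sum(self.table)


@dataclass(frozen=True)
class EntropyErrorMetrics:
    """Confusion-matrix metrics for the entropy flag as an error classifier.

    Condition positive = the deterministic prediction is incorrect; test
    positive = sampling entropy > 0. Sensitivity/specificity are NaN when
    no incorrect/correct records exist.
    """

    association: BinaryAssociation
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int


def sample_predictions(
    name: str,
    backend: Backend,
    k: int,
    config: BackendConfig,
) -> tuple[list[str], int]:
    """Collect k predicted labels for one structure, in sampling order.

    Labels are whitespace-trimmed (no-match spellings canonicalized) before
    downstream counting; NO_MATCH is a legal label. Returns (labels,
    n_failures); failed samples are dropped and counted, leaving the result
    incomplete rather than imputed.
    """
    if k < 1:
        raise TG263HarmError("k must be >= 1")
    if config.temperature == 0:
        warnings.warn(
            "sampling at temperature 0: all samples will be identical by contract",
            stacklevel=2,
        )
    labels: list[str] = []
    failures = 0
    for _ in range(k):
        try:
            prediction = backend.predict(name, config)
        except Exception:
            failures += 1
            continue
        labels.append(canonical_label(prediction.predicted_name))
    return labels, failures


def shannon_entropy(labels: Sequence[str]) -> float:
    """Shannon entropy (nats) of the relative frequencies of distinct labels.

    Computed as ln k - (1/k) * sum c_i ln c_i over the counts c_i, which is
    algebraically -sum p_i ln p_i but exact at the boundaries: a single
    distinct label gives exactly 0.0 and k distinct labels exactly ln k.
    """
    if not labels:
        raise InvalidNameError("cannot compute entropy of an empty label list")
    counts = Counter(str(lab).strip() for lab in labels)
    if len(counts) == 1:
        return 0.0
    k = sum(counts.values())
    acc = sum(c * math.log(c) for c in counts.values())
    return math.log(k) - acc / k


def uncertainty_for(
    name: str,
    backend: Backend,
    k: int,
    config: BackendConfig,
) -> UncertaintyResult:
    """Sample k labels for *name* and package counts, entropy, and flag."""
    labels, failures = sample_predictions(name, backend, k, config)
    if not labels:
        return UncertaintyResult(name, (), (), float("nan"), False, complete=False)
    counts = Counter(labels)
    total = sum(counts.values())
    return UncertaintyResult(
        raw_name=name,
        samples=tuple(labels),
        frequencies=tuple(c / total for c in counts.values()),
        entropy=shannon_entropy(labels),
        flagged=len(counts) >= 2,
        complete=failures == 0,
    )


def phi_correlation(x: Sequence, y: Sequence) -> BinaryAssociation:
    """Phi coefficient of two binary vectors.

    Equals the Pearson product-moment correlation of the 0/1 vectors;
    computed from the 2x2 table as (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).
    A zero margin yields NaN with the degenerate flag set.
    """
    if len(x) != len(y):
        raise TG263HarmError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise TG263HarmError("need at least two observations")
    xb = [bool(v) for v in x]
    yb = [bool(v) for v in y]
    a = sum(1 for u, v in zip(xb, yb) if u and v)
    b = sum(1 for u, v in zip(xb, yb) if u and not v)
    c = sum(1 for u, v in zip(xb, yb) if not u and v)
    d = len(xb) - a - b - c
    table = (a, b, c, d)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return BinaryAssociation(float("nan"), table, degenerate=True)
    return BinaryAssociation((a * d - b * c) / math.sqrt(denom), table)


def entropy_error_metrics(
    records: Sequence[tuple[bool, float]],
) -> EntropyErrorMetrics:
    """Evaluate the non-zero-entropy flag as a classifier of errors.

    *records* holds (deterministic_correct, entropy) per structure. TP = an
    incorrect structure with H > 0; sensitivity = TP/(TP+FN) over incorrect
    records; specificity = TN/(TN+FP) over correct ones; phi is computed on
    the (incorrect, H > 0) indicator pair.
    """
    if not records:
        raise TG263HarmError("no records")
    tp = sum(1 for correct, h in records if not correct and h > 0)
    fn = sum(1 for correct, h in records if not correct and not h > 0)
    fp = sum(1 for correct, h in records if correct and h > 0)
    tn = sum(1 for correct, h in records if correct and not h > 0)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    association = phi_correlation(
        [not correct for correct, _ in records],
        [h > 0 for _, h in records],
    )
    return EntropyErrorMetrics(
        association=association,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def confidence_error_correlation(records: Sequence) -> BinaryAssociation:
    """Phi between low self-reported confidence and prediction errors.

    Coding: confidence low/medium (and missing, conservatively) = 1,
    high = 0; wrong prediction = 1, correct = 0. *records* are
    :class:`~tg263harm.evaluation.EvaluationRecord`-like objects carrying
    ``correct`` and ``prediction.confidence``.
    """
    low_conf = [
        r.prediction.confidence is not Confidence.HIGH for r in records
    ]
    wrong = [not r.correct for r in records]
    return phi_correlation(low_conf, wrong)
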