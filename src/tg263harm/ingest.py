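"""Extract raw structure names from DICOM RT Structure Sets or tables,
filter out non-OAR structures, and collapse duplicates.

Clinics delineate many structures besides TG-263 organs-at-risk: target
volumes (PTV/CTV/GTV/...), couch and immobilization hardware, optimization
helpers. These are excluded by a transparent, user-overridable pattern rule
set, and every exclusion is reported with the rule that caused it so the
decision can be audited. Deduplication pools identical raw names across
centers, keeping multiplicities so that frequency-weighted (overall)
accuracy can later be distinguished from unique-name accuracy.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import ConfigurationError, IngestError
from .nomenclature import canonical_label

__all__ = [
    "RawStructure",
    "UniqueName",
    "ExclusionRule",
    "DEFAULT_EXCLUSION_RULES",
    "read_rtstruct_names",
    "read_structure_table",
    "write_structure_table",
    "filter_structures",
    "deduplicate",
]

_LANGUAGES = {"en", "de", "nl", "unknown"}


@dataclass(frozen=True)
class RawStructure:
    """One observed structure name, with provenance and optional truth label."""

    raw_name: str
    center_id: str = "unknown"
    patient_id: Optional[str] = None
    language_hint: str = "unknown"
    ground_truth: Optional[str] = None
    #: corruption-operator provenance, filled by the synthetic generator
    operators: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.raw_name.strip():
            raise IngestError("raw_name is empty")
        if self.language_hint not in _LANGUAGES:
            raise IngestError(f"unknown language_hint: {self.language_hint!r}")


@dataclass(frozen=True)
class UniqueName:
    """A distinct raw name with its multiplicity in the full dataset."""

    raw_name: str
    multiplicity: int
    source_centers: frozenset[str] = frozenset()
    ground_truth: Optional[str] = None


# -- DICOM -----------------------------------------------------------------


def read_rtstruct_names(path: str | Path) -> list[RawStructure]:
    """Read ROI names from a DICOM RT Structure Set, in file order.

    Only name metadata is touched; contour geometry is never loaded.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
    except (InvalidDicomError, FileNotFoundError, PermissionError) as exc:
        raise IngestError(f"{path}: not a readable DICOM file ({exc})") from exc
    if "StructureSetROISequence" not in ds:
        raise IngestError(f"{path}: DICOM object has no Structure Set ROI Sequence")
    center = str(getattr(ds, "InstitutionName", "") or "unknown")
    patient = str(getattr(ds, "PatientID", "") or "") or None
    records = []
    for roi in ds.StructureSetROISequence:
        name = str(getattr(roi, "ROIName", "") or "").strip()
        if name:
            records.append(
                RawStructure(raw_name=name, center_id=center, patient_id=patient)
            )
    return records


# -- tabular I/O ------------------------------------------------------------


def read_structure_table(path: str | Path) -> list[RawStructure]:
    """Read a tab-delimited table with columns raw_name [center_id patient_id
    language_hint ground_truth operators]."""
    path = Path(path)
    if not path.exists():
        raise IngestError(f"structure table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "raw_name" not in frame.columns:
        raise IngestError(f"{path}: missing required column 'raw_name'")
    records = []
    for _, row in frame.iterrows():
        gt = row.get("ground_truth", "")
        ops = tuple(filter(None, row.get("operators", "").split(";")))
        records.append(
            RawStructure(
                raw_name=row["raw_name"],
                center_id=row.get("center_id", "") or "unknown",
                patient_id=row.get("patient_id", "") or None,
                language_hint=row.get("language_hint", "") or "unknown",
                ground_truth=canonical_label(gt) if gt.strip() else None,
                operators=ops,
            )
        )
    return records


def write_structure_table(records: Sequence[RawStructure], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "raw_name": [r.raw_name for r in records],
            "center_id": [r.center_id for r in records],
            "patient_id": [r.patient_id or "" for r in records],
            "language_hint": [r.language_hint for r in records],
            "ground_truth": [r.ground_truth or "" for r in records],
            "operators": [";".join(r.operators) for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# -- filtering --------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionRule:
    """A tagged case-insensitive regex; matching structures are excluded."""

    tag: str
    pattern: str

    def compile(self) -> re.Pattern:
        try:
            return re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(
                f"exclusion rule {self.tag!r}: invalid pattern {self.pattern!r} ({exc})"
            ) from exc


#: Stand-in for the manual exclusion of target volumes and auxiliary planning
#: structures; fully overridable by the caller.
DEFAULT_EXCLUSION_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule("target", r"\b(ptv|ctv|gtv|itv)|boost"),
    ExclusionRule("auxiliary", r"\b(couch|table|bolus|mask|iso|dummy|marker|ring)\b"),
    ExclusionRule("auxiliary", r"\b(help|hulp|hilfs\w*)"),
    ExclusionRule("auxiliary", r"\bopt\b"),
)


def filter_structures(
    records: Sequence[RawStructure],
    rules: Sequence[ExclusionRule] = DEFAULT_EXCLUSION_RULES,
) -> tuple[list[RawStructure], list[tuple[RawStructure, str]]]:
    """Partition *records* into (kept, excluded-with-rule-tag).

    The first matching rule wins; with an empty rule set everything is kept.
    """
    compiled = [(rule.tag, rule.compile()) for rule in rules]
    kept: list[RawStructure] = []
    excluded: list[tuple[RawStructure, str]] = []
    for record in records:
        for tag, pattern in compiled:
            if pattern.search(record.raw_name):
                excluded.append((record, tag))
                break
        else:
            kept.append(record)
    return kept, excluded


# -- deduplication ----------------------------------------------------------


def deduplicate(records: Sequence[RawStructure]) -> list[UniqueName]:
    """Collapse records to distinct trimmed raw names, pooled across centers.

    Output is sorted by descending multiplicity, then name. Ground truth is
    carried over when all duplicates agree (conflicts keep the most frequent
    label).
    """
    counts: Counter[str] = Counter()
    centers: defaultdict[str, set[str]] = defaultdict(set)
    truths: defaultdict[str, Counter] = defaultdict(Counter)
    for record in records:
        key = record.raw_name.strip()
        counts[key] += 1
        centers[key].add(record.center_id)
        if record.ground_truth is not None:
            truths[key][record.ground_truth] += 1
    uniques = []
    for name, mult in counts.items():
        gt = truths[name].most_common(1)[0][0] if truths[name] else None
        uniques.append(
            UniqueName(
                raw_name=name,
                multiplicity=mult,
                source_centers=frozenset(centers[name]),
                ground_truth=gt,
            )
        )
    uniques.sort(key=lambda u: (-u.multiplicity, u.raw_name))
    return uniques


def write_unique_table(uniques: Sequence[UniqueName], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "raw_name": [u.raw_name for u in uniques],
            "multiplicity": [u.multiplicity for u in uniques],
            "source_centers": [",".join(sorted(u.source_centers)) for u in uniques],
            "ground_truth": [u.ground_truth or "" for u in uniques],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_unique_table(path: str | Path) -> list[UniqueName]:
    path = Path(path)
    if not path.exists():
        raise IngestError(f"unique-name table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "raw_name" not in frame.columns:
        raise IngestError(f"{path}: missing required column 'raw_name'")
    uniques = []
    for _, row in frame.iterrows():
        gt = row.get("ground_truth", "")
        uniques.append(
            UniqueName(
                raw_name=row["raw_name"],
                multiplicity=int(row.get("multiplicity", "1") or 1),
                source_centers=frozenset(
                    filter(None, row.get("source_centers", "").split(","))
                ),
                ground_truth=canonical_label(gt) if gt.strip() else None,
            )
        )
    return uniques
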