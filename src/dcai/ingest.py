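"""Cohort construction from LIDC-IDRI-style nodule annotations.

Each nodule carries ratings from three or four radiologists: a malignancy
score (ordinal 1-5) plus nine structured radiographic attributes.  This
module applies the cohort rules — keep nodules at least 3 mm in diameter with
at least three readers, derive a binary label from the rounded mean
malignancy score (1-2 benign, 4-5 malignant, 3 excluded), impute a missing
fourth reader by the rounded mean of the other three — and assembles the
9 attributes x 4 readers rating matrix S consumed by the classifier.

Input can be the original LIDC XML annotation files or an equivalent flat
CSV table (one row per nodule-reader); both produce the same records.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed attribute row order of the rating matrix.  Malignancy is excluded
#: (it is the classification target); diameter is per-nodule and replicated
#: across reader columns.
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "subtlety",
    "internal_structure",
    "calcification",
    "sphericity",
    "margin",
    "lobulation",
    "spiculation",
    "texture",
    "diameter",
)

#: Valid value range per attribute (LIDC ordinal scales; diameter in mm with
#: a fixed clip range used only for model-input scaling).
ORDINAL_RANGES: dict[str, tuple[float, float]] = {
    "subtlety": (1, 5),
    "internal_structure": (1, 4),
    "calcification": (1, 6),
    "sphericity": (1, 5),
    "margin": (1, 5),
    "lobulation": (1, 5),
    "spiculation": (1, 5),
    "texture": (1, 5),
    "diameter": (0.0, 40.0),
}

MIN_DIAMETER_MM = 3.0
MIN_READERS = 3
N_READERS = 4
N_ATTRIBUTES = len(ATTRIBUTE_NAMES)

BENIGN, MALIGNANT, EXCLUDED = "benign", "malignant", "excluded"
LABEL_CODES = {BENIGN: 0, MALIGNANT: 1}


class AnnotationError(ValueError):
    """Raised when an annotation violates the expected value ranges."""


@dataclass
class ReaderAnnotation:
    """One radiologist's ratings for one nodule."""

    reader_id: str
    malignancy: int | None
    attributes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.malignancy is not None and self.malignancy not in (1, 2, 3, 4, 5):
            raise AnnotationError(
                f"reader {self.reader_id}: malignancy {self.malignancy} not in 1..5")
        unknown = set(self.attributes) - set(ATTRIBUTE_NAMES)
        if unknown:
            raise AnnotationError(
                f"reader {self.reader_id}: unknown attributes {sorted(unknown)}")


@dataclass
class NoduleRecord:
    nodule_id: str
    scan_id: str
    centre_mm: tuple[float, float, float]  # (z, y, x) scanner frame
    diameter_mm: float
    annotations: list[ReaderAnnotation] = field(default_factory=list)


@dataclass
class RatingMatrix:
    """The 9x4 structured-feature matrix S (attribute rows, reader columns)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_ATTRIBUTES, N_READERS):
            raise ValueError(f"rating matrix must be 9x4, got {self.values.shape}")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rating matrix contains missing entries")
        for i, name in enumerate(ATTRIBUTE_NAMES):
            lo, hi = ORDINAL_RANGES[name]
            row = self.values[i]
            if row.min() < lo or row.max() > hi:
                raise ValueError(
                    f"{name} values {row} outside ordinal range [{lo}, {hi}]")


@dataclass
class LabeledSample:
    nodule_id: str
    rating_matrix: RatingMatrix
    label: int  # 0 benign, 1 malignant
    cube: "np.ndarray | None" = None  # filled by volume preparation


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (toward the larger integer)."""
    return int(math.floor(x + 0.5))


def round_half_even(x: float) -> int:
    return int(round(x))


_ROUNDERS = {"half_up": round_half_up, "half_even": round_half_even}


def select_cohort(records: list[NoduleRecord]) -> list[NoduleRecord]:
    """Keep nodules >= 3 mm in diameter annotated by at least three readers.

    Order-preserving and idempotent.  Records with no annotations at all are
    dropped with a logged reason rather than an exception.
    """
    selected = []
    for rec in records:
        if not rec.annotations:
            logger.warning("nodule %s rejected: no annotations", rec.nodule_id)
            continue
        if rec.diameter_mm < MIN_DIAMETER_MM:
            continue
        if len(rec.annotations) < MIN_READERS:
            continue
        selected.append(rec)
    return selected


def derive_label(malignancy_scores: list[int], tie_rule: str = "half_up",
                 nodule_id: str = "?") -> str:
    """Binary label from the rounded mean malignancy score.

    Mean over present scores, rounded to the nearest integer; 1-2 benign,
    4-5 malignant, 3 excluded (diagnostic uncertainty).
    """
    if not malignancy_scores:
        raise AnnotationError(f"nodule {nodule_id}: no malignancy scores")
    for s in malignancy_scores:
        if s not in (1, 2, 3, 4, 5):
            raise AnnotationError(
                f"nodule {nodule_id}: malignancy score {s} outside 1..5")
    rounded = _ROUNDERS[tie_rule](float(np.mean(malignancy_scores)))
    if rounded <= 2:
        return BENIGN
    if rounded >= 4:
        return MALIGNANT
    return EXCLUDED


def impute_reader(attribute_values: list[float], attribute: str,
                  tie_rule: str = "half_up") -> int:
    """Fourth-reader value: rounded mean of the three present annotations,
    clamped to the attribute's ordinal range."""
    if len(attribute_values) != 3:
        raise AnnotationError(
            f"imputation requires exactly 3 present values for {attribute}, "
            f"got {len(attribute_values)}")
    lo, hi = ORDINAL_RANGES[attribute]
    val = _ROUNDERS[tie_rule](float(np.mean(attribute_values)))
    return int(min(max(val, lo), hi))


def build_rating_matrix(record: NoduleRecord,
                        tie_rule: str = "half_up") -> RatingMatrix:
    """Assemble the 9x4 matrix for a cohort record.

    Reader columns are sorted by reader id; when only three readers annotated
    the nodule, the imputed reader occupies the fourth column.  The per-nodule
    diameter is replicated across all four columns.
    """
    readers = sorted(record.annotations, key=lambda a: str(a.reader_id))
    if not MIN_READERS <= len(readers) <= N_READERS:
        raise AnnotationError(
            f"nodule {record.nodule_id}: expected 3-4 readers, got {len(readers)}")
    values = np.full((N_ATTRIBUTES, N_READERS), np.nan)
    for i, name in enumerate(ATTRIBUTE_NAMES):
        if name == "diameter":
            values[i, :] = record.diameter_mm
            continue
        present = [a.attributes[name] for a in readers if name in a.attributes]
        if len(present) < 3:
            raise AnnotationError(
                f"nodule {record.nodule_id}: attribute {name} present for only "
                f"{len(present)} readers; imputation is defined only for one "
                f"missing reader")
        values[i, :len(present)] = present
        for j in range(len(present), N_READERS):
            values[i, j] = impute_reader(present[:3], name, tie_rule)
    matrix = RatingMatrix(values)
    matrix.validate()
    return matrix


def scale_ratings(values: np.ndarray) -> np.ndarray:
    """Affine per-attribute rescaling of a (..., 9, 4) rating array to [0, 1].

    Uses the fixed ordinal ranges, not data statistics, so scaling is
    identical across folds and datasets.  Diameter is clipped to its fixed
    range before scaling.
    """
    values = np.asarray(values, dtype=np.float64)
    lo = np.array([ORDINAL_RANGES[a][0] for a in ATTRIBUTE_NAMES])
    hi = np.array([ORDINAL_RANGES[a][1] for a in ATTRIBUTE_NAMES])
    lo = lo.reshape((9, 1))
    hi = hi.reshape((9, 1))
    clipped = np.clip(values, lo, hi)
    return (clipped - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["scan_id", "nodule_id", "reader_id", "malignancy",
                *[a for a in ATTRIBUTE_NAMES if a != "diameter"],
                "diameter_mm", "centre_z", "centre_y", "centre_x"]


def read_annotation_csv(path: str | Path) -> list[NoduleRecord]:
    """Read the flat annotation table: one row per nodule-reader.

    Required columns: scan_id, nodule_id, reader_id, malignancy, the eight
    per-reader attributes, diameter_mm, centre_z/y/x.  Attribute cells may be
    empty (missing annotation).
    """
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    records: dict[str, NoduleRecord] = {}
    for _, row in df.iterrows():
        key = f"{row['scan_id']}:{row['nodule_id']}"
        if key not in records:
            records[key] = NoduleRecord(
                nodule_id=str(row["nodule_id"]),
                scan_id=str(row["scan_id"]),
                centre_mm=(float(row["centre_z"]), float(row["centre_y"]),
                           float(row["centre_x"])),
                diameter_mm=float(row["diameter_mm"]),
            )
        attrs = {}
        for name in ATTRIBUTE_NAMES:
            if name == "diameter":
                continue
            val = row[name]
            if pd.notna(val):
                attrs[name] = float(val)
        mal = row["malignancy"]
        records[key].annotations.append(ReaderAnnotation(
            reader_id=str(row["reader_id"]),
            malignancy=int(mal) if pd.notna(mal) else None,
            attributes=attrs,
        ))
    return list(records.values())


_XML_ATTR_MAP = {
    "subtlety": "subtlety",
    "internalStructure": "internal_structure",
    "internalstructure": "internal_structure",
    "calcification": "calcification",
    "sphericity": "sphericity",
    "margin": "margin",
    "lobulation": "lobulation",
    "spiculation": "spiculation",
    "texture": "texture",
}


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_annotation_xml(path: str | Path, scan_id: str | None = None,
                        diameters: dict[str, float] | None = None,
                        centres: dict[str, tuple[float, float, float]] | None = None,
                        ) -> list[NoduleRecord]:
    """Read one LIDC-style XML annotation file (two-phase reading sessions).

    Each ``readingSession`` is one radiologist; each ``unblindedReadNodule``
    with a ``characteristics`` block is one nodule annotation.  Nodules are
    matched across readers by their ``noduleID``.  Diameter and centre are
    not part of the XML characteristics; they are supplied via ``diameters``
    and ``centres`` maps (as the external nodule list provides them), else
    NaN/zero placeholders are used.
    """
    root = ET.parse(str(path)).getroot()
    scan = scan_id or Path(path).stem
    records: dict[str, NoduleRecord] = {}
    reader_idx = 0
    for session in root.iter():
        if _strip_ns(session.tag) != "readingSession":
            continue
        reader_idx += 1
        reader_id = f"reader{reader_idx}"
        for nodule in session.iter():
            if _strip_ns(nodule.tag) != "unblindedReadNodule":
                continue
            nodule_id, malignancy, attrs = None, None, {}
            for el in nodule.iter():
                tag = _strip_ns(el.tag)
                text = (el.text or "").strip()
                if tag == "noduleID":
                    nodule_id = text
                elif tag == "malignancy" and text:
                    malignancy = int(float(text))
                elif tag in _XML_ATTR_MAP and text:
                    attrs[_XML_ATTR_MAP[tag]] = float(text)
            if nodule_id is None or not attrs:
                continue
            if nodule_id not in records:
                records[nodule_id] = NoduleRecord(
                    nodule_id=nodule_id,
                    scan_id=scan,
                    centre_mm=(centres or {}).get(nodule_id, (0.0, 0.0, 0.0)),
                    diameter_mm=(diameters or {}).get(nodule_id, float("nan")),
                )
            records[nodule_id].annotations.append(ReaderAnnotation(
                reader_id=reader_id, malignancy=malignancy, attributes=attrs))
    return list(records.values())


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(records: list[NoduleRecord], tie_rule: str = "half_up",
                 ) -> tuple[list[LabeledSample], dict[str, int]]:
    """Run selection, labeling and matrix assembly over raw records.

    Returns labeled samples (cubes unfilled) and a count summary with keys
    benign / malignant / excluded / rejected.
    """
    n_input = len(records)
    cohort = select_cohort(records)
    samples: list[LabeledSample] = []
    counts = {BENIGN: 0, MALIGNANT: 0, EXCLUDED: 0}
    for rec in cohort:
        scores = [a.malignancy for a in rec.annotations if a.malignancy is not None]
        label = derive_label(scores, tie_rule, nodule_id=rec.nodule_id)
        counts[label] += 1
        if label == EXCLUDED:
            continue
        matrix = build_rating_matrix(rec, tie_rule)
        samples.append(LabeledSample(
            nodule_id=f"{rec.scan_id}:{rec.nodule_id}",
            rating_matrix=matrix,
            label=LABEL_CODES[label],
        ))
    summary = {
        "benign": counts[BENIGN],
        "malignant": counts[MALIGNANT],
        "excluded": counts[EXCLUDED],
        "rejected": n_input - len(cohort),
        "total_labeled": counts[BENIGN] + counts[MALIGNANT],
    }
    return samples, summary


def cohort_manifest(samples: list[LabeledSample],
                    records: dict[str, NoduleRecord] | None = None) -> pd.DataFrame:
    """Flat manifest: one row per labeled nodule with the 9x4 values."""
    rows = []
    for s in samples:
        row: dict[str, object] = {"nodule_id": s.nodule_id, "label": s.label}
        for i, name in enumerate(ATTRIBUTE_NAMES):
            for j in range(N_READERS):
                row[f"{name}_r{j}"] = s.rating_matrix.values[i, j]
        if records and s.nodule_id in records:
            rec = records[s.nodule_id]
            row["centre_z"], row["centre_y"], row["centre_x"] = rec.centre_mm
        rows.append(row)
    return pd.DataFrame(rows)
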