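"""Warrick visual HRCT score (CoVR) for interstitial lung disease.

Two readers grade five abnormality patterns.  Severity adds a fixed point
value per pattern present (ground-glass 1, irregular pleural margins 2,
septal/subpleural lines 3, honeycombing 4, subpleural cysts 5).  Extent adds,
per pattern, a category for the number of bronchopulmonary segments involved
(0 segments -> 0, 1-3 -> 1, 4-9 -> 2, >9 -> 3).  Total = severity + extent,
range 0-30.  Dual-reader results are combined as the component-wise mean, or
by a consensus assessment supplied as data.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class Abnormality(enum.Enum):
    GROUND_GLASS = "ground_glass"
    IRREGULAR_PLEURAL_MARGINS = "irregular_pleural_margins"
    SEPTAL_SUBPLEURAL_LINES = "septal_subpleural_lines"
    HONEYCOMBING = "honeycombing"
    SUBPLEURAL_CYSTS = "subpleural_cysts"


_SEVERITY_POINTS: dict[Abnormality, int] = {
    Abnormality.GROUND_GLASS: 1,
    Abnormality.IRREGULAR_PLEURAL_MARGINS: 2,
    Abnormality.SEPTAL_SUBPLEURAL_LINES: 3,
    Abnormality.HONEYCOMBING: 4,
    Abnormality.SUBPLEURAL_CYSTS: 5,
}

#: 18-segment bronchopulmonary atlas: 10 right, 8 left (apicoposterior and
#: anteromedial-basal fused on the left).
SEGMENT_ATLAS: tuple[str, ...] = (
    "R_apical", "R_posterior", "R_anterior",
    "R_lateral", "R_medial",
    "R_superior", "R_medial_basal", "R_anterior_basal",
    "R_lateral_basal", "R_posterior_basal",
    "L_apicoposterior", "L_anterior",
    "L_superior_lingular", "L_inferior_lingular",
    "L_superior", "L_anteromedial_basal",
    "L_lateral_basal", "L_posterior_basal",
)
_SEGMENT_SET = frozenset(SEGMENT_ATLAS)
MAX_SEGMENTS = len(SEGMENT_ATLAS)


@dataclasses.dataclass
class WarrickFinding:
    """One abnormality pattern and the segments in which it was seen."""

    abnormality: Abnormality
    segments: frozenset[str]

    def __post_init__(self) -> None:
        self.abnormality = Abnormality(self.abnormality)
        segments = frozenset(self.segments)
        if not segments:
            raise ValueError("segments must be non-empty")
        unknown = segments - _SEGMENT_SET
        if unknown:
            raise ValueError(f"unknown segment identifiers: {sorted(unknown)}")
        self.segments = segments


@dataclasses.dataclass
class WarrickScore:
    severity: float
    extent: float
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.severity + self.extent)) > 1e-9:
            raise ValueError("total must equal severity + extent")
        if not (0 <= self.severity <= 15 and 0 <= self.extent <= 15):
            raise ValueError("severity and extent must lie in [0, 15]")


@dataclasses.dataclass
class ReaderAssessment:
    reader_id: str
    findings: list[WarrickFinding]

    def __post_init__(self) -> None:
        seen = [f.abnormality for f in self.findings]
        if len(seen) != len(set(seen)):
            raise ValueError("duplicate abnormality entries in assessment")


def severity_points(abnormality: Abnormality | str) -> int:
    """Fixed point value of an abnormality pattern."""
    try:
        return _SEVERITY_POINTS[Abnormality(abnormality)]
    except ValueError as exc:
        raise ValueError(f"unknown abnormality: {abnormality!r}") from exc


def extent_points(n_segments: int) -> int:
    """Extent category for the number of involved segments."""
    if n_segments < 0 or n_segments > MAX_SEGMENTS:
        raise ValueError(f"n_segments must be in [0, {MAX_SEGMENTS}]")
    if n_segments == 0:
        return 0
    if n_segments <= 3:
        return 1
    if n_segments <= 9:
        return 2
    return 3


def score_assessment(assessment: ReaderAssessment) -> WarrickScore:
    """Severity, extent and total for one reader's findings."""
    by_type = {f.abnormality: f for f in assessment.findings}
    severity = sum(severity_points(a) for a in by_type)
    extent = sum(
        extent_points(len(by_type[a].segments)) if a in by_type else 0
        for a in Abnormality
    )
    return WarrickScore(severity=severity, extent=extent, total=severity + extent)


def aggregate_readers(
    a1: WarrickScore,
    a2: WarrickScore,
    mode: str = "mean",
    adjudication: WarrickScore | None = None,
) -> WarrickScore:
    """Combine two readers' scores.

    ``mean`` takes the component-wise arithmetic mean; ``consensus`` returns
    the adjudicated assessment, which must be supplied by the caller (the
    adjudication is data, not computation).
    """
    if mode == "mean":
        return WarrickScore(
            severity=(a1.severity + a2.severity) / 2.0,
            extent=(a1.extent + a2.extent) / 2.0,
            total=(a1.total + a2.total) / 2.0,
        )
    if mode == "consensus":
        if adjudication is None:
            raise ValueError("consensus mode requires an adjudicated assessment")
        return adjudication
    raise ValueError(f"unknown aggregation mode: {mode!r}")


# ---------------------------------------------------------------------------
# CSV ingest: one row per (study, reader, abnormality, segment)
# ---------------------------------------------------------------------------

FINDINGS_COLUMNS = ("study_id", "reader_id", "abnormality", "segment_code")


def read_findings_csv(path: str | Path) -> dict[tuple[str, str], ReaderAssessment]:
    """Load per-segment findings and aggregate them into assessments."""
    frame = pd.read_csv(path, dtype=str)
    missing = set(FINDINGS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"findings CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], ReaderAssessment] = {}
    grouped = frame.groupby(["study_id", "reader_id"], sort=True)
    for (study, reader), rows in grouped:
        findings = [
            WarrickFinding(
                abnormality=Abnormality(abn),
                segments=frozenset(sub["segment_code"]),
            )
            for abn, sub in rows.groupby("abnormality", sort=True)
        ]
        out[(study, reader)] = ReaderAssessment(reader_id=reader, findings=findings)
    return out


def score_studies(
    assessments: Mapping[tuple[str, str], ReaderAssessment],
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Score every study; studies with two readers are aggregated.

    Returns one row per study with severity/extent/total (aggregated when
    two readers are present, the single reader's score otherwise).
    """
    studies: dict[str, list[WarrickScore]] = {}
    for (study, _reader), assessment in sorted(assessments.items()):
        studies.setdefault(study, []).append(score_assessment(assessment))
    rows = []
    for study, scores in studies.items():
        if len(scores) == 1:
            final = scores[0]
        elif len(scores) == 2:
            final = aggregate_readers(scores[0], scores[1], mode=aggregate)
        else:
            raise ValueError(f"study {study!r} has {len(scores)} readers; expected 1 or 2")
        rows.append(
            {
                "study_id": study,
                "severity": final.severity,
                "extent": final.extent,
                "total": final.total,
                "n_readers": len(scores),
            }
        )
    return pd.DataFrame(rows)
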