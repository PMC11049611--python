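"""Patient-cohort container, CSV I/O and the bundled reference cohort.

A cohort is an ordered collection of patients, each carrying three
immunohistochemical marker readings expressed as integer percentages --
p16-positive tumour cells, CD8-positive peritumoral tumour-infiltrating
lymphocytes (TILs) and the Ki67 proliferation index -- together with the
CDKN2A copy-number call obtained by dual-colour FISH (disomy, monosomy,
heterozygous deletion or homozygous deletion) and an optional test/validation
split label.

The bundled cohort of 23 multiple-primary/familial melanoma patients is the
reference dataset the scoring rubric was derived on; :func:`bundled_cohort`
returns it and :func:`reported_totals` exposes the originally reported
per-patient composite scores as regression metadata (the scorer never reads
them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Union

import pandas as pd

__all__ = [
    "Cdkn2aStatus",
    "Split",
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "bundled_cohort",
    "reported_totals",
]

_REQUIRED_COLUMNS = ("patient_id", "p16_pct", "cd8_pct", "ki67_pct", "cdkn2a")
_MARKER_FIELDS = ("p16_pct", "cd8_pct", "ki67_pct")
_FIXTURE_NAME = "mpm_fm_cohort.csv"


class CohortSchemaError(ValueError):
    """The CSV header does not carry the required columns."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (range, status, duplicate id)."""


class Cdkn2aStatus(Enum):
    """CDKN2A copy-number call from FISH.

    ``is_mutated`` groups homo- and heterozygous deletions (the "CDKN2A-mut"
    dichotomy used for group statistics); ``is_homozygous`` marks the class
    the triple score is designed to detect.
    """

    DISOMY = "disomy"
    MONOSOMY = "monosomy"
    HETEROZYGOUS_DELETION = "heterozygous_deletion"
    HOMOZYGOUS_DELETION = "homozygous_deletion"

    @property
    def is_mutated(self) -> bool:
        return self in (
            Cdkn2aStatus.HETEROZYGOUS_DELETION,
            Cdkn2aStatus.HOMOZYGOUS_DELETION,
        )

    @property
    def is_homozygous(self) -> bool:
        return self is Cdkn2aStatus.HOMOZYGOUS_DELETION

    @classmethod
    def parse(cls, text: str) -> "Cdkn2aStatus":
        """Parse a status string case-insensitively.

        Spaces and underscores are interchangeable, so both the machine form
        ``heterozygous_deletion`` and the display form ``Heterozygous
        deletion`` are accepted.
        """
        key = str(text).strip().lower().replace(" ", "_")
        try:
            return cls(key)
        except ValueError:
            raise CohortValidationError(f"unknown CDKN2A status: {text!r}") from None


class Split(Enum):
    """Test/validation assignment of a record within a cohort."""

    TEST = "test"
    VALIDATION = "validation"
    UNASSIGNED = "unassigned"

    @classmethod
    def parse(cls, text: str) -> "Split":
        key = str(text).strip().lower()
        if key in ("", "nan", "none"):
            return cls.UNASSIGNED
        try:
            return cls(key)
        except ValueError:
            raise CohortValidationError(f"unknown split label: {text!r}") from None


def _round_half_up(value: float) -> int:
    """Round a non-negative percentage half-up to the integer grid."""
    return int(math.floor(float(value) + 0.5))


@dataclass(frozen=True)
class PatientRecord:
    """One patient: marker percentages, CDKN2A call, optional split label."""

    patient_id: str
    p16_pct: int
    cd8_pct: int
    ki67_pct: int
    cdkn2a: Cdkn2aStatus
    split: Split = Split.UNASSIGNED

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, str) or not self.patient_id.strip():
            raise CohortValidationError("patient_id must be a non-empty string")
        for name in _MARKER_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name} must be an integer, got {value!r}"
                )
            if not 0 <= value <= 100:
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name}={value} outside [0, 100]"
                )
        if not isinstance(self.cdkn2a, Cdkn2aStatus):
            raise CohortValidationError(
                f"record {self.patient_id!r}: cdkn2a must be a Cdkn2aStatus"
            )
        if not isinstance(self.split, Split):
            raise CohortValidationError(
                f"record {self.patient_id!r}: split must be a Split"
            )


@dataclass(frozen=True)
class Cohort:
    """Ordered, duplicate-free collection of patient records."""

    records: tuple[PatientRecord, ...]
    name: str = "cohort"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortValidationError(
                    f"duplicate patient_id: {rec.patient_id!r}"
                )
            seen.add(rec.patient_id)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def filter_split(self, split: Union[Split, str, None]) -> "Cohort":
        """Restrict to one split label; ``None`` or ``"all"`` is a no-op."""
        if split is None or split == "all":
            return self
        split = Split(split) if not isinstance(split, Split) else split
        return Cohort(
            tuple(r for r in self.records if r.split is split),
            name=f"{self.name}[{split.value}]",
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per record, in input order."""
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "p16_pct": [r.p16_pct for r in self.records],
                "cd8_pct": [r.cd8_pct for r in self.records],
                "ki67_pct": [r.ki67_pct for r in self.records],
                "cdkn2a": [r.cdkn2a.value for r in self.records],
                "split": [r.split.value for r in self.records],
            }
        )


def _coerce_percent(raw: object, patient_id: str, column: str) -> int:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"record {patient_id!r}: {column}={raw!r} is not a number"
        ) from None
    if math.isnan(value):
        raise CohortValidationError(f"record {patient_id!r}: {column} is missing")
    if not 0 <= value <= 100:
        raise CohortValidationError(
            f"record {patient_id!r}: {column}={value} outside [0, 100]"
        )
    return _round_half_up(value)


def read_cohort(
    source: Union[str, Path, IO[str]],
    name: str | None = None,
    **csv_options: object,
) -> Cohort:
    """Read and validate a cohort from CSV.

    The header must contain at least ``patient_id, p16_pct, cd8_pct,
    ki67_pct, cdkn2a``; a ``split`` column is optional and further columns are
    ignored.  Percentages may be fractional in the file and are rounded
    half-up onto the integer grid the scoring rubric is defined on.  Status
    strings are matched case-insensitively with spaces and underscores
    interchangeable.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False, **csv_options)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    has_split = "split" in frame.columns

    records = []
    for row in frame.itertuples(index=False):
        patient_id = str(getattr(row, "patient_id")).strip()
        if not patient_id:
            raise CohortValidationError("empty patient_id")
        records.append(
            PatientRecord(
                patient_id=patient_id,
                p16_pct=_coerce_percent(getattr(row, "p16_pct"), patient_id, "p16_pct"),
                cd8_pct=_coerce_percent(getattr(row, "cd8_pct"), patient_id, "cd8_pct"),
                ki67_pct=_coerce_percent(
                    getattr(row, "ki67_pct"), patient_id, "ki67_pct"
                ),
                cdkn2a=Cdkn2aStatus.parse(getattr(row, "cdkn2a")),
                split=Split.parse(getattr(row, "split")) if has_split else Split.UNASSIGNED,
            )
        )
    if name is None:
        name = Path(source).stem if isinstance(source, (str, Path)) else "cohort"
    return Cohort(tuple(records), name=name)


def write_cohort(cohort: Cohort, destination: Union[str, Path, IO[str]]) -> None:
    """Write a cohort as CSV; ``read_cohort`` of the output reproduces it."""
    cohort.to_frame().to_csv(destination, index=False)


def bundled_cohort() -> Cohort:
    """The 23-patient multiple-primary/familial melanoma reference cohort.

    Contains 7 homozygous deletions, 3 heterozygous deletions, 6 monosomies
    and 7 disomies, with the original 11-patient test / 12-patient validation
    split encoded in the ``split`` field.
    """
    with resources.files("triplescore.data").joinpath(_FIXTURE_NAME).open(
        "r", encoding="utf-8"
    ) as handle:
        return read_cohort(handle, name="mpm_fm_cohort")


def reported_totals() -> dict[str, int]:
    """Originally reported composite score per bundled patient.

    Regression metadata only: one entry (CV005) is internally inconsistent
    with the published rubric and is documented as such where compared.
    """
    with resources.files("triplescore.data").joinpath(_FIXTURE_NAME).open(
        "r", encoding="utf-8"
    ) as handle:
        frame = pd.read_csv(handle)
    return dict(zip(frame["patient_id"], frame["reported_total"].astype(int)))
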