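"""Longitudinal cohort data model with decision-aligned labelling.

A cohort is a set of patients, each with an ordered timeline of MRI
sessions and a single clinical decision ("progressive" or "responsive")
assigned at one of those sessions by radiological response assessment.
Sessions are aligned on the decision session: offset 0 is the decision,
negative offsets precede it.  Labels propagate forward from the decision
(all sessions at and after the decision carry the decision class; earlier
sessions are unlabeled), which is what makes pre-decision sessions the
natural test bed for early relapse prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .schema import (
    CLASSES,
    DEFAULT_SCHEMA,
    FeatureSchema,
    SchemaError,
    SubsetSchema,
    UNLABELED,
    subset_schema,
)

ID_COLUMNS = ("patient_id", "session_index", "decision_class", "decision_session")


class CohortValidationError(ValueError):
    """Base class for feature-table validation failures."""


class DuplicateSessionError(CohortValidationError):
    """The same (patient, session) pair appears more than once."""


class AlwaysPresentError(CohortValidationError):
    """An always-present column has a missing value."""


class DecisionSessionError(CohortValidationError):
    """A patient's decision session is not among their sessions."""


@dataclass
class TimePoint:
    """One MRI session: feature vector, missingness mask, label state."""

    patient_id: str
    session_index: int
    features: np.ndarray
    missing_mask: np.ndarray
    offset: int | None = None
    label: str = UNLABELED

    def copy(self) -> "TimePoint":
        return replace(
            self,
            features=self.features.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()


@dataclass
class PatientRecord:
    """A patient's ordered timeline plus the clinical decision.

    The patient, not the session, is the unit of cross-validation.
    """

    patient_id: str
    decision_class: str
    decision_session: int
    timepoints: list[TimePoint] = field(default_factory=list)

    def validate(self) -> None:
        if self.decision_class not in CLASSES:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: decision_class must be one of "
                f"{CLASSES}, got {self.decision_class!r}"
            )
        sessions = [tp.session_index for tp in self.timepoints]
        if any(b <= a for a, b in zip(sessions, sessions[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: session indices not strictly increasing"
            )
        if self.decision_session not in sessions:
            raise DecisionSessionError(
                f"patient {self.patient_id!r}: decision_session "
                f"{self.decision_session} not among sessions {sessions}"
            )

    @property
    def decision_position(self) -> int:
        """Position of the decision session within the timeline."""
        for pos, tp in enumerate(self.timepoints):
            if tp.session_index == self.decision_session:
                return pos
        raise DecisionSessionError(
            f"patient {self.patient_id!r}: decision_session "
            f"{self.decision_session} not among sessions"
        )


@dataclass
class Cohort:
    """A schema plus a list of patient records."""

    schema: FeatureSchema | SubsetSchema
    patients: list[PatientRecord] = field(default_factory=list)

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise CohortValidationError("duplicate patient_ids")
        n = len(self.schema.names)
        always = getattr(self.schema, "always_present", frozenset())
        always_idx = [i for i, name in enumerate(self.schema.names) if name in always]
        for patient in self.patients:
            patient.validate()
            for tp in patient.timepoints:
                if tp.features.shape != (n,) or tp.missing_mask.shape != (n,):
                    raise CohortValidationError(
                        f"patient {patient.patient_id!r} session {tp.session_index}: "
                        f"expected {n} features"
                    )
                if tp.missing_mask[always_idx].any():
                    bad = [
                        self.schema.names[i]
                        for i in always_idx
                        if tp.missing_mask[i]
                    ]
                    raise AlwaysPresentError(
                        f"patient {patient.patient_id!r} session "
                        f"{tp.session_index}: missing always-present {bad}"
                    )

    def iter_timepoints(self) -> Iterator[TimePoint]:
        for patient in self.patients:
            yield from patient.timepoints

    @property
    def n_timepoints(self) -> int:
        return sum(len(p.timepoints) for p in self.patients)

    def copy(self) -> "Cohort":
        return Cohort(
            schema=self.schema,
            patients=[
                replace(p, timepoints=[tp.copy() for tp in p.timepoints])
                for p in self.patients
            ],
        )


def propagate_labels(patient: PatientRecord) -> PatientRecord:
    """Assign offsets and decision-aligned labels along a timeline.

    Offsets count ordinal positions in the session sequence relative to
    the decision session (follow-up intervals change over the study, so
    alignment is by session index, not calendar time).  Sessions at and
    after the decision carry the patient's decision class; all earlier
    sessions are unlabeled.  Idempotent.
    """
    patient.validate()
    pivot = patient.decision_position
    timepoints = []
    for pos, tp in enumerate(patient.timepoints):
        offset = pos - pivot
        label = patient.decision_class if offset >= 0 else UNLABELED
        timepoints.append(replace(tp.copy(), offset=offset, label=label))
    return replace(patient, timepoints=timepoints)


def propagate_all(cohort: Cohort) -> Cohort:
    """Apply :func:`propagate_labels` to every patient."""
    return Cohort(cohort.schema, [propagate_labels(p) for p in cohort.patients])


def select_complete(cohort: Cohort) -> Cohort:
    """Keep only fully observed sessions; drop patients left empty."""
    patients = []
    for patient in cohort.patients:
        kept = [tp.copy() for tp in patient.timepoints if tp.is_complete]
        if kept:
            patients.append(replace(patient, timepoints=kept))
    return Cohort(cohort.schema, patients)


def modality_subset(
    cohort: Cohort, modality: str, keep_clinical: bool = True
) -> Cohort:
    """Restrict every feature vector to one modality's columns.

    ``modality`` is one of ``perfusion`` / ``diffusion`` / ``spectroscopy``
    / ``all``.  The two always-present clinical codes (resection, group)
    are retained alongside the modality columns unless ``keep_clinical``
    is false; volume features never enter a single-modality subset.
    """
    if modality == "all":
        return cohort.copy()
    if not isinstance(cohort.schema, FeatureSchema):
        raise SchemaError("cohort is already a modality subset")
    sub = subset_schema(cohort.schema, modality, keep_clinical=keep_clinical)
    idx = list(sub.indices)
    patients = []
    for patient in cohort.patients:
        timepoints = [
            replace(
                tp,
                features=tp.features[idx].copy(),
                missing_mask=tp.missing_mask[idx].copy(),
            )
            for tp in patient.timepoints
        ]
        patients.append(replace(patient, timepoints=timepoints))
    return Cohort(sub, patients)


def counts_per_offset(cohort: Cohort) -> dict[int, int]:
    """Number of patients with a session at each offset (labels propagated)."""
    counts: dict[int, int] = {}
    for patient in cohort.patients:
        for tp in patient.timepoints:
            if tp.offset is None:
                raise CohortValidationError(
                    "offsets unset; run propagate_labels first"
                )
            counts[tp.offset] = counts.get(tp.offset, 0) + 1
    return dict(sorted(counts.items()))


def load_cohort(
    path: str | Path, schema: FeatureSchema = DEFAULT_SCHEMA
) -> Cohort:
    """Read a per-session feature table CSV into a validated Cohort.

    Expected columns: ``patient_id``, ``session_index``, ``decision_class``,
    ``decision_session``, then the 27 feature columns in schema order.
    Empty cells denote missing values; always-present columns must be
    filled.  Offsets and labels are propagated on load.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    expected = list(ID_COLUMNS) + list(schema.names)
    missing_cols = [c for c in expected if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    unknown = [c for c in frame.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    dupes = frame.duplicated(subset=["patient_id", "session_index"])
    if dupes.any():
        pairs = frame.loc[dupes, ["patient_id", "session_index"]].values.tolist()
        raise DuplicateSessionError(f"duplicate (patient, session) rows: {pairs}")

    patients = []
    for pid, rows in frame.groupby("patient_id", sort=False):
        rows = rows.sort_values("session_index")
        decision_class = rows["decision_class"].iloc[0]
        if rows["decision_class"].nunique() != 1:
            raise CohortValidationError(
                f"patient {pid!r}: inconsistent decision_class"
            )
        decision_session = int(rows["decision_session"].iloc[0])
        timepoints = []
        for _, row in rows.iterrows():
            values = row[list(schema.names)].to_numpy(dtype=float)
            mask = np.isnan(values)
            timepoints.append(
                TimePoint(
                    patient_id=str(pid),
                    session_index=int(row["session_index"]),
                    features=np.nan_to_num(values, nan=0.0),
                    missing_mask=mask,
                )
            )
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                decision_class=str(decision_class),
                decision_session=decision_session,
                timepoints=timepoints,
            )
        )
    cohort = propagate_all(Cohort(schema, patients))
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the feature-table CSV (empty cell = missing)."""
    records = []
    for patient in cohort.patients:
        for tp in patient.timepoints:
            row: dict[str, object] = {
                "patient_id": patient.patient_id,
                "session_index": tp.session_index,
                "decision_class": patient.decision_class,
                "decision_session": patient.decision_session,
            }
            for i, name in enumerate(cohort.schema.names):
                row[name] = np.nan if tp.missing_mask[i] else tp.features[i]
            records.append(row)
    frame = pd.DataFrame.from_records(
        records, columns=list(ID_COLUMNS) + list(cohort.schema.names)
    )
    frame.to_csv(path, index=False)


def labeled_timepoints(cohort: Cohort) -> list[TimePoint]:
    """All sessions at or after their patient's decision."""
    return [tp for tp in cohort.iter_timepoints() if tp.label != UNLABELED]
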