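"""Shared fixtures: programmatically built toy cohorts and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from relapsemri.cohort import Cohort, PatientRecord, TimePoint, propagate_all
from relapsemri.schema import DEFAULT_SCHEMA


def make_timepoint(
    patient_id: str,
    session_index: int,
    values: dict[str, float] | None = None,
    missing: tuple[str, ...] = (),
    base: float = 1.0,
) -> TimePoint:
    """A schema-conformant session with named overrides and masked features."""
    features = np.full(27, base)
    for name in DEFAULT_SCHEMA.modality_members("volume"):
        features[DEFAULT_SCHEMA.index(name)] = 2.0
    features[DEFAULT_SCHEMA.index("resection")] = 1.0
    features[DEFAULT_SCHEMA.index("group")] = 0.0
    for name, value in (values or {}).items():
        features[DEFAULT_SCHEMA.index(name)] = value
    mask = np.zeros(27, dtype=bool)
    for name in missing:
        mask[DEFAULT_SCHEMA.index(name)] = True
    return TimePoint(
        patient_id=patient_id,
        session_index=session_index,
        features=features,
        missing_mask=mask,
    )


def make_patient(
    patient_id: str,
    decision_class: str,
    n_sessions: int,
    decision_session: int,
    missing_by_session: dict[int, tuple[str, ...]] | None = None,
    values_by_session: dict[int, dict[str, float]] | None = None,
) -> PatientRecord:
    missing_by_session = missing_by_session or {}
    values_by_session = values_by_session or {}
    return PatientRecord(
        patient_id=patient_id,
        decision_class=decision_class,
        decision_session=decision_session,
        timepoints=[
            make_timepoint(
                patient_id,
                s,
                values=values_by_session.get(s),
                missing=missing_by_session.get(s, ()),
            )
            for s in range(n_sessions)
        ],
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    """Two patients, five sessions total, one masked diffusion cell."""
    cohort = Cohort(
        DEFAULT_SCHEMA,
        [
            make_patient(
                "A", "progressive", 3, 1, missing_by_session={0: ("MD_CE",)}
            ),
            make_patient("B", "responsive", 2, 1),
        ],
    )
    return propagate_all(cohort)


@pytest.fixture
def labeled_cohort() -> Cohort:
    """Fully labeled complete cohort with both classes, for imputer fitting."""
    cohort = Cohort(
        DEFAULT_SCHEMA,
        [
            make_patient(
                "R1", "responsive", 2, 0,
                values_by_session={0: {"MD_CE": 1.0}, 1: {"MD_CE": 3.0}},
            ),
            make_patient(
                "P1", "progressive", 1, 0,
                values_by_session={0: {"MD_CE": 8.0}},
            ),
        ],
    )
    return propagate_all(cohort)
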