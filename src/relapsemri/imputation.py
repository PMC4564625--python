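"""Volume-conditioned imputation of missing modality features.

The rule exploits the fact that a tumour region recorded with volume
exactly 0 is absent: anything that would have been measured there is
healthy tissue.  Perfusion parameters are normalised to normal-appearing
white matter, so healthy tissue has ratio 1 and missing perfusion values
over a zero-volume region are filled with the constant 1.  Missing
diffusion or spectroscopy values over a zero-volume region are filled
with the mean of that feature over responsive-labeled sessions (the
closest available surrogate for healthy tissue).  A missing value whose
region volume is positive is filled with the feature's mean over all
labeled sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .cohort import Cohort, TimePoint, labeled_timepoints
from .schema import (
    FeatureSchema,
    PERFUSION,
    RESPONSIVE,
    UNLABELED,
)

PERFUSION_FILL = 1.0  # NAWM-normalised ratio of normal tissue


class ImputationError(ValueError):
    """A required replacement mean could not be learned."""


@dataclass
class ImputationModel:
    """Learned per-feature replacement values.

    ``responsive_mean[f]`` averages feature *f* over responsive-labeled
    sessions where it is present; ``labeled_mean[f]`` averages over all
    labeled sessions where present.  Only features that were observed in
    at least one qualifying session have an entry.
    """

    responsive_mean: dict[str, float] = field(default_factory=dict)
    labeled_mean: dict[str, float] = field(default_factory=dict)
    perfusion_fill: float = PERFUSION_FILL

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "responsive_mean": self.responsive_mean,
                    "labeled_mean": self.labeled_mean,
                    "perfusion_fill": self.perfusion_fill,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ImputationModel":
        data = json.loads(Path(path).read_text())
        return cls(
            responsive_mean=data["responsive_mean"],
            labeled_mean=data["labeled_mean"],
            perfusion_fill=data.get("perfusion_fill", PERFUSION_FILL),
        )


def fit_imputer(
    labeled_points: Iterable[TimePoint], schema: FeatureSchema
) -> ImputationModel:
    """Learn replacement means from labeled sessions.

    Means are computed over present (unmasked) values only and are
    invariant to the order of the input points.  Features never observed
    among the qualifying points simply lack an entry; the error surfaces
    at impute time if such a feature is actually needed.
    """
    points = list(labeled_points)
    if not points:
        raise ImputationError("no labeled sessions to fit on")
    if any(tp.label == UNLABELED for tp in points):
        raise ImputationError("fit_imputer expects labeled sessions only")
    model = ImputationModel()
    for i, name in enumerate(schema.names):
        if schema.is_always_present(name):
            continue
        present = [tp.features[i] for tp in points if not tp.missing_mask[i]]
        if present:
            model.labeled_mean[name] = float(np.mean(present))
        resp = [
            tp.features[i]
            for tp in points
            if tp.label == RESPONSIVE and not tp.missing_mask[i]
        ]
        if resp:
            model.responsive_mean[name] = float(np.mean(resp))
    return model


def _fill_value(
    name: str, point: TimePoint, model: ImputationModel, schema: FeatureSchema
) -> float:
    region = schema.region_of.get(name)
    if region is not None:
        vol_idx = schema.index(schema.volume_feature_for_region(region))
        if point.features[vol_idx] == 0.0:  # exact zero: region absent
            if schema.modality_of[name] == PERFUSION:
                return model.perfusion_fill
            if name not in model.responsive_mean:
                raise ImputationError(
                    f"unfittable feature {name!r}: no responsive-labeled "
                    "observation to average"
                )
            return model.responsive_mean[name]
    if name not in model.labeled_mean:
        raise ImputationError(
            f"unfittable feature {name!r}: no labeled observation to average"
        )
    return model.labeled_mean[name]


def impute_point(
    point: TimePoint, model: ImputationModel, schema: FeatureSchema
) -> TimePoint:
    """Fill every missing feature of one session; present values untouched."""
    if not point.missing_mask.any():
        return point.copy()
    out = point.copy()
    for i, name in enumerate(schema.names):
        if out.missing_mask[i]:
            out.features[i] = _fill_value(name, out, model, schema)
            out.missing_mask[i] = False
    return out


def impute_cohort(cohort: Cohort, model: ImputationModel) -> Cohort:
    """Impute every session (labeled and unlabeled) of a cohort."""
    schema = cohort.schema
    if not isinstance(schema, FeatureSchema):
        raise ImputationError("imputation requires the full 27-feature schema")
    errors: list[str] = []
    patients = []
    for patient in cohort.patients:
        timepoints = []
        for tp in patient.timepoints:
            try:
                timepoints.append(impute_point(tp, model, schema))
            except ImputationError as exc:
                errors.append(str(exc))
        patients.append(replace(patient, timepoints=timepoints))
    if errors:
        raise ImputationError(
            "imputation failed: " + "; ".join(sorted(set(errors)))
        )
    return Cohort(schema, patients)


def fit_imputer_from_cohort(cohort: Cohort) -> ImputationModel:
    """Convenience: fit on a cohort's labeled sessions."""
    if not isinstance(cohort.schema, FeatureSchema):
        raise ImputationError("imputation requires the full 27-feature schema")
    return fit_imputer(labeled_timepoints(cohort), cohort.schema)
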