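"""Synthetic longitudinal GBM follow-up cohorts.

The generator emulates the structure of the study cohort the pipeline is
designed for: 29 patients, ~178 MRI sessions aligned on a clinical
decision session, class-dependent feature distributions, and heavy
block-wise missingness of the advanced-MR modalities (spectroscopy 66%,
diffusion 44%, perfusion 30% of sessions rejected).  Session-count
distributions default to the study's empirical per-offset sample counts,
so a default 29-patient cohort has 178 expected sessions.

Class separation is controlled by a single parameter ``class_separation``
(δ): modality features are drawn from class-conditional Gaussians whose
means differ by δ within-class standard deviations, and the class
contrast of the volume dynamics (responsive volumes decaying to exactly
0 after the decision, progressive volumes growing) is scaled by
min(δ, 1) so that δ = 0 yields exactly exchangeable classes.  Only the
direction and magnitude of separation are meaningful: the study reports
no per-feature distributional summaries to calibrate against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort, PatientRecord, TimePoint, propagate_all
from .schema import (
    CLINICAL,
    DEFAULT_SCHEMA,
    DIFFUSION,
    FeatureSchema,
    PERFUSION,
    PROGRESSIVE,
    RESPONSIVE,
    SPECTROSCOPY,
    VOLUME,
)


class SimulationError(ValueError):
    pass


#: patients with exactly k pre-decision sessions, k = 1..11 (successive
#: differences of the study's per-offset sample counts)
SESSIONS_BEFORE_WEIGHTS = {
    1: 5, 2: 8, 3: 3, 4: 1, 5: 4, 6: 2, 7: 1, 8: 1, 9: 1, 10: 1, 11: 2,
}
#: patients with exactly k post-decision sessions, k = 0..5
SESSIONS_AFTER_WEIGHTS = {0: 17, 1: 4, 2: 5, 3: 1, 4: 0, 5: 2}

#: treatment-protocol group prevalences (codes 0, 1, 2)
GROUP_WEIGHTS = (16, 7, 6)

DEFAULT_MISSINGNESS = {SPECTROSCOPY: 0.66, PERFUSION: 0.30, DIFFUSION: 0.44}

# responsive-class location and within-class SD per modality feature;
# perfusion is NAWM-normalised, so healthy/responsive tissue sits at 1
_FEATURE_PARAMS: dict[str, tuple[float, float]] = {
    **{n: (1.0, 0.20) for n in DEFAULT_SCHEMA.modality_members(PERFUSION)},
    "MK_CE": (0.60, 0.15), "MK_ED": (0.55, 0.15),
    "MD_CE": (1.10, 0.20), "MD_ED": (1.20, 0.20),
    "FA_CE": (0.25, 0.08), "FA_ED": (0.30, 0.08),
    **{n: (0.50, 0.15) for n in DEFAULT_SCHEMA.modality_members(SPECTROSCOPY)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_patients: int = 29
    fraction_progressive: float = 0.5
    sessions_before_decision: dict[int, float] = field(
        default_factory=lambda: dict(SESSIONS_BEFORE_WEIGHTS)
    )
    sessions_after_decision: dict[int, float] = field(
        default_factory=lambda: dict(SESSIONS_AFTER_WEIGHTS)
    )
    class_separation: float = 3.0
    #: per-session probability that a responsive region's volume drops to
    #: exactly 0 after the decision (scaled by min(δ, 1))
    volume_zero_prob: float = 0.5
    #: per-session multiplicative growth of progressive volumes after the
    #: decision (class contrast scaled by min(δ, 1))
    volume_growth: float = 1.3
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    #: extra masking probability for a modality block whose CE region
    #: volume is exactly 0 (missingness co-occurring with absent tissue)
    zero_volume_missing_coupling: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise SimulationError("n_patients must be >= 2")
        if not 0.0 <= self.fraction_progressive <= 1.0:
            raise SimulationError("fraction_progressive must be in [0, 1]")
        if self.class_separation < 0:
            raise SimulationError("class_separation must be >= 0")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"missingness[{name!r}] must be in [0, 1]")
        if not 0.0 <= self.zero_volume_missing_coupling <= 1.0:
            raise SimulationError("zero_volume_missing_coupling must be in [0, 1]")
        if not 0.0 <= self.volume_zero_prob <= 1.0:
            raise SimulationError("volume_zero_prob must be in [0, 1]")
        for dist in (self.sessions_before_decision, self.sessions_after_decision):
            if sum(dist.values()) <= 0 or any(v < 0 for v in dist.values()):
                raise SimulationError("session-count weights must be non-negative")


def _draw(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    weights = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=weights / weights.sum()))


def _volume_track(
    n_before: int,
    n_after: int,
    decision_class: str,
    contrast: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-session (CE, ED, N) volumes; responsive regions may hit exact 0."""
    base = np.array(
        [
            rng.lognormal(np.log(5.0), 0.5),
            rng.lognormal(np.log(10.0), 0.5),
            rng.lognormal(np.log(2.0), 0.7),
        ]
    )
    n_sessions = n_before + 1 + n_after
    track = np.empty((n_sessions, 3))
    zeroed = np.zeros(3, dtype=bool)
    current = base.copy()
    for pos in range(n_sessions):
        after = pos - n_before  # sessions past the decision
        if after > 0:
            if decision_class == RESPONSIVE:
                current = current * (1.0 - 0.5 * contrast)
                newly = rng.random(3) < config.volume_zero_prob * contrast
                zeroed |= newly
            else:
                current = current * (1.0 + (config.volume_growth - 1.0) * contrast)
        noisy = current * rng.lognormal(0.0, 0.1, size=3)
        noisy[zeroed] = 0.0
        track[pos] = noisy
    return track


def generate_cohort(
    config: SimulationConfig, schema: FeatureSchema = DEFAULT_SCHEMA
) -> Cohort:
    """Draw a complete (no missingness) labeled synthetic cohort."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    delta = config.class_separation
    contrast = min(1.0, delta)

    vol_idx = {r: schema.index(f"volume_{r}") for r in ("CE", "ED")}
    n_idx = schema.index("volume_N")
    patients = []
    for p in range(config.n_patients):
        decision_class = (
            PROGRESSIVE
            if rng.random() < config.fraction_progressive
            else RESPONSIVE
        )
        n_before = _draw(config.sessions_before_decision, rng)
        n_after = _draw(config.sessions_after_decision, rng)
        volumes = _volume_track(
            n_before, n_after, decision_class, contrast, config, rng
        )
        resection = float(rng.integers(0, 2))
        group = float(
            rng.choice(3, p=np.array(GROUP_WEIGHTS) / sum(GROUP_WEIGHTS))
        )
        timepoints = []
        for pos in range(n_before + 1 + n_after):
            features = np.zeros(len(schema.names))
            features[vol_idx["CE"]] = volumes[pos, 0]
            features[vol_idx["ED"]] = volumes[pos, 1]
            features[n_idx] = volumes[pos, 2]
            for name, (loc, sd) in _FEATURE_PARAMS.items():
                mean = loc + (delta * sd if decision_class == PROGRESSIVE else 0.0)
                features[schema.index(name)] = rng.normal(mean, sd)
            features[schema.index("resection")] = resection
            features[schema.index("group")] = group
            timepoints.append(
                TimePoint(
                    patient_id=f"P{p:03d}",
                    session_index=pos,
                    features=features,
                    missing_mask=np.zeros(len(schema.names), dtype=bool),
                )
            )
        patients.append(
            PatientRecord(
                patient_id=f"P{p:03d}",
                decision_class=decision_class,
                decision_session=n_before,
                timepoints=timepoints,
            )
        )
    cohort = propagate_all(Cohort(schema, patients))
    cohort.validate()
    return cohort


def inject_missingness(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Mask modality blocks per session at the configured rates.

    Whole modality blocks go missing together (a rejected acquisition
    loses all its parameters), always-present features are never masked,
    and a block whose CE region volume is exactly 0 is additionally
    masked with the coupling probability.
    """
    config.validate()
    schema = cohort.schema
    if not isinstance(schema, FeatureSchema):
        raise SimulationError("missingness injection requires the full schema")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ce_idx = schema.index("volume_CE")
    block_idx = {
        m: [schema.index(n) for n in schema.modality_members(m)]
        for m in config.missingness
    }
    out = cohort.copy()
    for tp in out.iter_timepoints():
        for modality, rate in config.missingness.items():
            if rate == 0.0:  # a never-rejected modality stays complete
                continue
            mask = rng.random() < rate
            if (
                not mask
                and tp.features[ce_idx] == 0.0
                and rng.random() < config.zero_volume_missing_coupling
            ):
                mask = True
            if mask:
                tp.missing_mask[block_idx[modality]] = True
    out.validate()
    return out


def simulate_cohort(
    config: SimulationConfig, schema: FeatureSchema = DEFAULT_SCHEMA
) -> Cohort:
    """Generate a cohort and inject the configured missingness."""
    return inject_missingness(generate_cohort(config, schema), config)
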