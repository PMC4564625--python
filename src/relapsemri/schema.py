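"""Feature schema for longitudinal multiparametric MRI feature tables.

Each MRI follow-up session is summarised by 27 features: three region
volumes (contrast enhancement CE, perilesional oedema ED, necrosis N),
six perfusion parameters (rrCBV, rrCBF, rDR over CE and ED, expressed
relative to normal-appearing white matter so healthy tissue is ~1), six
diffusion-kurtosis parameters (MK, MD, FA over CE and ED), ten metabolite
ratios from chemical shift imaging over the CE region, a total-resection
flag and a treatment-protocol group code.  The volumes and the two
clinical codes are always observed; the three advanced-MR modalities can
each be missing for a whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

VOLUME = "volume"
PERFUSION = "perfusion"
DIFFUSION = "diffusion"
SPECTROSCOPY = "spectroscopy"
CLINICAL = "clinical"

MODALITIES = (VOLUME, PERFUSION, DIFFUSION, SPECTROSCOPY, CLINICAL)
#: modalities that may be selected as single-modality feature subsets
SUBSET_MODALITIES = (PERFUSION, DIFFUSION, SPECTROSCOPY)

PROGRESSIVE = "progressive"
RESPONSIVE = "responsive"
UNLABELED = "unlabeled"
CLASSES = (PROGRESSIVE, RESPONSIVE)


class SchemaError(ValueError):
    """A feature table or schema definition violates the 27-feature contract."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 27-feature schema with per-feature modality and region tags.

    Parameters
    ----------
    names
        Feature identifiers in column order.
    modality_of
        Map feature name -> modality tag (one of :data:`MODALITIES`).
    always_present
        The features guaranteed non-missing in every session.
    region_of
        Map feature name -> tumour region ("CE" or "ED") used by the
        volume-conditioned imputation; spectroscopy ratios are measured
        over the CE region.
    """

    names: tuple[str, ...]
    modality_of: Mapping[str, str]
    always_present: frozenset[str]
    region_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise SchemaError("duplicate feature names")
        if len(self.names) != 27:
            raise SchemaError(f"expected 27 features, got {len(self.names)}")
        if set(self.modality_of) != set(self.names):
            raise SchemaError("modality_of must cover exactly the schema names")
        bad = set(self.modality_of.values()) - set(MODALITIES)
        if bad:
            raise SchemaError(f"unknown modalities: {sorted(bad)}")
        if len(self.always_present) != 5:
            raise SchemaError("always_present must have exactly 5 members")
        if not self.always_present <= set(self.names):
            raise SchemaError("always_present must be a subset of names")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def modality_members(self, modality: str) -> tuple[str, ...]:
        """Schema-ordered feature names belonging to one modality."""
        return tuple(n for n in self.names if self.modality_of[n] == modality)

    def is_always_present(self, name: str) -> bool:
        return name in self.always_present

    def volume_feature_for_region(self, region: str) -> str:
        if region not in ("CE", "ED"):
            raise SchemaError(f"unknown region {region!r}")
        return f"volume_{region}"


_VOLUMES = ("volume_CE", "volume_ED", "volume_N")
_PERFUSION = ("rrCBV_CE", "rrCBV_ED", "rrCBF_CE", "rrCBF_ED", "rDR_CE", "rDR_ED")
_DIFFUSION = ("MK_CE", "MK_ED", "MD_CE", "MD_ED", "FA_CE", "FA_ED")
_SPECTROSCOPY = (
    "NAA/tCho", "NAA/sum", "tCho/sum", "NAA/Cre", "Lips/tCho",
    "tCho/Cre", "Myo/sum", "Cre/sum", "Lips/Cre", "Glx/sum",
)
_CLINICAL = ("resection", "group")


def _default_regions() -> dict[str, str]:
    regions: dict[str, str] = {}
    for name in _PERFUSION + _DIFFUSION:
        regions[name] = name.rsplit("_", 1)[1]
    for name in _SPECTROSCOPY:  # CSI voxels are selected over CE
        regions[name] = "CE"
    return regions


DEFAULT_SCHEMA = FeatureSchema(
    names=_VOLUMES + _PERFUSION + _DIFFUSION + _SPECTROSCOPY + _CLINICAL,
    modality_of={
        **{n: VOLUME for n in _VOLUMES},
        **{n: PERFUSION for n in _PERFUSION},
        **{n: DIFFUSION for n in _DIFFUSION},
        **{n: SPECTROSCOPY for n in _SPECTROSCOPY},
        **{n: CLINICAL for n in _CLINICAL},
    },
    always_present=frozenset(_VOLUMES + _CLINICAL),
    region_of=_default_regions(),
)


def subset_schema(
    schema: FeatureSchema,
    modality: str,
    keep_clinical: bool = True,
) -> "SubsetSchema":
    """Restricted view of a schema for single-modality experiments.

    Volumes are their own feature category and are excluded from all
    three single-modality subsets; the two always-present clinical codes
    are retained by default.
    """
    if modality == "all":
        return SubsetSchema(schema, schema.names)
    if modality not in SUBSET_MODALITIES:
        raise SchemaError(
            f"unknown modality {modality!r}; expected one of "
            f"{SUBSET_MODALITIES + ('all',)}"
        )
    names = schema.modality_members(modality)
    if keep_clinical:
        names = names + schema.modality_members(CLINICAL)
    return SubsetSchema(schema, names)


@dataclass(frozen=True)
class SubsetSchema:
    """A column selection over a parent :class:`FeatureSchema`."""

    parent: FeatureSchema
    names: tuple[str, ...]

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(self.parent.index(n) for n in self.names)
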