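"""Label vocabularies, the 113-feature registry, and cohort file I/O.

The feature schema mirrors the default output of the standard radiomics
extractor (107 features over seven groups: first-order intensity, shape,
GLCM, GLRLM, GLSZM, NGTDM, GLDM) plus six SISN slice-position features
computed from the nodule segmentation, for a 113-dimensional vector per
nodule.  Semantic labels cover nodule location (six lobes), texture
(attenuation class) and margin (boundary appearance).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "LocationLabel",
    "TextureLabel",
    "MarginLabel",
    "SemanticLabels",
    "FeatureRegistry",
    "NoduleRecord",
    "Cohort",
    "Violation",
    "SchemaError",
    "LabelError",
    "IntegrityError",
    "build_default_registry",
    "read_cohort",
    "write_cohort",
    "validate_record",
]


class SchemaError(ValueError):
    """A cohort file does not conform to the feature registry."""


class LabelError(ValueError):
    """A label token cannot be parsed against the vocabulary."""


class IntegrityError(ValueError):
    """Structural integrity violation (e.g. duplicate record ids)."""


def _normalize_token(token: str) -> str:
    return "".join(ch for ch in token.lower() if ch.isalnum())


class _ParsableLabel(enum.Enum):
    """Enum base with case/space/underscore-insensitive parsing."""

    def __str__(self) -> str:  # canonical surface spelling
        return self.value

    @classmethod
    def parse(cls, token: str):
        key = _normalize_token(str(token))
        for member in cls:
            if key in (_normalize_token(member.value), _normalize_token(member.name)):
                return member
        raise LabelError(
            f"cannot parse {token!r} as {cls.__name__}; "
            f"expected one of {[m.value for m in cls]}"
        )


class LocationLabel(_ParsableLabel):
    """Anatomical lobe containing the nodule (canonical report order)."""

    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    LLL = "LLL"
    LINGULAR_LOBE = "Lingular Lobe"


class TextureLabel(_ParsableLabel):
    """Nodule attenuation class, listed from higher to lower density."""

    SOLID = "Solid"
    SUBSOLID = "Subsolid"
    PURE_GGO = "Pure GGO"


class MarginLabel(_ParsableLabel):
    """Nodule boundary appearance; spiculation is malignancy-associated."""

    SHARP_CIRCUMSCRIBED = "Sharp Circumscribed"
    LOBULATED = "Lobulated"
    INDISTINCT = "Indistinct"
    SPICULATED = "Spiculated"


@dataclass(frozen=True)
class SemanticLabels:
    """The complete label triple for one nodule; no partial triples."""

    location: LocationLabel
    texture: TextureLabel
    margin: MarginLabel


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

# Default feature names of the standard radiomics extractor, original image
# type, so CSV exports from that tool load without renaming.
_FIRSTORDER = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
)
_SHAPE = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)
_GLCM = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
_GLRLM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
_GLSZM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
_NGTDM = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
_GLDM = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

SISN_FEATURE_NAMES = (
    "SISN_ratio", "SISN_first", "SISN_last",
    "SISN_centroid", "SISN_span", "SISN_peak",
)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered registry of feature names grouped by feature family.

    ``groups`` maps group name to the ordered tuple of fully qualified
    feature names.  Radiomics groups precede SISN; iteration order defines
    the layout of every feature matrix built from a cohort.
    """

    groups: dict[str, tuple[str, ...]]

    @property
    def radiomics_names(self) -> tuple[str, ...]:
        return tuple(
            name for group, names in self.groups.items() if group != "SISN"
            for name in names
        )

    @property
    def sisn_names(self) -> tuple[str, ...]:
        return self.groups.get("SISN", ())

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.radiomics_names + self.sisn_names

    @property
    def n_features(self) -> int:
        return len(self.all_names)

    def group_slices(self) -> dict[str, slice]:
        """Half-open index ranges of each group in the full feature vector."""
        out: dict[str, slice] = {}
        start = 0
        for group, names in self.groups.items():
            out[group] = slice(start, start + len(names))
            start += len(names)
        return out

    def to_json(self) -> str:
        """Registry dump for documentation."""
        return json.dumps({g: list(n) for g, n in self.groups.items()}, indent=2)

    def __post_init__(self) -> None:
        names = self.all_names
        if len(set(names)) != len(names):
            raise IntegrityError("feature names must be unique")


def build_default_registry() -> FeatureRegistry:
    """Registry matching the standard extractor's default feature set.

    Groups and cardinalities: Intensity 18, Shape 14, GLCM 24, GLRLM 16,
    GLSZM 16, NGTDM 5, GLDM 14 (107 radiomics) plus SISN 6, 113 total.
    """
    groups = {
        "Intensity": tuple(f"original_firstorder_{n}" for n in _FIRSTORDER),
        "Shape": tuple(f"original_shape_{n}" for n in _SHAPE),
        "GLCM": tuple(f"original_glcm_{n}" for n in _GLCM),
        "GLRLM": tuple(f"original_glrlm_{n}" for n in _GLRLM),
        "GLSZM": tuple(f"original_glszm_{n}" for n in _GLSZM),
        "NGTDM": tuple(f"original_ngtdm_{n}" for n in _NGTDM),
        "GLDM": tuple(f"original_gldm_{n}" for n in _GLDM),
        "SISN": SISN_FEATURE_NAMES,
    }
    return FeatureRegistry(groups=groups)


# ---------------------------------------------------------------------------
# Records and cohorts
# ---------------------------------------------------------------------------


@dataclass
class NoduleRecord:
    """One nodule: 113 named feature values, size in mm, optional labels."""

    record_id: str
    features: dict[str, float]
    size_mm: float
    labels: Optional[SemanticLabels] = None


@dataclass
class Cohort:
    """Ordered collection of nodule records sharing one feature registry."""

    records: list[NoduleRecord]
    registry: FeatureRegistry
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices) -> "Cohort":
        return Cohort(
            records=[self.records[i] for i in indices],
            registry=self.registry,
            provenance=dict(self.provenance),
        )

    @property
    def labeled(self) -> bool:
        return all(r.labels is not None for r in self.records)


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    field: str
    rule: str
    severity: str = "error"

    def __str__(self) -> str:
        return f"[{self.severity}] {self.field}: {self.rule}"


#: Study inclusion bound on the longest nodule diameter (mm); sizes at or
#: above it are flagged as warnings for user data, enforced by the generator.
MAX_NODULE_DIAMETER_MM = 30.0

_LABEL_COLUMNS = {
    "location": LocationLabel,
    "texture": TextureLabel,
    "margin": MarginLabel,
}


def validate_record(record: NoduleRecord, registry: FeatureRegistry) -> list[Violation]:
    """Check one record against the registry invariants.

    Returns a list of violations (empty when the record conforms).  Missing
    or non-finite features and out-of-range SISN values are errors; a size at
    or above the 30 mm study inclusion bound is a warning, since user data
    may legitimately exceed it.
    """
    violations: list[Violation] = []
    for name in registry.all_names:
        if name not in record.features:
            violations.append(Violation(name, "feature value missing"))
            continue
        value = record.features[name]
        if value is None or value != value or value in (float("inf"), float("-inf")):
            violations.append(Violation(name, f"feature value not finite: {value!r}"))
    for name in registry.sisn_names:
        value = record.features.get(name)
        if value is not None and value == value and not 0.0 <= value <= 1.0:
            violations.append(Violation(name, f"SISN value {value} outside [0, 1]"))
    if not record.size_mm > 0:
        violations.append(Violation("size_mm", f"size_mm {record.size_mm} must be > 0"))
    elif record.size_mm >= MAX_NODULE_DIAMETER_MM:
        violations.append(
            Violation(
                "size_mm",
                f"size_mm {record.size_mm} at or above the {MAX_NODULE_DIAMETER_MM:g} mm "
                "study inclusion bound",
                severity="warning",
            )
        )
    return violations


def read_cohort(path: Union[str, Path], registry: FeatureRegistry) -> Cohort:
    """Read a cohort CSV/TSV file against ``registry``.

    The header must contain ``record_id``, ``size_mm`` and every registry
    feature column; ``location``/``texture``/``margin`` columns are optional
    and parsed case-insensitively.  Column order is irrelevant.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round_trip parsing keeps write->read bitwise-lossless on doubles
    frame = pd.read_csv(path, sep=sep, dtype={"record_id": str},
                        float_precision="round_trip")

    for required in ("record_id", "size_mm"):
        if required not in frame.columns:
            raise SchemaError(f"missing required column {required!r}")
    missing = [n for n in registry.all_names if n not in frame.columns]
    if missing:
        raise SchemaError(f"missing feature column {missing[0]!r} "
                          f"({len(missing)} of {registry.n_features} absent)")

    label_cols = [c for c in _LABEL_COLUMNS if c in frame.columns]
    if label_cols and len(label_cols) != 3:
        raise SchemaError(
            f"partial label columns {label_cols}: provide all of "
            "location/texture/margin or none"
        )

    ids = frame["record_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IntegrityError(f"duplicate record_id values: {sorted(dupes)}")

    records = []
    for _, row in frame.iterrows():
        labels = None
        if label_cols:
            parsed = {}
            for col, enum_cls in _LABEL_COLUMNS.items():
                token = row[col]
                try:
                    parsed[col] = enum_cls.parse(token)
                except LabelError as exc:
                    raise LabelError(
                        f"record {row['record_id']!r}: {exc}"
                    ) from exc
            labels = SemanticLabels(**parsed)
        records.append(
            NoduleRecord(
                record_id=str(row["record_id"]),
                features={n: float(row[n]) for n in registry.all_names},
                size_mm=float(row["size_mm"]),
                labels=labels,
            )
        )
    return Cohort(records=records, registry=registry,
                  provenance={"source": str(path)})


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV (or TSV by extension); lossless round-trip.

    Feature values are serialized with shortest-exact float repr so that
    ``read_cohort(write_cohort(c))`` reproduces ``c`` bitwise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    names = cohort.registry.all_names
    columns = ["record_id", "size_mm"]
    with_labels = len(cohort) > 0 and cohort.labeled
    if with_labels:
        columns += list(_LABEL_COLUMNS)
    columns += list(names)

    rows = []
    for record in cohort:
        row: dict = {"record_id": record.record_id, "size_mm": repr(record.size_mm)}
        if with_labels:
            row["location"] = record.labels.location.value
            row["texture"] = record.labels.texture.value
            row["margin"] = record.labels.margin.value
        for name in names:
            row[name] = repr(float(record.features[name]))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep=sep, index=False)


def cohort_matrix(cohort: Cohort):
    """Feature matrix (n × 113) in registry order, as float64.

    Helper shared by the model and evaluation layers; raises on records with
    missing features so downstream numerics never see NaN.
    """
    import numpy as np

    names = cohort.registry.all_names
    out = np.empty((len(cohort), len(names)), dtype=np.float64)
    for i, record in enumerate(cohort):
        for j, name in enumerate(names):
            try:
                out[i, j] = record.features[name]
            except KeyError:
                raise SchemaError(
                    f"record {record.record_id!r} missing feature {name!r}"
                ) from None
    if not np.isfinite(out).all():
        bad = [cohort.records[i].record_id
               for i in sorted(set(np.argwhere(~np.isfinite(out))[:, 0].tolist()))]
        raise ValueError(f"non-finite feature values in records {bad}")
    return out
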