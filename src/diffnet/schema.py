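"""Registry of the 107-feature-per-phase radiomics schema.

Four contrast phases of an abdominal CT study are encoded by single-letter
prefixes (P = non-contrast, A = cortico-medullary, V = nephrographic,
D = excretory).  Within a phase, features are numbered ``X1``..``X107`` and a
full column name concatenates the two, e.g. ``PX11`` is non-contrast-phase
Sphericity.

The 107 features fall into the seven standard radiomics classes (shape,
first-order intensity statistics, and the five texture-matrix families).
Feature names follow the pyradiomics naming convention; within each class the
features are ordered alphabetically and the classes are laid out in fixed
blocks:

====================  =======  ======
class                 indices  count
====================  =======  ======
shape                 1-14     14
first-order           15-32    18
GLCM                  33-56    24
GLDM                  57-70    14
GLRLM                 71-86    16
GLSZM                 87-102   16
NGTDM                 103-107  5
====================  =======  ======

Only a subset of index->name pairs is externally anchored; the remainder of
the registry is a documented convention (see docs/methods.md).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "FeatureSchema",
    "SchemaError",
    "PHASE_CODES",
    "CLASS_COUNTS",
    "default_schema",
]

#: phase code -> phase long name
PHASE_CODES = {
    "P": "NCP",  # non-contrast phase
    "A": "CMP",  # cortico-medullary phase
    "V": "NP",  # nephrographic phase
    "D": "EP",  # excretory phase
}

_SHAPE = [
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
]

_FIRST_ORDER = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]

_GLCM = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]

_GLDM = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

_GLRLM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

_GLSZM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

_NGTDM = [
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
]

#: class -> block, in registry order
_BLOCKS = [
    ("shape", _SHAPE),
    ("first-order", _FIRST_ORDER),
    ("GLCM", _GLCM),
    ("GLDM", _GLDM),
    ("GLRLM", _GLRLM),
    ("GLSZM", _GLSZM),
    ("NGTDM", _NGTDM),
]

#: expected number of features per class
CLASS_COUNTS = {
    "first-order": 18,
    "shape": 14,
    "GLCM": 24,
    "GLSZM": 16,
    "GLRLM": 16,
    "GLDM": 14,
    "NGTDM": 5,
}

_COLUMN_RE = re.compile(r"^([A-Z])X(\d+)$")


class SchemaError(ValueError):
    """A column name does not conform to the phase/index schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Mapping from feature index ``k`` in 1..107 to ``(name, class)``.

    Parameters
    ----------
    registry:
        ``{k: (name, feature_class)}`` with keys exactly 1..107.
    phases:
        Phase codes recognised by :meth:`parse_column`.
    """

    registry: dict[int, tuple[str, str]]
    phases: tuple[str, ...] = tuple(PHASE_CODES)

    def __post_init__(self) -> None:
        if sorted(self.registry) != list(range(1, 108)):
            raise SchemaError("registry must map exactly indices 1..107")

    @property
    def n_features(self) -> int:
        return len(self.registry)

    def name(self, index: int) -> str:
        return self.registry[index][0]

    def feature_class(self, index: int) -> str:
        return self.registry[index][1]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, cls in self.registry.values():
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def column(self, phase: str, index: int) -> str:
        """Full column name, e.g. ``column('P', 11) == 'PX11'``."""
        if phase not in self.phases:
            raise SchemaError(f"unknown phase code {phase!r}")
        if index not in self.registry:
            raise SchemaError(f"feature index {index} outside 1..{self.n_features}")
        return f"{phase}X{index}"

    def columns(self, phases: tuple[str, ...] | None = None) -> list[str]:
        """All column names for the given phases (default: all four)."""
        phases = tuple(phases) if phases is not None else self.phases
        return [self.column(ph, k) for ph in phases for k in range(1, self.n_features + 1)]

    def parse_column(self, column: str) -> tuple[str, int]:
        """Split ``'PX11'`` into ``('P', 11)``; raise :class:`SchemaError` otherwise."""
        m = _COLUMN_RE.match(column)
        if m is None:
            raise SchemaError(f"column {column!r} does not match <phase>X<index>")
        phase, index = m.group(1), int(m.group(2))
        if phase not in self.phases:
            raise SchemaError(f"column {column!r}: unknown phase code {phase!r}")
        if index not in self.registry:
            raise SchemaError(
                f"column {column!r}: feature index {index} outside 1..{self.n_features}"
            )
        return phase, index

    def describe(self, column: str) -> str:
        """Human-readable description, e.g. ``'PX11' -> 'NCP Sphericity (shape)'``."""
        phase, index = self.parse_column(column)
        name, cls = self.registry[index]
        return f"{PHASE_CODES[phase]} {name} ({cls})"


def default_schema() -> FeatureSchema:
    """The shipped 107-feature registry (class blocks as in the module docstring)."""
    registry: dict[int, tuple[str, str]] = {}
    k = 1
    for cls, names in _BLOCKS:
        for name in names:
            registry[k] = (name, cls)
            k += 1
    return FeatureSchema(registry=registry)
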