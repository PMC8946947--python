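"""Full feature extraction for one ROI: the 178-name contract."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io_preproc import LabelMask, Volume
from .discretize import discretize
from .firstorder import SIGNAL_BASED_FEATURES, first_order_features
from .matrices import (
    compute_gldm,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from .shape import shape_features
from .texture_features import (
    GLCM_NAMES,
    NGTDM_NAMES,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["ExtractionConfig", "FeatureVector", "extract_all", "EXPECTED_FEATURE_COUNT"]

EXPECTED_FEATURE_COUNT = 178


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings.

    distances:
        Neighbor distances (voxels) for the GLCM and NGTDM families.
    bin_width:
        Fixed bin width for gray-level discretization (intensity units).
    gldm_alpha:
        Dependence tolerance in gray levels.
    excluded_firstorder:
        Signal-based first-order features removed from the selection view.
    """

    distances: tuple[int, ...] = (1, 4, 7)
    bin_width: float = 25.0
    bin_count: int | None = None
    gldm_alpha: int = 0
    distances_in_mm: bool = False
    excluded_firstorder: frozenset = SIGNAL_BASED_FEATURES

    def voxel_distance(self, delta: int, spacing: np.ndarray) -> int:
        if not self.distances_in_mm:
            return delta
        return max(int(round(delta / float(np.min(spacing)))), 1)


@dataclass
class FeatureVector:
    """Ordered feature-name -> value map with degenerate-distance flags."""

    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.values) != len(set(self.values)):
            raise ValueError("duplicate feature names")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def names(self) -> list[str]:
        return list(self.values)

    def texture_safe(self, excluded: frozenset = SIGNAL_BASED_FEATURES) -> "FeatureVector":
        """Drop signal-based first-order features (selection never sees them)."""
        keep = {
            k: v
            for k, v in self.values.items()
            if not (k.startswith("firstorder_") and k.split("_", 1)[1] in excluded)
        }
        return FeatureVector(keep, list(self.flags))

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, name=name)


def extract_all(
    swi: Volume,
    mask: LabelMask,
    structure: str = "putamen",
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Extract the full 178-feature vector for one structure of the SWI image.

    GLCM and NGTDM are computed at each configured neighbor distance and their
    names carry the distance digit; GLRLM, GLSZM and GLDM use unit distance.
    If the ROI supports no voxel pair at some distance, that distance's
    features are set to 0 and recorded in ``flags`` (with a warning) rather
    than silently dropped.
    """
    config = config or ExtractionConfig()
    if not swi.same_grid(mask):
        raise ValueError("SWI volume and mask must share a grid")

    values: dict[str, float] = {}
    flags: list[str] = []

    fo = first_order_features(swi, mask, structure, bin_width=config.bin_width or 25.0)
    values.update({f"firstorder_{k}": v for k, v in fo.items()})

    f3, f2 = shape_features(mask, structure)
    values.update({f"shape_{k}": v for k, v in f3.items()})
    values.update({f"shape2D_{k}": v for k, v in f2.items()})

    d = discretize(swi, mask, structure, bin_width=config.bin_width,
                   bin_count=config.bin_count)

    for delta in config.distances:
        dv = config.voxel_distance(delta, d.spacing)
        try:
            values.update(
                {f"glcm_{k}{delta}": v
                 for k, v in glcm_features(compute_glcm(d, dv)).items()}
            )
        except ValueError:
            flags.append(f"glcm_distance_{delta}_empty")
            warnings.warn(
                f"ROI {structure!r} has no voxel pairs at distance {delta}; "
                "GLCM features at that distance set to 0",
                stacklevel=2,
            )
            values.update({f"glcm_{k}{delta}": 0.0 for k in GLCM_NAMES})
        try:
            values.update(
                {f"ngtdm_{k}{delta}": v
                 for k, v in ngtdm_features(compute_ngtdm(d, dv)).items()}
            )
        except ValueError:
            flags.append(f"ngtdm_distance_{delta}_empty")
            warnings.warn(
                f"ROI {structure!r} has no neighbors at distance {delta}; "
                "NGTDM features at that distance set to 0",
                stacklevel=2,
            )
            values.update({f"ngtdm_{k}{delta}": 0.0 for k in NGTDM_NAMES})

    values.update({f"glrlm_{k}": v for k, v in glrlm_features(compute_glrlm(d)).items()})
    values.update({f"glszm_{k}": v for k, v in glszm_features(compute_glszm(d)).items()})
    values.update(
        {f"gldm_{k}": v
         for k, v in gldm_features(compute_gldm(d, alpha=config.gldm_alpha)).items()}
    )

    fv = FeatureVector(values, flags)
    if len(fv) != EXPECTED_FEATURE_COUNT and len(config.distances) == 3:
        raise AssertionError(
            f"feature count contract violated: {len(fv)} != {EXPECTED_FEATURE_COUNT}"
        )
    return fv
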