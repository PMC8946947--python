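"""First-order intensity statistics, tagged signal-based vs texture-safe.

SWI intensity is not a quantitative susceptibility measure, so features that
read the raw signal level (mean, extrema, percentiles, range, RMS, total
energy) are tagged signal-based and excluded from downstream selection; only
distribution-shape features survive the filter view.
"""

from __future__ import annotations

import numpy as np

from ..io_preproc import LabelMask, Volume

__all__ = ["first_order_features", "SIGNAL_BASED_FEATURES", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "StandardDeviation", "TotalEnergy", "Uniformity", "Variance",
)

#: default signal-based exclusion set: the seven named level-reading features
#: plus RootMeanSquared and TotalEnergy, which also scale with raw signal
SIGNAL_BASED_FEATURES = frozenset(
    {
        "Minimum", "Maximum", "Mean", "Median", "10Percentile", "90Percentile",
        "Range", "RootMeanSquared", "TotalEnergy",
    }
)


def first_order_features(
    vol: Volume,
    mask: LabelMask,
    structure: str,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """The standard 19-feature first-order set over one structure's voxels.

    Entropy and Uniformity operate on the fixed-bin-width discretized
    histogram (same rule as the texture families); all others on raw
    intensities. Moments use population (biased) estimators.
    """
    roi = mask.structure_mask(structure)
    if not roi.any():
        raise ValueError(f"structure {structure!r} has no voxels")
    x = vol.data[roi].astype(np.float64)
    n = x.size
    voxel_volume = float(np.prod(vol.spacing))

    mean = float(x.mean())
    centered = x - mean
    m2 = float((centered**2).mean())
    m3 = float((centered**3).mean())
    m4 = float((centered**4).mean())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    lev = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p_hist = np.bincount(lev).astype(np.float64) / n
    p_nz = p_hist[p_hist > 0]

    f = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": voxel_volume * float((x**2).sum()),
        "Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": float(np.sqrt(m2)),
        "Skewness": 0.0 if m2 == 0 else float(m3 / m2**1.5),
        "Kurtosis": 0.0 if m2 == 0 else float(m4 / m2**2),
        "Variance": m2,
        "Uniformity": float((p_nz**2).sum()),
    }
    return {k: f[k] for k in FIRSTORDER_NAMES}


def texture_safe(features: dict[str, float],
                 excluded: frozenset[str] = SIGNAL_BASED_FEATURES) -> dict[str, float]:
    """Filter view of a first-order dict with signal-based features removed."""
    return {k: v for k, v in features.items() if k not in excluded}
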