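"""Gray-level discretization of an ROI with a fixed-bin-width rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io_preproc import LabelMask, Volume

__all__ = ["DiscretizedROI", "discretize"]


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels inside an ROI, 0 outside.

    ``levels`` is cropped to the ROI bounding box (one-voxel margin) so texture
    matrices operate on small arrays; ``spacing`` is carried for shape- and
    mm-aware computations. ``ng`` is the number of spanned bins: the maximum
    level assigned. In-ROI voxels always have levels in ``[1, ng]``.
    """

    levels: np.ndarray
    ng: int
    mask: np.ndarray
    spacing: np.ndarray
    bin_width: float | None
    bin_count: int | None = None

    def __post_init__(self):
        if self.ng < 1:
            raise ValueError("ng must be >= 1")
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("discretized ROI is empty")
        if inside.min() < 1 or inside.max() > self.ng:
            raise ValueError("in-ROI levels must lie in [1, ng]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def gray_levels(self) -> np.ndarray:
        """Sorted distinct levels actually present in the ROI."""
        return np.unique(self.levels[self.mask])


def _crop(mask: np.ndarray, margin: int = 1):
    idx = np.nonzero(mask)
    sl = tuple(
        slice(max(int(a.min()) - margin, 0), min(int(a.max()) + 1 + margin, n))
        for a, n in zip(idx, mask.shape)
    )
    return sl


def discretize(
    vol: Volume,
    mask: LabelMask,
    structure: str,
    bin_width: float = 25.0,
    bin_count: int | None = None,
) -> DiscretizedROI:
    """Discretize intensities of one structure.

    Fixed-bin-width rule (default): ``level = floor((x - min) / W) + 1``; a
    constant ROI collapses to a single level. Passing ``bin_count`` switches
    to equal-width bins spanning [min, max] instead.
    """
    roi = mask.structure_mask(structure)
    if not roi.any():
        raise ValueError(f"structure {structure!r} has no voxels")
    if not vol.same_grid(mask):
        raise ValueError("volume and mask must share a grid")
    values = vol.data[roi]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite intensities inside the ROI")

    sl = _crop(roi)
    roi_c = roi[sl]
    data_c = vol.data[sl]

    lo, hi = float(values.min()), float(values.max())
    if bin_count is not None:
        if bin_count < 1:
            raise ValueError("bin count must be >= 1")
        if hi == lo:
            lev_in = np.ones(roi_c.sum(), dtype=np.int64)
            ng = 1
        else:
            width = (hi - lo) / bin_count
            lev_in = np.minimum(
                np.floor((data_c[roi_c] - lo) / width).astype(np.int64), bin_count - 1
            ) + 1
            ng = bin_count
        used_width = None
    else:
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        lev_in = np.floor((data_c[roi_c] - lo) / bin_width).astype(np.int64) + 1
        ng = int(lev_in.max())
        used_width = float(bin_width)

    levels = np.zeros(roi_c.shape, dtype=np.int64)
    levels[roi_c] = lev_in
    return DiscretizedROI(
        levels=levels,
        ng=ng,
        mask=roi_c,
        spacing=vol.spacing,
        bin_width=used_width,
        bin_count=bin_count,
    )
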