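"""Hybrid-contrast (HC) synthesis: HC = w1·T1w + w2·SWI.

The weights are chosen so the HC image's mean intensity in the putamen and
globus pallidus matches a reference template (typically MNI-like contrast with
strong deep-gray delineation):

    (w1*, w2*) = argmin || M @ (w1, w2)^T - b ||^2

with M = [[I_put^T1w, I_put^SWI], [I_pall^T1w, I_pall^SWI]] and
b = (I_put^ref, I_pall^ref). For a non-singular 2x2 system the least-squares
minimizer is the exact linear solve and the residual is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io_preproc import PALLIDUM, PUTAMEN, LabelMask, Volume

__all__ = ["ROIMeanSystem", "HCWeights", "CollinearContrastError",
           "roi_mean", "build_system", "solve_weights", "fuse"]


class CollinearContrastError(ValueError):
    """T1w and SWI ROI-mean columns are (near-)proportional; weights undefined."""


@dataclass(frozen=True)
class ROIMeanSystem:
    """The six ROI means that define the weight optimization."""

    put_t1w: float
    put_swi: float
    pall_t1w: float
    pall_swi: float
    put_mni: float
    pall_mni: float

    def __post_init__(self):
        vals = [self.put_t1w, self.put_swi, self.pall_t1w,
                self.pall_swi, self.put_mni, self.pall_mni]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ROI means must all be finite")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([[self.put_t1w, self.put_swi],
                         [self.pall_t1w, self.pall_swi]], dtype=float)

    @property
    def targets(self) -> np.ndarray:
        return np.array([self.put_mni, self.pall_mni], dtype=float)


@dataclass(frozen=True)
class HCWeights:
    w1: float
    w2: float
    residual: float
    system: ROIMeanSystem

    def __post_init__(self):
        if self.residual < -1e-12:
            raise ValueError("residual must be non-negative")

    def to_json(self, path) -> None:
        payload = {
            "w1": self.w1,
            "w2": self.w2,
            "residual": self.residual,
            "roi_means": {
                "putamen_t1w": self.system.put_t1w,
                "putamen_swi": self.system.put_swi,
                "pallidum_t1w": self.system.pall_t1w,
                "pallidum_swi": self.system.pall_swi,
                "putamen_template": self.system.put_mni,
                "pallidum_template": self.system.pall_mni,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def roi_mean(vol: Volume, mask: LabelMask, structure: str) -> float:
    """Arithmetic mean of ``vol`` over the voxels of one named structure."""
    voxels = mask.structure_mask(structure)
    n = int(voxels.sum())
    if n == 0:
        raise ValueError(f"structure {structure!r} has no voxels in the mask")
    return float(vol.data[voxels].sum() / n)


def build_system(
    t1w: Volume,
    swi: Volume,
    init_mask: LabelMask,
    template: Volume,
    template_mask: LabelMask,
) -> ROIMeanSystem:
    """Assemble the ROI-mean system from subject images (initial deep-gray
    mask) and the reference template with its own label map."""
    return ROIMeanSystem(
        put_t1w=roi_mean(t1w, init_mask, PUTAMEN),
        put_swi=roi_mean(swi, init_mask, PUTAMEN),
        pall_t1w=roi_mean(t1w, init_mask, PALLIDUM),
        pall_swi=roi_mean(swi, init_mask, PALLIDUM),
        put_mni=roi_mean(template, template_mask, PUTAMEN),
        pall_mni=roi_mean(template, template_mask, PALLIDUM),
    )


def solve_weights(
    sys: ROIMeanSystem,
    cond_threshold: float = 1e10,
    nonnegative: bool = False,
) -> HCWeights:
    """Least-squares weight solve; exact (zero-residual) for the square case.

    Raises :class:`CollinearContrastError` when the T1w and SWI columns are
    proportional (condition number above ``cond_threshold``), in which case no
    unique weighting exists.
    """
    m = sys.coefficients
    if np.linalg.cond(m) > cond_threshold:
        raise CollinearContrastError(
            "T1w and SWI ROI-mean columns are collinear "
            f"(condition number {np.linalg.cond(m):.3g}); cannot solve weights"
        )
    w, *_ = np.linalg.lstsq(m, sys.targets, rcond=None)
    if nonnegative:
        from scipy.optimize import nnls

        w, _ = nnls(m, sys.targets)
    residual = float(np.sum((m @ w - sys.targets) ** 2))
    return HCWeights(float(w[0]), float(w[1]), residual, sys)


def fuse(t1w: Volume, swi: Volume, w: HCWeights) -> Volume:
    """Voxelwise linear combination w1·T1w + w2·SWI on a shared grid."""
    if not t1w.same_grid(swi):
        raise ValueError("T1w and SWI must be on the identical grid before fusion")
    return Volume(w.w1 * t1w.data + w.w2 * swi.data, t1w.affine, "HC")
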