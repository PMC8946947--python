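"""Template-label propagation onto the subject through the hybrid-contrast image.

The subject's HC image is registered to the anatomical template, and template
deep-gray labels are carried back to the subject grid by nearest-neighbor
transport through the recovered mapping (inverse warping). Non-linear engines
are not re-implemented: a :class:`DeformationProvider` either wraps the
in-repo affine registration or an externally computed dense displacement field
on the template grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_preproc import (
    PUTAMEN,
    AffineTransform,
    LabelMask,
    RegistrationConfig,
    Volume,
    register_affine,
    resample_mask,
)

__all__ = [
    "DeformationProvider",
    "propagate_labels",
    "mask_quality_report",
    "misalign_mask",
]


@dataclass(frozen=True)
class DeformationProvider:
    """Mapping from subject world coordinates into template world coordinates.

    kind:
        ``"affine-internal"`` — payload is an :class:`AffineTransform` mapping
        subject world points to template world points (as returned by
        registering the subject image to the template).
        ``"external-field"`` — payload is a dense displacement field of shape
        ``template_shape + (3,)`` in mm on the template grid, as produced by an
        external diffeomorphic engine; the subject-to-template map is then
        recovered by resampling through the field's inverse use.
    """

    kind: str
    payload: object

    def __post_init__(self):
        if self.kind not in ("affine-internal", "external-field"):
            raise ValueError(f"unknown provider kind {self.kind!r}")
        if self.kind == "affine-internal" and not isinstance(self.payload, AffineTransform):
            raise TypeError("affine-internal provider needs an AffineTransform payload")

    @classmethod
    def from_registration(
        cls, subject: Volume, template: Volume, config: RegistrationConfig | None = None
    ) -> "DeformationProvider":
        """Register the subject image to the template with the in-repo affine
        engine. The returned transform maps subject world -> template world
        (i.e. registering template as 'moving' onto the subject 'fixed' grid)."""
        t = register_affine(moving=template, fixed=subject, config=config)
        return cls("affine-internal", t)


def propagate_labels(
    hc: Volume,
    template: Volume,
    template_labels: LabelMask,
    provider: DeformationProvider,
    required: tuple[str, ...] = (PUTAMEN,),
) -> LabelMask:
    """Carry template labels to the subject grid (nearest-neighbor transport).

    Every output label existed in the template legend; structures listed in
    ``required`` must be non-empty in the result.
    """
    if template_labels.labels.shape != template.shape:
        raise ValueError("template labels must live on the template grid")

    if provider.kind == "affine-internal":
        out = resample_mask(template_labels, provider.payload, hc)
    else:
        field = np.asarray(provider.payload, dtype=float)
        if field.shape != template.shape + (3,):
            raise ValueError(
                "external displacement field must have shape template_shape + (3,), "
                f"got {field.shape}"
            )
        # subject world x maps to template world x + u(x) sampled on the
        # template grid: evaluate u at the subject voxel's world position.
        idx = np.indices(hc.shape).reshape(3, -1)
        world = (hc.affine[:3, :3] @ idx + hc.affine[:3, 3:4])
        tmpl_idx = np.linalg.inv(template.affine) @ np.vstack([world, np.ones(world.shape[1])])
        coords = tmpl_idx[:3]
        disp = np.stack(
            [
                ndimage.map_coordinates(field[..., k], coords, order=1, mode="nearest")
                for k in range(3)
            ]
        )
        warped_world = world + disp
        warped_idx = np.linalg.inv(template.affine) @ np.vstack(
            [warped_world, np.ones(warped_world.shape[1])]
        )
        labels = ndimage.map_coordinates(
            template_labels.labels.astype(np.float64),
            warped_idx[:3],
            order=0,
            mode="constant",
            cval=0.0,
        )
        out = LabelMask(
            np.rint(labels).astype(np.int32).reshape(hc.shape), hc, template_labels.legend
        )

    for name in required:
        if not out.structure_mask(name).any():
            raise ValueError(
                f"propagated mask is empty for required structure {name!r}"
            )
    return out


def mask_quality_report(pred: LabelMask, truth: LabelMask) -> dict:
    """Per-structure Dice, voxel counts, and centroid displacement (mm)."""
    if pred.shape != truth.shape or not np.allclose(pred.affine, truth.affine):
        raise ValueError("prediction and truth must share a grid")
    report: dict[str, dict] = {}
    names = {name for name in truth.legend.values()} | set(pred.legend.values())
    for name in sorted(names):
        try:
            p = pred.structure_mask(name)
        except KeyError:
            p = np.zeros(pred.shape, bool)
        try:
            t = truth.structure_mask(name)
        except KeyError:
            t = np.zeros(truth.shape, bool)
        inter = int(np.logical_and(p, t).sum())
        np_, nt = int(p.sum()), int(t.sum())
        dice = 2.0 * inter / (np_ + nt) if (np_ + nt) else float("nan")
        disp = float("nan")
        if np_ and nt:
            spacing = truth.grid.spacing
            cp = np.array(np.nonzero(p)).mean(axis=1) * spacing
            ct = np.array(np.nonzero(t)).mean(axis=1) * spacing
            disp = float(np.linalg.norm(cp - ct))
        report[name] = {
            "dice": dice,
            "pred_voxels": np_,
            "truth_voxels": nt,
            "centroid_displacement_mm": disp,
        }
    return report


def _shift_block(labels: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    shifted = np.zeros_like(labels)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(offset):
        n = labels.shape[ax]
        if abs(off) >= n:
            raise ValueError("offset exceeds grid size")
        if off >= 0:
            dst[ax] = slice(off, n)
            src[ax] = slice(0, n - off)
        else:
            dst[ax] = slice(0, n + off)
            src[ax] = slice(-off, n)
    shifted[tuple(dst)] = labels[tuple(src)]
    return shifted


def misalign_mask(
    mask: LabelMask,
    offset_voxels: tuple[int, int, int],
    mirror_axis: int | None = 0,
) -> LabelMask:
    """Displace labels by an integer voxel offset, the iron-blind surrogate.

    Emulates the systematic placement error of a T1w-only atlas segmentation,
    which drifts off the iron-rich lateral rim and includes tissue without
    iron deposits. With ``mirror_axis`` set (default: the left-right axis),
    the offset along that axis is applied toward the midline on each
    hemisphere — a medial drift on both sides — while the remaining axes
    shift globally. ``mirror_axis=None`` applies one rigid shift.
    """
    if mirror_axis is None:
        return LabelMask(
            _shift_block(mask.labels, offset_voxels), mask.grid, mask.legend
        )
    n = mask.labels.shape[mirror_axis]
    half = n // 2
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[mirror_axis] = slice(0, half)
    hi[mirror_axis] = slice(half, n)
    off_lo = list(offset_voxels)
    off_hi = list(offset_voxels)
    off_hi[mirror_axis] = -off_hi[mirror_axis]
    shifted = np.zeros_like(mask.labels)
    left = np.zeros_like(mask.labels)
    left[tuple(lo)] = mask.labels[tuple(lo)]
    right = np.zeros_like(mask.labels)
    right[tuple(hi)] = mask.labels[tuple(hi)]
    left = _shift_block(left, tuple(off_lo))
    right = _shift_block(right, tuple(off_hi))
    shifted = np.where(left > 0, left, right)
    return LabelMask(shifted, mask.grid, mask.legend)
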