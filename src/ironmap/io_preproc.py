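"""Volume I/O, white-matter intensity normalization, affine registration and resampling.

All volumes are 3D scalar images carried together with their voxel spacing and
a NIfTI-style voxel-to-world affine (RAS+ world coordinates, mm). Transforms act
in world space: an :class:`AffineTransform` maps fixed-image world coordinates to
moving-image world coordinates, which is the resampling convention — applying it
to the output grid of a resampling pulls intensities from the moving image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMask",
    "AffineTransform",
    "RegistrationConfig",
    "RegistrationError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_t1w_wm",
    "register_affine",
    "resample",
]

#: canonical structure names used throughout the pipeline
PUTAMEN = "putamen"
PALLIDUM = "globus pallidus"
WHITE_MATTER = "white matter"


class RegistrationError(RuntimeError):
    """Raised when intensity-based registration fails to converge.

    Carries the final similarity-metric value in :attr:`final_metric`.
    """

    def __init__(self, message: str, final_metric: float | None = None):
        super().__init__(message)
        self.final_metric = final_metric


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with geometry and a modality tag.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units). Must be finite everywhere.
    affine:
        4x4 voxel-to-world (RAS+, mm) map, NIfTI convention.
    modality:
        One of ``{"T1w", "SWI", "HC", "template"}`` (free-form tags are not
        rejected, but the pipeline only produces these four).
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "T1w"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume must have exactly 3 axes, got {data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite voxels")
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive along every axis")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume":
        return Volume(data, self.affine, modality or self.modality)

    def same_grid(self, other: "Volume | LabelMask", atol: float = 1e-6) -> bool:
        other_affine = other.affine if isinstance(other, Volume) else other.grid.affine
        other_shape = other.shape if isinstance(other, Volume) else other.labels.shape
        return self.shape == tuple(other_shape) and np.allclose(
            self.affine, other_affine, atol=atol
        )


@dataclass(frozen=True)
class LabelMask:
    """Integer-labeled volume on a reference grid.

    ``legend`` maps label values to structure names; 0 is background and must
    not appear in the legend.
    """

    labels: np.ndarray
    grid: Volume
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label array must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integers")
            labels = labels.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"label shape {labels.shape} does not match grid {self.grid.shape}"
            )
        if 0 in dict(self.legend):
            raise ValueError("label 0 is reserved for background")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "legend", dict(self.legend))

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_of(self, structure: str) -> int:
        for value, name in self.legend.items():
            if name == structure:
                return value
        raise KeyError(f"structure {structure!r} not in legend {self.legend}")

    def structure_mask(self, structure: str) -> np.ndarray:
        """Boolean mask of one named structure; may be empty."""
        return self.labels == self.label_of(structure)

    def empty_structures(self) -> list[str]:
        present = set(np.unique(self.labels))
        return [name for value, name in self.legend.items() if value not in present]


@dataclass(frozen=True)
class AffineTransform:
    """World-space (mm) affine map x -> matrix @ x + translation."""

    matrix: np.ndarray
    translation: np.ndarray

    #: determinant magnitude below which the transform is considered degenerate
    DET_TOL = 1e-8

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(matrix)) < self.DET_TOL:
            raise ValueError("affine matrix is singular (|det| below tolerance)")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "translation", translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of world points."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )

    def as_homogeneous(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.matrix
        out[:3, 3] = self.translation
        return out

    @classmethod
    def from_homogeneous(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path) -> None:
        np.savetxt(path, self.as_homogeneous(), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_homogeneous(np.loadtxt(path))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, modality: str = "T1w") -> Volume:
    """Read a 3D NIfTI volume.

    Rejects missing files, images that are not exactly 3D, and images with
    non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3D image, got {data.ndim} axes {data.shape}"
        )
    return Volume(np.asarray(data, dtype=np.float64), img.affine, modality)


def write_volume(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


def read_mask(path, legend: Mapping[int, str], grid: Volume | None = None) -> LabelMask:
    """Read an integer label map; ``grid`` defaults to the mask's own geometry."""
    vol = read_volume(path, modality="template")
    labels = np.rint(vol.data).astype(np.int32)
    return LabelMask(labels, grid if grid is not None else vol.with_data(vol.data), legend)


def write_mask(mask: LabelMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine), str(path))


# ---------------------------------------------------------------------------
# White-matter intensity normalization
# ---------------------------------------------------------------------------

def normalize_t1w_wm(
    vol: Volume, wm: LabelMask, target: float = 110.0, structure: str = WHITE_MATTER
) -> Volume:
    """Scale a T1w volume so its mean white-matter intensity equals ``target``.

    One global multiplicative factor ``target / mean(vol | WM)`` is applied to
    the whole volume, mirroring the conventional FreeSurfer-style convention of
    anchoring white matter at 110.
    """
    wm_voxels = wm.structure_mask(structure)
    n = int(wm_voxels.sum())
    if n == 0:
        raise ValueError("white-matter mask is empty; cannot normalize")
    wm_mean = float(vol.data[wm_voxels].mean())
    if wm_mean == 0.0:
        raise ValueError("white-matter mean intensity is zero; cannot normalize")
    return vol.with_data(vol.data * (target / wm_mean))


# ---------------------------------------------------------------------------
# Affine registration (SimpleITK engine)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for intensity-based affine registration.

    metric:
        ``"mi"`` (Mattes mutual information) or ``"msq"`` (mean squares).
    shrink_factors / smoothing_sigmas:
        Multi-resolution pyramid (coarse to fine).
    sampling_fraction:
        Fraction of voxels sampled per iteration; 1.0 uses every voxel
        (fully deterministic).
    """

    metric: str = "mi"
    bins: int = 32
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    iterations: int = 200
    sampling_fraction: float = 1.0
    seed: int = 12345
    initialize_from_headers: bool = True
    min_final_metric: float | None = None
    mode: str = "affine"  # "affine" or "translation"

    @classmethod
    def fast(cls) -> "RegistrationConfig":
        """Two-level pyramid with seeded 25% sampling: ~20x faster than the
        default on 64-voxel grids with near-identical alignment quality;
        intended for cohort-scale synthetic runs."""
        return cls(
            shrink_factors=(4, 2),
            smoothing_sigmas=(2.0, 1.0),
            iterations=100,
            sampling_fraction=0.25,
        )


_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])


def _to_sitk(vol: Volume) -> sitk.Image:
    """Convert to a SimpleITK image with faithful world geometry (LPS)."""
    affine_lps = np.diag([-1.0, -1.0, 1.0, 1.0]) @ vol.affine
    linear = affine_lps[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    direction = linear / spacing
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in affine_lps[:3, 3]))
    img.SetDirection(tuple(float(d) for d in direction.ravel(order="C")))
    return img


def register_affine(
    moving: Volume, fixed: Volume, config: RegistrationConfig | None = None
) -> AffineTransform:
    """Estimate the world-space affine mapping fixed coordinates onto moving.

    Multi-resolution optimization of an intensity-similarity criterion
    (Mattes mutual information by default), seeded and deterministic for a
    given config. The returned transform is in RAS world coordinates and is
    directly usable by :func:`resample` to pull the moving image onto the
    fixed grid.
    """
    config = config or RegistrationConfig()
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    reg = sitk.ImageRegistrationMethod()
    if config.metric == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.bins)
    elif config.metric == "msq":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown metric {config.metric!r}")
    if config.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(config.sampling_fraction, config.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=config.iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()

    if config.mode == "translation":
        initial = sitk.TranslationTransform(3)
    else:
        initial = sitk.AffineTransform(3)
    if config.initialize_from_headers:
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, initial, sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
    reg.SetInitialTransform(initial, inPlace=True)

    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # e.g. disjoint fields of view, all-zero overlap
        raise RegistrationError(f"registration failed: {exc}") from exc

    final_metric = reg.GetMetricValue()
    if config.min_final_metric is not None and final_metric > config.min_final_metric:
        raise RegistrationError(
            f"registration did not converge (final metric {final_metric:.5f})",
            final_metric=final_metric,
        )

    tx = result
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(tx.GetNumberOfTransforms() - 1)
    if isinstance(tx, sitk.TranslationTransform):
        matrix_lps = np.eye(3)
        trans_lps = np.asarray(tx.GetOffset())
    else:
        tx = sitk.AffineTransform(tx)
        matrix_lps = np.asarray(tx.GetMatrix()).reshape(3, 3)
        center = np.asarray(tx.GetCenter())
        trans_lps = np.asarray(tx.GetTranslation()) + center - matrix_lps @ center
    # sitk maps fixed LPS -> moving LPS; convert both sides to RAS
    matrix = _RAS_TO_LPS @ matrix_lps @ _RAS_TO_LPS
    translation = _RAS_TO_LPS @ trans_lps
    return AffineTransform(matrix, translation)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(
    vol: Volume,
    t: AffineTransform,
    grid: Volume,
    interp: str = "linear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``vol`` onto ``grid`` through the world-space transform ``t``.

    For every output voxel the world position is pushed through ``t`` and the
    input is interpolated there. ``interp="nearest"`` never invents values;
    ``interp="linear"`` output is bounded by the input range.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if np.any(np.asarray(grid.shape) <= 0):
        raise ValueError("degenerate target grid")
    # full index->index map: vol_index = inv(A_vol) @ T @ A_grid @ grid_index
    m = np.linalg.inv(vol.affine) @ t.as_homogeneous() @ grid.affine
    order = 1 if interp == "linear" else 0
    out = ndimage.affine_transform(
        vol.data,
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=grid.shape,
        order=order,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return Volume(out, grid.affine, vol.modality)


def resample_mask(
    mask: LabelMask, t: AffineTransform, grid: Volume
) -> LabelMask:
    """Nearest-neighbor label transport onto ``grid`` (labels never invented)."""
    vol = Volume(mask.labels.astype(np.float64), mask.affine, "template")
    out = resample(vol, t, grid, interp="nearest", fill=0.0)
    return LabelMask(np.rint(out.data).astype(np.int32), grid, mask.legend)
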