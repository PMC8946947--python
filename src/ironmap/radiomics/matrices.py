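"""Texture-matrix construction over a discretized ROI.

All matrices follow the conventions of the standard radiomics feature
definitions: 13 unique 3D directions with symmetric accumulation for GLCM and
GLRLM, 26-connected zones for GLSZM, 26-neighborhoods for GLDM, and a
Chebyshev neighborhood of configurable radius for NGTDM. Gray levels index
rows 1..Ng (row 0 of the stored arrays corresponds to level 1); levels absent
from the ROI simply contribute empty rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "ANGLES_13",
    "TextureMatrix",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "compute_ngtdm",
]

#: the 13 unique direction vectors of a 3D 26-neighborhood (one per +/- pair)
ANGLES_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

_NEIGHBORS_26 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass(frozen=True)
class TextureMatrix:
    """One texture matrix plus the metadata needed to interpret it.

    ``values`` is 2D for GLCM/GLRLM/GLSZM/GLDM (rows = gray level 1..Ng) and a
    per-level table for NGTDM (columns: n_i, p_i, s_i). ``angle`` is the
    direction vector for per-angle kinds, or ``"aggregate"``.
    """

    kind: str
    values: np.ndarray
    distance: int = 1
    angle: tuple[int, int, int] | str = "aggregate"
    normalized: bool = False

    def __post_init__(self):
        if self.kind not in ("GLCM", "GLRLM", "GLSZM", "GLDM", "NGTDM"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("texture matrix entries must be non-negative")

    @property
    def empty(self) -> bool:
        return float(np.sum(self.values)) == 0.0


def _pairs_at_offset(levels: np.ndarray, offset: tuple[int, int, int]):
    """Slicing views of the two endpoints of every in-image pair at ``offset``."""
    src, dst = [], []
    for off, n in zip(offset, levels.shape):
        if abs(off) >= n:
            return None, None
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    return levels[tuple(src)], levels[tuple(dst)]


def compute_glcm(
    d: DiscretizedROI, delta: int = 1, normalize: bool = True
) -> list[TextureMatrix]:
    """Per-angle gray-level co-occurrence matrices at neighbor distance ``delta``.

    Entry (i, j) counts voxel pairs separated by ``delta * angle`` where both
    endpoints lie inside the ROI, accumulated symmetrically (each ordered pair
    and its reverse). Each angle's matrix is normalized to unit mass when
    ``normalize`` is set; angles with no valid pair produce an empty matrix,
    which the feature layer skips.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    ng = d.ng
    out = []
    for angle in ANGLES_13:
        offset = tuple(delta * a for a in angle)
        a, b = _pairs_at_offset(d.levels, offset)
        mat = np.zeros((ng, ng), dtype=np.float64)
        if a is not None:
            valid = (a > 0) & (b > 0)
            if valid.any():
                i = a[valid] - 1
                j = b[valid] - 1
                counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
                mat = (counts + counts.T).astype(np.float64)
        total = mat.sum()
        if normalize and total > 0:
            mat = mat / total
        out.append(
            TextureMatrix("GLCM", mat, distance=delta, angle=angle,
                          normalized=normalize and total > 0)
        )
    return out


def compute_glrlm(d: DiscretizedROI) -> list[TextureMatrix]:
    """Per-direction gray-level run-length matrices.

    A run is a maximal set of consecutive in-ROI voxels of equal level along a
    direction; out-of-ROI voxels break runs. Entry (i, r) counts runs of level
    i and length r (column r-1 of the stored array).
    """
    levels = d.levels
    ng = d.ng
    max_run = int(np.ceil(np.linalg.norm(levels.shape)) + 2)
    out = []
    for angle in ANGLES_13:
        # a voxel starts a run if its predecessor along -angle is absent or differs
        prev, cur = _pairs_at_offset(levels, angle)
        continues = np.zeros(levels.shape, dtype=bool)
        if prev is not None:
            sl_dst = tuple(
                slice(a, n) if a >= 0 else slice(0, n + a)
                for a, n in zip(angle, levels.shape)
            )
            continues[sl_dst] = (prev == cur) & (cur > 0)
        starts = (levels > 0) & ~continues
        run_level = levels[starts]
        pos = np.array(np.nonzero(starts)).T  # (n_runs, 3)
        length = np.ones(len(pos), dtype=np.int64)
        alive = np.arange(len(pos))
        cur_pos = pos.copy()
        step = np.array(angle)
        while alive.size:
            nxt = cur_pos[alive] + step
            inb = np.all((nxt >= 0) & (nxt < np.array(levels.shape)), axis=1)
            ok = np.zeros(len(alive), dtype=bool)
            if inb.any():
                vals = levels[tuple(nxt[inb].T)]
                ok[inb] = vals == run_level[alive[inb]]
            length[alive[ok]] += 1
            cur_pos[alive[ok]] = nxt[ok]
            alive = alive[ok]
        mat = np.zeros((ng, max_run), dtype=np.float64)
        if len(run_level):
            np.add.at(mat, (run_level - 1, length - 1), 1.0)
        # trim trailing all-zero run-length columns
        nz = np.nonzero(mat.sum(axis=0))[0]
        mat = mat[:, : nz.max() + 1] if nz.size else mat[:, :1]
        out.append(TextureMatrix("GLRLM", mat, distance=1, angle=angle))
    return out


def compute_glszm(d: DiscretizedROI) -> TextureMatrix:
    """Gray-level size-zone matrix: zones are 26-connected equal-level components."""
    ng = d.ng
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level: list[tuple[int, int]] = []
    max_size = 1
    for level in np.unique(d.levels[d.mask]):
        comp, n = ndimage.label(d.levels == level, structure=structure)
        if n:
            counts = np.bincount(comp.ravel())[1:]
            for c in counts:
                sizes_per_level.append((int(level), int(c)))
                max_size = max(max_size, int(c))
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for level, size in sizes_per_level:
        mat[level - 1, size - 1] += 1.0
    return TextureMatrix("GLSZM", mat)


def compute_gldm(d: DiscretizedROI, alpha: int = 0) -> TextureMatrix:
    """Gray-level dependence matrix.

    The dependence of a voxel is the count of its 26-neighbors (center
    excluded) that are in the ROI and within ``alpha`` gray levels of it;
    entry (i, k) of the stored array counts voxels of level i with dependence
    k (k = 0..26). An isolated single-voxel ROI has dependence 0.
    """
    levels = d.levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for offset in _NEIGHBORS_26:
        a, b = _pairs_at_offset(levels, offset)
        if a is None:
            continue
        sl_dst = tuple(
            slice(o, n) if o >= 0 else slice(0, n + o)
            for o, n in zip(offset, levels.shape)
        )
        hit = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= alpha)
        dep[sl_dst] += hit
    inside = d.mask
    ng = d.ng
    max_dep = int(dep[inside].max()) if inside.any() else 0
    mat = np.zeros((ng, max_dep + 1), dtype=np.float64)
    np.add.at(mat, (levels[inside] - 1, dep[inside]), 1.0)
    return TextureMatrix("GLDM", mat)


def compute_ngtdm(d: DiscretizedROI, delta: int = 1) -> TextureMatrix:
    """Neighboring gray-tone difference table at Chebyshev radius ``delta``.

    For each level i: n_i voxels (those with at least one in-ROI neighbor),
    p_i = n_i / N, and s_i = sum over those voxels of |i - A|, A being the
    mean level of the in-ROI neighbors in the cube of side 2*delta+1 minus the
    center. Stored as a (Ng, 3) table of columns (n_i, p_i, s_i).
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    size = 2 * delta + 1
    lev = d.levels.astype(np.float64)
    inroi = d.mask.astype(np.float64)
    cube_sum = ndimage.uniform_filter(lev * inroi, size=size, mode="constant") * size**3
    cube_cnt = ndimage.uniform_filter(inroi, size=size, mode="constant") * size**3
    neigh_sum = cube_sum - lev * inroi
    neigh_cnt = np.rint(cube_cnt - inroi)
    valid = d.mask & (neigh_cnt > 0)
    ng = d.ng
    table = np.zeros((ng, 3), dtype=np.float64)
    if valid.any():
        lv = d.levels[valid]
        a = neigh_sum[valid] / neigh_cnt[valid]
        diff = np.abs(lv.astype(np.float64) - a)
        n_i = np.bincount(lv - 1, minlength=ng).astype(np.float64)
        s_i = np.bincount(lv - 1, weights=diff, minlength=ng)
        table[:, 0] = n_i
        table[:, 1] = n_i / n_i.sum()
        table[:, 2] = s_i
    return TextureMatrix("NGTDM", table, distance=delta)
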