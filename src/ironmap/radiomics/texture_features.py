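"""Feature formulas for the five texture-matrix families.

Formulas follow the standard radiomics definitions. Per-angle families (GLCM,
GLRLM) compute features on each direction's matrix and average over
directions, skipping directions with no valid pairs/runs. Gray-level indices
``i`` enter the formulas with their discretized values (1..Ng); degenerate
cases follow explicit guards documented per feature.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

_EPS = np.finfo(np.float64).eps

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: denominator guard for NGTDM Coarseness
_COARSENESS_EPS = 1e-30


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    # diagonal (|i-j|) and cross (i+j) marginals
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((p * ii * jj).sum())
    spread = ii + jj - ux - uy
    f["ClusterProminence"] = float((p * spread**4).sum())
    f["ClusterShade"] = float((p * spread**3).sum())
    f["ClusterTendency"] = float((p * spread**2).sum())
    f["Contrast"] = float((p * (ii - jj) ** 2).sum())
    # flat region: perfectly correlated by convention
    f["Correlation"] = (
        1.0 if sx * sy == 0 else float(((p * ii * jj).sum() - ux * uy) / (sx * sy))
    )
    da = float((k_diff * p_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = float(-_xlog2(p_diff).sum())
    f["DifferenceVariance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    absdiff = np.abs(ii - jj)
    f["Id"] = float((p / (1.0 + absdiff)).sum())
    f["Idm"] = float((p / (1.0 + absdiff**2)).sum())
    f["Idmn"] = float((p / (1.0 + absdiff**2 / ng**2)).sum())
    f["Idn"] = float((p / (1.0 + absdiff / ng)).sum())

    hxy = float(-_xlog2(p).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.where(pxpy > 0, np.log2(np.maximum(pxpy, _EPS)), 0.0)).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    f["Imc1"] = 0.0 if max(hx, hy) == 0 else float((hxy - hxy1) / max(hx, hy))
    f["Imc2"] = 0.0 if hxy2 <= hxy else float(np.sqrt(1.0 - np.exp(-2.0 * (hxy2 - hxy))))

    off = absdiff > 0
    f["InverseVariance"] = float((p[off] / absdiff[off] ** 2).sum()) if off.any() else 0.0
    f["JointAverage"] = ux
    f["JointEnergy"] = float((p**2).sum())
    f["JointEntropy"] = hxy
    f["MCC"] = _mcc(p, px, py)
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((k_sum * p_sum).sum())
    f["SumEntropy"] = float(-_xlog2(p_sum).sum())
    f["SumSquares"] = float((p * (ii - ux) ** 2).sum())
    return f


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Second-largest eigenvalue (sqrt) of the GLCM transition kernel.

    Defined as 0 for single-level ROIs, where no second mode exists.
    """
    present = px > 0
    if present.sum() < 2:
        return 0.0
    pp = p[np.ix_(present, present)]
    pxp = px[present]
    pyp = py[present]
    q = (pp / pxp[:, None]) @ (pp / pyp[:, None]).T
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig))[::-1]
    second = float(eig[1]) if eig.size > 1 else 0.0
    return float(np.sqrt(max(second, 0.0)))


def _average(per_angle: list[dict[str, float]], names) -> dict[str, float]:
    return {k: float(np.mean([f[k] for f in per_angle])) for k in names}


def glcm_features(mats: list[TextureMatrix]) -> dict[str, float]:
    """The 24-feature GLCM set, averaged over non-empty angle matrices."""
    usable = [m for m in mats if m.kind == "GLCM" and not m.empty]
    if not usable:
        raise ValueError("all GLCM angle matrices are empty at this distance")
    per_angle = []
    for m in usable:
        p = m.values / m.values.sum() if not m.normalized else m.values
        per_angle.append(_glcm_single(p, p.shape[0]))
    return _average(per_angle, GLCM_NAMES)


def _glrlm_single(mat: np.ndarray) -> dict[str, float]:
    ng, nr_len = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    r = np.arange(1, nr_len + 1, dtype=np.float64)[None, :]
    nr = mat.sum()
    npix = float((mat * r).sum())  # each voxel belongs to exactly one run
    p = mat / nr
    f = {}
    f["ShortRunEmphasis"] = float((mat / r**2).sum() / nr)
    f["LongRunEmphasis"] = float((mat * r**2).sum() / nr)
    f["GrayLevelNonUniformity"] = float((mat.sum(axis=1) ** 2).sum() / nr)
    f["GrayLevelNonUniformityNormalized"] = float((mat.sum(axis=1) ** 2).sum() / nr**2)
    f["RunLengthNonUniformity"] = float((mat.sum(axis=0) ** 2).sum() / nr)
    f["RunLengthNonUniformityNormalized"] = float((mat.sum(axis=0) ** 2).sum() / nr**2)
    f["RunPercentage"] = float(nr / npix)
    mu_i = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    mu_r = float((p * r).sum())
    f["RunVariance"] = float((p * (r - mu_r) ** 2).sum())
    f["RunEntropy"] = float(-_xlog2(p).sum())
    f["LowGrayLevelRunEmphasis"] = float((mat / i**2).sum() / nr)
    f["HighGrayLevelRunEmphasis"] = float((mat * i**2).sum() / nr)
    f["ShortRunLowGrayLevelEmphasis"] = float((mat / (i**2 * r**2)).sum() / nr)
    f["ShortRunHighGrayLevelEmphasis"] = float((mat * i**2 / r**2).sum() / nr)
    f["LongRunLowGrayLevelEmphasis"] = float((mat * r**2 / i**2).sum() / nr)
    f["LongRunHighGrayLevelEmphasis"] = float((mat * (i * r) ** 2).sum() / nr)
    return f


def glrlm_features(mats: list[TextureMatrix]) -> dict[str, float]:
    """The 16-feature GLRLM set, averaged over directions."""
    usable = [m for m in mats if m.kind == "GLRLM" and not m.empty]
    if not usable:
        raise ValueError("ROI produced no runs")
    return _average([_glrlm_single(m.values) for m in usable], GLRLM_NAMES)


def glszm_features(mat: TextureMatrix) -> dict[str, float]:
    """The 16-feature GLSZM set (single aggregate matrix)."""
    m = mat.values
    if m.sum() == 0:
        raise ValueError("empty size-zone matrix")
    ng, ns = m.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    nz = m.sum()
    npix = float((m * s).sum())
    p = m / nz
    f = {}
    f["SmallAreaEmphasis"] = float((m / s**2).sum() / nz)
    f["LargeAreaEmphasis"] = float((m * s**2).sum() / nz)
    f["GrayLevelNonUniformity"] = float((m.sum(axis=1) ** 2).sum() / nz)
    f["GrayLevelNonUniformityNormalized"] = float((m.sum(axis=1) ** 2).sum() / nz**2)
    f["SizeZoneNonUniformity"] = float((m.sum(axis=0) ** 2).sum() / nz)
    f["SizeZoneNonUniformityNormalized"] = float((m.sum(axis=0) ** 2).sum() / nz**2)
    f["ZonePercentage"] = float(nz / npix)
    mu_i = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    mu_s = float((p * s).sum())
    f["ZoneVariance"] = float((p * (s - mu_s) ** 2).sum())
    f["ZoneEntropy"] = float(-_xlog2(p).sum())
    f["LowGrayLevelZoneEmphasis"] = float((m / i**2).sum() / nz)
    f["HighGrayLevelZoneEmphasis"] = float((m * i**2).sum() / nz)
    f["SmallAreaLowGrayLevelEmphasis"] = float((m / (i**2 * s**2)).sum() / nz)
    f["SmallAreaHighGrayLevelEmphasis"] = float((m * i**2 / s**2).sum() / nz)
    f["LargeAreaLowGrayLevelEmphasis"] = float((m * s**2 / i**2).sum() / nz)
    f["LargeAreaHighGrayLevelEmphasis"] = float((m * (i * s) ** 2).sum() / nz)
    return {k: f[k] for k in GLSZM_NAMES}


def gldm_features(mat: TextureMatrix) -> dict[str, float]:
    """The 14-feature GLDM set.

    The stored matrix column k is the raw neighbor count (0..26); feature
    formulas weight dependence as j = k + 1, counting the center voxel as part
    of its own dependence set, which keeps the small-dependence emphases
    defined for isolated voxels.
    """
    m = mat.values
    if m.sum() == 0:
        raise ValueError("empty dependence matrix")
    ng, nd = m.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    nz = m.sum()
    p = m / nz
    f = {}
    f["SmallDependenceEmphasis"] = float((m / j**2).sum() / nz)
    f["LargeDependenceEmphasis"] = float((m * j**2).sum() / nz)
    f["GrayLevelNonUniformity"] = float((m.sum(axis=1) ** 2).sum() / nz)
    f["DependenceNonUniformity"] = float((m.sum(axis=0) ** 2).sum() / nz)
    f["DependenceNonUniformityNormalized"] = float((m.sum(axis=0) ** 2).sum() / nz**2)
    mu_i = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    mu_j = float((p * j).sum())
    f["DependenceVariance"] = float((p * (j - mu_j) ** 2).sum())
    f["DependenceEntropy"] = float(-_xlog2(p).sum())
    f["LowGrayLevelEmphasis"] = float((m / i**2).sum() / nz)
    f["HighGrayLevelEmphasis"] = float((m * i**2).sum() / nz)
    f["SmallDependenceLowGrayLevelEmphasis"] = float((m / (i**2 * j**2)).sum() / nz)
    f["SmallDependenceHighGrayLevelEmphasis"] = float((m * i**2 / j**2).sum() / nz)
    f["LargeDependenceLowGrayLevelEmphasis"] = float((m * j**2 / i**2).sum() / nz)
    f["LargeDependenceHighGrayLevelEmphasis"] = float((m * (i * j) ** 2).sum() / nz)
    return {k: f[k] for k in GLDM_NAMES}


def ngtdm_features(mat: TextureMatrix) -> dict[str, float]:
    """The 5-feature NGTDM set (Coarseness, Contrast, Busyness, Complexity,
    Strength) from the per-level (n_i, p_i, s_i) table."""
    table = mat.values
    n_i, p_i, s_i = table[:, 0], table[:, 1], table[:, 2]
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("NGTDM has no voxels with in-ROI neighbors")
    present = p_i > 0
    ngp = int(present.sum())
    lv = np.arange(1, table.shape[0] + 1, dtype=np.float64)

    f = {}
    f["Coarseness"] = float(1.0 / ((p_i * s_i).sum() + _COARSENESS_EPS))
    if ngp == 1:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Strength"] = 0.0
        f["Complexity"] = 0.0
        return {k: f[k] for k in NGTDM_NAMES}

    ip, pp, sp = lv[present], p_i[present], s_i[present]
    di = ip[:, None] - ip[None, :]
    f["Contrast"] = float(
        (pp[:, None] * pp[None, :] * di**2).sum()
        / (ngp * (ngp - 1))
        * (s_i.sum() / nvp)
    )
    denom = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
    f["Busyness"] = float((pp * sp).sum() / denom) if denom > 0 else 0.0
    f["Complexity"] = float(
        (
            np.abs(di)
            * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        ).sum()
        / nvp
    )
    ssum = s_i.sum()
    f["Strength"] = (
        float(((pp[:, None] + pp[None, :]) * di**2).sum() / ssum) if ssum > 0 else 0.0
    )
    return {k: f[k] for k in NGTDM_NAMES}
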