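"""Seeded paired T1w/SWI phantom cohorts with ground-truth deep-gray masks.

Each phantom is a parametric "brain": an ellipsoidal white-matter shell
containing bilateral putamen and globus pallidus nuclei. Iron deposition is
rendered as SWI hypointensity with the class-specific topography described
for parkinsonian syndromes:

* MSA-P — posterolateral putaminal hypointensity with a lateral-to-medial
  gradient, plus involvement of the lateral pallidal rim;
* PSP — hypointensity of the anterior and medial aspects of the globus
  pallidus;
* PD — a slit-like hypointensity along the lateral margin of the putamen;
* MSA-C — mild, diffuse putaminal signal change.

T1w is rendered nearly iron-insensitive with weak deep-gray contrast, so a
hybrid T1w+SWI contrast has genuine added value for iron-reflecting
segmentation. Per-subject disease severity scales the effect (log-normal),
and a small random affine jitter perturbs the geometry, so classes overlap
rather than being point masses. Identical seed + spec reproduces a phantom
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_preproc import PALLIDUM, PUTAMEN, WHITE_MATTER, LabelMask, Volume

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "DEFAULT_CLASS_COUNTS",
    "generate_subject",
    "generate_template",
    "generate_cohort",
]

CLASSES = ("MSA-P", "MSA-C", "PSP", "PD")

#: cohort sizes of the four diagnostic groups used as simulation defaults
DEFAULT_CLASS_COUNTS: dict[str, int] = {"MSA-P": 34, "MSA-C": 21, "PSP": 17, "PD": 56}

LEGEND = {1: PUTAMEN, 2: PALLIDUM, 3: WHITE_MATTER}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast, pathology and noise settings of one phantom.

    Effect sizes are in SWI intensity units (depth of the iron-related
    hypointensity at full expression); ``severity_sigma`` is the log-normal
    spread of per-subject disease severity; geometric jitter emulates
    head-position and anatomy variation.
    """

    class_name: str = "PD"
    grid_size: int = 64
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # intensity model (arbitrary units)
    t1w_wm: float = 110.0
    t1w_putamen: float = 100.0
    t1w_pallidum: float = 95.0
    swi_wm: float = 160.0
    swi_putamen: float = 150.0
    swi_pallidum: float = 130.0
    # pathology
    depth: float = 60.0  # hypointensity depth scale at severity 1
    mean_drop_fraction: float = 0.2  # putaminal mean drop, as a fraction of depth
    gradient: float = 0.7  # posterior emphasis of the MSA-P gradient
    slit_width: float = 1.5  # PD slit thickness, voxels
    severity_sigma: float = 0.25
    t1w_iron_sensitivity: float = 0.08
    # per-subject pattern variability (biological heterogeneity)
    gradient_jitter: float = 0.15  # sd of the posterior-emphasis draw
    slit_width_jitter: float = 0.4  # sd of the slit-width draw, voxels
    # noise model (scanner-like nuisance)
    noise_sd: float = 10.0
    smoothing_sigma: float = 0.6
    swi_gain_sigma: float = 0.08  # log-normal per-subject receive gain
    swi_offset_sd: float = 5.0  # per-subject global offset, intensity units
    bias_amplitude: float = 8.0  # smooth intensity-inhomogeneity strength
    bias_scale: float = 12.0  # correlation length of the bias field, voxels
    # geometric jitter (per-subject)
    jitter_translation_sd: float = 1.0  # voxels
    jitter_scale_sd: float = 0.03
    jitter_rotation_sd: float = 2.0  # degrees, about the axial axis
    seed: int = 0

    def __post_init__(self):
        if self.class_name not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}")
        if min(self.depth, self.slit_width, self.noise_sd, self.smoothing_sigma) < 0:
            raise ValueError("effect sizes and noise parameters must be >= 0")


@dataclass(frozen=True)
class PhantomSubject:
    t1w: Volume
    swi: Volume
    truth: LabelMask
    class_name: str
    spec: PhantomSpec


def _affine(spec: PhantomSpec) -> np.ndarray:
    a = np.diag([*spec.spacing, 1.0])
    a[:3, 3] = -np.asarray(spec.spacing) * spec.grid_size / 2.0
    return a


def _jittered_frame(spec: PhantomSpec, rng: np.random.Generator):
    """Per-subject coordinate frame: rotation, scale and shift of the anatomy."""
    n = spec.grid_size
    t = rng.normal(0.0, spec.jitter_translation_sd, size=3)
    s = rng.normal(1.0, spec.jitter_scale_sd)
    theta = np.deg2rad(rng.normal(0.0, spec.jitter_rotation_sd))
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    grid = np.indices((n, n, n), dtype=np.float64)
    center = (n - 1) / 2.0
    coords = grid - center
    # anatomy coordinates: undo shift, rotation and scale of the subject head
    xyz = np.einsum("ij,jabc->iabc", rot.T, coords - t[:, None, None, None]) / s
    return xyz


def _ellipsoid(xyz, center, semi):
    u = [(xyz[i] - center[i]) / semi[i] for i in range(3)]
    return u[0] ** 2 + u[1] ** 2 + u[2] ** 2 <= 1.0


# nucleus geometry in centered anatomy coordinates (voxel units):
# axis 0 = left-right (lateral away from 0), axis 1 = posterior-anterior,
# axis 2 = inferior-superior
_BRAIN = ((0.0, 0.0, 0.0), (27.0, 29.0, 25.0))
_PUT_SEMI = (5.0, 9.0, 7.5)
_PUT_CENTER_X = 16.0
_PALL_SEMI = (3.5, 5.5, 4.5)
_PALL_CENTER = (9.0, 1.0, -1.0)  # (|x|, y, z)


def _build_anatomy(xyz):
    brain = _ellipsoid(xyz, *_BRAIN)
    put = np.zeros(xyz.shape[1:], dtype=bool)
    pall = np.zeros_like(put)
    lateralness = np.zeros(xyz.shape[1:], dtype=np.float64)
    posteriorness = np.zeros_like(lateralness)
    pall_anteromedial = np.zeros_like(lateralness)
    pall_lateral = np.zeros_like(lateralness)
    for side in (-1.0, 1.0):
        pc = (side * _PUT_CENTER_X, 0.0, 0.0)
        p = _ellipsoid(xyz, pc, _PUT_SEMI)
        put |= p
        # normalized position inside the nucleus, used by the pathology fields
        lat = np.clip(side * (xyz[0] - pc[0]) / _PUT_SEMI[0], -1.0, 1.0)
        post = np.clip(-(xyz[1] - pc[1]) / _PUT_SEMI[1], -1.0, 1.0)
        lateralness[p] = np.clip(lat[p], 0.0, 1.0)
        posteriorness[p] = np.clip(post[p], 0.0, 1.0)

        gc = (side * _PALL_CENTER[0], _PALL_CENTER[1], _PALL_CENTER[2])
        g = _ellipsoid(xyz, gc, _PALL_SEMI)
        g &= ~put  # putamen wins where the abutting nuclei touch
        pall |= g
        med = np.clip(-side * (xyz[0] - gc[0]) / _PALL_SEMI[0], -1.0, 1.0)
        ant = np.clip((xyz[1] - gc[1]) / _PALL_SEMI[1], -1.0, 1.0)
        pall_anteromedial[g] = np.clip(0.5 * (med[g] + ant[g]), 0.0, 1.0)
        pall_lateral[g] = np.clip(-med[g], 0.0, 1.0)
    labels = np.zeros(xyz.shape[1:], dtype=np.int32)
    labels[brain] = 3
    labels[pall] = 2
    labels[put] = 1
    fields = {
        "lateralness": lateralness,
        "posteriorness": posteriorness,
        "pall_anteromedial": pall_anteromedial,
        "pall_lateral": pall_lateral,
    }
    return labels, fields


def _iron_field(
    spec: PhantomSpec, labels, fields, severity: float, rng: np.random.Generator
) -> np.ndarray:
    """SWI signal drop (positive = darker) encoding the class topography.

    The putaminal fields of all classes are normalized to the same mean drop
    (``mean_drop_fraction * depth * severity``): what distinguishes the
    classes is the spatial arrangement of the hypointensity, not its total
    amount — reading only the overall signal level cannot separate them, the
    topographic pattern can. Pallidal involvement stays class-specific and
    un-normalized (features are extracted from the putamen).
    """
    put = labels == 1
    pall = labels == 2
    depth = spec.depth * severity
    iron = np.zeros(labels.shape, dtype=np.float64)
    if depth == 0.0:
        return iron
    g = float(np.clip(rng.normal(spec.gradient, spec.gradient_jitter), 0.0, 1.0))
    slit_width = max(float(rng.normal(spec.slit_width, spec.slit_width_jitter)), 0.5)
    shape = np.zeros(labels.shape, dtype=np.float64)
    if spec.class_name == "MSA-P":
        w = fields["lateralness"] * ((1.0 - g) + g * fields["posteriorness"])
        shape[put] = w[put]
        iron[pall] = 0.5 * depth * fields["pall_lateral"][pall]
    elif spec.class_name == "PSP":
        # focal anteromedial maximum on a moderate whole-pallidum pedestal
        w = 0.3 + 0.7 * fields["pall_anteromedial"][pall]
        iron[pall] = depth * w
        shape[put] = 1.0  # mild diffuse putaminal involvement
    elif spec.class_name == "PD":
        slit = put & (fields["lateralness"] >= 1.0 - slit_width / _PUT_SEMI[0])
        shape[slit] = 0.8
        shape[put & ~slit] = 0.1
    elif spec.class_name == "MSA-C":
        shape[put] = 1.0
        iron[pall] = 0.1 * depth
    mean_shape = shape[put].mean()
    if mean_shape > 0:
        iron[put] = shape[put] * (spec.mean_drop_fraction * depth / mean_shape)
    return iron


def _render(spec: PhantomSpec, labels, iron, rng) -> tuple[np.ndarray, np.ndarray]:
    t1w = np.zeros(labels.shape, dtype=np.float64)
    swi = np.zeros_like(t1w)
    for lab, (t_val, s_val) in {
        3: (spec.t1w_wm, spec.swi_wm),
        1: (spec.t1w_putamen, spec.swi_putamen),
        2: (spec.t1w_pallidum, spec.swi_pallidum),
    }.items():
        t1w[labels == lab] = t_val
        swi[labels == lab] = s_val
    swi = swi - iron
    t1w = t1w - spec.t1w_iron_sensitivity * iron
    if spec.smoothing_sigma > 0:
        t1w = ndimage.gaussian_filter(t1w, spec.smoothing_sigma)
        swi = ndimage.gaussian_filter(swi, spec.smoothing_sigma)
    # scanner-like nuisance on the SWI channel: per-subject receive gain and
    # offset plus a smooth intensity-inhomogeneity field
    gain = float(np.exp(rng.normal(0.0, spec.swi_gain_sigma)))
    offset = float(rng.normal(0.0, spec.swi_offset_sd))
    swi = gain * swi + offset
    if spec.bias_amplitude > 0:
        field = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=swi.shape), spec.bias_scale
        )
        sd = field.std()
        if sd > 0:
            swi = swi + spec.bias_amplitude * (field / sd)
    if spec.noise_sd > 0:
        t1w = t1w + rng.normal(0.0, spec.noise_sd, size=t1w.shape)
        swi = swi + rng.normal(0.0, spec.noise_sd, size=swi.shape)
    return t1w, swi


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Render one phantom subject (deterministic in seed + spec)."""
    rng = np.random.default_rng(spec.seed)
    xyz = _jittered_frame(spec, rng)
    labels, fields = _build_anatomy(xyz)
    if not (labels == 1).any() or not (labels == 2).any():
        raise ValueError("nuclei fall outside the grid; enlarge grid_size")
    severity = float(np.exp(rng.normal(0.0, spec.severity_sigma)))
    iron = _iron_field(spec, labels, fields, severity, rng)
    t1w_data, swi_data = _render(spec, labels, iron, rng)

    affine = _affine(spec)
    t1w = Volume(t1w_data, affine, "T1w")
    swi = Volume(swi_data, affine, "SWI")
    truth = LabelMask(labels, t1w, LEGEND)
    return PhantomSubject(t1w, swi, truth, spec.class_name, spec)


def generate_template(spec: PhantomSpec | None = None) -> tuple[Volume, LabelMask]:
    """The reference anatomy: noise-free, jitter-free, iron-free, with
    MNI-like T1w contrast (strong deep-gray delineation)."""
    spec = replace(
        spec or PhantomSpec(),
        class_name="PD",
        depth=0.0,
        noise_sd=0.0,
        jitter_translation_sd=0.0,
        jitter_scale_sd=0.0,
        jitter_rotation_sd=0.0,
        t1w_wm=110.0,
        t1w_putamen=70.0,
        t1w_pallidum=50.0,
        seed=0,
    )
    subject = generate_subject(spec)
    template = subject.t1w.with_data(subject.t1w.data, modality="template")
    return template, LabelMask(subject.truth.labels, template, LEGEND)


def generate_cohort(
    class_counts: dict[str, int] | None = None,
    spec_template: PhantomSpec | None = None,
    master_seed: int = 0,
) -> list[PhantomSubject]:
    """Independent seeded subjects for each class.

    Per-subject seeds derive deterministically from ``master_seed``; each
    subject carries its own geometric jitter and severity draw.
    """
    class_counts = class_counts or DEFAULT_CLASS_COUNTS
    spec_template = spec_template or PhantomSpec()
    subjects = []
    i = 0
    for class_name in CLASSES:
        n = int(class_counts.get(class_name, 0))
        if n < 0:
            raise ValueError("class counts must be >= 0")
        for _ in range(n):
            seed = (master_seed * 1_000_003 + i) % (2**31 - 1)
            spec = replace(spec_template, class_name=class_name, seed=seed)
            subjects.append(generate_subject(spec))
            i += 1
    return subjects
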