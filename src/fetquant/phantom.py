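"""Synthetic FET-PET phantom cohorts with attenuation-correction bias.

Emulates the study material of a brain-tumor PET/MR quantification study:
an ellipsoidal brain with uniform background uptake, one or more tumor foci
at 2-5x background (optionally with a photopenic resection cavity),
extratumoral high-uptake structures in the scalp (skin/vascular), and a
contralateral curved-slab ("banana") background ROI. Attenuation-correction
error is modelled post hoc as a multiplicative bias field composed of

* a global under/over-estimation (the dominant, method-specific error),
* a radial gradient from the brain surface toward the center (bone
  misclassification biases activity most near the skull),
* focal Gaussian nodules (local over/under-estimated tissue classes), and
* spherical signal-void depressions (metal-implant artifacts),

applied to the noiseless ground truth together with i.i.d. relative
Gaussian noise. Cohort generation draws subject-specific bias parameters
from per-method truncated-normal profiles whose defaults reproduce the
reported global T_MEAN error triplets of the three MR-based methods
(RESOLUTE -1.9 +/- 1.9% max -7.6; Dixon -14.9 +/- 5.2% max -29.3;
UTE -7.2 +/- 3.1% max -16.9) against a CT-based reference.

Each tumor focus has a uniform core and a finite linear penumbra calibrated
so that, on the noiseless truth, the 1.6 x background isocontour falls
exactly at the stated focus radius. The ground-truth mask therefore equals
the analytic sphere while the contour remains sensitive to spatially
varying bias — the phenomenon the cohort exists to propagate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

__all__ = [
    "PhantomError",
    "TumorFocus",
    "Cavity",
    "ExtratumoralSource",
    "PhantomSpec",
    "Nodule",
    "Void",
    "BiasFieldModel",
    "PhantomScene",
    "MethodProfile",
    "StudyRecord",
    "DEFAULT_METHOD_PROFILES",
    "generate_phantom",
    "make_bias_field",
    "apply_bias",
    "make_followup",
    "generate_cohort",
    "sample_bias_model",
    "sample_scale_errors",
]

logger = logging.getLogger(__name__)

#: Tumor tissue is defined above this multiple of the background mean.
TRUTH_THRESHOLD_RATIO = 1.6

#: Brain ellipsoid semi-axes as fractions of the grid extent per axis.
BRAIN_SEMI_AXIS_FRACTIONS = (0.36, 0.40, 0.33)

FWHM_TO_SIGMA = 0.42466090014400953


class PhantomError(ValueError):
    """A phantom specification cannot be realised."""


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TumorFocus:
    """A spherical tumor focus.

    ``radius_mm`` is the radius of the 1.6 x background isocontour of the
    noiseless truth; ``contrast`` the uniform-core multiplier vs background;
    ``penumbra_mm`` the width of the linear falloff straddling the contour.
    """

    center_vox: tuple[int, int, int]
    radius_mm: float
    contrast: float
    penumbra_mm: float = 6.0
    #: fractional extra uptake at the focus centre relative to the core
    #: plateau; gives the tumor a unique, noise-robust peak ("hot spot").
    core_peaking: float = 0.08


@dataclass(frozen=True)
class Cavity:
    """A photopenic resection cavity (uptake below background)."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    uptake_fraction: float = 0.3


@dataclass(frozen=True)
class ExtratumoralSource:
    """A high-uptake structure outside the brain (skin, vessel)."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    contrast: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_uptake: float = 1.0
    tumor_foci: tuple[TumorFocus, ...] | None = None  # None -> auto-placed focus
    cavity: Cavity | None = None
    extratumoral_sources: tuple[ExtratumoralSource, ...] | None = None
    noise_sd: float = 0.02
    seed: int = 0
    roi_volume_ml: float = 15.0
    roi_min_distance_mm: float = 15.0


@dataclass(frozen=True)
class Nodule:
    center_vox: tuple[int, int, int]
    fwhm_mm: float
    amplitude: float


@dataclass(frozen=True)
class Void:
    center_vox: tuple[int, int, int]
    radius_mm: float
    amplitude: float


@dataclass(frozen=True)
class BiasFieldModel:
    """Multiplicative attenuation-correction error model.

    With all parameters at identity (scale 1, zero gradient, no nodules or
    voids) the resulting field is exactly 1 everywhere.
    """

    global_scale: float = 1.0
    gradient_surface: float = 0.0
    gradient_center: float = 0.0
    nodules: tuple[Nodule, ...] = ()
    voids: tuple[Void, ...] = ()
    seed: int = 0


@dataclass
class PhantomScene:
    """A generated study: ground truth plus per-method biased images."""

    truth_activity: VolumeImage
    brain_mask: np.ndarray
    skull_mask: np.ndarray
    tumor_truth_mask: np.ndarray
    exclusion_mask: np.ndarray
    background_roi_mask: np.ndarray
    spec: PhantomSpec
    biased_images: dict[str, VolumeImage] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _grid_mm(shape, spacing):
    """Per-axis voxel-centre coordinates in mm (origin at voxel 0)."""
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _radius_mm_from(center_vox, shape, spacing):
    ax = _grid_mm(shape, spacing)
    c = [center_vox[i] * spacing[i] for i in range(3)]
    dx = (ax[0] - c[0]) ** 2
    dy = (ax[1] - c[1]) ** 2
    dz = (ax[2] - c[2]) ** 2
    return np.sqrt(dx[:, None, None] + dy[None, :, None] + dz[None, None, :])


def _brain_geometry(shape, spacing):
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    semi = [f * e for f, e in zip(BRAIN_SEMI_AXIS_FRACTIONS, extent)]
    ax = _grid_mm(shape, spacing)
    u0 = ((ax[0] - center[0]) / semi[0]) ** 2
    u1 = ((ax[1] - center[1]) / semi[1]) ** 2
    u2 = ((ax[2] - center[2]) / semi[2]) ** 2
    rho2 = u0[:, None, None] + u1[None, :, None] + u2[None, None, :]
    rho = np.sqrt(rho2)
    brain = rho <= 1.0
    skull = (rho > 1.03) & (rho <= 1.10)
    return brain, skull, center, semi, rho


def _focus_profile(focus: TumorFocus, r_mm: np.ndarray) -> np.ndarray:
    """Radial weight g(r) in [0, 1]: 1 in the core, linear penumbra, 0 outside.

    For contrast > 1.6 the ramp is positioned so that the noiseless truth
    crosses 1.6 x background exactly at ``radius_mm``:
    value = B * (1 + (contrast - 1) * g(r)) = 1.6 B  at  r = radius_mm.
    """
    w = focus.penumbra_mm
    if focus.contrast > TRUTH_THRESHOLD_RATIO:
        t_star = (TRUTH_THRESHOLD_RATIO - 1.0) / (focus.contrast - 1.0)
    else:
        t_star = 0.5  # ramp centred on the radius; never crosses threshold
    r_a = focus.radius_mm - w * (1.0 - t_star)
    g = np.clip((r_a + w - r_mm) / w, 0.0, 1.0)
    if focus.core_peaking > 0 and r_a > 0:
        core = r_mm < r_a
        g = np.where(core, 1.0 + focus.core_peaking * (1.0 - r_mm / r_a), g)
    return g


def _default_focus(shape, spacing) -> TumorFocus:
    _, _, center, semi, _ = _brain_geometry(shape, spacing)
    center_vox = tuple(
        int(round((center[i] + off * semi[i]) / spacing[i]))
        for i, off in enumerate((0.45, 0.25, 0.10))
    )
    return TumorFocus(center_vox=center_vox, radius_mm=12.0, contrast=3.0)


def _default_sources(shape, spacing) -> tuple[ExtratumoralSource, ...]:
    _, _, center, semi, _ = _brain_geometry(shape, spacing)
    # one skin/vascular hot spot on the scalp, anterior-superior
    center_vox = tuple(
        int(round((center[i] + off * semi[i]) / spacing[i]))
        for i, off in enumerate((0.0, 0.95, 0.45))
    )
    return (ExtratumoralSource(center_vox=center_vox, radius_mm=6.0, contrast=3.0),)


def _validate_spec(spec: PhantomSpec, foci: Sequence[TumorFocus]) -> None:
    if any(s <= 0 for s in spec.spacing):
        raise PhantomError(f"spacing must be positive, got {spec.spacing}")
    if spec.background_uptake <= 0:
        raise PhantomError("background uptake must be positive")
    if spec.noise_sd < 0:
        raise PhantomError("noise SD must be non-negative")
    if not foci:
        raise PhantomError("at least one tumor focus is required (no BTV possible)")
    max_sp = max(spec.spacing)
    for f in foci:
        if f.contrast <= 0:
            raise PhantomError("tumor contrast must be positive")
        if f.radius_mm <= max_sp:
            raise PhantomError(
                f"focus radius {f.radius_mm} mm must exceed one voxel ({max_sp} mm)"
            )
    delineable = [
        f
        for f in foci
        if f.contrast > TRUTH_THRESHOLD_RATIO
        and (4.0 / 3.0) * math.pi * f.radius_mm**3 >= 1000.0
    ]
    if not delineable:
        raise PhantomError(
            "no focus with contrast > 1.6 and volume >= 1 mL: no BTV above the "
            "inclusion limit is possible"
        )
    if spec.cavity is not None and not (0 <= spec.cavity.uptake_fraction < 1):
        raise PhantomError("cavity uptake fraction must be in [0, 1)")
    for s in spec.extratumoral_sources or ():
        if s.contrast <= 0:
            raise PhantomError("extratumoral contrast must be positive")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomScene:
    """Build the noiseless ground-truth scene for one subject.

    Deterministic: the same spec (including seed) yields a bit-identical
    scene. The background ROI is auto-placed as a curved slab in the
    hemisphere contralateral to the first focus, above the mid-axial plane
    and at least ``roi_min_distance_mm`` from every focus surface.
    """
    shape, spacing = spec.grid_shape, spec.spacing
    foci = spec.tumor_foci if spec.tumor_foci is not None else (
        _default_focus(shape, spacing),
    )
    sources = (
        spec.extratumoral_sources
        if spec.extratumoral_sources is not None
        else _default_sources(shape, spacing)
    )
    _validate_spec(spec, foci)

    brain, skull, center, semi, _ = _brain_geometry(shape, spacing)
    bg = spec.background_uptake

    activity = np.zeros(shape, dtype=np.float64)
    activity[brain] = bg

    bump = np.zeros(shape, dtype=np.float64)
    focus_region = np.zeros(shape, dtype=bool)
    for f in foci:
        r = _radius_mm_from(f.center_vox, shape, spacing)
        g = _focus_profile(f, r)
        bump += (f.contrast - 1.0) * g
        focus_region |= g > 0
    activity[brain] += bg * bump[brain]

    cavity_mask = np.zeros(shape, dtype=bool)
    if spec.cavity is not None:
        r = _radius_mm_from(spec.cavity.center_vox, shape, spacing)
        cavity_mask = (r < spec.cavity.radius_mm) & brain
        activity[cavity_mask] = bg * spec.cavity.uptake_fraction

    source_region = np.zeros(shape, dtype=bool)
    for s in sources:
        r = _radius_mm_from(s.center_vox, shape, spacing)
        sphere = (r < s.radius_mm) & ~brain
        activity[sphere] = bg * s.contrast
        source_region |= r < (s.radius_mm + 4.0)
    exclusion = source_region & ~brain

    tumor_truth = (
        brain & focus_region & (activity > TRUTH_THRESHOLD_RATIO * bg) & ~cavity_mask
    )

    roi = _place_background_roi(spec, foci, brain, center, spacing, tumor_truth)

    truth = VolumeImage(activity, spacing)
    return PhantomScene(
        truth_activity=truth,
        brain_mask=brain,
        skull_mask=skull,
        tumor_truth_mask=tumor_truth,
        exclusion_mask=exclusion,
        background_roi_mask=roi,
        spec=replace(spec, tumor_foci=tuple(foci), extratumoral_sources=tuple(sources)),
    )


def _place_background_roi(spec, foci, brain, center, spacing, tumor_truth):
    shape = brain.shape
    depth = ndimage.distance_transform_edt(brain, sampling=spacing)
    band = brain & (depth >= 3.0) & (depth <= 10.0)

    ax = _grid_mm(shape, spacing)
    first = foci[0]
    focus_x_mm = first.center_vox[0] * spacing[0]
    side = 1.0 if focus_x_mm >= center[0] else -1.0
    # contralateral: opposite side of the mid-sagittal plane, 5 mm margin
    contralateral = ((ax[0] - center[0]) * side < -5.0)[:, None, None]
    upper = (ax[2] > center[2])[None, None, :]
    eligible = band & contralateral & upper & ~tumor_truth

    for f in foci:
        r = _radius_mm_from(f.center_vox, shape, spacing)
        eligible &= r >= (f.radius_mm + spec.roi_min_distance_mm)

    vox_ml = float(np.prod(spacing)) / 1000.0
    n_target = int(math.ceil(spec.roi_volume_ml / vox_ml))
    idx = np.argwhere(eligible)
    if idx.shape[0] * vox_ml < min(5.0, spec.roi_volume_ml):
        raise PhantomError(
            "background ROI cannot be placed: the contralateral hemisphere "
            "offers too little eligible tissue at the requested distance from "
            "the tumor"
        )
    # localise a banana-shaped patch: keep the eligible voxels whose
    # direction from the brain centre is closest to a seed direction
    # opposite the tumor and tilted upward
    seed_dir = np.array([-side * 0.8, 0.0, 0.6])
    seed_dir /= np.linalg.norm(seed_dir)
    pos = idx * np.asarray(spacing) - np.asarray(center)
    pos_norm = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    score = pos_norm @ seed_dir
    order = np.argsort(-score, kind="stable")
    chosen = idx[order[: min(n_target, idx.shape[0])]]
    roi = np.zeros(shape, dtype=bool)
    roi[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return roi


def make_bias_field(
    model: BiasFieldModel,
    brain_mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> VolumeImage:
    """Realise a bias model on a grid.

    Inside the brain:
        field = global_scale * (1 + g(depth)) * prod(nodules) * prod(voids)
    where depth is the distance to the brain edge normalised to [0, 1] and
    g interpolates linearly from ``gradient_surface`` (depth 0) to
    ``gradient_center`` (depth 1). Outside the brain the field equals
    ``global_scale``. Nodules are Gaussian bumps 1 + A exp(-r^2 / 2 sigma^2);
    voids multiply by 1 + amplitude inside their sphere.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise PhantomError("brain mask is empty")
    spacing = tuple(float(s) for s in spacing)
    shape = brain.shape

    field_arr = np.full(shape, model.global_scale, dtype=np.float64)

    d = ndimage.distance_transform_edt(brain, sampling=spacing)
    d_in = d[brain]
    d_min, d_max = float(d_in.min()), float(d_in.max())
    if d_max > d_min:
        depth = (d - d_min) / (d_max - d_min)
    else:
        depth = np.zeros_like(d)
    g = model.gradient_surface + (model.gradient_center - model.gradient_surface) * depth

    inside = np.ones(shape, dtype=np.float64)
    inside *= 1.0 + g
    for nod in model.nodules:
        r = _radius_mm_from(nod.center_vox, shape, spacing)
        sigma = nod.fwhm_mm * FWHM_TO_SIGMA
        inside *= 1.0 + nod.amplitude * np.exp(-(r**2) / (2.0 * sigma**2))
    for void in model.voids:
        r = _radius_mm_from(void.center_vox, shape, spacing)
        inside *= np.where(r < void.radius_mm, 1.0 + void.amplitude, 1.0)

    field_arr[brain] = model.global_scale * inside[brain]
    if field_arr.min() <= 0:
        raise PhantomError(
            f"bias field is not strictly positive (min {field_arr.min():.4g})"
        )
    return VolumeImage(field_arr, spacing)


def apply_bias(
    truth: VolumeImage,
    field: VolumeImage,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VolumeImage:
    """Biased emission image: truth * field * (1 + eps), eps ~ N(0, noise_sd).

    ``noise_sd = 0`` gives the exact product. Negative outputs (possible in
    the Gaussian noise tails) are clipped to zero with a logged count.
    """
    truth.require_same_grid(field, "bias field")
    out = truth.values * field.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out * (1.0 + rng.normal(0.0, noise_sd, size=out.shape))
    n_neg = int((out < 0).sum())
    if n_neg:
        logger.warning("apply_bias: clipped %d negative voxels to 0", n_neg)
        out = np.clip(out, 0.0, None)
    return truth.copy_with(out)


def make_followup(
    scene: PhantomScene,
    btv_change_pct: float,
    tbr_change_pct: float,
    seed: int | None = None,
) -> PhantomScene:
    """Second-timepoint scene with prescribed ground-truth changes.

    The tumor radius is rescaled by (1 + btv_change_pct/100)^(1/3) and the
    contrast by (1 + tbr_change_pct/100), so the noiseless BTV and T_MAX/B
    change by the requested percentages up to voxelization; everything else
    is held fixed. Shrinkage below the 1 mL inclusion floor is rejected.
    """
    spec = scene.spec
    if spec.tumor_foci is None or not spec.tumor_foci:
        raise PhantomError("scene has no tumor foci")
    vol_factor = 1.0 + btv_change_pct / 100.0
    tbr_factor = 1.0 + tbr_change_pct / 100.0
    if vol_factor <= 0 or tbr_factor <= 0:
        raise PhantomError("requested change implies a non-positive metric")
    radius_factor = vol_factor ** (1.0 / 3.0)

    new_foci = tuple(
        replace(f, radius_mm=f.radius_mm * radius_factor, contrast=f.contrast * tbr_factor)
        for f in spec.tumor_foci
    )
    total_ml = sum(
        (4.0 / 3.0) * math.pi * f.radius_mm**3 / 1000.0
        for f in new_foci
        if f.contrast > TRUTH_THRESHOLD_RATIO
    )
    if total_ml < 1.0:
        raise PhantomError(
            f"follow-up tumor volume {total_ml:.2f} mL is below the 1 mL "
            "inclusion floor"
        )
    new_spec = replace(
        spec, tumor_foci=new_foci, seed=spec.seed if seed is None else seed
    )
    return generate_phantom(new_spec)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethodProfile:
    """Distribution of bias parameters for one attenuation-correction method.

    The global scale error is drawn from a normal truncated at
    ``|error| <= scale_err_max`` (the reported maximum); gradient endpoints
    are normal; a fraction ``nodule_prob`` of subjects receive focal
    nodules, ``void_prob`` a metal-void artifact.
    """

    scale_err_mean: float
    scale_err_sd: float
    scale_err_max: float
    gradient_surface_mean: float = 0.0
    gradient_surface_sd: float = 0.0
    gradient_center_mean: float = 0.0
    gradient_center_sd: float = 0.0
    nodule_prob: float = 0.0
    nodule_amplitude_mean: float = 0.1
    nodule_amplitude_sd: float = 0.03
    nodule_fwhm_mm: float = 25.0
    void_prob: float = 0.0
    void_amplitude: float = -0.35
    void_radius_mm: float = 8.0


#: Defaults parameterised from the reported per-method global T_MEAN error
#: triplets (mean +/- SD, truncated at the reported maximum) with spatial
#: components at magnitudes consistent with the reported gradient and warp
#: phenomenology.
DEFAULT_METHOD_PROFILES: Mapping[str, MethodProfile] = {
    "DIXON": MethodProfile(
        scale_err_mean=-0.149,
        scale_err_sd=0.052,
        scale_err_max=0.293,
        gradient_surface_mean=-0.03,
        gradient_surface_sd=0.055,
        gradient_center_mean=-0.01,
        gradient_center_sd=0.020,
        nodule_prob=0.37,
        nodule_amplitude_mean=0.15,
        nodule_amplitude_sd=0.05,
        nodule_fwhm_mm=30.0,
        void_prob=0.04,
    ),
    "UTE": MethodProfile(
        scale_err_mean=-0.072,
        scale_err_sd=0.031,
        scale_err_max=0.169,
        gradient_surface_mean=-0.015,
        gradient_surface_sd=0.028,
        gradient_center_mean=-0.005,
        gradient_center_sd=0.010,
        nodule_prob=0.11,
        nodule_amplitude_mean=0.08,
        nodule_amplitude_sd=0.025,
        nodule_fwhm_mm=25.0,
    ),
    "RESOLUTE": MethodProfile(
        scale_err_mean=-0.019,
        scale_err_sd=0.019,
        scale_err_max=0.076,
        gradient_surface_sd=0.005,
        gradient_center_sd=0.003,
    ),
}


def sample_scale_errors(
    profile: MethodProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n global scale errors from the profile's truncated normal."""
    out = np.empty(n)
    for i in range(n):
        while True:
            e = rng.normal(profile.scale_err_mean, profile.scale_err_sd)
            if abs(e) <= profile.scale_err_max:
                out[i] = e
                break
    return out


def sample_bias_model(
    profile: MethodProfile,
    rng: np.random.Generator,
    brain_mask: np.ndarray,
    spacing: tuple[float, float, float],
    seed: int = 0,
) -> BiasFieldModel:
    """Draw one subject's bias model from a method profile."""
    scale_err = float(sample_scale_errors(profile, 1, rng)[0])
    gs = float(rng.normal(profile.gradient_surface_mean, profile.gradient_surface_sd)) \
        if profile.gradient_surface_sd > 0 else profile.gradient_surface_mean
    gc = float(rng.normal(profile.gradient_center_mean, profile.gradient_center_sd)) \
        if profile.gradient_center_sd > 0 else profile.gradient_center_mean

    brain = np.asarray(brain_mask, dtype=bool)
    d = ndimage.distance_transform_edt(brain, sampling=spacing)
    d_max = float(d.max()) if d.max() > 0 else 1.0
    shallow = np.argwhere(brain & (d <= 0.6 * d_max))

    nodules: list[Nodule] = []
    if profile.nodule_prob > 0 and rng.random() < profile.nodule_prob:
        n_nod = int(rng.integers(1, 3))
        for _ in range(n_nod):
            center = tuple(int(v) for v in shallow[rng.integers(shallow.shape[0])])
            amp = float(rng.normal(profile.nodule_amplitude_mean,
                                   profile.nodule_amplitude_sd))
            nodules.append(Nodule(center, profile.nodule_fwhm_mm, amp))
    voids: list[Void] = []
    if profile.void_prob > 0 and rng.random() < profile.void_prob:
        center = tuple(int(v) for v in shallow[rng.integers(shallow.shape[0])])
        voids.append(Void(center, profile.void_radius_mm, profile.void_amplitude))

    return BiasFieldModel(
        global_scale=1.0 + scale_err,
        gradient_surface=gs,
        gradient_center=gc,
        nodules=tuple(nodules),
        voids=tuple(voids),
        seed=seed,
    )


@dataclass
class StudyRecord:
    """One examination of one subject under every AC method."""

    subject_id: str
    study_id: str
    timepoint: str  # "baseline" | "followup"
    scene: PhantomScene
    bias_models: dict[str, BiasFieldModel]

    @property
    def injected(self) -> dict[str, dict]:
        """Serializable record of the injected bias parameters per method."""
        out = {}
        for label, model in self.bias_models.items():
            out[label] = {
                "global_scale": model.global_scale,
                "scale_err_pct": 100.0 * (model.global_scale - 1.0),
                "gradient_surface": model.gradient_surface,
                "gradient_center": model.gradient_center,
                "n_nodules": len(model.nodules),
                "n_voids": len(model.voids),
            }
        return out


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def generate_cohort(
    n_subjects: int,
    method_profiles: Mapping[str, MethodProfile] | None = None,
    followup_fraction: float = 0.0,
    seed: int = 0,
    *,
    reference_label: str = "CTAC",
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    noise_sd: float = 0.02,
) -> list[StudyRecord]:
    """Generate a reproducible study cohort.

    Per subject: a randomised tumor (side, position, radius 9-16 mm,
    contrast 2.2-4.0), a reference image (identity bias) and one biased
    image per method with subject-specific parameters drawn from the
    profiles. ``round(followup_fraction * n_subjects)`` subjects (the first
    ones, deterministically) receive a follow-up examination with a
    randomised true change in BTV and T_MAX/B and freshly drawn bias
    parameters (the attenuation map is re-acquired at follow-up).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    profiles = dict(method_profiles or DEFAULT_METHOD_PROFILES)
    if reference_label in profiles:
        raise ValueError(f"reference label {reference_label!r} collides with a profile")

    master = np.random.SeedSequence(seed)
    subject_seqs = master.spawn(n_subjects)
    n_followup = _round_half_away(followup_fraction * n_subjects)

    records: list[StudyRecord] = []
    for i, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        subject_id = f"S{i + 1:03d}"

        side = 1.0 if rng.random() < 0.5 else -1.0
        off = (
            side * rng.uniform(0.30, 0.55),
            rng.uniform(-0.35, 0.35),
            rng.uniform(-0.20, 0.25),
        )
        _, _, center, semi, _ = _brain_geometry(grid_shape, spacing)
        center_vox = tuple(
            int(round((center[j] + off[j] * semi[j]) / spacing[j])) for j in range(3)
        )
        focus = TumorFocus(
            center_vox=center_vox,
            radius_mm=float(rng.uniform(9.0, 16.0)),
            contrast=float(rng.uniform(2.2, 4.0)),
        )
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            tumor_foci=(focus,),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = generate_phantom(spec)
        records.append(
            _realise_study(scene, profiles, rng, subject_id, f"{subject_id}-T0",
                           "baseline", reference_label, noise_sd)
        )

        if i < n_followup:
            btv_change = float(np.clip(rng.normal(0.0, 20.0), -45.0, 60.0))
            tbr_change = float(np.clip(rng.normal(0.0, 8.0), -25.0, 25.0))
            while True:
                try:
                    fu_scene = make_followup(
                        scene, btv_change, tbr_change,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    break
                except PhantomError:
                    btv_change /= 2.0  # shrink the change until realisable
                    tbr_change /= 2.0
            records.append(
                _realise_study(fu_scene, profiles, rng, subject_id,
                               f"{subject_id}-T1", "followup", reference_label,
                               noise_sd)
            )
    return records


def _realise_study(
    scene: PhantomScene,
    profiles: Mapping[str, MethodProfile],
    rng: np.random.Generator,
    subject_id: str,
    study_id: str,
    timepoint: str,
    reference_label: str,
    noise_sd: float,
) -> StudyRecord:
    spacing = scene.truth_activity.spacing
    identity = BiasFieldModel()
    models: dict[str, BiasFieldModel] = {reference_label: identity}
    ones = scene.truth_activity.copy_with(np.ones(scene.truth_activity.shape))
    scene.biased_images[reference_label] = apply_bias(
        scene.truth_activity, ones, noise_sd, seed=int(rng.integers(0, 2**31 - 1))
    )
    for label in sorted(profiles):
        model = sample_bias_model(
            profiles[label], rng, scene.brain_mask, spacing,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        field_img = make_bias_field(model, scene.brain_mask, spacing)
        scene.biased_images[label] = apply_bias(
            scene.truth_activity, field_img, noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        models[label] = model
    return StudyRecord(
        subject_id=subject_id,
        study_id=study_id,
        timepoint=timepoint,
        scene=scene,
        bias_models=models,
    )
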