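"""Synthetic PET phantoms and simulated observer delineations.

Patient imaging of the kind this pipeline analyses cannot be redistributed,
so every stage is exercised on synthetic data with known ground truth:

* ``make_phantom`` builds an ellipsoidal high-uptake lesion on a low
  physiological background, blurs it with an isotropic Gaussian standing in
  for the scanner point-spread function, and adds Gaussian image-domain
  noise. An optional nearby spherical "decoy" hot spot emulates the
  pituitary gland, whose strong physiological SSTR-tracer uptake is the
  classical confounder for threshold segmentation.
* ``simulate_observers`` draws observer contours around a known truth under
  two error models: ``iid_flip`` (voxel-wise independent errors with planted
  sensitivity/specificity — exactly the generative model STAPLE assumes, so
  parameter recovery is well-posed) and ``boundary_field`` (the truth
  surface displaced by a per-observer constant bias plus a smooth random
  field — contiguous over/under-contoured regions like real raters produce).
* ``make_study`` assembles a full multi-lesion two-condition study bundle,
  with the second condition ("MRI_PET") generated under tighter observer
  errors than the first ("MRI"), emulating the variability reduction that
  functional imaging brings to manual contouring.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, ImageGrid, SUVVolume
from .staple import ObserverDelineationSet

__all__ = [
    "DEFAULT_GRID",
    "LesionPhantomSpec",
    "ObserverErrorModel",
    "make_phantom",
    "simulate_observers",
    "make_study",
    "make_isocontour_phantom",
    "make_leakage_phantom",
    "StudyLesion",
    "StudyBundle",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: default phantom grid: PET-like voxel size, small enough to iterate fast
DEFAULT_GRID = ImageGrid(shape=(64, 64, 32), spacing=(4.0, 4.0, 5.0))


@dataclass
class LesionPhantomSpec:
    """Parameters of one synthetic lesion phantom.

    Uptake values are in SUV; geometry in mm (world coordinates).
    """

    grid: ImageGrid = DEFAULT_GRID
    lesion_center: tuple = (128.0, 128.0, 80.0)
    semi_axes: tuple = (16.0, 14.0, 12.0)
    lesion_uptake: float = 8.0
    background_uptake: float = 0.3
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.1
    decoy_hotspot: tuple | None = None  # (center_mm, radius_mm, uptake)
    allow_decoy_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.lesion_uptake > self.background_uptake >= 0:
            raise ValueError("need lesion_uptake > background_uptake >= 0")
        if min(self.semi_axes) < min(self.grid.spacing):
            raise ValueError("lesion semi-axes must be at least one voxel spacing")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be >= 0")


def _ellipsoid_mask(grid: ImageGrid, center_mm, semi_axes_mm) -> np.ndarray:
    centers = grid.voxel_centers_mm()
    rel = (centers - np.asarray(center_mm, dtype=float)) / np.asarray(
        semi_axes_mm, dtype=float
    )
    return (rel**2).sum(axis=-1) <= 1.0


def make_phantom(spec: LesionPhantomSpec):
    """Build ``(truth, pet)`` for one lesion phantom.

    Truth contains the voxels whose centers lie inside the ellipsoid. The
    PET image is the piecewise-constant uptake map (background, lesion,
    optional decoy) convolved with an isotropic Gaussian of FWHM
    ``psf_fwhm_mm``, plus iid Gaussian noise of sd ``noise_sd``, clipped at
    zero. Deterministic given ``spec.seed``.
    """
    grid = spec.grid
    truth = _ellipsoid_mask(grid, spec.lesion_center, spec.semi_axes)
    if not truth.any():
        raise ValueError("lesion lies outside the grid (empty truth mask)")
    lo = grid.world_to_index(np.asarray(spec.lesion_center) - np.asarray(spec.semi_axes))
    hi = grid.world_to_index(np.asarray(spec.lesion_center) + np.asarray(spec.semi_axes))
    if np.any(np.minimum(lo, hi) < -0.5) or np.any(
        np.maximum(lo, hi) > np.asarray(grid.shape) - 0.5
    ):
        raise ValueError("lesion extends beyond the grid")

    img = np.full(grid.shape, spec.background_uptake, dtype=float)
    img[truth] = spec.lesion_uptake
    if spec.decoy_hotspot is not None:
        d_center, d_radius, d_uptake = spec.decoy_hotspot
        decoy = _ellipsoid_mask(grid, d_center, (d_radius,) * 3)
        if (decoy & truth).any() and not spec.allow_decoy_overlap:
            raise ValueError(
                "decoy hot spot overlaps the lesion; pass allow_decoy_overlap=True "
                "if intended"
            )
        img[decoy] = d_uptake

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / np.asarray(grid.spacing)
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return BinaryMask(grid, truth), SUVVolume(grid, img.astype(np.float32))


@dataclass
class ObserverErrorModel:
    """Generative error model for simulated raters.

    ``iid_flip``: each voxel decided independently — occupied with
    probability ``p_j`` (sensitivity) inside the truth, with probability
    ``1 - q_j`` (false positive) outside.

    ``boundary_field``: observer ``j`` contours the region where the signed
    Euclidean distance to the truth surface (positive outside, mm) is at
    most ``bias_mm[j] + ε_j(x)``, with ``ε_j`` a smooth zero-mean Gaussian
    field of sd ``boundary_sd_mm`` and correlation length
    ``correlation_length_mm`` (white noise filtered with a Gaussian kernel,
    so disagreement comes in contiguous patches, not salt-and-pepper).
    """

    mode: str = "boundary_field"
    sensitivity: tuple = ()  # p_j per observer (iid_flip)
    specificity: tuple = ()  # q_j per observer (iid_flip)
    boundary_sd_mm: float = 2.0
    bias_mm: tuple = ()  # per observer; scalar broadcast via float
    correlation_length_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("iid_flip", "boundary_field"):
            raise ValueError(f"unknown observer error mode {self.mode!r}")
        if self.mode == "iid_flip":
            for name, vals in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
                if not vals:
                    raise ValueError(f"iid_flip requires per-observer {name}")
                if not all(0.5 < v < 1 for v in vals):
                    raise ValueError(f"iid_flip {name} values must lie in (0.5, 1)")
        if self.boundary_sd_mm < 0:
            raise ValueError("boundary_sd_mm must be >= 0")


def _signed_distance_mm(truth: np.ndarray, spacing) -> np.ndarray:
    """Signed distance to the truth boundary: positive outside, negative inside."""
    d_out = ndimage.distance_transform_edt(~truth, sampling=spacing)
    d_in = ndimage.distance_transform_edt(truth, sampling=spacing)
    return d_out - d_in


def _smooth_field(shape, spacing, correlation_length_mm, sd, rng) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=shape)
    sigma_vox = correlation_length_mm * FWHM_TO_SIGMA / np.asarray(spacing)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def simulate_observers(
    truth: BinaryMask, model: ObserverErrorModel, n_observers: int,
    lesion_id: str = "lesion", modality: str = "MRI",
) -> ObserverDelineationSet:
    """Draw ``n_observers`` contours around ``truth`` under ``model``."""
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    if truth.is_empty():
        raise ValueError("cannot simulate observers of an empty truth mask")
    rng = np.random.default_rng(model.seed)
    entries = []
    if model.mode == "iid_flip":
        p = _per_observer(model.sensitivity, n_observers, "sensitivity")
        q = _per_observer(model.specificity, n_observers, "specificity")
        t = truth.values
        for j in range(n_observers):
            u = rng.random(t.shape)
            occ = np.where(t, u < p[j], u < 1 - q[j])
            entries.append((f"obs{j + 1}", BinaryMask(truth.grid, occ)))
    else:
        bias = _per_observer(model.bias_mm if model.bias_mm else (0.0,) * n_observers,
                             n_observers, "bias_mm")
        sdist = _signed_distance_mm(truth.values, truth.grid.spacing)
        for j in range(n_observers):
            eps = _smooth_field(
                truth.values.shape, truth.grid.spacing,
                model.correlation_length_mm, model.boundary_sd_mm, rng,
            )
            occ = sdist <= bias[j] + eps
            entries.append((f"obs{j + 1}", BinaryMask(truth.grid, occ)))
    return ObserverDelineationSet(entries=entries, lesion_id=lesion_id, modality=modality)


def _per_observer(values, n, name):
    vals = list(values)
    if len(vals) == 1:
        vals = vals * n
    if len(vals) != n:
        raise ValueError(f"{name}: expected 1 or {n} values, got {len(vals)}")
    return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# Full synthetic study


@dataclass
class StudyLesion:
    lesion_id: str
    truth: BinaryMask
    pet: SUVVolume
    delineations: dict  # modality -> ObserverDelineationSet
    planted: dict = field(default_factory=dict)


@dataclass
class StudyBundle:
    """A complete synthetic delineation study, consumable by the pipeline."""

    lesions: list
    manifest: dict

    @property
    def lesion_ids(self):
        return [l.lesion_id for l in self.lesions]


#: default per-condition observer error levels (mm). The PET-assisted
#: condition is tighter, emulating the IOV reduction functional imaging
#: brings; biases are drawn per observer around zero so raters come in
#: systematic over- and under-contourers.
DEFAULT_MRI_ERROR = {"boundary_sd_mm": 3.8, "bias_sd_mm": 1.8}
DEFAULT_PET_ERROR = {"boundary_sd_mm": 3.2, "bias_sd_mm": 1.5}


def make_study(
    n_lesions: int = 27,
    n_observers: int = 5,
    grid: ImageGrid = DEFAULT_GRID,
    semi_axes_range_mm: tuple = (8.0, 20.0),
    lesion_uptake_range: tuple = (5.0, 15.0),
    background_uptake: float = 0.3,
    psf_fwhm_mm: float = 7.0,
    noise_sd: float = 0.1,
    mri_error: dict | None = None,
    pet_error: dict | None = None,
    modalities: tuple = ("MRI", "MRI_PET"),
    seed: int = 0,
) -> StudyBundle:
    """Generate a multi-lesion, two-condition synthetic delineation study.

    Defaults mirror a realistic single-institution cohort: 27 lesions, five
    observers, PET-like 4x4x5 mm voxels, lesion volumes of a few to a few
    tens of cm^3, high lesion-to-background uptake contrast, and smoother
    (boundary_field) observer errors that are tighter in the PET-assisted
    condition than in the anatomical-imaging-only condition.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    mri_error = dict(DEFAULT_MRI_ERROR, **(mri_error or {}))
    pet_error = dict(DEFAULT_PET_ERROR, **(pet_error or {}))
    condition_errors = {"MRI": mri_error, "MRI_PET": pet_error}

    ss = np.random.SeedSequence(seed)
    master_rng = np.random.default_rng(ss)
    lesions = []
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    for i in range(n_lesions):
        child_seeds = [int(s) for s in ss.spawn(1)[0].generate_state(4) % (2**31)]
        semi_axes = master_rng.uniform(*semi_axes_range_mm, size=3)
        margin = semi_axes + 2 * psf_fwhm_mm
        center = np.array(
            [master_rng.uniform(m, e - m) for m, e in zip(margin, extent)]
        ) + np.asarray(grid.origin)
        uptake = float(master_rng.uniform(*lesion_uptake_range))
        spec = LesionPhantomSpec(
            grid=grid,
            lesion_center=tuple(center),
            semi_axes=tuple(semi_axes),
            lesion_uptake=uptake,
            background_uptake=background_uptake,
            psf_fwhm_mm=psf_fwhm_mm,
            noise_sd=noise_sd,
            seed=child_seeds[0],
        )
        truth, pet = make_phantom(spec)
        delineations = {}
        planted_models = {}
        for k, modality in enumerate(modalities):
            err = condition_errors[modality]
            bias = tuple(
                master_rng.normal(0.0, err["bias_sd_mm"], size=n_observers)
            )
            model = ObserverErrorModel(
                mode="boundary_field",
                boundary_sd_mm=err["boundary_sd_mm"],
                bias_mm=bias,
                seed=child_seeds[1 + k],
            )
            delineations[modality] = simulate_observers(
                truth, model, n_observers,
                lesion_id=f"lesion{i + 1:02d}", modality=modality,
            )
            planted_models[modality] = asdict(model)
        lesions.append(
            StudyLesion(
                lesion_id=f"lesion{i + 1:02d}",
                truth=truth,
                pet=pet,
                delineations=delineations,
                planted={
                    "phantom": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(spec).items()
                        if k != "grid"
                    },
                    "observer_models": planted_models,
                },
            )
        )
    manifest = {
        "seed": seed,
        "n_lesions": n_lesions,
        "n_observers": n_observers,
        "grid": {
            "shape": list(grid.shape),
            "spacing": list(grid.spacing),
            "origin": list(grid.origin),
        },
        "modalities": list(modalities),
        "condition_errors": condition_errors,
        "lesions": {l.lesion_id: l.planted for l in lesions},
    }
    return StudyBundle(lesions=lesions, manifest=manifest)


# ---------------------------------------------------------------------------
# Purpose-built phantoms for threshold studies


def make_isocontour_phantom(
    t_percent: float,
    seed: int = 0,
    grid: ImageGrid = DEFAULT_GRID,
    noise_sd: float = 0.0,
    t_step: float = 0.5,
):
    """Phantom whose reference mask IS a planted SUVmax-percentage isocontour.

    Builds a blurred ellipsoid lesion and takes the reference to be the
    connected suprathreshold region at ``t_percent`` % of SUVmax of the
    generated PET. Because voxel values are discrete, a whole interval of
    thresholds reproduces that exact region; the *planted* threshold is the
    canonical representative a smallest-threshold tie-break must recover:
    the smallest multiple of ``t_step`` whose absolute cutoff exceeds the
    hottest voxel 26-adjacent to (but outside) the reference region. It is
    computed directly from the voxel values, independently of any sweep.

    Returns ``(pet, roi, reference, t_planted)``.
    """
    from .threshold import lesion_suvmax, roi_from_masks, threshold_segment

    rng = np.random.default_rng(seed)
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    semi_axes = rng.uniform(12.0, 24.0, size=3)
    center = np.array(
        [rng.uniform(m, e - m) for m, e in zip(semi_axes + 16.0, extent)]
    ) + np.asarray(grid.origin)
    spec = LesionPhantomSpec(
        grid=grid,
        lesion_center=tuple(center),
        semi_axes=tuple(semi_axes),
        lesion_uptake=float(rng.uniform(5.0, 15.0)),
        background_uptake=0.2,
        psf_fwhm_mm=7.0,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    truth, pet = make_phantom(spec)
    roi = roi_from_masks([truth], lesion_id=f"iso{seed}", pad=4)
    reference = threshold_segment(pet, roi, t_percent, clip_to_roi=False)

    suvmax, _ = lesion_suvmax(pet, roi)
    ring = ndimage.binary_dilation(
        reference.values, structure=ndimage.generate_binary_structure(3, 3)
    ) & ~reference.values
    v_adjacent = float(pet.values[ring].max())
    # smallest grid threshold whose cutoff strictly exceeds the hottest
    # adjacent outside voxel — below it the region grows, so Dice drops
    k = 0
    while (k * t_step / 100.0) * suvmax <= v_adjacent:
        k += 1
    t_planted = k * t_step
    if t_planted > t_percent:
        raise AssertionError("planted threshold exceeded the requested one")
    return pet, roi, reference, t_planted


def make_leakage_phantom(grid: ImageGrid = DEFAULT_GRID, seed: int = 0):
    """Lesion plus a pituitary-like decoy hot spot bridged by blur.

    The decoy sits just outside the lesion ROI with comparable uptake; at
    low thresholds the blurred uptake between lesion and decoy stays
    suprathreshold, so unclipped component growth leaks into the decoy —
    the failure mode a region clip is meant to prevent. Returns
    ``(pet, roi, truth, decoy_region)``.
    """
    center = np.asarray(grid.origin) + 0.5 * np.asarray(grid.shape) * np.asarray(
        grid.spacing
    )
    decoy_center = center + np.array([34.0, 0.0, 0.0])
    spec = LesionPhantomSpec(
        grid=grid,
        lesion_center=tuple(center),
        semi_axes=(16.0, 14.0, 12.0),
        lesion_uptake=8.0,
        background_uptake=0.3,
        psf_fwhm_mm=10.0,
        noise_sd=0.02,
        decoy_hotspot=(tuple(decoy_center), 8.0, 8.0),
        seed=seed,
    )
    truth, pet = make_phantom(spec)
    from .threshold import roi_from_masks

    roi = roi_from_masks([truth], lesion_id="leakage", pad=2)
    decoy_region = BinaryMask(grid, _ellipsoid_mask(grid, decoy_center, (8.0,) * 3))
    return pet, roi, truth, decoy_region
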