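"""Seeded synthetic brain phantom generator.

Produces aligned T1/FLAIR pairs, ground-truth tissue labels, a lesion mask,
a brain mask and a smoothed-ground-truth probabilistic atlas with the
contrast structure the segmentation algorithms assume:

* nested ellipsoids — central CSF ventricle, WM core, GM ribbon, CSF shell;
* optional hypointense-T1 / hyperintense-FLAIR spherical lesions placed
  strictly inside WM (the MS failure mode: lesion T1 intensity sits at the
  GM level, so unassisted clustering mislabels lesions as GM);
* optional smooth multiplicative bias field (grayscale inhomogeneity);
* additive Gaussian noise.

All phantom intensities already live on the [0, 1] clustering scale. The
geometry is analytic, so generation is fully determined by the spec and its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import (
    CSF,
    GM,
    WM,
    BrainMask,
    IntensityVolume,
    LabelMap,
    ProbabilisticAtlas,
    ValidationError,
    normalize_atlas,
)
from .lesion import LesionMask

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "default_validation_suite"]

# normalized radii of the nested ellipsoid boundaries (fractions of the
# brain semi-axes): ventricle | WM core | GM ribbon | CSF shell
_R_VENT, _R_WM, _R_GM = 0.17, 0.60, 0.83
_BRAIN_FRACTION = 0.46  # brain semi-axis as a fraction of each grid dimension


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject."""

    shape: tuple[int, int, int] = (48, 48, 48)
    t1_means: tuple[float, float, float] = (0.15, 0.50, 0.80)     # CSF < GM < WM
    flair_means: tuple[float, float, float] = (0.10, 0.60, 0.45)  # CSF suppressed
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.0
    lesion_count: int = 0
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)
    lesion_t1_intensity: float = 0.50   # hypointense: sits at the GM level
    lesion_flair_intensity: float = 0.90  # hyperintense
    atlas_smoothing_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t1_means[0] < self.t1_means[1] < self.t1_means[2]):
            raise ValidationError("t1_means must be strictly increasing (CSF < GM < WM)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValidationError("bias_amplitude must be in [0, 1)")
        if self.lesion_count < 0:
            raise ValidationError("lesion_count must be >= 0")
        if self.lesion_radius_range[0] < 1 or self.lesion_radius_range[1] < self.lesion_radius_range[0]:
            raise ValidationError("lesion radii must be >= 1 voxel and ordered")
        if min(self.shape) < 16:
            raise ValidationError("phantom grid too small (min dimension 16)")


@dataclass
class PhantomBundle:
    """All products of one phantom draw, on a single grid."""

    t1: IntensityVolume
    flair: IntensityVolume
    gt_labels: LabelMap
    lesion_gt: LesionMask
    mask: BrainMask
    atlas: ProbabilisticAtlas
    spec: PhantomSpec


def _geometry(shape: tuple[int, int, int]) -> np.ndarray:
    """Ground-truth label ellipsoids; raises if any shell is thinner than a voxel."""
    semi = np.array(shape) * _BRAIN_FRACTION
    thinnest = min((_R_GM - _R_WM), (1.0 - _R_GM), (_R_WM - _R_VENT)) * semi.min()
    if thinnest < 1.0 or _R_VENT * semi.min() < 1.0:
        raise ValidationError(f"geometry infeasible for shape {shape}: "
                              "a tissue shell would be thinner than one voxel")
    center = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r = np.sqrt(sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)))
    gt = np.zeros(shape, dtype=np.int16)
    gt[r <= 1.0] = CSF          # outer CSF shell
    gt[r <= _R_GM] = GM         # cortical ribbon
    gt[r <= _R_WM] = WM         # WM core
    gt[r <= _R_VENT] = CSF      # central ventricle
    return gt


def _place_lesions(gt: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw non-overlapping lesion spheres strictly inside WM."""
    lesions = np.zeros(gt.shape, dtype=bool)
    if spec.lesion_count == 0:
        return lesions
    wm = gt == WM
    edt = ndimage.distance_transform_edt(wm)
    grids = np.meshgrid(*(np.arange(n) for n in gt.shape), indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    lo, hi = spec.lesion_radius_range
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(spec.lesion_count):
        radius = float(rng.uniform(lo, hi))
        # candidate centers keep the whole sphere >= 1 voxel inside WM
        ok = edt.ravel() > radius + 1.0
        for c, rc in zip(centers, radii):
            # keep >= 2 voxels between sphere surfaces so components stay
            # 26-disconnected after voxelization
            ok &= np.linalg.norm(coords - c, axis=1) > radius + rc + 2.0
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            raise ValidationError(
                f"cannot place {spec.lesion_count} non-overlapping lesions of radius "
                f"[{lo}, {hi}] inside WM for shape {gt.shape}")
        choice = coords[rng.choice(idx)]
        centers.append(choice)
        radii.append(radius)
        dist = np.linalg.norm(coords - choice, axis=1).reshape(gt.shape)
        lesions |= dist <= radius
    return lesions


def _bias_field(shape: tuple[int, int, int], amplitude: float) -> np.ndarray:
    """Smooth separable low-frequency multiplicative field, peak deviation
    ``amplitude`` from unity."""
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.cos(0.5 * np.pi * (2 * np.arange(n) / (n - 1) - 1)) for n in shape]
    g = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return 1.0 + amplitude * (2.0 * g - 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate one phantom bundle, fully determined by ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    gt = _geometry(spec.shape)
    mask = gt > 0
    lesions = _place_lesions(gt, spec, rng)

    t1 = np.zeros(spec.shape)
    flair = np.zeros(spec.shape)
    for k, (mt1, mfl) in enumerate(zip(spec.t1_means, spec.flair_means), start=1):
        t1[gt == k] = mt1
        flair[gt == k] = mfl
    t1[lesions] = spec.lesion_t1_intensity
    flair[lesions] = spec.lesion_flair_intensity

    bias = _bias_field(spec.shape, spec.bias_amplitude)
    t1 = np.where(mask, t1 * bias, 0.0)
    flair = np.where(mask, flair * bias, 0.0)
    if spec.noise_sigma > 0:
        t1 = np.where(mask, t1 + rng.normal(0.0, spec.noise_sigma, spec.shape), 0.0)
        flair = np.where(mask, flair + rng.normal(0.0, spec.noise_sigma, spec.shape), 0.0)

    onehot = np.stack([(gt == k).astype(float) for k in (CSF, GM, WM)], axis=-1)
    if spec.atlas_smoothing_sigma > 0:
        smoothed = np.stack(
            [ndimage.gaussian_filter(onehot[..., i], spec.atlas_smoothing_sigma)
             for i in range(3)], axis=-1)
    else:
        smoothed = onehot
    atlas = normalize_atlas(smoothed, BrainMask(data=mask))

    return PhantomBundle(
        t1=IntensityVolume(data=t1),
        flair=IntensityVolume(data=flair),
        gt_labels=LabelMap(data=gt),
        lesion_gt=LesionMask(data=lesions),
        mask=BrainMask(data=mask),
        atlas=atlas,
        spec=spec,
    )


def default_validation_suite(seed: int = 0) -> list[PhantomSpec]:
    """The three canonical validation phantoms.

    (a) clean 48^3 — noiseless, bias-free, lesion-free; every fitter must
        recover the ground truth exactly;
    (b) noisy 48^3 — additive Gaussian noise sigma = 0.08; exercises the
        spatial penalty's noise robustness;
    (c) lesioned 64^3 — sigma = 0.05 with 5 WM lesions; exercises lesion
        screening and filling.
    """
    base = PhantomSpec(seed=seed)
    return [
        replace(base, shape=(48, 48, 48), noise_sigma=0.0, bias_amplitude=0.0,
                lesion_count=0),
        replace(base, shape=(48, 48, 48), noise_sigma=0.08, bias_amplitude=0.0,
                lesion_count=0),
        replace(base, shape=(64, 64, 64), noise_sigma=0.05, bias_amplitude=0.0,
                lesion_count=5, lesion_radius_range=(2.0, 4.0)),
    ]
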