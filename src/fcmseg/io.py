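"""NIfTI input/output, geometry validation and intensity normalization.

All volumes belonging to one subject must live on a single grid; the axial
(slice) axis is the third array axis. Intensities are brought onto a fixed
[0, 1] scale before clustering so that the penalty weights and the
convergence threshold of the fitters are meaningful regardless of scanner
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ValidationError",
    "IntensityVolume",
    "BrainMask",
    "LabelMap",
    "ProbabilisticAtlas",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "load_atlas",
    "write_atlas",
    "write_membership",
    "normalize_intensities",
    "derive_mask",
]

#: label coding used throughout: background, CSF, GM, WM
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_LABELS = (CSF, GM, WM)
TISSUE_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}


class ValidationError(ValueError):
    """An input volume, mask or atlas violates a geometric or value contract."""


def _default_affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class IntensityVolume:
    """A 3-D scalar image (T1 or FLAIR carrier) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D volume, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if bad:
            raise ValidationError(f"volume contains {bad} non-finite voxel(s)")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BrainMask:
    """Boolean brain mask on the subject grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D mask, got {self.data.ndim}-D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValidationError("brain mask is empty")


@dataclass
class LabelMap:
    """Integer tissue labels: 0=background, 1=CSF, 2=GM, 3=WM."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.int16)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D label map, got {self.data.ndim}-D")
        bad = np.setdiff1d(np.unique(self.data), [0, 1, 2, 3])
        if bad.size:
            raise ValidationError(f"labels outside {{0,1,2,3}}: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ProbabilisticAtlas:
    """Per-voxel tissue prior probabilities, channels ordered (CSF, GM, WM)."""

    probs: np.ndarray  # (X, Y, Z, K)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4:
            raise ValidationError(f"expected 4-D atlas, got {self.probs.ndim}-D")
        if np.any(self.probs < -1e-9) or np.any(self.probs > 1 + 1e-9):
            raise ValidationError("atlas probabilities outside [0, 1]")
        np.clip(self.probs, 0.0, 1.0, out=self.probs)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.probs.shape[:3]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[3]


def require_same_grid(*shapes_named: tuple[str, tuple[int, ...]]) -> None:
    """Raise unless every named object shares one grid shape."""
    names = [n for n, _ in shapes_named]
    shapes = [s for _, s in shapes_named]
    if len(set(shapes)) > 1:
        detail = ", ".join(f"{n}={s}" for n, s in zip(names, shapes))
        raise ValidationError(f"grid mismatch: {detail}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return nib.load(str(path))


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3-D NIfTI intensity volume; spacing comes from the header."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"expected 3-D image, got {data.ndim}-D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(path: str | Path, volume: IntensityVolume | np.ndarray,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 check_finite: bool = True) -> None:
    """Write a volume as float64 NIfTI.

    ``check_finite=False`` is the raw escape hatch that allows writing
    non-finite voxels (used to build deliberately corrupt test inputs).
    """
    if isinstance(volume, IntensityVolume):
        data, affine = volume.data, volume.affine
    else:
        data = np.asarray(volume, dtype=np.float64)
        affine = _default_affine(tuple(float(s) for s in spacing))
        if check_finite and not np.isfinite(data).all():
            raise ValidationError("refusing to write non-finite voxels (pass check_finite=False)")
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BrainMask:
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3-D mask, got {data.ndim}-D in {path}")
    return BrainMask(data=data > 0)


def write_mask(path: str | Path, mask: BrainMask,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _default_affine(spacing))
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabelMap:
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3-D label map, got {data.ndim}-D in {path}")
    return LabelMap(data=np.rint(data).astype(np.int16))


def write_labels(path: str | Path, labels: LabelMap,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), _default_affine(spacing))
    nib.save(img, str(path))


def load_atlas(path: str | Path, mask: BrainMask) -> ProbabilisticAtlas:
    """Read a 4-D (3-channel) probabilistic atlas aligned to the subject grid.

    Inside the mask each voxel's probabilities are renormalized to sum to 1;
    voxels whose stored sum is below 1e-6 fall back to the uninformative
    uniform prior (1/3, 1/3, 1/3).
    """
    img = _load(path)
    probs = np.asarray(img.dataobj, dtype=np.float64)
    if probs.ndim != 4:
        raise ValidationError(f"expected 4-D atlas, got {probs.ndim}-D in {path}")
    return normalize_atlas(probs, mask)


def normalize_atlas(probs: np.ndarray, mask: BrainMask) -> ProbabilisticAtlas:
    """Renormalize raw per-voxel tissue probabilities inside the mask."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[-1] != 3:
        raise ValidationError(f"expected 3 atlas channels, got {probs.shape[-1]}")
    require_same_grid(("atlas", probs.shape[:3]), ("mask", mask.shape))
    probs = np.clip(probs, 0.0, None)
    out = probs.copy()
    s = probs.sum(axis=3)
    inside = mask.data
    degenerate = inside & (s < 1e-6)
    ok = inside & ~degenerate
    out[ok] = probs[ok] / s[ok][:, None]
    out[degenerate] = 1.0 / 3.0
    out[~inside] = 0.0
    return ProbabilisticAtlas(probs=out)


def write_atlas(path: str | Path, atlas: ProbabilisticAtlas,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(atlas.probs.astype(np.float64), _default_affine(spacing))
    nib.save(img, str(path))


def write_membership(path: str | Path, u: np.ndarray,
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Export a (X, Y, Z, K) membership stack as 4-D NIfTI."""
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 4:
        raise ValidationError(f"expected 4-D membership stack, got {u.ndim}-D")
    nib.save(nib.Nifti1Image(u, _default_affine(spacing)), str(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_intensities(volume: IntensityVolume, mask: BrainMask) -> IntensityVolume:
    """Map masked intensities onto [0, 1] with 1st/99th percentile clipping.

    Values are clipped to the [p1, p99] range of the masked voxels and then
    affinely rescaled so p1 -> 0 and p99 -> 1. Voxels outside the mask are
    set to 0. The mapping is monotone on the clipped range.
    """
    mask.require_nonempty()
    require_same_grid(("volume", volume.shape), ("mask", mask.shape))
    vals = volume.data[mask.data]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi - lo <= 0:
        raise ValidationError("degenerate intensity range: masked image is (nearly) constant")
    out = np.zeros_like(volume.data)
    out[mask.data] = (np.clip(vals, lo, hi) - lo) / (hi - lo)
    return IntensityVolume(data=out, spacing=volume.spacing, affine=volume.affine)


def derive_mask(volume: IntensityVolume) -> BrainMask:
    """Default brain mask for brain-extracted inputs: strictly positive voxels."""
    return BrainMask(data=volume.data > 0)
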