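"""FLAIR lesion screening, S-Lesion-Filling of T1, and the combined
lesion-filling + atlas-constrained segmentation pipeline (LFA-FCM).

MS lesions are hyperintense on FLAIR (brighter than GM) and hypointense on
T1 (near the GM level), so an unassisted tissue clustering mislabels
white-matter lesions as gray matter. The pipeline screens lesion candidates
on FLAIR against coarse GM statistics, replaces their T1 intensities with
draws that mimic normal-appearing white matter (NAWM), and only then runs
the atlas-constrained segmentation on the "healthy" synthetic T1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .clustering import (
    AtlasFCM,
    ClusterConfig,
    FCMResults,
    FuzzyCMeans,
    hard_labels,
    redistribute_boundaries,
)
from .io import (
    GM,
    WM,
    BrainMask,
    IntensityVolume,
    LabelMap,
    ProbabilisticAtlas,
    ValidationError,
    require_same_grid,
)

__all__ = [
    "LesionConfig",
    "LesionMask",
    "SliceStats",
    "StageError",
    "segment_lesions_flair",
    "compute_slice_stats",
    "slf_fill",
    "LesionFillingPipeline",
    "PipelineResults",
    "run_lfa_fcm",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class LesionConfig:
    """Knobs of the FLAIR screening and filling steps.

    alpha            hyperintensity threshold multiplier: candidates must
                     exceed mu_GM + alpha * sigma_GM on FLAIR
    min_size         smallest surviving 26-connected candidate component
    overlap_classes  coarse-segmentation labels a lesion may overlap
                     (CSF is excluded: FLAIR suppresses CSF)
    fill_seed        RNG seed for the filling draws
    """

    alpha: float = 2.0
    min_size: int = 10
    overlap_classes: tuple[int, ...] = (GM, WM)
    fill_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if self.min_size < 1:
            raise ValidationError(f"min_size must be >= 1, got {self.min_size}")


@dataclass
class LesionMask:
    """Binary volume of lesion-candidate voxels."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D lesion mask, got {self.data.ndim}-D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SliceStats:
    """NAWM intensity statistics of one axial slice (population convention)."""

    mu: float
    sigma: float
    count: int
    used_global_fallback: bool = False


def segment_lesions_flair(flair: IntensityVolume, coarse_labels: LabelMap,
                          mask: BrainMask, config: LesionConfig) -> LesionMask:
    """Screen lesion candidates on FLAIR against coarse-GM statistics.

    Candidates are masked voxels whose FLAIR intensity exceeds
    mu_GM + alpha * sigma_GM (statistics over the coarse GM voxels),
    restricted to the coarse GM/WM region (lesions never overlap CSF, which
    FLAIR suppresses), with 26-connected components smaller than
    ``min_size`` voxels discarded as noise specks.
    """
    require_same_grid(("flair", flair.shape), ("coarse_labels", coarse_labels.shape),
                      ("mask", mask.shape))
    gm = coarse_labels.data == GM
    if not gm.any():
        raise ValidationError("cannot estimate GM statistics: coarse segmentation has no GM voxels")
    vals = flair.data[gm]
    mu, sigma = float(vals.mean()), float(vals.std())  # population std
    cand = mask.data & (flair.data > mu + config.alpha * sigma)
    cand &= np.isin(coarse_labels.data, config.overlap_classes)
    if cand.any() and config.min_size > 1:
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        comp, n = ndimage.label(cand, structure=structure)
        sizes = np.bincount(comp.ravel())
        keep = sizes >= config.min_size
        keep[0] = False
        cand = keep[comp]
    return LesionMask(data=cand)


def _nawm_stats(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(values.std())


def compute_slice_stats(t1: IntensityVolume, wm_mask: BrainMask,
                        lesion_mask: LesionMask, slice_index: int) -> SliceStats:
    """Mean/std of NAWM (WM minus lesion) T1 intensity on one axial slice.

    Slices without any NAWM voxel fall back to the volume-global NAWM
    statistics and are flagged. Population (divide-by-count) standard
    deviation throughout.
    """
    require_same_grid(("t1", t1.shape), ("wm_mask", wm_mask.shape),
                      ("lesion_mask", lesion_mask.shape))
    if not 0 <= slice_index < t1.shape[2]:
        raise ValidationError(f"slice_index {slice_index} out of range [0, {t1.shape[2]})")
    nawm = wm_mask.data & ~lesion_mask.data
    if not nawm.any():
        raise ValidationError("no NAWM reference tissue in the volume")
    sl = nawm[:, :, slice_index]
    if sl.any():
        mu, sigma = _nawm_stats(t1.data[:, :, slice_index][sl])
        return SliceStats(mu=mu, sigma=sigma, count=int(sl.sum()))
    mu, sigma = _nawm_stats(t1.data[nawm])
    return SliceStats(mu=mu, sigma=sigma, count=0, used_global_fallback=True)


def slf_fill(t1: IntensityVolume, lesion_mask: LesionMask, wm_mask: BrainMask,
             seed: int = 0) -> IntensityVolume:
    """S-Lesion-Filling: replace lesion T1 intensities slice by slice.

    For each axial slice containing lesion voxels, every lesion voxel is
    replaced by an independent draw from Normal(mu, sigma / 2) where mu and
    sigma are that slice's NAWM statistics. Non-lesion voxels are returned
    bit-identical. One RNG stream is seeded per call; slices are processed
    in ascending index and voxels in row-major order, so a fixed seed gives
    identical output everywhere. Draws are not clipped.
    """
    require_same_grid(("t1", t1.shape), ("lesion_mask", lesion_mask.shape),
                      ("wm_mask", wm_mask.shape))
    out = t1.data.copy()
    if not lesion_mask.data.any():
        return IntensityVolume(data=out, spacing=t1.spacing, affine=t1.affine)
    nawm = wm_mask.data & ~lesion_mask.data
    if not nawm.any():
        raise ValidationError("no NAWM reference tissue in the volume")
    rng = np.random.default_rng(seed)
    for z in range(t1.shape[2]):
        les = lesion_mask.data[:, :, z]
        n = int(les.sum())
        if n == 0:
            continue
        stats = compute_slice_stats(t1, wm_mask, lesion_mask, z)
        draws = rng.normal(stats.mu, stats.sigma / 2.0, size=n)
        plane = out[:, :, z]
        plane[les] = draws  # row-major assignment order
    return IntensityVolume(data=out, spacing=t1.spacing, affine=t1.affine)


# ---------------------------------------------------------------------------
# LFA-FCM pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResults:
    """Outputs of a lesion-filling segmentation run."""

    labels: LabelMap
    lesion_mask: LesionMask
    fit: FCMResults
    filled_t1: IntensityVolume
    coarse_labels: LabelMap

    def summary(self) -> str:
        lines = [
            "LFA-FCM pipeline",
            f"  lesion voxels : {self.lesion_mask.n_voxels}",
            f"  filled slices : "
            f"{int(np.unique(np.nonzero(self.lesion_mask.data)[2]).size)}",
        ]
        return "\n".join(lines) + "\n" + self.fit.summary()


class LesionFillingPipeline:
    """End-to-end LFA-FCM: coarse FCM -> FLAIR screening -> SLF fill ->
    AR-FCM -> morphological boundary redistribution.

    ``morph_atlas`` defaults to the statistical atlas when not supplied.
    """

    def __init__(self, t1: IntensityVolume, flair: IntensityVolume,
                 atlas: ProbabilisticAtlas, mask: BrainMask,
                 cluster_config: ClusterConfig | None = None,
                 lesion_config: LesionConfig | None = None,
                 morph_atlas: ProbabilisticAtlas | None = None) -> None:
        self.t1 = t1
        self.flair = flair
        self.atlas = atlas
        self.mask = mask
        self.cluster_config = cluster_config or ClusterConfig.for_arfcm()
        self.lesion_config = lesion_config or LesionConfig()
        self.morph_atlas = morph_atlas if morph_atlas is not None else atlas

    @staticmethod
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - tag and re-raise per contract
            raise StageError(f"{name}: {exc}") from exc

    def run(self) -> PipelineResults:
        from dataclasses import replace

        cfg = self.cluster_config
        # 1. coarse plain-FCM segmentation of T1
        coarse_cfg = replace(cfg, beta=0.0, gamma=0.0)
        coarse = self._stage("coarse_fcm",
                             lambda: FuzzyCMeans(self.t1, self.mask, coarse_cfg).fit())
        coarse_labels = coarse.labels()
        # 2. FLAIR lesion screening against coarse GM statistics
        lesions = self._stage("segment_lesions_flair", segment_lesions_flair,
                              self.flair, coarse_labels, self.mask, self.lesion_config)
        # 3. fill lesion T1 intensities from NAWM statistics
        wm = BrainMask(data=coarse_labels.data == WM)
        filled = self._stage("slf_fill", slf_fill, self.t1, lesions, wm,
                             self.lesion_config.fill_seed)
        # 4. atlas-constrained segmentation of the filled T1
        fit = self._stage("fit_arfcm",
                          lambda: AtlasFCM(filled, self.mask, self.atlas, cfg).fit())
        labels = fit.labels()
        # 5. morphological-atlas boundary redistribution
        labels = self._stage("redistribute_boundaries", redistribute_boundaries,
                             labels, fit.membership, self.morph_atlas, self.mask)
        return PipelineResults(labels=labels, lesion_mask=lesions, fit=fit,
                               filled_t1=filled, coarse_labels=coarse_labels)


def run_lfa_fcm(t1: IntensityVolume, flair: IntensityVolume,
                atlas: ProbabilisticAtlas, mask: BrainMask,
                cluster_config: ClusterConfig, lesion_config: LesionConfig,
                morph_atlas: ProbabilisticAtlas | None = None,
                ) -> tuple[LabelMap, LesionMask, FCMResults]:
    """Functional wrapper around :class:`LesionFillingPipeline`."""
    res = LesionFillingPipeline(t1, flair, atlas, mask, cluster_config,
                                lesion_config, morph_atlas).run()
    return res.labels, res.lesion_mask, res.fit
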