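"""Energy-minimization tissue clustering: FCM, spatial-penalty RFCM and
atlas-constrained AR-FCM, plus defuzzification and morphological-atlas
boundary redistribution.

The three fitters share one alternate-minimization skeleton over the masked
voxels of a normalized intensity volume:

    J(u, v) = sum_j sum_k u_jk^q * ( |y_j - v_k|^2 + r_jk(u) )

where the regularizer r_jk is

    FCM     r = 0
    RFCM    r = beta * sum_{l in N_j} sum_{m != k} u_lm^q   (6-neighborhood)
    AR-FCM  r = gamma * (1 - pi_jk)^w                        (atlas prior)

Membership and centroid updates are the closed-form coordinate minimizers;
for RFCM the membership step treats neighbor memberships as fixed (a Jacobi
sweep), so a backtracking line search guards the monotone-energy guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .io import (
    BrainMask,
    IntensityVolume,
    LabelMap,
    ProbabilisticAtlas,
    ValidationError,
    require_same_grid,
)

__all__ = [
    "ClusterConfig",
    "MembershipField",
    "FCMResults",
    "FuzzyCMeans",
    "SpatialFCM",
    "AtlasFCM",
    "fit_fcm",
    "fit_rfcm",
    "fit_arfcm",
    "hard_labels",
    "redistribute_boundaries",
]

_ZERO_DIST = 1e-15  # below this a cost counts as an exact centroid hit


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the fuzzy clustering energy.

    q     fuzziness exponent (> 1)
    beta  spatial neighborhood penalty weight (RFCM)
    gamma atlas penalty weight (AR-FCM)
    w     atlas penalty exponent
    n     maximum number of iterations
    thr   convergence threshold on the max centroid change
          (normalized intensity units)
    K     number of tissue classes
    """

    q: float = 2.0
    beta: float = 0.0
    gamma: float = 0.0
    w: float = 1.0
    n: int = 200
    thr: float = 1e-3
    K: int = 3

    def __post_init__(self) -> None:
        if self.q <= 1:
            raise ValidationError(f"fuzziness exponent q must be > 1, got {self.q}")
        if self.n < 1:
            raise ValidationError(f"iteration cap n must be >= 1, got {self.n}")
        if self.thr <= 0:
            raise ValidationError(f"threshold thr must be > 0, got {self.thr}")
        if self.beta < 0 or self.gamma < 0:
            raise ValidationError("penalty weights beta/gamma must be >= 0")
        if self.w <= 0:
            raise ValidationError(f"atlas exponent w must be > 0, got {self.w}")
        if self.K < 1:
            raise ValidationError(f"need at least one class, got K={self.K}")

    # published defaults for the three methods
    @classmethod
    def for_fcm(cls, **kw) -> "ClusterConfig":
        return cls(**{"q": 2.0, "beta": 0.0, "gamma": 0.0, "n": 500, "thr": 1e-3, **kw})

    @classmethod
    def for_rfcm(cls, **kw) -> "ClusterConfig":
        return cls(**{"q": 2.0, "beta": 1.0, "gamma": 0.0, "n": 500, "thr": 1e-3, **kw})

    @classmethod
    def for_arfcm(cls, **kw) -> "ClusterConfig":
        return cls(**{"q": 2.0, "beta": 0.0, "gamma": 0.025, "w": 1.0, "n": 200, "thr": 1e-3, **kw})


@dataclass
class MembershipField:
    """Fuzzy memberships u_jk for the masked voxels, classes along last axis.

    ``u`` has shape (M, K) over the M masked voxels in C (row-major) order;
    ``mask`` maps rows back onto the grid.
    """

    u: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 2 or self.u.shape[0] != self.mask.n_voxels:
            raise ValidationError("membership rows must match masked voxel count")
        if np.any(self.u < -1e-12) or np.any(self.u > 1 + 1e-12):
            raise ValidationError("memberships outside [0, 1]")
        rows = self.u.sum(axis=1)
        if self.u.shape[0] and np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValidationError("membership rows must sum to 1 (within 1e-9)")

    @property
    def n_classes(self) -> int:
        return self.u.shape[1]

    def to_grid(self) -> np.ndarray:
        """Expand to a dense (X, Y, Z, K) stack, zero outside the mask."""
        out = np.zeros(self.mask.shape + (self.n_classes,))
        out[self.mask.data] = self.u
        return out


@dataclass
class FCMResults:
    """Converged state of a fuzzy clustering fit.

    Classes are sorted by ascending centroid, so on T1 input class 0 is CSF,
    1 is GM and 2 is WM.
    """

    membership: MembershipField
    centroids: np.ndarray
    objective_trace: np.ndarray
    iterations_used: int
    converged: bool
    config: ClusterConfig
    method: str = "fcm"

    def labels(self) -> LabelMap:
        """Maximum-membership defuzzification to the 0/1/2/3 label coding."""
        return hard_labels(self.membership, self.membership.mask, self.centroids)

    def summary(self) -> str:
        c = self.config
        lines = [
            f"{self.method.upper()} fit: K={c.K}, q={c.q}, beta={c.beta}, "
            f"gamma={c.gamma}, w={c.w}",
            f"  masked voxels : {self.membership.mask.n_voxels}",
            f"  iterations    : {self.iterations_used} / {c.n} "
            f"({'converged' if self.converged else 'iteration cap reached'}, thr={c.thr})",
            f"  centroids     : {np.array2string(self.centroids, precision=4)}",
            f"  objective     : {self.objective_trace[0]:.6g} -> {self.objective_trace[-1]:.6g}",
        ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Plot the (non-increasing) energy trace over iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.objective_trace) + 1), self.objective_trace, marker=".")
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective J")
        ax.set_title(f"{self.method.upper()} energy trace")
        return ax


# ---------------------------------------------------------------------------
# shared numerical pieces
# ---------------------------------------------------------------------------

def _memberships_from_costs(a: np.ndarray, q: float) -> np.ndarray:
    """Closed-form membership minimizer: u_jk propto a_jk^(-1/(q-1)).

    Rows containing an (effectively) zero cost get one-hot membership on the
    first such class — the standard singular-case convention for voxels that
    sit exactly on a centroid.
    """
    expo = -1.0 / (q - 1.0)
    zero = a <= _ZERO_DIST
    safe = np.where(zero, 1.0, a)
    u = safe ** expo
    u /= u.sum(axis=1, keepdims=True)
    rows = np.nonzero(zero.any(axis=1))[0]
    if rows.size:
        u[rows] = 0.0
        u[rows, np.argmax(zero[rows], axis=1)] = 1.0
    return u


def _quantile_init(y: np.ndarray, K: int) -> np.ndarray:
    """Deterministic centroid init at the (2i+1)/(2K) masked-intensity quantiles."""
    qs = (2 * np.arange(K) + 1) / (2 * K)
    return np.quantile(y, qs)


def _neighbor_sum(grid: np.ndarray) -> np.ndarray:
    """Sum each voxel's 6-connected neighbors (outside-grid treated as zero)."""
    out = np.zeros_like(grid)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        out[tuple(lo)] += grid[tuple(hi)]
        out[tuple(hi)] += grid[tuple(lo)]
    return out


def _sort_classes(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(v, kind="stable")
    return u[:, order], v[order]


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class FuzzyCMeans:
    """Plain fuzzy C-means on the masked voxels of a normalized volume.

    Parameters
    ----------
    volume : IntensityVolume
        Intensities on the clustering scale (normalize first).
    mask : BrainMask
        Nonempty brain mask; clustering only sees masked voxels.
    config : ClusterConfig
        Energy parameters; ``beta`` and ``gamma`` are ignored by this model.
    initial_centroids : sequence of float, optional
        Override the deterministic quantile initialization.
    """

    method = "fcm"

    def __init__(self, volume: IntensityVolume, mask: BrainMask | None = None,
                 config: ClusterConfig | None = None,
                 initial_centroids: Sequence[float] | None = None) -> None:
        from .io import derive_mask

        self.volume = volume
        self.mask = mask if mask is not None else derive_mask(volume)
        self.mask.require_nonempty()
        require_same_grid(("volume", volume.shape), ("mask", self.mask.shape))
        self.config = config if config is not None else self._default_config()
        self.y = volume.data[self.mask.data]
        if np.unique(self.y).size < self.config.K:
            raise ValidationError(
                "underdetermined clustering: fewer distinct masked intensities "
                f"({np.unique(self.y).size}) than classes (K={self.config.K})"
            )
        self._v0 = (np.asarray(initial_centroids, dtype=np.float64)
                    if initial_centroids is not None else self._init_centroids())
        if self._v0.shape != (self.config.K,):
            raise ValidationError(f"initial_centroids must have length K={self.config.K}")

    def _default_config(self) -> ClusterConfig:
        return ClusterConfig.for_fcm()

    def _init_centroids(self) -> np.ndarray:
        return _quantile_init(self.y, self.config.K)

    # regularizer r_jk(u); the base model has none
    def _regularizer(self, u: np.ndarray) -> np.ndarray | float:
        return 0.0

    # True iff r depends on u (then the membership step needs a line search)
    _coupled = False

    def _objective(self, u: np.ndarray, v: np.ndarray) -> float:
        d2 = (self.y[:, None] - v[None, :]) ** 2
        return float(np.sum(u ** self.config.q * d2))

    def fit(self) -> FCMResults:
        cfg = self.config
        y, q = self.y, cfg.q
        v = self._v0.copy()
        d2 = (y[:, None] - v[None, :]) ** 2
        u = _memberships_from_costs(d2, q)  # regularizer not yet available at init
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.n + 1):
            d2 = (y[:, None] - v[None, :]) ** 2
            r = self._regularizer(u)
            u_new = _memberships_from_costs(d2 + r, q)
            if self._coupled:
                u_new = self._backtrack(u, u_new, v)
            u = u_new
            uq = u ** q
            denom = uq.sum(axis=0)
            v_new = np.where(denom > 0, uq.T @ y / np.where(denom > 0, denom, 1.0), v)
            trace.append(self._objective(u, v_new))
            dv = float(np.max(np.abs(v_new - v)))
            v = v_new
            if dv < cfg.thr:
                converged = True
                break
        u, v = _sort_classes(u, v)
        return FCMResults(
            membership=MembershipField(u=u, mask=self.mask),
            centroids=v,
            objective_trace=np.asarray(trace),
            iterations_used=it,
            converged=converged,
            config=cfg,
            method=self.method,
        )

    def _backtrack(self, u_old: np.ndarray, u_cand: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Damp the membership step until the energy does not increase.

        Convex combinations of two row-stochastic matrices stay row-stochastic,
        so the simplex constraint is preserved at every step size.
        """
        j_old = self._objective(u_old, v)
        t = 1.0
        while t > 1e-6:
            u_t = u_cand if t == 1.0 else u_old + t * (u_cand - u_old)
            if self._objective(u_t, v) <= j_old + 1e-12 * (1.0 + abs(j_old)):
                return u_t
            t *= 0.5
        return u_old


class SpatialFCM(FuzzyCMeans):
    """Robust FCM: FCM plus a 6-neighborhood cross-class membership penalty.

    The penalty (weight ``beta``) behaves like a Markov-random-field prior,
    discouraging a voxel's membership in class k when its neighbors favor
    other classes; neighbors outside the mask do not contribute.
    """

    method = "rfcm"
    _coupled = True

    def _default_config(self) -> ClusterConfig:
        return ClusterConfig.for_rfcm()

    def _regularizer(self, u: np.ndarray) -> np.ndarray | float:
        beta = self.config.beta
        if beta == 0.0:
            return 0.0
        uq_grid = np.zeros(self.mask.shape + (self.config.K,))
        uq_grid[self.mask.data] = u ** self.config.q
        s_grid = uq_grid.sum(axis=3)
        nb_s = _neighbor_sum(s_grid)
        pen = np.empty_like(u)
        for k in range(self.config.K):
            nb_k = _neighbor_sum(uq_grid[..., k])
            pen[:, k] = (nb_s - nb_k)[self.mask.data]
        return beta * pen

    def _objective(self, u: np.ndarray, v: np.ndarray) -> float:
        d2 = (self.y[:, None] - v[None, :]) ** 2
        uq = u ** self.config.q
        base = float(np.sum(uq * d2))
        r = self._regularizer(u)
        if isinstance(r, float):
            return base
        return base + 0.5 * float(np.sum(uq * r))


class AtlasFCM(FuzzyCMeans):
    """Atlas-constrained FCM (AR-FCM).

    Adds the prior penalty gamma * (1 - pi_jk)^w, pulling each voxel's
    membership toward the tissues a registered probabilistic atlas considers
    plausible there. Default initialization places centroids at the
    atlas-weighted intensity means.
    """

    method = "arfcm"
    _coupled = False

    def __init__(self, volume: IntensityVolume, mask: BrainMask,
                 atlas: ProbabilisticAtlas, config: ClusterConfig | None = None,
                 initial_centroids: Sequence[float] | None = None) -> None:
        require_same_grid(("volume", volume.shape), ("atlas", atlas.shape))
        self.atlas = atlas
        self._pi = None  # set after mask known
        super().__init__(volume, mask, config, initial_centroids)
        if atlas.n_classes != self.config.K:
            raise ValidationError(
                f"atlas has {atlas.n_classes} channels but config.K={self.config.K}")

    def _default_config(self) -> ClusterConfig:
        return ClusterConfig.for_arfcm()

    @property
    def pi(self) -> np.ndarray:
        if self._pi is None:
            self._pi = self.atlas.probs[self.mask.data]
        return self._pi

    def _init_centroids(self) -> np.ndarray:
        pi = self.atlas.probs[self.mask.data]
        wsum = pi.sum(axis=0)
        if np.any(wsum <= 0):
            return _quantile_init(self.y, self.config.K)
        return pi.T @ self.y / wsum

    def _regularizer(self, u: np.ndarray) -> np.ndarray | float:
        if self.config.gamma == 0.0:
            return 0.0
        return self.config.gamma * (1.0 - self.pi) ** self.config.w

    def _objective(self, u: np.ndarray, v: np.ndarray) -> float:
        d2 = (self.y[:, None] - v[None, :]) ** 2
        uq = u ** self.config.q
        r = self._regularizer(u)
        if isinstance(r, float):
            return float(np.sum(uq * d2))
        return float(np.sum(uq * (d2 + r)))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_fcm(volume: IntensityVolume, mask: BrainMask, config: ClusterConfig,
            initial_centroids: Sequence[float] | None = None) -> FCMResults:
    """Fit plain FCM (beta and gamma are ignored)."""
    return FuzzyCMeans(volume, mask, replace(config, beta=0.0, gamma=0.0),
                       initial_centroids).fit()


def fit_rfcm(volume: IntensityVolume, mask: BrainMask, config: ClusterConfig,
             initial_centroids: Sequence[float] | None = None) -> FCMResults:
    """Fit RFCM with the 6-neighborhood spatial penalty (weight config.beta)."""
    return SpatialFCM(volume, mask, replace(config, gamma=0.0), initial_centroids).fit()


def fit_arfcm(volume: IntensityVolume, mask: BrainMask, atlas: ProbabilisticAtlas,
              config: ClusterConfig,
              initial_centroids: Sequence[float] | None = None) -> FCMResults:
    """Fit atlas-constrained AR-FCM (penalty weight config.gamma, exponent config.w)."""
    return AtlasFCM(volume, mask, atlas, replace(config, beta=0.0), initial_centroids).fit()


def hard_labels(membership: MembershipField, mask: BrainMask | None = None,
                centroids: np.ndarray | None = None) -> LabelMap:
    """Maximum-membership labels on the 0/1/2/3 coding.

    If ``centroids`` is given, classes are first reordered by ascending
    centroid so label 1 < 2 < 3 tracks CSF < GM < WM intensity on T1. Ties go
    to the lower class index.
    """
    mask = mask if mask is not None else membership.mask
    u = membership.u
    if centroids is not None:
        u = u[:, np.argsort(np.asarray(centroids), kind="stable")]
    out = np.zeros(mask.shape, dtype=np.int16)
    out[mask.data] = np.argmax(u, axis=1) + 1  # argmax takes the first maximum
    return LabelMap(data=out)


def redistribute_boundaries(labels: LabelMap, membership: MembershipField,
                            morph_atlas: ProbabilisticAtlas,
                            mask: BrainMask | None = None) -> LabelMap:
    """Reassign tissue-boundary voxels using a morphological label atlas.

    A masked voxel is a boundary voxel iff at least one of its 6-neighbors
    carries a different nonzero label. Each boundary voxel is relabeled to
    argmax_k u_jk * m_jk, where m_jk is the morphological-atlas probability;
    all other voxels are untouched. This counteracts partial-volume blurring
    at tissue interfaces.
    """
    mask = mask if mask is not None else membership.mask
    require_same_grid(("labels", labels.shape), ("mask", mask.shape),
                      ("morph_atlas", morph_atlas.shape))
    lab = labels.data
    boundary = np.zeros(lab.shape, dtype=bool)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        a, b = lab[tuple(lo)], lab[tuple(hi)]
        differ = (a != b) & (a > 0) & (b > 0)
        boundary[tuple(lo)] |= differ
        boundary[tuple(hi)] |= differ
    boundary &= mask.data
    out = lab.copy()
    if boundary.any():
        u_grid = membership.to_grid()
        score = u_grid[boundary] * morph_atlas.probs[boundary]
        out[boundary] = np.argmax(score, axis=1) + 1
    return LabelMap(data=out)
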