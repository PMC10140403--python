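"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (scipy EDT, vectorized
counting) so they can serve as oracles: set arithmetic on explicit voxel
coordinate lists and all-pairs distances.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def dsc_bruteforce(seg: np.ndarray, gt: np.ndarray) -> float:
    a = {tuple(c) for c in np.argwhere(seg)}
    b = {tuple(c) for c in np.argwhere(gt)}
    if not a and not b:
        return 100.0
    return 200.0 * len(a & b) / (len(a) + len(b))


def vs_bruteforce(seg: np.ndarray, gt: np.ndarray) -> float:
    ns, ng = int(np.count_nonzero(seg)), int(np.count_nonzero(gt))
    return 100.0 * (1.0 - abs(ng - ns) / (ng + ns))


def surface_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbor outside (grid edge = outside)."""
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= np.array(mask.shape)).any() or not mask[tuple(nb)]:
                    out[tuple(idx)] = True
    return out


def hd95_bruteforce(seg: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    sp = np.asarray(spacing, dtype=float)
    ps = np.argwhere(surface_bruteforce(seg)) * sp
    pg = np.argwhere(surface_bruteforce(gt)) * sp
    d = cdist(ps, pg)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95.0))


def fcm_bruteforce(y: np.ndarray, v0: np.ndarray, q: float = 2.0,
                   n_iter: int = 300, tol: float = 1e-12):
    """Plain alternate minimization of the FCM objective, loop form."""
    v = np.asarray(v0, dtype=float).copy()
    K = v.size
    u = np.zeros((y.size, K))
    for _ in range(n_iter):
        for j, yj in enumerate(y):
            d2 = (yj - v) ** 2
            if np.any(d2 < 1e-15):
                u[j] = 0.0
                u[j, int(np.argmax(d2 < 1e-15))] = 1.0
            else:
                inv = d2 ** (-1.0 / (q - 1.0))
                u[j] = inv / inv.sum()
        v_new = np.array([np.sum(u[:, k] ** q * y) / np.sum(u[:, k] ** q)
                          for k in range(K)])
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    return u, v
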