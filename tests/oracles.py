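"""Independent brute-force oracles used to pin the fast implementations.

Everything here is deliberately naive — direct set arithmetic, all-pairs
distance scans, exhaustive sign enumeration — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import cdist

NEIGHBORS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_boundary(a: np.ndarray) -> set:
    """Occupied voxels with a face-adjacent background/out-of-bounds voxel."""
    shape = a.shape
    out = set()
    for idx in np.argwhere(a):
        i, j, k = (int(v) for v in idx)
        for di, dj, dk in NEIGHBORS_6:
            ni, nj, nk = i + di, j + dj, k + dk
            inside = 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
            if not inside or not a[ni, nj, nk]:
                out.add((i, j, k))
                break
    return out


def brute_hausdorff(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs max-min boundary distance in mm (voxel centers)."""
    pa = np.array(sorted(brute_boundary(a)), dtype=float) * np.asarray(spacing)
    pb = np.array(sorted(brute_boundary(b)), dtype=float) * np.asarray(spacing)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def exact_wilcoxon_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Zero differences must already be removed. The null distribution of the
    positive-rank sum T+ over sign flips is symmetric about S/2 (S = sum of
    all ranks), so the two-sided p is 2*min(P(T<=t), P(T>=t)) capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    n = len(d)
    ranks = _average_ranks(np.abs(d))
    t_obs = ranks[d > 0].sum()
    t_all = np.array(
        [ranks[list(signs)].sum() for signs in itertools.product([False, True], repeat=n)]
    )
    p_le = np.mean(t_all <= t_obs + 1e-12)
    p_ge = np.mean(t_all >= t_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def spearman_rho_oracle(x, y) -> float:
    """Rank (average ties) then Pearson."""
    rx = _average_ranks(np.asarray(x, dtype=float))
    ry = _average_ranks(np.asarray(y, dtype=float))
    return float(np.corrcoef(rx, ry)[0, 1])


def random_mask(rng, shape=(12, 12, 8), p=0.25, ensure_nonempty=True) -> np.ndarray:
    """Random blobby mask: thresholded smoothed noise, non-empty by default."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=1.5)
    mask = field > np.quantile(field, 1 - p)
    if ensure_nonempty and not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return mask
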