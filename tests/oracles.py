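"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately literal -- per-voxel Python loops, O(n^2)
scans -- so it shares no code path with the vectorized implementations it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def loop_gradient(data: np.ndarray, spacing) -> list[np.ndarray]:
    """Central differences (one-sided at boundaries), explicit loops."""
    data = np.asarray(data, dtype=float)
    out = [np.zeros_like(data) for _ in range(data.ndim)]
    it = np.ndindex(*data.shape)
    for idx in it:
        for ax in range(data.ndim):
            n = data.shape[ax]
            i = idx[ax]
            lo = list(idx)
            hi = list(idx)
            if i == 0:
                hi[ax] = 1
                diff = (data[tuple(hi)] - data[tuple(idx)]) / spacing[ax]
            elif i == n - 1:
                lo[ax] = n - 2
                diff = (data[tuple(idx)] - data[tuple(lo)]) / spacing[ax]
            else:
                lo[ax] = i - 1
                hi[ax] = i + 1
                diff = (data[tuple(hi)] - data[tuple(lo)]) / (2.0 * spacing[ax])
            out[ax][idx] = diff
    return out


def loop_rst(data: np.ndarray, spacing, params) -> np.ndarray:
    """Literal per-voxel implementation of the gradient-voting transform.

    Mirrors the documented recipe step by step: per-radius orientation and
    magnitude accumulation with per-axis rounded physical offsets, saturation
    at k_n, the strictness exponent, per-radius Gaussian smoothing, and the
    arithmetic mean over radii.
    """
    from cmbdetect.rst import shell_vote_count

    data = np.asarray(data, dtype=float)
    ndim = data.ndim
    spacing = tuple(float(s) for s in spacing)
    grads = np.gradient(data, *spacing)
    if ndim == 1:
        grads = [grads]
    mag = np.sqrt(sum(g * g for g in grads))
    gmax = float(mag.max())
    if gmax == 0.0:
        return np.zeros_like(data)
    cutoff = params.grad_threshold_frac * gmax

    accum = np.zeros_like(data)
    for n in params.radii_mm:
        o_img = np.zeros_like(data)
        m_img = np.zeros_like(data)
        for idx in np.ndindex(*data.shape):
            m = mag[idx]
            if m <= cutoff:
                continue
            unit = [grads[a][idx] / m for a in range(ndim)]
            directions = []
            if params.polarity in ("dark", "both"):
                directions.append(-1)
            if params.polarity in ("bright", "both"):
                directions.append(+1)
            for direction in directions:
                target = tuple(
                    idx[a] + direction * int(np.rint(n * unit[a] / spacing[a]))
                    for a in range(ndim)
                )
                if all(0 <= target[a] < data.shape[a] for a in range(ndim)):
                    sign = 1.0 if params.polarity != "both" else float(direction)
                    o_img[target] += sign
                    m_img[target] += sign * m
        k_n = min(shell_vote_count(n, spacing), params.k_saturation)
        o_cl = np.minimum(np.abs(o_img), k_n)
        f_n = (np.abs(m_img) / k_n) * (o_cl / k_n) ** params.alpha
        sigma_vox = [params.smooth_sigma_factor * n / s for s in spacing]
        accum += gaussian_filter(f_n, sigma=sigma_vox)
    return accum / len(params.radii_mm)


def percentile_interpolated(values, q: float) -> float:
    """Sort-and-interpolate percentile (linear between order statistics)."""
    v = sorted(float(x) for x in values)
    if not v:
        raise ValueError("empty")
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def brute_force_frontier(points):
    """All-pairs dominance scan mirroring the documented frontier rule."""
    kept = []
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            if (
                q.sensitivity >= p.sensitivity
                and q.mean_candidates_per_participant <= p.mean_candidates_per_participant
                and (
                    q.sensitivity > p.sensitivity
                    or q.mean_candidates_per_participant < p.mean_candidates_per_participant
                )
            ):
                dominated = True
                break
            if (
                q.sensitivity == p.sensitivity
                and q.mean_candidates_per_participant == p.mean_candidates_per_participant
                and (q.t3d, q.t2d) > (p.t3d, p.t2d)
            ):
                dominated = True
                break
        if not dominated:
            kept.append(p)
    return sorted(
        kept, key=lambda p: (p.mean_candidates_per_participant, -p.sensitivity)
    )


def exhaustive_halo_max(values: np.ndarray, index, halo: int) -> float:
    """Scan every voxel; keep the max within Chebyshev distance halo."""
    best = -np.inf
    for idx in np.ndindex(*values.shape):
        if all(abs(idx[a] - index[a]) <= halo for a in range(values.ndim)):
            best = max(best, values[idx])
    return float(best)
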