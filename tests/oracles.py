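"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit Python loops, direct
formulas) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def gaussian_kernel(p: int, sd: float) -> np.ndarray:
    if p == 0:
        return np.ones((1, 1))
    k = np.empty((2 * p + 1, 2 * p + 1))
    for dy in range(-p, p + 1):
        for dx in range(-p, p + 1):
            k[dy + p, dx + p] = math.exp(-(dy * dy + dx * dx) / (2.0 * sd * sd))
    return k / k.sum()


def pad(a: np.ndarray, r: int, boundary: str) -> np.ndarray:
    mode = {"reflect": "reflect", "edge": "edge"}[boundary]
    return np.pad(a, r, mode=mode) if r else a


def naive_patch_distance(a, i, j, p, sd, boundary="reflect") -> float:
    padded = pad(a, p, boundary)
    k = gaussian_kernel(p, sd)
    d = 0.0
    for dy in range(-p, p + 1):
        for dx in range(-p, p + 1):
            pi = padded[i[0] + p + dy, i[1] + p + dx]
            pj = padded[j[0] + p + dy, j[1] + p + dx]
            d += k[dy + p, dx + p] * (pi - pj) ** 2
    return d


def naive_cosine(a, i, j, p, boundary="reflect", const_rel=1e-12) -> float:
    padded = pad(a, p, boundary)
    pi = padded[i[0] : i[0] + 2 * p + 1, i[1] : i[1] + 2 * p + 1].ravel()
    pj = padded[j[0] : j[0] + 2 * p + 1, j[1] : j[1] + 2 * p + 1].ravel()
    ci = pi - pi.mean()
    cj = pj - pj.mean()
    ni, nj = float(ci @ ci), float(cj @ cj)
    n = pi.size
    const_i = ni <= const_rel * n * (1.0 + pi.mean() ** 2)
    const_j = nj <= const_rel * n * (1.0 + pj.mean() ** 2)
    if const_i and const_j:
        return 1.0
    if const_i or const_j:
        return 0.0
    return max(-1.0, min(1.0, float(ci @ cj) / math.sqrt(ni * nj)))


def naive_nlm(a, mu, p, s, sd, gamma=0.0, center_rule="max_other", boundary="reflect"):
    """Triple-loop NLM reference."""
    h, w = a.shape
    out = np.empty_like(a, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            weights = []
            values = []
            padded_big = pad(a, s, boundary)
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    if dy == 0 and dx == 0:
                        continue
                    jy, jx = y + dy, x + dx
                    # neighbor coordinates in the search-padded frame
                    d = naive_patch_distance_padded(a, (y, x), (jy, jx), p, s, sd, boundary)
                    wt = math.exp(-d / mu)
                    if gamma > 0:
                        wt *= ((1.0 + naive_cosine_padded(a, (y, x), (jy, jx), p, s, boundary)) / 2.0) ** gamma
                    weights.append(wt)
                    values.append(padded_big[jy + s, jx + s])
            if center_rule == "max_other":
                wc = max(weights)
            elif center_rule == "one":
                wc = 1.0
            else:
                wc = 0.0
            weights.append(wc)
            values.append(a[y, x])
            wsum = sum(weights)
            if wsum <= 0:
                out[y, x] = a[y, x]
            else:
                out[y, x] = sum(wt * v for wt, v in zip(weights, values)) / wsum
    return out


def naive_patch_distance_padded(a, i, j, p, s, sd, boundary):
    """Distance where indices may lie up to s outside the image (single m=s+p pad)."""
    m = s + p
    padded = pad(a, m, boundary)
    k = gaussian_kernel(p, sd)
    d = 0.0
    for dy in range(-p, p + 1):
        for dx in range(-p, p + 1):
            pi = padded[i[0] + m + dy, i[1] + m + dx]
            pj = padded[j[0] + m + dy, j[1] + m + dx]
            d += k[dy + p, dx + p] * (pi - pj) ** 2
    return d


def naive_cosine_padded(a, i, j, p, s, boundary, const_rel=1e-12):
    m = s + p
    padded = pad(a, m, boundary)
    pi = padded[i[0] + m - p : i[0] + m + p + 1, i[1] + m - p : i[1] + m + p + 1].ravel()
    pj = padded[j[0] + m - p : j[0] + m + p + 1, j[1] + m - p : j[1] + m + p + 1].ravel()
    ci = pi - pi.mean()
    cj = pj - pj.mean()
    ni, nj = float(ci @ ci), float(cj @ cj)
    n = pi.size
    const_i = ni <= const_rel * n * (1.0 + pi.mean() ** 2)
    const_j = nj <= const_rel * n * (1.0 + pj.mean() ** 2)
    if const_i and const_j:
        return 1.0
    if const_i or const_j:
        return 0.0
    return max(-1.0, min(1.0, float(ci @ cj) / math.sqrt(ni * nj)))


def naive_mse(a, b) -> float:
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / (a.shape[0] * a.shape[1])


def brute_ring(mask: np.ndarray, width_px: float) -> np.ndarray:
    """O(N * |mask|) nearest-distance scan."""
    h, w = mask.shape
    pts = np.argwhere(mask)
    ring = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                continue
            dmin = min(math.hypot(y - py, x - px) for py, px in pts)
            if dmin <= width_px:
                ring[y, x] = True
    return ring


def pairwise_auc(case_scores, control_scores) -> float:
    """Mann-Whitney statistic: P(case > control) + 0.5 P(tie)."""
    total = 0.0
    for c in case_scores:
        for k in control_scores:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(case_scores) * len(control_scores))


def exhaustive_youden(case_scores, control_scores):
    """Best J over a dense sweep of cutoffs (score > t rule)."""
    scores = sorted(set(list(case_scores) + list(control_scores)))
    candidates = [scores[0] - 1.0]
    for a, b in zip(scores[:-1], scores[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(scores[-1] + 1.0)
    best = None
    for t in candidates:
        sens = sum(1 for s in case_scores if s > t) / len(case_scores)
        spec = sum(1 for s in control_scores if s <= t) / len(control_scores)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-15:
            best = (j, t, sens, spec)
    return best
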