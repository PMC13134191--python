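"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written the slow, obvious way (explicit
loops, exhaustive enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def dice_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    inter = 0
    na = nb = 0
    for idx in np.ndindex(a.shape):
        na += bool(a[idx])
        nb += bool(b[idx])
        inter += bool(a[idx]) and bool(b[idx])
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def _surface_points(mask: np.ndarray) -> list[tuple[int, int, int]]:
    pts = []
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        for ax in range(3):
            for d in (-1, 1):
                nb = list(idx)
                nb[ax] += d
                if not (0 <= nb[ax] < mask.shape[ax]) or not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return pts


def masd_bruteforce(gt: np.ndarray, pred: np.ndarray, spacing) -> float | None:
    gt = np.asarray(gt, bool)
    pred = np.asarray(pred, bool)
    sg = _surface_points(gt)
    sp_ = _surface_points(pred)
    if not sg or not sp_:
        return None
    sc = np.asarray(spacing, float)

    def mean_min(src, dst):
        total = 0.0
        for p in src:
            best = min(
                np.sqrt((((np.array(p) - np.array(q)) * sc) ** 2).sum()) for q in dst
            )
            total += best
        return total / len(src)

    return 0.5 * (mean_min(sg, sp_) + mean_min(sp_, sg))


def auc_bruteforce(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def neighbors26(idx, shape):
    out = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            out.append(nb)
    return out


def glszm_zones_bruteforce(levels: np.ndarray, mask: np.ndarray):
    """(level, size) per 26-connected equal-level zone via explicit flood fill."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    seen = np.zeros(levels.shape, bool)
    zones = []
    for start in np.ndindex(levels.shape):
        if not mask[start] or seen[start]:
            continue
        lvl = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for nb in neighbors26(cur, levels.shape):
                if mask[nb] and not seen[nb] and levels[nb] == lvl:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(lvl), size))
    return zones


def lae_bruteforce(levels, mask) -> float:
    zones = glszm_zones_bruteforce(levels, mask)
    return sum(s ** 2 for _, s in zones) / len(zones)


def gldm_entries_bruteforce(levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0):
    """(level, dependence) per ROI voxel by explicit neighbor counting."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    entries = []
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        dep = 1
        for nb in neighbors26(idx, levels.shape):
            if mask[nb] and abs(int(levels[nb]) - int(levels[idx])) <= alpha:
                dep += 1
        entries.append((int(levels[idx]), dep))
    return entries


def ngtdm_bruteforce(levels: np.ndarray, mask: np.ndarray):
    """Per-level (n_i, p_i, s_i) by direct evaluation; returns dicts keyed by level."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    n: dict[int, int] = {}
    s: dict[int, float] = {}
    nvp = 0
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        nb_vals = [int(levels[nb]) for nb in neighbors26(idx, levels.shape) if mask[nb]]
        if not nb_vals:
            continue
        nvp += 1
        lvl = int(levels[idx])
        n[lvl] = n.get(lvl, 0) + 1
        s[lvl] = s.get(lvl, 0.0) + abs(lvl - sum(nb_vals) / len(nb_vals))
    p = {k: v / nvp for k, v in n.items()}
    return n, p, s, nvp


def ngtdm_strength_bruteforce(levels, mask) -> float:
    n, p, s, nvp = ngtdm_bruteforce(levels, mask)
    s_total = sum(s.values())
    if s_total == 0:
        return 0.0
    num = 0.0
    for i in p:
        for j in p:
            num += (p[i] + p[j]) * (i - j) ** 2
    return num / s_total


def separable_convolve_bruteforce(volume: np.ndarray, fx, fy, fz) -> np.ndarray:
    """Direct separable convolution with periodic boundaries (matches the
    package's wavelet sub-band filtering contract)."""
    volume = np.asarray(volume, float)
    out = np.zeros_like(volume)
    nx, ny, nz = volume.shape
    fx, fy, fz = (np.asarray(f, float) for f in (fx, fy, fz))

    def conv_axis(data, filt, axis):
        res = np.zeros_like(data)
        n = data.shape[axis]
        m = len(filt)
        # scipy.ndimage.convolve1d alignment: origin at the filter center
        half = m // 2
        for i in range(n):
            acc = np.zeros([s for a, s in enumerate(data.shape) if a != axis])
            for k in range(m):
                src = (i + half - k) % n
                sl = [slice(None)] * 3
                sl[axis] = src
                acc = acc + filt[k] * data[tuple(sl)]
            sl = [slice(None)] * 3
            sl[axis] = i
            res[tuple(sl)] = acc
        return res

    out = conv_axis(volume, fx, 0)
    out = conv_axis(out, fy, 1)
    out = conv_axis(out, fz, 2)
    return out


def point_in_hull_fill(mask: np.ndarray) -> np.ndarray:
    """Half-space point-in-convex-hull filling of a single binary component."""
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask).astype(float)
    if len(pts) < 4:
        return mask.copy()
    try:
        hull = ConvexHull(pts)
    except Exception:
        return mask.copy()
    out = np.zeros_like(mask, dtype=bool)
    eqs = hull.equations  # (A | b): A @ x + b <= 0 inside
    for idx in np.ndindex(mask.shape):
        x = np.asarray(idx, float)
        if np.all(eqs[:, :3] @ x + eqs[:, 3] <= 1e-9):
            out[idx] = True
    return out


def mann_whitney_u_exact_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (n1+n2 <= 12)."""
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = {}

    def u_stat(group_idx):
        vals = sorted((pooled[i], i) for i in range(len(pooled)))
        # midranks
        r = [0.0] * len(pooled)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[j + 1][0] == vals[i][0]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[vals[k][1]] = avg
            i = j + 1
        rsum = sum(r[i] for i in group_idx)
        return rsum - n1 * (n1 + 1) / 2.0

    obs = u_stat(list(range(n1)))
    mu = n1 * n2 / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = u_stat(list(comb))
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return obs, count / total
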