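"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (python loops, exhaustive scans,
per-pixel searches) and shares no code path with the package.
"""
from __future__ import annotations

import numpy as np


def loop_integrated_intensity(channel: np.ndarray, mask: np.ndarray) -> int:
    total = 0
    h, w = channel.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                total += int(channel[r, c])
    return total


def loop_otsu(hist) -> int:
    """Exhaustive between-class-variance scan, plain python."""
    hist = list(hist)
    total = sum(hist)
    total_sum = sum(v * n for v, n in enumerate(hist))
    best_t, best_bcv = None, -1.0
    n0 = 0.0
    s0 = 0.0
    for t in range(1, len(hist)):
        n0 += hist[t - 1]
        s0 += (t - 1) * hist[t - 1]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = s0 / n0
        mu1 = (total_sum - s0) / n1
        bcv = n0 * n1 * (mu0 - mu1) ** 2
        if bcv > best_bcv + 1e-9 * max(best_bcv, 1.0):
            best_bcv, best_t = bcv, t
    assert best_t is not None
    return best_t


def bfs_component_count(binary: np.ndarray, min_area: int, max_area: int) -> int:
    """8-connected component count with an area filter, by flood fill."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            area = 0
            while stack:
                r, c = stack.pop()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and binary[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if min_area <= area <= max_area:
                count += 1
    return count


def nearest_label_dilation(labels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel nearest-original-label assignment within ``radius``.

    Distances are computed by explicit broadcasting against each label's
    pixel list; ties go to the lower label id.
    """
    out = np.zeros_like(labels)
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    best = np.full((h, w), np.inf)
    for k in range(1, int(labels.max()) + 1):
        pr, pc = np.nonzero(labels == k)
        if pr.size == 0:
            continue
        d2 = ((rr[..., None] - pr) ** 2 + (cc[..., None] - pc) ** 2).min(axis=-1)
        d = np.sqrt(d2)
        take = (d <= radius) & (d < best)
        out[take] = k
        best[take] = d[take]
    return out


def anova_two_way_sums(values: dict[tuple[str, str], float]):
    """Explicit-sum randomized-complete-block decomposition.

    ``values[(group, culture)]`` -> dict with SS/df/MS/F for treatment,
    culture ("block") and residual, computed from group/block/grand means
    by direct summation.
    """
    groups = sorted({g for g, _ in values})
    blocks = sorted({b for _, b in values})
    a, b = len(groups), len(blocks)
    grand = sum(values.values()) / (a * b)
    gmean = {g: sum(values[(g, bl)] for bl in blocks) / b for g in groups}
    bmean = {bl: sum(values[(g, bl)] for g in groups) / a for bl in blocks}
    ss_t = b * sum((gmean[g] - grand) ** 2 for g in groups)
    ss_b = a * sum((bmean[bl] - grand) ** 2 for bl in blocks)
    ss_res = sum((values[(g, bl)] - gmean[g] - bmean[bl] + grand) ** 2
                 for g in groups for bl in blocks)
    df_t, df_b, df_res = a - 1, b - 1, (a - 1) * (b - 1)
    ms_res = ss_res / df_res
    return {
        "ss_treatment": ss_t, "df_treatment": df_t,
        "ms_treatment": ss_t / df_t, "f_treatment": (ss_t / df_t) / ms_res,
        "ss_culture": ss_b, "df_culture": df_b,
        "ss_residual": ss_res, "df_residual": df_res, "ms_residual": ms_res,
    }


def anova_one_way_sums(groups: dict[str, list[float]]):
    """Explicit-sum one-way decomposition."""
    n_total = sum(len(v) for v in groups.values())
    grand = sum(sum(v) for v in groups.values()) / n_total
    ss_between = sum(len(v) * (sum(v) / len(v) - grand) ** 2
                     for v in groups.values())
    ss_within = sum(sum((x - sum(v) / len(v)) ** 2 for x in v)
                    for v in groups.values())
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    return {
        "ss_treatment": ss_between, "df_treatment": df_b,
        "ss_residual": ss_within, "df_residual": df_w,
        "f_treatment": (ss_between / df_b) / (ss_within / df_w),
    }


def pooled_t(x: list[float], y: list[float]):
    """Textbook pooled-variance unpaired t statistic."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def wol_scan(fluor: np.ndarray, window_size: int, baseline_cycles: int,
             min_efficiency: float = 1.1, plateau_fraction: float = 0.08,
             noise_floor_sd: float = 5.0):
    """Exhaustive all-windows regression scan with closed-form least squares."""
    f = np.asarray(fluor, dtype=float)
    corrected = f - f[:baseline_cycles].mean()
    ceiling = plateau_fraction * max(corrected)
    floor = noise_floor_sd * float(np.std(f[:baseline_cycles])) if baseline_cycles > 1 else 0.0
    best = None
    for start in range(len(f) - window_size + 1):
        seg = corrected[start:start + window_size]
        if any(s <= floor for s in seg) or max(seg) > ceiling:
            continue
        x = np.arange(start, start + window_size, dtype=float)
        y = np.log10(seg)
        xm, ym = x.mean(), y.mean()
        sxx = ((x - xm) ** 2).sum()
        sxy = ((x - xm) * (y - ym)).sum()
        slope = sxy / sxx
        if 10.0 ** slope <= min_efficiency:
            continue
        syy = ((y - ym) ** 2).sum()
        r2 = 1.0 if syy == 0 else (sxy ** 2) / (sxx * syy)
        if best is None or r2 > best[1]:
            best = (start, r2, 10.0 ** slope)
    return best  # (window start, r2, efficiency) or None
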