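"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, flood fill, direct
sums of squares) kept independent of the library code paths they check.
"""

import numpy as np


def boxcar_smooth_naive(img: np.ndarray, size: int) -> np.ndarray:
    """Mean filter with nearest-edge clamping, by explicit loops."""
    ns, nt = img.shape
    half = size // 2
    out = np.empty_like(img, dtype=float)
    for i in range(ns):
        for j in range(nt):
            acc = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    ii = min(max(i + di, 0), ns - 1)
                    jj = min(max(j + dj, 0), nt - 1)
                    acc += img[ii, jj]
            out[i, j] = acc / (size * size)
    return out


def brute_force_spark_regions(dff0, mask, threshold, min_area, merge_gap,
                              smooth_size=3):
    """Threshold + connected components by flood fill.

    Mirrors the documented detection semantics: smooth, threshold, dilate
    the binary image by ``merge_gap`` (8-neighbourhood), label the dilated
    image, keep only true supra-threshold pixels, drop small regions.
    Returns a list of (peak_i, peak_j, area) sorted by peak coordinates,
    peak = argmax of the smoothed image within the region.
    """
    sm = boxcar_smooth_naive(np.asarray(dff0, float), smooth_size)
    ns, nt = sm.shape
    binary = [[bool(sm[i][j] > threshold and mask[i][j])
               for j in range(nt)] for i in range(ns)]
    grown = [row[:] for row in binary]
    for _ in range(merge_gap):
        nxt = [row[:] for row in grown]
        for i in range(ns):
            for j in range(nt):
                if grown[i][j]:
                    continue
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < ns and 0 <= jj < nt and grown[ii][jj]:
                            nxt[i][j] = True
        grown = nxt
    seen = [[False] * nt for _ in range(ns)]
    regions = []
    for i0 in range(ns):
        for j0 in range(nt):
            if not grown[i0][j0] or seen[i0][j0]:
                continue
            stack = [(i0, j0)]
            seen[i0][j0] = True
            members = []
            while stack:
                i, j = stack.pop()
                if binary[i][j]:
                    members.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if (0 <= ii < ns and 0 <= jj < nt
                                and grown[ii][jj] and not seen[ii][jj]):
                            seen[ii][jj] = True
                            stack.append((ii, jj))
            if len(members) < min_area:
                continue
            peak = max(members, key=lambda p: sm[p[0], p[1]])
            regions.append((peak[0], peak[1], len(members)))
    regions.sort(key=lambda r: (r[1], r[0]))
    return regions


def anova_f_sum_of_squares(groups):
    """One-way ANOVA F by direct between/within sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = all_vals.size - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def auroc_rank(scores, labels):
    """AUROC by the rank-sum (Mann-Whitney) formula."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    ranks[order] = np.arange(1, scores.size + 1)
    # midranks for ties
    s_sorted = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
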