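"""Independent brute-force GLCM oracle for the tests.

Everything here is deliberately naive and self-contained: explicit loops
over windows, directions and pixel pairs, an explicit G x G co-occurrence
matrix, and textbook formulas.  It shares no code with the package paths it
checks (only the same definitions).
"""

import numpy as np

OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}
METRICS = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")


def oracle_quantize(grid, mask, G, p_lo=1.0, p_hi=99.0):
    vals = np.asarray(grid, float)[np.asarray(mask, bool)]
    lo = np.percentile(vals, p_lo)
    hi = np.percentile(vals, p_hi)
    out = np.zeros(np.shape(grid), dtype=int)
    if hi > lo:
        for r in range(out.shape[0]):
            for c in range(out.shape[1]):
                s = (grid[r][c] - lo) / (hi - lo)
                s = min(max(s, 0.0), 1.0)
                out[r, c] = min(int(s * G), G - 1)
    return out


def oracle_window_features(levels, valid, direction, G):
    """Feature dict of one window for one direction, or None if no pair."""
    dr, dc = OFFSETS[direction]
    H, W = levels.shape
    P = np.zeros((G, G))
    npairs = 0
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and valid[r, c] and valid[r2, c2]:
                i, j = levels[r, c], levels[r2, c2]
                P[i, j] += 1
                P[j, i] += 1
                npairs += 1
    if npairs == 0:
        return None
    P = P / P.sum()
    mea = var = hom = con = dis = ent = sec = 0.0
    u = 0.0
    for i in range(G):
        for j in range(G):
            u += i * P[i, j]
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            mea += i * p
            var += (i - u) ** 2 * p
            hom += p / (1 + (i - j) ** 2)
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            if p > 0:
                ent -= p * np.log(p)
            sec += p * p
    mi = sum(i * P[i, j] for i in range(G) for j in range(G))
    mj = sum(j * P[i, j] for i in range(G) for j in range(G))
    vi = sum((i - mi) ** 2 * P[i, j] for i in range(G) for j in range(G))
    vj = sum((j - mj) ** 2 * P[i, j] for i in range(G) for j in range(G))
    if vi * vj > 0:
        cor = sum((i - mj) * (j - mi) * P[i, j]
                  for i in range(G) for j in range(G)) / np.sqrt(vi * vj)
    else:
        cor = np.nan
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con, "DIS": dis,
            "ENT": ent, "SEC": sec, "COR": cor}


def oracle_band_textures(levels, valid, G, window=5, min_frac=0.6,
                         directions=(0, 45, 90, 135)):
    """Plot-level values of one quantized band, brute force."""
    H, W = levels.shape
    sums = {m: [] for m in METRICS}
    for r0 in range(H - window + 1):
        for c0 in range(W - window + 1):
            lv = levels[r0:r0 + window, c0:c0 + window]
            vv = valid[r0:r0 + window, c0:c0 + window]
            if vv.mean() < min_frac:
                continue
            per_dir = {m: [] for m in METRICS}
            for d in directions:
                f = oracle_window_features(lv, vv, d, G)
                if f is None:
                    continue
                for m in METRICS:
                    per_dir[m].append(f[m])
            for m in METRICS:
                xs = [x for x in per_dir[m] if np.isfinite(x)]
                if xs:
                    sums[m].append(float(np.mean(xs)))
    return {m: (float(np.mean(v)) if v else np.nan) for m, v in sums.items()}
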