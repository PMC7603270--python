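"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (explicit loops, no shared code
with the package) so it can serve as a second, independent route to the
same quantities.
"""

import math

import numpy as np


def brute_runs(levels, mask, direction):
    """Enumerate maximal same-level in-mask runs by walking each voxel."""
    shape = levels.shape
    d = direction

    def inside(p):
        return all(0 <= p[i] < shape[i] for i in range(3))

    def at(p):
        return levels[p[0], p[1], p[2]]

    def masked(p):
        return bool(mask[p[0], p[1], p[2]])

    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                p = (x, y, z)
                if not masked(p):
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if inside(prev) and masked(prev) and at(prev) == at(p):
                    continue  # not a run start
                length = 1
                nxt = (x + d[0], y + d[1], z + d[2])
                while inside(nxt) and masked(nxt) and at(nxt) == at(p):
                    length += 1
                    nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                runs.append((int(at(p)), length))
    return runs


def brute_glrlm_features(levels, mask, directions):
    acc = {k: 0.0 for k in ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                            "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE")}
    n_vox = int(np.sum(mask))
    for d in directions:
        runs = brute_runs(levels, mask, d)
        nr = len(runs)
        gl_counts = {}
        rl_counts = {}
        for i, j in runs:
            gl_counts[i] = gl_counts.get(i, 0) + 1
            rl_counts[j] = rl_counts.get(j, 0) + 1
        acc["SRE"] += sum(1.0 / j**2 for _, j in runs) / nr
        acc["LRE"] += sum(j**2 for _, j in runs) / nr
        acc["GLN"] += sum(c**2 for c in gl_counts.values()) / nr
        acc["RLN"] += sum(c**2 for c in rl_counts.values()) / nr
        acc["RP"] += nr / n_vox
        acc["LGRE"] += sum(1.0 / i**2 for i, _ in runs) / nr
        acc["HGRE"] += sum(i**2 for i, _ in runs) / nr
        acc["SRLGLE"] += sum(1.0 / (i**2 * j**2) for i, j in runs) / nr
        acc["SRHGLE"] += sum(i**2 / j**2 for i, j in runs) / nr
        acc["LRLGLE"] += sum(j**2 / i**2 for i, j in runs) / nr
        acc["LRHGLE"] += sum(i**2 * j**2 for i, j in runs) / nr
    return {k: v / len(directions) for k, v in acc.items()}


def brute_glcm_imc1(levels, mask, directions):
    """Direction-averaged IMC1 from explicitly enumerated voxel pairs."""
    shape = levels.shape
    n_levels = int(levels.max())
    vals = []
    for d in directions:
        counts = np.zeros((n_levels, n_levels))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    q = (x + d[0], y + d[1], z + d[2])
                    if not all(0 <= q[i] < shape[i] for i in range(3)):
                        continue
                    if not (mask[x, y, z] and mask[q]):
                        continue
                    counts[levels[x, y, z] - 1, levels[q] - 1] += 1
        counts = counts + counts.T
        if counts.sum() == 0:
            continue
        p = counts / counts.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        hx = -sum(v * math.log2(v) for v in px if v > 0)
        hy = -sum(v * math.log2(v) for v in py if v > 0)
        if max(hx, hy) == 0:
            vals.append(0.0)
            continue
        hxy = hxy1 = 0.0
        for i in range(n_levels):
            for j in range(n_levels):
                if p[i, j] > 0:
                    hxy -= p[i, j] * math.log2(p[i, j])
                    hxy1 -= p[i, j] * math.log2(px[i] * py[j])
        vals.append((hxy - hxy1) / max(hx, hy))
    return float(np.mean(vals)) if vals else 0.0


def brute_first_order(values, n_bins):
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    lo, hi = x[0], x[-1]
    counts = [0] * n_bins
    for v in x:
        b = n_bins - 1 if v == hi else int((v - lo) / (hi - lo) * n_bins) \
            if hi > lo else 0
        counts[min(b, n_bins - 1)] += 1
    probs = [c / n for c in counts if c > 0]
    med = (x[n // 2] if n % 2 else 0.5 * (x[n // 2 - 1] + x[n // 2]))
    # linear-interpolation quantile, matching the standard convention
    h = (n - 1) * 0.75
    q3 = x[int(h)] + (h - int(h)) * (x[min(int(h) + 1, n - 1)] - x[int(h)])
    skew = 0.0 if sd == 0 else sum((v - mean) ** 3 for v in x) / n / sd**3
    return {
        "Energy": sum(v**2 for v in x),
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Maximum": hi,
        "Mean": mean,
        "Mean absolute deviation": sum(abs(v - mean) for v in x) / n,
        "Median": med,
        "Range": hi - lo,
        "Root mean square": math.sqrt(sum(v**2 for v in x) / n),
        "Skewness": skew,
        "Standard deviation": sd,
        "Third quartile": q3,
        "Uniformity": sum(p**2 for p in probs),
        "Variance": var,
    }


def irls_logistic(x, y, ridge, max_iter=200, tol=1e-12):
    """Penalized IRLS (Newton) for logistic regression.

    Ridge applies to coefficients only (not the intercept) on the given
    feature scale; returns (coefficients, intercept).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, p = x.shape
    xa = np.hstack([x, np.ones((n, 1))])
    beta = np.zeros(p + 1)
    pen = np.diag([ridge] * p + [0.0])
    for _ in range(max_iter):
        eta = xa @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = xa.T @ (y - mu) - pen @ beta
        hess = xa.T @ (xa * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[:p], beta[p]


def brute_logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank statistic from the explicit risk-set table."""
    records = ([(t, e, 0) for t, e in zip(times_a, events_a)]
               + [(t, e, 1) for t, e in zip(times_b, events_b)])
    event_times = sorted({t for t, e, _ in records if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [r for r in records if r[0] >= t]
        n = len(at_risk)
        n1 = sum(1 for r in at_risk if r[2] == 0)
        d = sum(1 for r in at_risk if r[0] == t and r[1] == 1)
        d1 = sum(1 for r in at_risk if r[0] == t and r[1] == 1 and r[2] == 0)
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
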