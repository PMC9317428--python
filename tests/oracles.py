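"""Independent brute-force oracles for radiomic features and statistics.

Everything here is written as plain Python loops over voxels, pairs, runs,
zones and matrix entries — no shared code with the production
implementations — so that agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _log2(x: float) -> float:
    return math.log(x, 2)


def percentile(values, q) -> float:
    """Linear interpolation between order statistics."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


# ---------------------------------------------------------------------------
# first-order / intensity histogram
# ---------------------------------------------------------------------------

def first_order(values, voxel_volume=None) -> dict[str, float]:
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    p10, p25, med, p75, p90 = (percentile(xs, q) for q in (10, 25, 50, 75, 90))
    robust = [x for x in xs if p10 <= x <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    rmad = sum(abs(x - rmean) for x in robust) / len(robust) if robust else 0.0
    energy = sum(x * x for x in xs)
    out = {
        "Mean": mean,
        "Variance": m2,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Median": med,
        "Minimum": min(xs),
        "Percentile10": p10,
        "Percentile25": p25,
        "Percentile75": p75,
        "Percentile90": p90,
        "Maximum": max(xs),
        "InterquartileRange": p75 - p25,
        "Range": max(xs) - min(xs),
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in xs) / n,
        "RobustMeanAbsoluteDeviation": rmad,
        "MedianAbsoluteDeviation": sum(abs(x - med) for x in xs) / n,
        "CoefficientOfVariation": math.sqrt(m2) / mean if mean != 0 else 0.0,
        "QuartileCoefficientOfDispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
        ),
        "Energy": energy,
        "RootMeanSquare": math.sqrt(energy / n),
    }
    if voxel_volume is not None:
        out["TotalEnergy"] = voxel_volume * energy
    return out


def intensity_histogram(levels, ng: int) -> dict[str, float]:
    xs = [int(v) for v in levels]
    counts = [0] * ng
    for x in xs:
        counts[x - 1] += 1
    n = len(xs)
    probs = [c / n for c in counts]
    base = first_order(xs)
    mode = 1 + max(range(ng), key=lambda i: (counts[i], -i))
    if ng == 1:
        grad = [0.0]
    else:
        grad = [0.0] * ng
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        for k in range(1, ng - 1):
            grad[k] = (counts[k + 1] - counts[k - 1]) / 2.0
    imax = max(range(ng), key=lambda i: (grad[i], -i))
    imin = min(range(ng), key=lambda i: (grad[i], i))
    out = {
        k: base[k]
        for k in (
            "Mean", "Variance", "Skewness", "Kurtosis", "Median", "Minimum",
            "Percentile10", "Percentile90", "Maximum", "InterquartileRange",
            "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
            "MedianAbsoluteDeviation", "CoefficientOfVariation",
            "QuartileCoefficientOfDispersion",
        )
    }
    out["Mode"] = float(mode)
    out["Entropy"] = -sum(p * _log2(p) for p in probs if p > 0)
    out["Uniformity"] = sum(p * p for p in probs)
    out["MaximumHistogramGradient"] = float(grad[imax])
    out["MaximumHistogramGradientLevel"] = float(imax + 1)
    out["MinimumHistogramGradient"] = float(grad[imin])
    out["MinimumHistogramGradientLevel"] = float(imin + 1)
    return out


# ---------------------------------------------------------------------------
# matrix construction by exhaustive enumeration
# ---------------------------------------------------------------------------

def _masked_voxels(mask):
    nx, ny, nz = len(mask), len(mask[0]), len(mask[0][0])
    return [
        (x, y, z)
        for x in range(nx)
        for y in range(ny)
        for z in range(nz)
        if mask[x][y][z]
    ]


def glcm_counts(levels, mask) -> dict[tuple[int, int], float]:
    """Every ordered in-mask voxel pair at any of the 26 unit offsets."""
    vox = set(_masked_voxels(mask))
    counts: dict[tuple[int, int], float] = {}
    for (x, y, z) in vox:
        for dx, dy, dz in OFFSETS_26:
            w = (x + dx, y + dy, z + dz)
            if w in vox:
                key = (levels[x][y][z], levels[w[0]][w[1]][w[2]])
                counts[key] = counts.get(key, 0.0) + 1.0
    return counts


def glcm_probabilities(levels, mask) -> dict[tuple[int, int], float]:
    counts = glcm_counts(levels, mask)
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def glrlm_runs(levels, mask) -> list[tuple[int, int]]:
    """All maximal equal-level runs for each of the 13 directions."""
    vox = set(_masked_voxels(mask))
    runs = []
    for d in DIRECTIONS_13:
        for v in vox:
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if prev in vox and levels[prev[0]][prev[1]][prev[2]] == levels[v[0]][v[1]][v[2]]:
                continue
            length = 1
            nxt = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while nxt in vox and levels[nxt[0]][nxt[1]][nxt[2]] == levels[v[0]][v[1]][v[2]]:
                length += 1
                nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
            runs.append((levels[v[0]][v[1]][v[2]], length))
    return runs


def glszm_zones(levels, mask) -> list[tuple[int, int]]:
    """26-connected equal-level zones by flood fill."""
    vox = set(_masked_voxels(mask))
    seen = set()
    zones = []
    for v in sorted(vox):
        if v in seen:
            continue
        lev = levels[v[0]][v[1]][v[2]]
        stack, comp = [v], set()
        seen.add(v)
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for dx, dy, dz in OFFSETS_26:
                w = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                if w in vox and w not in seen and levels[w[0]][w[1]][w[2]] == lev:
                    seen.add(w)
                    stack.append(w)
        zones.append((lev, len(comp)))
    return zones


def ngtdm_accumulators(levels, mask, ng: int):
    vox = set(_masked_voxels(mask))
    n_i = [0.0] * ng
    s_i = [0.0] * ng
    for v in vox:
        nbrs = []
        for dx, dy, dz in OFFSETS_26:
            w = (v[0] + dx, v[1] + dy, v[2] + dz)
            if w in vox:
                nbrs.append(levels[w[0]][w[1]][w[2]])
        if not nbrs:
            continue
        lev = levels[v[0]][v[1]][v[2]]
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - sum(nbrs) / len(nbrs))
    return n_i, s_i


# ---------------------------------------------------------------------------
# feature formulas evaluated entry by entry
# ---------------------------------------------------------------------------

def glcm_features(p: dict[tuple[int, int], float], ng: int) -> dict[str, float]:
    px = [sum(v for (i, j), v in p.items() if i == k) for k in range(1, ng + 1)]
    py = [sum(v for (i, j), v in p.items() if j == k) for k in range(1, ng + 1)]
    mu_x = sum((k + 1) * px[k] for k in range(ng))
    mu_y = sum((k + 1) * py[k] for k in range(ng))
    sd_x = math.sqrt(sum(px[k] * (k + 1 - mu_x) ** 2 for k in range(ng)))
    sd_y = math.sqrt(sum(py[k] * (k + 1 - mu_y) ** 2 for k in range(ng)))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j - 2] += v
    da = sum(k * p_diff[k] for k in range(ng))
    sa = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))
    hxy = -sum(v * _log2(v) for v in p.values() if v > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hxy1 = -sum(
        v * _log2(px[i - 1] * py[j - 1]) for (i, j), v in p.items() if v > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    auto = sum(i * j * v for (i, j), v in p.items())
    out = {
        "JointMaximum": max(p.values()),
        "JointAverage": sum(i * v for (i, j), v in p.items()),
        "JointVariance": 0.0,
        "JointEntropy": hxy,
        "DifferenceAverage": da,
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "DifferenceEntropy": -sum(v * _log2(v) for v in p_diff if v > 0),
        "SumAverage": sa,
        "SumVariance": sum((k + 2 - sa) ** 2 * p_sum[k] for k in range(2 * ng - 1)),
        "SumEntropy": -sum(v * _log2(v) for v in p_sum if v > 0),
        "AngularSecondMoment": sum(v * v for v in p.values()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "InverseDifference": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "InverseDifferenceNormalised": sum(
            v / (1 + abs(i - j) / ng) for (i, j), v in p.items()
        ),
        "InverseDifferenceMoment": sum(
            v / (1 + (i - j) ** 2) for (i, j), v in p.items()
        ),
        "InverseDifferenceMomentNormalised": sum(
            v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()
        ),
        "InverseVariance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "Correlation": (
            (auto - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
        ),
        "Autocorrelation": auto,
        "ClusterTendency": sum(
            (i + j - mu_x - mu_y) ** 2 * v for (i, j), v in p.items()
        ),
        "ClusterShade": sum(
            (i + j - mu_x - mu_y) ** 3 * v for (i, j), v in p.items()
        ),
        "ClusterProminence": sum(
            (i + j - mu_x - mu_y) ** 4 * v for (i, j), v in p.items()
        ),
        "InformationCorrelation1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "InformationCorrelation2": math.sqrt(
            max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
        ),
    }
    mu = out["JointAverage"]
    out["JointVariance"] = sum((i - mu) ** 2 * v for (i, j), v in p.items())
    return out


def _rl_features(items, n_units, kind):
    """items: (level, length) runs or (level, size) zones."""
    ns = len(items)
    f = {}
    short, long_ = ("ShortRun", "LongRun") if kind == "run" else ("SmallZone", "LargeZone")
    lw = "RunLength" if kind == "run" else "ZoneSize"
    lg = "Run" if kind == "run" else "Zone"
    f[f"{short}Emphasis"] = sum(1.0 / l**2 for _, l in items) / ns
    f[f"{long_}Emphasis"] = sum(float(l**2) for _, l in items) / ns
    f[f"LowGrayLevel{lg}Emphasis"] = sum(1.0 / i**2 for i, _ in items) / ns
    f[f"HighGrayLevel{lg}Emphasis"] = sum(float(i**2) for i, _ in items) / ns
    f[f"{short}LowGrayLevelEmphasis"] = sum(1.0 / (i**2 * l**2) for i, l in items) / ns
    f[f"{short}HighGrayLevelEmphasis"] = sum(i**2 / l**2 for i, l in items) / ns
    f[f"{long_}LowGrayLevelEmphasis"] = sum(l**2 / i**2 for i, l in items) / ns
    f[f"{long_}HighGrayLevelEmphasis"] = sum(float(i**2 * l**2) for i, l in items) / ns
    level_counts: dict[int, int] = {}
    len_counts: dict[int, int] = {}
    for i, l in items:
        level_counts[i] = level_counts.get(i, 0) + 1
        len_counts[l] = len_counts.get(l, 0) + 1
    f["GrayLevelNonUniformity"] = sum(c**2 for c in level_counts.values()) / ns
    f["GrayLevelNonUniformityNormalised"] = (
        sum(c**2 for c in level_counts.values()) / ns**2
    )
    f[f"{lw}NonUniformity"] = sum(c**2 for c in len_counts.values()) / ns
    f[f"{lw}NonUniformityNormalised"] = sum(c**2 for c in len_counts.values()) / ns**2
    f["RunPercentage" if kind == "run" else "ZonePercentage"] = ns / n_units
    mu_i = sum(i for i, _ in items) / ns
    mu_l = sum(l for _, l in items) / ns
    f["GrayLevelVariance"] = sum((i - mu_i) ** 2 for i, _ in items) / ns
    f[f"{lw}Variance"] = sum((l - mu_l) ** 2 for _, l in items) / ns
    probs: dict[tuple[int, int], float] = {}
    for item in items:
        probs[item] = probs.get(item, 0.0) + 1.0 / ns
    f["RunEntropy" if kind == "run" else "ZoneEntropy"] = -sum(
        v * _log2(v) for v in probs.values()
    )
    return f


def glrlm_features(runs, n_masked: int, n_directions: int = 13) -> dict[str, float]:
    return _rl_features(runs, n_directions * n_masked, "run")


def glszm_features(zones, n_masked: int) -> dict[str, float]:
    return _rl_features(zones, n_masked, "zone")


def ngtdm_features(n_i, s_i, coarseness_cap: float = 1.0e6) -> dict[str, float]:
    ng = len(n_i)
    nv = sum(n_i)
    p = [c / nv for c in n_i]
    present = [k for k in range(ng) if p[k] > 0]
    denom = sum(p[k] * s_i[k] for k in range(ng))
    f = {"Coarseness": 1.0 / denom if denom > 0 else coarseness_cap}
    ngp = len(present)
    if ngp > 1:
        acc = sum(
            p[a] * p[b] * (a - b) ** 2 for a in present for b in present
        )
        f["Contrast"] = acc / (ngp * (ngp - 1)) * sum(s_i) / nv
    else:
        f["Contrast"] = 0.0
    busy = sum(
        abs((a + 1) * p[a] - (b + 1) * p[b]) for a in present for b in present
    )
    f["Busyness"] = denom / busy if busy > 0 else 0.0
    f["Complexity"] = sum(
        abs(a - b) * (p[a] * s_i[a] + p[b] * s_i[b]) / (p[a] + p[b])
        for a in present
        for b in present
    ) / nv
    s_tot = sum(s_i)
    f["Strength"] = (
        sum((p[a] + p[b]) * (a - b) ** 2 for a in present for b in present) / s_tot
        if s_tot > 0
        else 0.0
    )
    return f


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def pooled_t(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance Student t and two-sided p (closed form)."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), na + nb - 2)
    return t, p
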