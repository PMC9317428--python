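"""Texture features computed from GLCM/GLRLM/GLSZM/NGTDM matrices.

Conventions (shared with the enumeration oracle in the test suite):

* entropies use log base 2, with 0 * log 0 = 0;
* degenerate inputs take documented fallbacks rather than NaN —
  a single-level matrix has correlation 0, information correlations 0,
  inverse variance 0; NGTDM coarseness is capped at 1e6 when every
  neighbourhood difference vanishes, and contrast/busyness/strength are 0
  when undefined.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glcm_features",
    "glcm_cluster_shade",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "COARSENESS_CAP",
]

COARSENESS_CAP = 1.0e6


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _check_glcm(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be a square matrix")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalised to probabilities")
    return p


def glcm_cluster_shade(p: np.ndarray) -> float:
    """Cluster shade: third co-occurrence moment sum_ij (i+j-mu_i-mu_j)^3 p(i,j).

    Stored signed; a negatively skewed co-occurrence distribution (dark
    outlier levels) gives negative values.  Reports that mirror the study
    table print the absolute value.
    """
    p = _check_glcm(p)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    mu_i = (p.sum(axis=1) * i).sum()
    mu_j = (p.sum(axis=0) * i).sum()
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return float((((ii + jj - mu_i - mu_j) ** 3) * p).sum())


def glcm_features(p: np.ndarray) -> dict[str, float]:
    p = _check_glcm(p)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sd_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sd_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # difference and sum marginals
    k_diff = np.arange(ng, dtype=float)  # |i-j| in 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    pxy = np.outer(px, py)
    joint_nz = p > 0
    hxy1 = float(-(p[joint_nz] * np.log2(pxy[joint_nz])).sum())
    hxy2 = float(-_xlog2(pxy).sum())

    feats: dict[str, float] = {}
    feats["JointMaximum"] = float(p.max())
    feats["JointAverage"] = mu_x
    feats["JointVariance"] = float(((ii - mu_x) ** 2 * p).sum())
    feats["JointEntropy"] = hxy
    feats["DifferenceAverage"] = da
    feats["DifferenceVariance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    feats["DifferenceEntropy"] = float(-_xlog2(p_diff).sum())
    feats["SumAverage"] = sa
    feats["SumVariance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    feats["SumEntropy"] = float(-_xlog2(p_sum).sum())
    feats["AngularSecondMoment"] = float((p**2).sum())
    feats["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    feats["Dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    feats["InverseDifference"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    feats["InverseDifferenceNormalised"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    feats["InverseDifferenceMoment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    feats["InverseDifferenceMomentNormalised"] = float(
        (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
    )
    off = ii != jj
    feats["InverseVariance"] = float((p[off] / (ii[off] - jj[off]) ** 2).sum())
    auto = float((ii * jj * p).sum())
    feats["Correlation"] = (
        (auto - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
    )
    feats["Autocorrelation"] = auto
    centred = ii + jj - mu_x - mu_y
    feats["ClusterTendency"] = float((centred**2 * p).sum())
    feats["ClusterShade"] = float((centred**3 * p).sum())
    feats["ClusterProminence"] = float((centred**4 * p).sum())
    feats["InformationCorrelation1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    feats["InformationCorrelation2"] = float(np.sqrt(max(arg, 0.0)))
    return feats


def _rl_style_features(m: np.ndarray, n_voxel_units: float, kind: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``m`` is a (ng x L) count matrix over (level, run length | zone size);
    ``n_voxel_units`` is the voxel total the percentage feature divides by
    (directions x n_masked for runs, n_masked for zones).
    """
    ns = m.sum()
    if ns == 0:
        raise ValueError("empty count matrix")
    ng, max_l = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, max_l + 1, dtype=float)[None, :]
    marg_level = m.sum(axis=1)
    marg_len = m.sum(axis=0)
    p = m / ns
    mu_i = float((p * i).sum())
    mu_l = float((p * l).sum())

    short, long_ = ("ShortRun", "LongRun") if kind == "run" else ("SmallZone", "LargeZone")
    len_word = "RunLength" if kind == "run" else "ZoneSize"
    f: dict[str, float] = {}
    f[f"{short}Emphasis"] = float((m / l**2).sum() / ns)
    f[f"{long_}Emphasis"] = float((m * l**2).sum() / ns)
    f["LowGrayLevelEmphasis"] = float((m / i**2).sum() / ns)
    f["HighGrayLevelEmphasis"] = float((m * i**2).sum() / ns)
    f[f"{short}LowGrayLevelEmphasis"] = float((m / (i**2 * l**2)).sum() / ns)
    f[f"{short}HighGrayLevelEmphasis"] = float((m * i**2 / l**2).sum() / ns)
    f[f"{long_}LowGrayLevelEmphasis"] = float((m * l**2 / i**2).sum() / ns)
    f[f"{long_}HighGrayLevelEmphasis"] = float((m * i**2 * l**2).sum() / ns)
    f["GrayLevelNonUniformity"] = float((marg_level**2).sum() / ns)
    f["GrayLevelNonUniformityNormalised"] = float((marg_level**2).sum() / ns**2)
    f[f"{len_word}NonUniformity"] = float((marg_len**2).sum() / ns)
    f[f"{len_word}NonUniformityNormalised"] = float((marg_len**2).sum() / ns**2)
    pct_name = "RunPercentage" if kind == "run" else "ZonePercentage"
    f[pct_name] = float(ns / n_voxel_units)
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    f[f"{len_word}Variance"] = float((p * (l - mu_l) ** 2).sum())
    ent_name = "RunEntropy" if kind == "run" else "ZoneEntropy"
    f[ent_name] = float(-_xlog2(p).sum())
    return f


_RLM_RENAME = {
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
}
_SZM_RENAME = {
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
}


def glrlm_features(matrix: np.ndarray, n_masked: int, n_directions: int = 13) -> dict[str, float]:
    """Run-length features; RunPercentage divides by directions x n_masked,
    since each direction's runs partition the mask."""
    out = _rl_style_features(np.asarray(matrix, float), n_directions * n_masked, "run")
    return {_RLM_RENAME.get(k, k): v for k, v in out.items()}


def glszm_features(matrix: np.ndarray, n_masked: int) -> dict[str, float]:
    out = _rl_style_features(np.asarray(matrix, float), n_masked, "zone")
    return {_SZM_RENAME.get(k, k): v for k, v in out.items()}


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n_i = np.asarray(n_i, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    nv = n_i.sum()
    if nv == 0:
        raise ValueError("no voxel with a valid neighbourhood")
    ng = len(n_i)
    i = np.arange(1, ng + 1, dtype=float)
    p = n_i / nv
    present = p > 0
    ip = i[present]
    pp = p[present]
    sp = s_i[present]

    f: dict[str, float] = {}
    denom = float((p * s_i).sum())
    f["Coarseness"] = 1.0 / denom if denom > 0 else COARSENESS_CAP
    ngp = int(present.sum())
    if ngp > 1:
        pij = np.subtract.outer(ip, ip) ** 2 * np.outer(pp, pp)
        f["Contrast"] = float(pij.sum() / (ngp * (ngp - 1)) * (s_i.sum() / nv))
    else:
        f["Contrast"] = 0.0
    busy_denom = float(np.abs(np.subtract.outer(ip * pp, ip * pp)).sum())
    f["Busyness"] = float((p * s_i).sum() / busy_denom) if busy_denom > 0 else 0.0
    num = np.abs(np.subtract.outer(ip, ip)) * (
        np.add.outer(pp * sp, pp * sp) / np.add.outer(pp, pp)
    )
    f["Complexity"] = float(num.sum() / nv)
    s_tot = float(s_i.sum())
    if s_tot > 0:
        f["Strength"] = float(
            (np.add.outer(pp, pp) * np.subtract.outer(ip, ip) ** 2).sum() / s_tot
        )
    else:
        f["Strength"] = 0.0
    return f
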