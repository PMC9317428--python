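"""The radiomic feature panel and its extraction driver.

The study table width fixes the per-patient imaging feature count at 251:
40 ROI statistics (8 biomarkers x 5 statistics, assembled elsewhere) plus
the 211 radiomic features defined here on the ADC and iAUC60 maps.  The
exact membership below is package configuration: per map 20 first-order,
23 intensity-histogram, 25 GLCM, 16 GLRLM, 16 GLSZM and 5 NGTDM features
(105 per map), with ``ADC_fo_TotalEnergy`` additionally included on the ADC
map — 211 is odd, so the two map panels cannot be identical.
"""

from __future__ import annotations

import numpy as np

from .discretise import discretise
from .features import glcm_features, glrlm_features, glszm_features, ngtdm_features
from .firstorder import first_order_features, intensity_histogram_features
from .matrices import DIRECTIONS_13, build_glcm, build_glrlm, build_glszm, build_ngtdm

__all__ = ["DEFAULT_NG", "default_panel", "extract_radiomics", "panel_size"]

DEFAULT_NG = 32

_FO = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Median", "Minimum",
    "Percentile10", "Percentile25", "Percentile75", "Percentile90", "Maximum",
    "InterquartileRange", "Range", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "MedianAbsoluteDeviation",
    "CoefficientOfVariation", "QuartileCoefficientOfDispersion",
    "Energy", "RootMeanSquare",
)
_IH = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Median", "Minimum",
    "Percentile10", "Percentile90", "Maximum", "Mode", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "MedianAbsoluteDeviation", "CoefficientOfVariation",
    "QuartileCoefficientOfDispersion", "Entropy", "Uniformity",
    "MaximumHistogramGradient", "MaximumHistogramGradientLevel",
    "MinimumHistogramGradient", "MinimumHistogramGradientLevel",
)
_GLCM = (
    "JointMaximum", "JointAverage", "JointVariance", "JointEntropy",
    "DifferenceAverage", "DifferenceVariance", "DifferenceEntropy",
    "SumAverage", "SumVariance", "SumEntropy", "AngularSecondMoment",
    "Contrast", "Dissimilarity", "InverseDifference",
    "InverseDifferenceNormalised", "InverseDifferenceMoment",
    "InverseDifferenceMomentNormalised", "InverseVariance", "Correlation",
    "Autocorrelation", "ClusterTendency", "ClusterShade", "ClusterProminence",
    "InformationCorrelation1", "InformationCorrelation2",
)
_GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalised", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalised", "RunPercentage", "GrayLevelVariance",
    "RunLengthVariance", "RunEntropy",
)
_GLSZM = (
    "SmallZoneEmphasis", "LargeZoneEmphasis", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallZoneLowGrayLevelEmphasis",
    "SmallZoneHighGrayLevelEmphasis", "LargeZoneLowGrayLevelEmphasis",
    "LargeZoneHighGrayLevelEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalised", "ZoneSizeNonUniformity",
    "ZoneSizeNonUniformityNormalised", "ZonePercentage", "GrayLevelVariance",
    "ZoneSizeVariance", "ZoneEntropy",
)
_NGTDM = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def default_panel() -> dict[str, dict[str, tuple[str, ...]]]:
    """Feature panel: map name -> family -> ordered feature names."""
    per_map = {
        "fo": _FO, "ih": _IH, "glcm": _GLCM,
        "glrlm": _GLRLM, "glszm": _GLSZM, "ngtdm": _NGTDM,
    }
    panel = {"ADC": {k: tuple(v) for k, v in per_map.items()},
             "iAUC60": {k: tuple(v) for k, v in per_map.items()}}
    panel["ADC"]["fo"] = _FO + ("TotalEnergy",)
    return panel


def panel_size(panel=None) -> int:
    panel = panel or default_panel()
    return sum(len(names) for fams in panel.values() for names in fams.values())


def extract_radiomics(
    maps: dict[str, np.ndarray],
    mask: np.ndarray,
    ng: int = DEFAULT_NG,
    panel: dict | None = None,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """Compute the configured radiomic panel on each input map.

    Per map, voxels that are masked and finite form the effective ROI.
    Returns an ordered ``{"<map>_<family>_<Feature>": value}`` mapping;
    a map named in the panel but missing from ``maps`` raises.
    """
    panel = panel or default_panel()
    mask = np.asarray(mask, dtype=bool)
    out: dict[str, float] = {}
    for map_name, families in panel.items():
        if map_name not in maps:
            raise KeyError(f"required map '{map_name}' not provided")
        map3d = np.asarray(maps[map_name], dtype=float)
        eff = mask & np.isfinite(map3d)
        if not eff.any():
            raise ValueError(f"map '{map_name}' has no valid masked voxel")
        n_masked = int(eff.sum())
        roi = discretise(map3d, eff, ng)
        values: dict[str, dict[str, float]] = {}
        values["fo"] = first_order_features(map3d, eff, voxel_volume=voxel_volume)
        values["ih"] = intensity_histogram_features(roi.levels[eff], ng)
        values["glcm"] = glcm_features(build_glcm(roi))
        values["glrlm"] = glrlm_features(build_glrlm(roi), n_masked, len(DIRECTIONS_13))
        values["glszm"] = glszm_features(build_glszm(roi), n_masked)
        values["ngtdm"] = ngtdm_features(*build_ngtdm(roi))
        for family, names in families.items():
            for name in names:
                out[f"{map_name}_{family}_{name}"] = values[family][name]
    return out
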