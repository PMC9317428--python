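"""Per-patient feature assembly, two-step selection and group statistics.

Voxel-wise biomarker maps are summarised into five ROI statistics each
(mean, median, standard deviation, 25th and 75th percentile); together with
the radiomic panel this yields the 251-column imaging feature table.  The
two-step selection removes low-variance then mutually correlated columns;
group differences are assessed with two-sample pooled-variance t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffusion import diffusion_maps
from .perfusion import perfusion_maps
from .radiomics import DEFAULT_NG, extract_radiomics
from .synthetic import CLINICAL_FLAGS, SyntheticPatient

__all__ = [
    "ROI_STATS",
    "BIOMARKERS",
    "roi_statistics",
    "FeatureTable",
    "assemble_table",
    "patient_imaging_features",
    "cohort_feature_table",
    "SelectionResult",
    "variance_filter",
    "correlation_filter",
    "select_features",
    "compare_groups",
]

ROI_STATS = ("mean", "median", "std", "p25", "p75")
BIOMARKERS = ("iAUC60", "InitialSlope", "Peak", "TTP", "ADC", "D", "D_star", "f")


def roi_statistics(map3d: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Five ROI statistics over the valid (finite) masked voxels.

    Percentiles interpolate linearly between order statistics; the standard
    deviation is the population SD of the voxel values.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(map3d, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid masked voxel")
    p25, med, p75 = np.percentile(vals, [25, 50, 75])
    return {
        "mean": float(np.mean(vals)),
        "median": float(med),
        "std": float(np.std(vals)),
        "p25": float(p25),
        "p75": float(p75),
    }


@dataclass
class FeatureTable:
    """Patients x features with pCR labels and per-column provenance."""

    data: pd.DataFrame
    labels: pd.Series  # 1 = pCR
    provenance: dict[str, str]  # column -> "imaging" | "clinical"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient id")
        if self.data.isna().any().any():
            raise ValueError("missing values in feature table")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValueError("feature names must be unique")
        missing = set(self.data.columns) - set(self.provenance)
        if missing:
            raise ValueError(f"columns without provenance: {sorted(missing)[:3]}")

    def _view(self, kind: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if self.provenance[c] == kind]
        return self.data[cols]

    @property
    def imaging(self) -> pd.DataFrame:
        return self._view("imaging")

    @property
    def clinical(self) -> pd.DataFrame:
        return self._view("clinical")

    @property
    def combined(self) -> pd.DataFrame:
        return self.data


def patient_imaging_features(
    patient: SyntheticPatient, ng: int = DEFAULT_NG
) -> dict[str, float]:
    """Run the full extraction for one patient: perfusion and diffusion maps,
    their ROI statistics, and the radiomic panel on ADC and iAUC60."""
    perf = perfusion_maps(patient.dce, patient.mask)
    diff = diffusion_maps(patient.dwi, patient.mask)
    maps = {**perf.as_dict(), **diff.as_dict()}
    feats: dict[str, float] = {}
    for name in BIOMARKERS:
        for stat, value in roi_statistics(maps[name], patient.mask).items():
            feats[f"{name}_{stat}"] = value
    voxel_volume = float(np.prod(patient.dce.spacing))
    feats.update(
        extract_radiomics(
            {"ADC": maps["ADC"], "iAUC60": maps["iAUC60"]},
            patient.mask, ng=ng, voxel_volume=voxel_volume,
        )
    )
    return feats


def assemble_table(
    patient_ids: list[str],
    imaging: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: pd.Series,
) -> FeatureTable:
    """Join imaging and clinical blocks into one table with stable order."""
    for block, name in ((imaging, "imaging"), (clinical, "clinical"), (labels, "labels")):
        missing = set(patient_ids) - set(block.index)
        if missing:
            raise ValueError(f"missing {name} rows for patients {sorted(missing)[:3]}")
    imaging = imaging.loc[patient_ids]
    clinical = clinical.loc[patient_ids]
    data = pd.concat([imaging, clinical], axis=1)
    prov = {c: "imaging" for c in imaging.columns}
    prov.update({c: "clinical" for c in clinical.columns})
    return FeatureTable(data=data, labels=labels.loc[patient_ids], provenance=prov)


def cohort_feature_table(
    patients: list[SyntheticPatient], ng: int = DEFAULT_NG
) -> FeatureTable:
    ids = [p.patient_id for p in patients]
    imaging = pd.DataFrame(
        [patient_imaging_features(p, ng=ng) for p in patients], index=ids
    )
    clinical = pd.DataFrame(
        [{k: p.clinical[k] for k in CLINICAL_FLAGS} for p in patients], index=ids,
        dtype=float,
    )
    labels = pd.Series([int(p.pcr) for p in patients], index=ids, name="pcr")
    return assemble_table(ids, imaging, clinical, labels)


# ---------------------------------------------------------------------------
# two-step feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    retained: list[str]
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["name", "reason", "partner", "r"])
    )

    @property
    def removal_log(self) -> pd.DataFrame:
        return self.removed


def _scaled(df: pd.DataFrame, scaling: str) -> pd.DataFrame:
    if scaling == "raw":
        return df
    if scaling == "minmax":
        rng = df.max() - df.min()
        safe = rng.replace(0.0, 1.0)
        return (df - df.min()) / safe
    raise ValueError(f"unknown scaling '{scaling}' (use 'raw' or 'minmax')")


def variance_filter(
    table: pd.DataFrame, threshold: float = 0.1, scaling: str = "minmax"
) -> SelectionResult:
    """Remove every column with sample variance <= threshold (inclusive).

    A raw-units threshold is meaningless across features spanning many
    orders of magnitude (mm^2/s vs seconds), so by default columns are
    min-max scaled to [0, 1] before thresholding; ``scaling='raw'``
    reproduces thresholding in original units.
    """
    var = _scaled(table, scaling).var(ddof=1)
    drop = var[var <= threshold].index.tolist()
    if len(drop) == len(table.columns):
        raise ValueError(
            "variance filter removed every column; review the threshold/scaling"
        )
    removed = pd.DataFrame(
        {"name": drop, "reason": "low_variance", "partner": None, "r": np.nan}
    )
    retained = [c for c in table.columns if c not in set(drop)]
    return SelectionResult(retained=retained, removed=removed)


def correlation_filter(
    table: pd.DataFrame, threshold: float = 0.8, scaling: str = "raw"
) -> SelectionResult:
    """Greedy redundancy elimination: among each pair with |Pearson r| >
    threshold, drop the lower-variance column; ties broken by name order.
    Pairs are processed in descending |r|, so the result is deterministic.

    The keep rule compares raw variance: proportional duplicates (Y = kX)
    must resolve to the larger-scaled copy, which any scale-invariant
    variance measure would leave tied.
    """
    cols = list(table.columns)
    corr = table.corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    var = _scaled(table, scaling).var(ddof=1)
    pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = corr[a, b]
            if abs(r) > threshold:
                pairs.append((abs(r), cols[a], cols[b], r))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(cols)
    log_rows = []
    for _, a, b, r in pairs:
        if a not in alive or b not in alive:
            continue
        if (var[a], b) > (var[b], a):  # keep higher variance; tie -> earlier name
            keep, drop = a, b
        else:
            keep, drop = b, a
        alive.discard(drop)
        log_rows.append({"name": drop, "reason": "correlated", "partner": keep, "r": r})
    retained = [c for c in cols if c in alive]
    removed = pd.DataFrame(log_rows, columns=["name", "reason", "partner", "r"])
    return SelectionResult(retained=retained, removed=removed)


def select_features(
    table: pd.DataFrame,
    var_threshold: float = 0.1,
    corr_threshold: float = 0.8,
    scaling: str = "minmax",
) -> SelectionResult:
    """Two-step selection: variance filter, then correlation filter."""
    step1 = variance_filter(table, var_threshold, scaling)
    step2 = correlation_filter(table[step1.retained], corr_threshold)
    removed = pd.concat([step1.removed, step2.removed], ignore_index=True)
    return SelectionResult(retained=step2.retained, removed=removed)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sample pooled-variance (Student) t-test per feature, two-sided.

    Returns one row per feature with group means and sample SDs (pCR vs
    non-pCR), the t statistic and p-value.  Degenerate identical constant
    groups are reported as t = 0, p = 1.
    """
    labels = labels.loc[table.index]
    a = table[labels == 1]
    b = table[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    rows = []
    for col in table.columns:
        res = stats.ttest_ind(a[col], b[col], equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # zero pooled variance
            diff = float(a[col].mean() - b[col].mean())
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        rows.append(
            {
                "feature": col,
                "mean_pcr": float(a[col].mean()),
                "sd_pcr": float(a[col].std(ddof=1)),
                "mean_non_pcr": float(b[col].mean()),
                "sd_non_pcr": float(b[col].std(ddof=1)),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
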