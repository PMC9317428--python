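"""Diffusion-weighted MRI model fitting: mono-exponential ADC and IVIM.

The DWI signal at diffusion weighting b [s/mm^2] is modelled either as a
mono-exponential decay S(b) = S0 exp(-b * ADC), or by the intravoxel
incoherent motion (IVIM) bi-exponential

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ],

separating pure (tissue) diffusion D from pseudo-diffusion D* attributable
to capillary perfusion, with vascular fraction f.  With only four b-values
(0, 150, 400, 1000) a full nonlinear 4-parameter fit is ill-posed, so the
community-standard segmented fit is used:

1. D and the high-b intercept from a log-linear fit over b >= b_threshold
   (the perfusion compartment has fully decayed there),
2. f = 1 - intercept / S(0),
3. D* by bounded one-dimensional least squares on the full curve with D and
   f held fixed, constrained to D* >= D.

f is reported in percent.  D* is known to be the least reproducible IVIM
parameter; downstream accuracy claims are deliberately confined to D and f.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["DWISeries", "DiffusionMaps", "fit_adc", "fit_ivim", "diffusion_maps"]

DSTAR_UPPER = 0.5  # mm^2/s, physical plausibility bound for pseudo-diffusion


@dataclass
class DWISeries:
    """b-value-keyed 3D volumes sharing one grid."""

    volumes: dict[float, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volumes = {float(b): np.asarray(v, dtype=float) for b, v in self.volumes.items()}
        bvals = sorted(self.volumes)
        if any(b < 0 for b in bvals):
            raise ValueError("negative b-value")
        if 0.0 not in self.volumes:
            raise ValueError("b = 0 volume is required")
        if len(bvals) < 3:
            raise ValueError("at least 3 distinct b-values are required")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError("all b-value volumes must share one grid")

    @property
    def bvalues(self) -> np.ndarray:
        return np.array(sorted(self.volumes), dtype=float)

    def signals_at(self, idx) -> np.ndarray:
        return np.array([self.volumes[b][idx] for b in self.bvalues])


@dataclass
class DiffusionMaps:
    """Voxel-wise diffusion parameters on the mask (NaN outside/invalid)."""

    adc: np.ndarray
    d: np.ndarray
    dstar: np.ndarray
    f: np.ndarray  # percent
    mask: np.ndarray
    valid: np.ndarray
    invalid_causes: dict[str, int]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"ADC": self.adc, "D": self.d, "D_star": self.dstar, "f": self.f}


def fit_adc(signals, bvalues) -> float:
    """Mono-exponential ADC [mm^2/s] as the least-squares slope of
    -ln S(b) versus b across all b-values."""
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if s.size < 2:
        raise ValueError("at least 2 signals required")
    if np.any(s <= 0):
        raise ValueError("non-positive signal")
    slope, _ = np.polyfit(b, np.log(s), 1)
    return float(-slope)


def fit_ivim(signals, bvalues, b_threshold: float = 200.0) -> tuple[float, float, float]:
    """Segmented IVIM fit returning (D [mm^2/s], D* [mm^2/s], f [%])."""
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if np.any(s <= 0):
        raise ValueError("non-positive signal")
    hi = b >= b_threshold
    lo = ~hi
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError(
            f"segmented fit needs >= 2 b-values on each side of {b_threshold:g}"
        )
    s0 = s[np.argmin(b)]
    if not np.isclose(b.min(), 0.0):
        raise ValueError("b = 0 signal required")

    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    d = float(-slope)
    if d <= 0:
        raise ValueError("non-positive diffusion coefficient")
    amp = float(np.exp(intercept))
    f = float(np.clip(1.0 - amp / s0, 0.0, 1.0))

    if f == 0.0:
        return d, d, 0.0  # bi-exponential degenerates to the mono-exponential

    def sse(dstar: float) -> float:
        model = s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))
        return float(np.sum((model - s) ** 2))

    res = minimize_scalar(sse, bounds=(d, DSTAR_UPPER), method="bounded",
                          options={"xatol": 1e-9})
    if not res.success:
        raise ValueError("D* optimisation did not converge")
    dstar = float(max(res.x, d))
    return d, dstar, 100.0 * f


def diffusion_maps(
    series: DWISeries, mask: np.ndarray, b_threshold: float = 200.0
) -> DiffusionMaps:
    """Fit ADC and IVIM voxel-by-voxel within the mask.

    Invalid voxels (non-positive signals, non-positive fitted coefficients,
    non-convergent D*) are excluded and tallied by cause; if every masked
    voxel is invalid an error lists the cause counts.
    """
    mask = np.asarray(mask, dtype=bool)
    grid = next(iter(series.volumes.values())).shape
    if mask.shape != grid:
        raise ValueError("mask grid does not match the DWI grid")
    if not mask.any():
        raise ValueError("empty mask")
    b = series.bvalues
    shape = mask.shape
    maps = {k: np.full(shape, np.nan) for k in ("adc", "d", "dstar", "f")}
    valid = np.zeros(shape, dtype=bool)
    causes: Counter[str] = Counter()
    for idx in zip(*np.nonzero(mask)):
        sig = series.signals_at(idx)
        try:
            adc = fit_adc(sig, b)
            if adc <= 0:
                raise ValueError("non-positive ADC")
            d, dstar, f = fit_ivim(sig, b, b_threshold)
        except ValueError as exc:
            causes[str(exc)] += 1
            continue
        maps["adc"][idx] = adc
        maps["d"][idx] = d
        maps["dstar"][idx] = dstar
        maps["f"][idx] = f
        valid[idx] = True
    if not valid.any():
        raise ValueError(f"all masked voxels invalid; causes: {dict(causes)}")
    return DiffusionMaps(
        adc=maps["adc"], d=maps["d"], dstar=maps["dstar"], f=maps["f"],
        mask=mask, valid=valid, invalid_causes=dict(causes),
    )
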