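"""Semi-quantitative perfusion analysis of DCE-MRI series.

A dynamic contrast-enhanced (DCE) acquisition repeatedly images the breast
after a gadolinium bolus.  Within a tumour mask, each voxel's signal curve is
converted to a concentration proxy (relative enhancement) and summarised by
four classical semi-quantitative biomarkers:

* ``iAUC60`` — initial area under the concentration curve over the first 60 s
  after the start of contrast administration [mM.s],
* ``initial_slope`` — steepest ascending slope of the curve once contrast
  begins to enter the region [mM/s],
* ``peak`` — maximum of the concentration curve [mM],
* ``ttp`` — time-to-peak, measured from the start of contrast
  administration [s].

All voxel-wise times are referenced to the injection start (t = 0 at
injection); dynamics acquired before the injection provide the pre-contrast
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DCESeries",
    "ConcentrationSeries",
    "PerfusionMaps",
    "signal_to_concentration",
    "compute_peak",
    "compute_ttp",
    "compute_iauc60",
    "compute_initial_slope",
    "perfusion_maps",
]


@dataclass
class DCESeries:
    """4D dynamic series: ``intensities[x, y, z, t]`` in scanner units.

    ``times`` are acquisition time stamps in seconds (strictly increasing),
    ``injection_time`` the contrast-administration start on the same clock.
    """

    intensities: np.ndarray
    times: np.ndarray
    injection_time: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("DCE intensities must be a 4D (x, y, z, t) array")
        if self.times.ndim != 1 or self.times.size != self.intensities.shape[3]:
            raise ValueError("times must be 1D with one entry per dynamic")
        if self.times.size < 3:
            raise ValueError("a DCE series needs at least 3 dynamics")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if not np.any(self.times < self.injection_time):
            raise ValueError("at least one pre-injection dynamic is required")

    @property
    def n_dynamics(self) -> int:
        return int(self.times.size)


@dataclass
class ConcentrationSeries:
    """Concentration-proxy series (mM); same grid/clock as the source DCE."""

    values: np.ndarray
    times: np.ndarray
    injection_time: float
    valid: np.ndarray = field(default=None)  # voxels with a usable baseline

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.values.shape[:3], dtype=bool)


@dataclass
class PerfusionMaps:
    """Voxel-wise perfusion biomarkers on the masked region (NaN elsewhere)."""

    iauc60: np.ndarray
    initial_slope: np.ndarray
    peak: np.ndarray
    ttp: np.ndarray
    mask: np.ndarray
    valid: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "iAUC60": self.iauc60,
            "InitialSlope": self.initial_slope,
            "Peak": self.peak,
            "TTP": self.ttp,
        }


def signal_to_concentration(
    series: DCESeries, relaxivity_scale: float = 1.0
) -> ConcentrationSeries:
    """Convert signal to a concentration proxy via relative enhancement.

    c(t) = relaxivity_scale * (S(t) - S0) / S0 with S0 the per-voxel mean of
    the pre-injection dynamics.  Voxels with S0 <= 0 are flagged invalid and
    excluded from downstream maps.
    """
    pre = series.times < series.injection_time
    s0 = series.intensities[..., pre].mean(axis=-1)
    valid = s0 > 0
    safe_s0 = np.where(valid, s0, 1.0)
    conc = relaxivity_scale * (series.intensities - safe_s0[..., None]) / safe_s0[..., None]
    conc[~valid] = np.nan
    return ConcentrationSeries(
        values=conc, times=series.times, injection_time=series.injection_time, valid=valid
    )


def _post_injection(curve: np.ndarray, times: np.ndarray, injection_time: float):
    sel = times >= injection_time
    if not np.any(sel):
        raise ValueError("no post-injection samples in the acquisition window")
    return np.asarray(curve, dtype=float)[sel], np.asarray(times, dtype=float)[sel]


def compute_peak(curve, times, injection_time: float) -> float:
    """Maximum of the concentration curve over post-injection samples [mM]."""
    c, _ = _post_injection(curve, times, injection_time)
    return float(np.max(c))


def compute_ttp(curve, times, injection_time: float) -> float:
    """Time-to-peak [s]: time from injection to the first sample attaining the
    post-injection maximum (first attainment breaks plateau ties)."""
    c, t = _post_injection(curve, times, injection_time)
    idx = int(np.argmax(c))  # np.argmax returns the first maximal index
    return float(t[idx] - injection_time)


def compute_iauc60(curve, times, injection_time: float, window: float = 60.0) -> float:
    """Trapezoidal area under the concentration curve over the first
    ``window`` seconds after injection [mM.s].

    The endpoints (injection time and injection time + window) almost never
    coincide with a dynamic; both are obtained by linear interpolation
    between the bracketing samples.
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    t_end = injection_time + window
    if times[-1] < t_end:
        raise ValueError(
            f"acquisition window ends at {times[-1]:g} s but iAUC requires "
            f"coverage to {t_end:g} s"
        )
    interior = (times > injection_time) & (times < t_end)
    nodes = np.concatenate(([injection_time], times[interior], [t_end]))
    values = np.interp(nodes, times, curve)
    return float(np.trapezoid(values, nodes))


def compute_initial_slope(
    curve, times, injection_time: float, onset_frac: float = 0.05
) -> float:
    """Initial ascending slope [mM/s].

    Maximum forward finite-difference slope between consecutive
    post-injection samples, taken from contrast onset (first sample exceeding
    ``onset_frac`` of the peak) up to and including the peak sample.  A flat
    (non-enhancing) curve yields 0; a peak at the first post-injection sample
    falls back to the single available pre-peak interval of the full series.
    """
    c, t = _post_injection(curve, times, injection_time)
    peak_idx = int(np.argmax(c))
    peak_val = c[peak_idx]
    if peak_val <= 0:
        return 0.0
    above = np.nonzero(c > onset_frac * peak_val)[0]
    onset_idx = int(above[0]) if above.size else peak_idx
    if onset_idx >= peak_idx:
        # peak at (or before) onset: use the one interval ending at the peak,
        # reaching back into the pre-injection samples if needed
        full_c = np.asarray(curve, dtype=float)
        full_t = np.asarray(times, dtype=float)
        gidx = int(np.nonzero(full_t == t[peak_idx])[0][0])
        if gidx == 0:
            return 0.0
        return float((full_c[gidx] - full_c[gidx - 1]) / (full_t[gidx] - full_t[gidx - 1]))
    slopes = np.diff(c[onset_idx : peak_idx + 1]) / np.diff(t[onset_idx : peak_idx + 1])
    return float(np.max(slopes))


def perfusion_maps(
    series: DCESeries,
    mask: np.ndarray,
    relaxivity_scale: float = 1.0,
    onset_frac: float = 0.05,
) -> PerfusionMaps:
    """Compute all four perfusion biomarkers voxel-by-voxel within the mask.

    Voxels whose baseline is unusable (S0 <= 0) are excluded and reported via
    the ``valid`` map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.intensities.shape[:3]:
        raise ValueError("mask grid does not match the DCE grid")
    if not mask.any():
        raise ValueError("empty mask")
    conc = signal_to_concentration(series, relaxivity_scale)
    shape = mask.shape
    out = {k: np.full(shape, np.nan) for k in ("iauc60", "slope", "peak", "ttp")}
    valid = mask & conc.valid
    for idx in zip(*np.nonzero(valid)):
        curve = conc.values[idx]
        out["peak"][idx] = compute_peak(curve, conc.times, conc.injection_time)
        out["ttp"][idx] = compute_ttp(curve, conc.times, conc.injection_time)
        out["iauc60"][idx] = compute_iauc60(curve, conc.times, conc.injection_time)
        out["slope"][idx] = compute_initial_slope(
            curve, conc.times, conc.injection_time, onset_frac
        )
    return PerfusionMaps(
        iauc60=out["iauc60"],
        initial_slope=out["slope"],
        peak=out["peak"],
        ttp=out["ttp"],
        mask=mask,
        valid=valid,
    )
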