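"""Synthetic multiparametric MRI cohorts with known ground truth.

Emulates the inputs of a neoadjuvant-chemotherapy response study: for each
patient a DCE-MRI dynamic series, a multi-b DWI series, a spherical tumour
mask, four binary clinical covariates and a binary pathological complete
response (pCR) label.  Group-level parameter shifts are calibrated to the
reported responder/non-responder differences: responders (pCR) receive
shorter time-to-peak, smaller voxel-wise D* dispersion and a smoother
(more homogeneous) ADC map.

Forward models
--------------
DCE: each voxel follows a piecewise-linear uptake curve (see
:func:`uptake_curve`): zero until contrast onset t0, a linear rise, a
symmetric triangular apex of half-width 40 s (one temporal-resolution unit)
peaking at exactly (ttp, peak), and a slower linear washout — the rapid
initial rise with delayed washout typical of malignant breast lesions.
The apex is symmetric over a full sampling interval on purpose: it makes
the sampled argmax land on the grid point nearest the true peak, so
noiseless extraction recovers the truth TTP to within half the temporal
resolution for every sampling phase.  (A gamma-variate apex is right-skewed
enough to break that guarantee in a narrow phase window regardless of its
width.)  Signal is S(t) = S0 * (1 + c(t)) plus additive Gaussian noise
(concentration is recovered downstream as relative enhancement).

DWI: the IVIM bi-exponential (see :mod:`mpmri.diffusion`) with Rician
noise of scale S0 / snr_dwi, the standard magnitude-MRI noise model.

The default acquisition keeps the clinical 40 s temporal resolution but
covers 14 dynamics: the reported TTP distributions (means 237.67 s and
302.40 s for different TTP statistics) extend well beyond a 6 x 40 s window,
and the reported total sequence duration (7 min 42 s) indicates a longer
effective coverage.  A strict 6-dynamic protocol remains available via
``n_dynamics=6`` for in-window curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .diffusion import DWISeries
from .perfusion import DCESeries

__all__ = [
    "CohortSpec",
    "TruthMaps",
    "SyntheticPatient",
    "gamma_variate",
    "uptake_curve",
    "APEX_HALFWIDTH",
    "ivim_signal",
    "sphere_mask",
    "generate_dce",
    "generate_dwi",
    "generate_patient",
    "generate_cohort",
    "sample_truth_features",
]

CLINICAL_FLAGS = ("age_over_40", "premenopausal", "stage_iii", "grade_iii")

DWI_BVALUES = (0.0, 150.0, 400.0, 1000.0)  # s/mm^2
GAMMA_ALPHA = 3.0  # gamma-variate shape (alternative curve family)
APEX_HALFWIDTH = 40.0  # s, symmetric apex half-width = one temporal-resolution unit
APEX_DROP = 0.1  # fraction of peak lost across the apex half-width
WASHOUT_SLOPE_FRAC = 0.25  # washout slope as a fraction of the apex slope
DCE_BASELINE = 100.0  # arbitrary scanner units
DWI_S0 = 1000.0
DSTAR_FLOOR = 0.015  # mm^2/s; keeps exp(-b D*) negligible for b >= 400


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-group synthetic cohort.

    Group-valued fields are ``(responders, non_responders)`` pairs; defaults
    reproduce the reported cohort (12 pCR / 46 non-pCR) with TTP-statistic
    means/SDs 187.47 (51.27) s vs 237.67 (79.20) s and voxel-wise D*
    dispersion 0.006 vs 0.007 mm^2/s.
    """

    n_responders: int = 12
    n_nonresponders: int = 46
    ttp_mean_by_group: tuple[float, float] = (187.47, 237.67)  # s
    ttp_sd_by_group: tuple[float, float] = (51.27, 79.20)  # s, between patients
    ttp_voxel_sd: float = 15.0  # s, within-patient voxel jitter
    dstar_sd_by_group: tuple[float, float] = (0.006, 0.007)  # mm^2/s
    dstar_sd_spread: float = 0.002  # between-patient SD of the dispersion
    texture_homogeneity_by_group: tuple[float, float] = (0.7, 0.35)
    snr_dwi: float = 50.0
    noise_dce: float = 2.0  # additive signal SD, scanner units (baseline 100)
    voxel_spacing: tuple[float, float, float] = (1.2, 1.2, 1.2)  # mm
    roi_radius: int = 4  # voxels
    n_dynamics: int = 14
    dt: float = 40.0  # s, temporal resolution
    injection_delay: float = 20.0  # s after the end of the first dynamic
    d_mean: float = 1.0e-3  # mm^2/s, pure diffusion (no group shift reported)
    dstar_mean: float = 0.03  # mm^2/s
    f_mean: float = 8.0  # %
    peak_mean: float = 1.0  # mM
    clinical_p_by_group: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.80, 0.45, 0.35, 0.60),  # responders: P(flag = 1) per CLINICAL_FLAGS
        (0.80, 0.40, 0.55, 0.40),  # non-responders
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("group counts must be >= 1")
        if any(sd < 0 for sd in self.ttp_sd_by_group) or self.ttp_voxel_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(sd < 0 for sd in self.dstar_sd_by_group) or self.dstar_sd_spread < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.snr_dwi <= 0:
            raise ValueError("snr_dwi must be > 0")
        if self.roi_radius < 2:
            raise ValueError("roi_radius must be >= 2")
        if self.dt <= 0:
            raise ValueError("temporal resolution must be positive")
        if not all(0.0 <= h <= 1.0 for h in self.texture_homogeneity_by_group):
            raise ValueError("texture homogeneity must lie in [0, 1]")

    # -- derived acquisition geometry ------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Dynamic time stamps (start-of-dynamic, seconds)."""
        return self.dt * np.arange(self.n_dynamics, dtype=float)

    @property
    def injection_time(self) -> float:
        """Injection starts ``injection_delay`` s after the first dynamic ends."""
        return self.dt + self.injection_delay

    @property
    def post_window(self) -> float:
        """Last sample time measured from injection start."""
        return float(self.times[-1] - self.injection_time)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        n = 2 * (self.roi_radius + 2) + 1
        return (n, n, n)

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def strong_imaging_signal(cls, **kw) -> "CohortSpec":
        """Constructed condition for classifier comparisons: imaging features
        carry a clear group signal, clinical flags stay weakly informative."""
        base = dict(
            ttp_mean_by_group=(160.0, 300.0),
            ttp_sd_by_group=(40.0, 70.0),
            dstar_sd_by_group=(0.004, 0.009),
            texture_homogeneity_by_group=(0.8, 0.3),
        )
        base.update(kw)
        return cls(**base)


@dataclass
class TruthMaps:
    """Ground-truth voxel parameters, ordered as ``np.nonzero(mask)``."""

    voxels: np.ndarray  # (N, 3) integer coordinates
    ttp: np.ndarray  # s, from injection start
    peak: np.ndarray  # mM
    onset: np.ndarray  # s, contrast-arrival delay
    d: np.ndarray  # mm^2/s
    dstar: np.ndarray  # mm^2/s
    f: np.ndarray  # %

    def concentration(self, i: int, t) -> np.ndarray:
        """Continuous truth concentration curve of voxel ``i`` (t from injection)."""
        return uptake_curve(t, self.onset[i], self.ttp[i], self.peak[i])

    def map_of(self, values: np.ndarray, shape) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[tuple(self.voxels.T)] = values
        return out


@dataclass
class SyntheticPatient:
    patient_id: str
    dce: DCESeries
    dwi: DWISeries
    mask: np.ndarray
    truth: TruthMaps
    clinical: dict[str, int]
    pcr: bool


def gamma_variate(t, t0: float, ttp: float, peak: float, alpha: float = GAMMA_ALPHA):
    """Gamma-variate uptake curve with maximum ``peak`` at t = ``ttp``.

    Alternative smooth curve family; its analytic maximum location/height
    make it a convenient oracle for curve-level biomarker checks.
    """
    t = np.asarray(t, dtype=float)
    if ttp <= t0:
        raise ValueError("time-to-peak must exceed the onset delay")
    tau = np.clip((t - t0) / (ttp - t0), 0.0, None)
    with np.errstate(over="ignore"):
        c = peak * tau**alpha * np.exp(alpha * (1.0 - tau))
    return c


def uptake_curve(
    t,
    t0: float,
    ttp: float,
    peak: float,
    apex_halfwidth: float = APEX_HALFWIDTH,
    apex_drop: float = APEX_DROP,
    washout_slope_frac: float = WASHOUT_SLOPE_FRAC,
):
    """Piecewise-linear uptake: rise, symmetric apex at (ttp, peak), washout.

    Zero before onset ``t0``; linear rise to the apex region; within
    ``|t - ttp| <= apex_halfwidth`` the curve is the symmetric tent
    peak - m |t - ttp| with m = apex_drop * peak / apex_halfwidth; beyond,
    a washout of slope ``washout_slope_frac * m`` (floored at zero), i.e. a
    delayed washout slower than the initial rise.  Requires
    ttp - apex_halfwidth > t0.
    """
    t = np.asarray(t, dtype=float)
    w = apex_halfwidth
    if ttp - w <= t0:
        raise ValueError("time-to-peak must exceed onset by more than the apex half-width")
    m = apex_drop * peak / w
    shoulder = peak * (1.0 - apex_drop)
    rise = shoulder * np.clip((t - t0) / (ttp - w - t0), 0.0, None)
    apex = peak - m * np.abs(t - ttp)
    washout = shoulder - washout_slope_frac * m * (t - (ttp + w))
    c = np.where(
        t < ttp - w, rise, np.where(t <= ttp + w, apex, np.maximum(washout, 0.0))
    )
    return c


def ivim_signal(b, s0: float, f_percent: float, d: float, dstar: float):
    """IVIM bi-exponential forward model; ``f_percent`` in %, b in s/mm^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if not 0.0 <= f_percent <= 100.0:
        raise ValueError("f must lie in [0, 100] %")
    if dstar < d:
        raise ValueError("D* < D: the fast compartment must be faster")
    frac = f_percent / 100.0
    return s0 * (frac * np.exp(-b * dstar) + (1.0 - frac) * np.exp(-b * d))


def sphere_mask(shape, radius: int) -> np.ndarray:
    """Digital sphere centred on the grid."""
    centre = [(n - 1) / 2 for n in shape]
    zz = np.indices(shape, dtype=float)
    dist2 = sum((zz[k] - centre[k]) ** 2 for k in range(3))
    return dist2 <= radius**2


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-SD spatially correlated Gaussian field."""
    noise = rng.standard_normal(shape)
    fld = gaussian_filter(noise, sigma=sigma)
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def _draw_patient_params(spec: CohortSpec, responder: bool, rng: np.random.Generator):
    """Per-voxel ground-truth parameter draws for one patient.

    Returns (mask, TruthMaps).  Voxel TTP is the patient-level centre (drawn
    from the group distribution) plus symmetric voxel jitter, clipped to the
    sampled window so the analytic maximum stays recoverable.
    """
    g = 0 if responder else 1
    shape = spec.grid_shape
    mask = sphere_mask(shape, spec.roi_radius)
    vox = np.argwhere(mask)
    n = len(vox)

    onset = float(rng.uniform(5.0, 15.0))
    lo, hi = onset + APEX_HALFWIDTH + 10.0, spec.post_window
    ttp_centre = float(np.clip(
        rng.normal(spec.ttp_mean_by_group[g], spec.ttp_sd_by_group[g]), lo + 5.0, hi - 5.0
    ))
    ttp = np.clip(ttp_centre + spec.ttp_voxel_sd * rng.standard_normal(n), lo, hi)

    peak_centre = max(0.3, rng.normal(spec.peak_mean, 0.2))
    peak = peak_centre * np.clip(1.0 + 0.10 * rng.standard_normal(n), 0.5, 1.5)

    # ADC texture: correlated field plus a low-ADC component whose depth
    # scales with (1 - homogeneity), producing the negatively skewed maps
    # (more negative cluster shade) of heterogeneous tumours.
    h = spec.texture_homogeneity_by_group[g]
    d_centre = max(0.4e-3, rng.normal(spec.d_mean, 0.1e-3))
    fld = _smooth_field(rng, shape, sigma=0.6 + 1.6 * h)
    necro = _smooth_field(rng, shape, sigma=1.2)
    low = necro > np.quantile(necro[mask], 0.85)
    d_map = d_centre * (1.0 + 0.10 * fld)
    d_map[low] *= 1.0 - 0.55 * (1.0 - h)
    d = np.clip(d_map[mask], 0.2e-3, None)

    f_centre = max(2.0, rng.normal(spec.f_mean, 2.0))
    f = np.clip(f_centre + 1.5 * rng.standard_normal(n), 1.0, 30.0)

    # D* floored well above D so the perfusion compartment is fully decayed
    # at b >= 400 (validity condition of the segmented IVIM fit)
    dstar_centre = max(0.02, rng.normal(spec.dstar_mean, 0.003))
    dstar_sd = max(0.5e-3, rng.normal(spec.dstar_sd_by_group[g], spec.dstar_sd_spread))
    dstar = dstar_centre + dstar_sd * rng.standard_normal(n)
    dstar = np.maximum(dstar, np.maximum(2.0 * d, DSTAR_FLOOR))

    truth = TruthMaps(
        voxels=vox, ttp=ttp, peak=peak,
        onset=np.full(n, onset), d=d, dstar=dstar, f=f,
    )
    return mask, truth


def generate_dce(
    spec: CohortSpec, truth: TruthMaps, rng: np.random.Generator, mask: np.ndarray | None = None
) -> DCESeries:
    """Render the dynamic series implied by per-voxel truth curves.

    Noise is additive Gaussian with SD ``spec.noise_dce`` (scanner units).
    Raises if any truth TTP lies outside the sampled post-injection window.
    """
    if np.any(truth.ttp > spec.post_window) or np.any(
        truth.ttp <= truth.onset + APEX_HALFWIDTH
    ):
        raise ValueError("TTP outside the acquisition window")
    shape = spec.grid_shape if mask is None else mask.shape
    times = spec.times
    t_post = times - spec.injection_time
    vol = np.full(shape + (len(times),), DCE_BASELINE)
    for i, idx in enumerate(truth.voxels):
        c = truth.concentration(i, t_post)
        vol[tuple(idx)] = DCE_BASELINE * (1.0 + c)
    if spec.noise_dce > 0:
        vol = vol + rng.normal(0.0, spec.noise_dce, size=vol.shape)
    return DCESeries(
        intensities=vol, times=times, injection_time=spec.injection_time,
        spacing=spec.voxel_spacing,
    )


def generate_dwi(
    spec: CohortSpec, truth: TruthMaps, rng: np.random.Generator, mask: np.ndarray | None = None
) -> DWISeries:
    """Render multi-b DWI volumes with Rician noise of scale S0 / snr_dwi."""
    shape = spec.grid_shape if mask is None else mask.shape
    sigma = DWI_S0 / spec.snr_dwi if np.isfinite(spec.snr_dwi) else 0.0
    volumes: dict[float, np.ndarray] = {}
    for b in DWI_BVALUES:
        # background: non-enhancing mono-exponential tissue
        vol = np.full(shape, DWI_S0 * np.exp(-b * spec.d_mean))
        for i, idx in enumerate(truth.voxels):
            vol[tuple(idx)] = ivim_signal(b, DWI_S0, truth.f[i], truth.d[i], truth.dstar[i])
        if sigma > 0:
            real = vol + rng.normal(0.0, sigma, size=shape)
            imag = rng.normal(0.0, sigma, size=shape)
            vol = np.sqrt(real**2 + imag**2)
        volumes[b] = vol
    return DWISeries(volumes=volumes, spacing=spec.voxel_spacing)


def _draw_clinical(spec: CohortSpec, responder: bool, rng: np.random.Generator) -> dict[str, int]:
    probs = spec.clinical_p_by_group[0 if responder else 1]
    return {name: int(rng.random() < p) for name, p in zip(CLINICAL_FLAGS, probs)}


def generate_patient(
    spec: CohortSpec, patient_id: str, responder: bool, rng: np.random.Generator
) -> SyntheticPatient:
    mask, truth = _draw_patient_params(spec, responder, rng)
    dce = generate_dce(spec, truth, rng, mask)
    dwi = generate_dwi(spec, truth, rng, mask)
    clinical = _draw_clinical(spec, responder, rng)
    return SyntheticPatient(
        patient_id=patient_id, dce=dce, dwi=dwi, mask=mask, truth=truth,
        clinical=clinical, pcr=responder,
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Deterministic cohort: exactly ``n_responders`` patients labelled pCR."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_responders + spec.n_nonresponders)
    patients = []
    n_total = spec.n_responders + spec.n_nonresponders
    width = len(str(n_total))
    for i, child in enumerate(seeds):
        responder = i < spec.n_responders
        pid = f"P{i + 1:0{width}d}"
        patients.append(
            generate_patient(spec, pid, responder, np.random.default_rng(child))
        )
    return patients


def sample_truth_features(spec: CohortSpec) -> pd.DataFrame:
    """Patient-level summaries of the ground-truth voxel draws (no rendering).

    Fast path used for distribution calibration and statistical power
    analyses: per patient the TTP voxel distribution's mean/median/p25 and
    the voxel-wise D* standard deviation, with the pCR label.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_responders + spec.n_nonresponders)
    rows = []
    for i, child in enumerate(seeds):
        responder = i < spec.n_responders
        rng = np.random.default_rng(child)
        _, truth = _draw_patient_params(spec, responder, rng)
        rows.append(
            {
                "TTP_mean": float(np.mean(truth.ttp)),
                "TTP_median": float(np.median(truth.ttp)),
                "TTP_p25": float(np.percentile(truth.ttp, 25)),
                "D_star_std": float(np.std(truth.dstar)),
                "pcr": int(responder),
            }
        )
    return pd.DataFrame(rows)
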