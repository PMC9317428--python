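"""NIfTI-1 + JSON-sidecar layout for synthetic studies and derived maps.

One file per DCE dynamic (``dce_t000.nii.gz`` ...) and per b-value
(``dwi_b0.nii.gz`` ...), a binary ``mask.nii.gz``, and a ``series.json``
sidecar carrying acquisition times, injection time, b-values and voxel
spacing.  Cohort manifests and truth tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .diffusion import DWISeries
from .perfusion import DCESeries
from .synthetic import CLINICAL_FLAGS, SyntheticPatient

__all__ = [
    "write_patient",
    "read_dce",
    "read_dwi",
    "read_mask",
    "write_map",
    "write_cohort",
    "read_manifest",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _save(vol: np.ndarray, spacing, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), _affine(spacing)), path)


def write_patient(patient: SyntheticPatient, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = patient.dce.spacing
    for t in range(patient.dce.n_dynamics):
        _save(patient.dce.intensities[..., t], spacing, out / f"dce_t{t:03d}.nii.gz")
    for b, vol in patient.dwi.volumes.items():
        _save(vol, spacing, out / f"dwi_b{int(b)}.nii.gz")
    _save(patient.mask.astype(np.float32), spacing, out / "mask.nii.gz")
    sidecar = {
        "patient_id": patient.patient_id,
        "times_s": patient.dce.times.tolist(),
        "injection_time_s": patient.dce.injection_time,
        "bvalues_s_per_mm2": sorted(patient.dwi.volumes),
        "spacing_mm": list(spacing),
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=2))
    truth = pd.DataFrame(
        {
            "x": patient.truth.voxels[:, 0],
            "y": patient.truth.voxels[:, 1],
            "z": patient.truth.voxels[:, 2],
            "ttp_s": patient.truth.ttp,
            "peak_mM": patient.truth.peak,
            "onset_s": patient.truth.onset,
            "d_mm2_s": patient.truth.d,
            "dstar_mm2_s": patient.truth.dstar,
            "f_percent": patient.truth.f,
        }
    )
    truth.to_csv(out / "truth.csv", index=False)
    return out


def read_dce(patient_dir: str | Path) -> DCESeries:
    p = Path(patient_dir)
    meta = json.loads((p / "series.json").read_text())
    times = np.asarray(meta["times_s"], dtype=float)
    vols = [
        np.asarray(nib.load(p / f"dce_t{t:03d}.nii.gz").get_fdata())
        for t in range(len(times))
    ]
    return DCESeries(
        intensities=np.stack(vols, axis=-1),
        times=times,
        injection_time=float(meta["injection_time_s"]),
        spacing=tuple(meta["spacing_mm"]),
    )


def read_dwi(patient_dir: str | Path) -> DWISeries:
    p = Path(patient_dir)
    meta = json.loads((p / "series.json").read_text())
    volumes = {
        float(b): np.asarray(nib.load(p / f"dwi_b{int(b)}.nii.gz").get_fdata())
        for b in meta["bvalues_s_per_mm2"]
    }
    return DWISeries(volumes=volumes, spacing=tuple(meta["spacing_mm"]))


def read_mask(patient_dir: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(patient_dir) / "mask.nii.gz").get_fdata()) > 0.5


def write_map(map3d: np.ndarray, spacing, path: str | Path) -> None:
    _save(map3d, spacing, Path(path))


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        write_patient(patient, out / patient.patient_id)
        row = {"patient_id": patient.patient_id, "pcr": int(patient.pcr)}
        row.update({k: patient.clinical[k] for k in CLINICAL_FLAGS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(cohort_dir) / "manifest.csv").set_index("patient_id")
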