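"""NIfTI / JSON sidecar I/O.

All images use a diagonal affine with 2.5 mm isotropic voxels (the
acquisition resolution) and the slice axis third.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import ASLTimeseries
from .protocol import AcquisitionProtocol

VOXEL_MM = 2.5


def _affine() -> np.ndarray:
    return np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])


def save_nifti(data: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine()), path)
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata(), dtype=float)


def save_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_timeseries(series: ASLTimeseries, stem, extra_sidecar: dict | None = None):
    """Write SERIES.nii.gz + SERIES.json (+ SERIES_motion.tsv if moving)."""
    stem = Path(stem)
    save_nifti(series.data, stem.with_suffix(".nii.gz"))
    sidecar = series.protocol.to_sidecar(Corrections=list(series.corrections))
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    save_json(sidecar, stem.with_suffix(".json"))
    if series.motion_trace is not None:
        np.savetxt(
            stem.parent / (stem.name + "_motion.tsv"),
            series.motion_trace,
            delimiter="\t",
            fmt="%.6f",
        )


def load_timeseries(stem) -> ASLTimeseries:
    stem = Path(stem)
    data = load_nifti(stem.with_suffix(".nii.gz"))
    sidecar = load_json(stem.with_suffix(".json"))
    protocol = AcquisitionProtocol.from_sidecar(sidecar)
    motion_path = stem.parent / (stem.name + "_motion.tsv")
    motion = None
    if motion_path.exists():
        motion = np.loadtxt(motion_path, delimiter="\t").reshape(-1, 3)
    return ASLTimeseries(
        data=data,
        protocol=protocol,
        motion_trace=motion,
        corrections=tuple(sidecar.get("Corrections", ())),
    )
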