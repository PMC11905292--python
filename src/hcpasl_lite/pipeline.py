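"""End-to-end orchestration, QC metrics and parcel summaries.

``process_dataset`` ties the stages together in the standard order:
saturation-recovery fit on the control images -> saturation-recovery and
empirical banding correction (motion-resolved when a motion trace is
present) -> bias-field division (the field is an input) -> motion
correction -> GLM subtraction -> CSF reference-region M0 -> kinetic fit ->
calibration -> optional PVEc.  ``run_pipeline`` wraps it with file I/O, a
provenance record and a JSON QC report.

The band discontinuity index (BDI) quantifies banding as the ratio of the
mean absolute slice-mean intensity jump across band boundaries to the mean
jump between within-band neighbours; ~1 for band-free images.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, debanding, io, kinetic, subtraction
from . import pvec as pvec_mod
from .containers import ASLTimeseries, PerfusionMaps
from .protocol import AcquisitionProtocol

log = logging.getLogger("hcpasl_lite")


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------


def band_discontinuity_index(
    image: np.ndarray, band_size: int, mask: np.ndarray | None = None
) -> float:
    """Ratio of inter-band to intra-band slice-mean intensity jumps.

    With ``m(s)`` the masked mean intensity of slice ``s``, the BDI is
    mean(|m(s+1) - m(s)|) over band boundaries divided by the same mean
    over within-band neighbours.  Degenerate (constant) images return 1.
    """
    image = np.asarray(image, dtype=float)
    n_slices = image.shape[2]
    if n_slices < 2 * band_size:
        raise ValueError("need at least two bands")
    m = np.full(n_slices, np.nan)
    for s in range(n_slices):
        sl = image[:, :, s]
        vals = sl[mask[:, :, s]] if mask is not None else sl.ravel()
        if vals.size:
            m[s] = np.mean(vals)
    jumps = np.abs(np.diff(m))
    boundary = np.array(
        [(s + 1) % band_size == 0 for s in range(n_slices - 1)]
    )
    ok = np.isfinite(jumps)
    inter = jumps[boundary & ok]
    intra = jumps[~boundary & ok]
    if inter.size == 0 or intra.size == 0:
        raise ValueError("mask leaves no usable slice pairs")
    scale = np.nanmax(np.abs(m)) if np.any(np.isfinite(m)) else 0.0
    denom = float(np.mean(intra))
    numer = float(np.mean(inter))
    if denom <= 1e-12 * max(scale, 1.0):
        return 1.0
    return numer / denom


def compute_idps(
    values: np.ndarray,
    parcel_labels: np.ndarray,
    valid_mask: np.ndarray | None = None,
    measure: str = "value",
) -> pd.DataFrame:
    """Per-parcel n/mean/std (population std) of a parameter map.

    Label 0 is background and never emitted; parcels with no valid voxels
    are omitted with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(parcel_labels)
    if labels.shape != values.shape:
        raise ValueError("parcel label map must match the parameter map grid")
    sel = labels > 0
    if valid_mask is not None:
        sel &= valid_mask.astype(bool)
    if not np.any(sel):
        raise ValueError("no overlap between parcels and valid voxels")
    rows = []
    all_ids = np.unique(labels[labels > 0])
    for pid in all_ids:
        v = values[(labels == pid) & sel]
        if v.size == 0:
            log.warning("parcel %d has no valid voxels; omitted", pid)
            continue
        rows.append(
            dict(
                parcel=int(pid),
                measure=measure,
                n_voxels=int(v.size),
                mean=float(np.mean(v)),
                std=float(np.std(v)),  # population std (ddof=0)
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# In-memory pipeline
# ---------------------------------------------------------------------------


@dataclass
class ProcessOptions:
    """Stage toggles and tunables for one pipeline run."""

    satrecov: bool = True
    empirical: bool = True
    bias: bool = True
    glm: bool = True
    fit: bool = True
    calibrate: bool = True
    pvec: bool = False
    fit_arterial: bool = True
    empirical_gradient: float | None = None  # None -> estimate from calibration
    smoothness: float = 0.1
    kinetic_priors: kinetic.KineticPriors = field(default_factory=kinetic.KineticPriors)
    pvec_priors: pvec_mod.PVEcPriors = field(default_factory=pvec_mod.PVEcPriors)
    calib_params: calibration.CalibrationParams = field(
        default_factory=calibration.CalibrationParams
    )
    gm_pv_threshold: float = 0.7


def process_dataset(
    series: ASLTimeseries,
    calib: np.ndarray,
    pv_gm: np.ndarray,
    pv_wm: np.ndarray,
    csf_mask: np.ndarray,
    bias_field: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    options: ProcessOptions | None = None,
) -> dict:
    """Run the correction and estimation stages in memory.

    ``calib`` is (X, Y, Z, 2) or a single 3D image; only the first
    calibration image is used for calibration, though both are corrected.
    Returns a dict of intermediates, parameter maps and the QC report.
    """
    opt = options or ProcessOptions()
    protocol = series.protocol
    if brain_mask is None:
        brain_mask = (pv_gm + pv_wm) + 0.0 > 0.0
        brain_mask |= csf_mask.astype(bool)
    calib = np.asarray(calib, dtype=float)
    if calib.ndim == 3:
        calib = calib[..., None]
    results: dict = {"options": opt}
    qc: dict = {"mask_sizes": {"brain": int(np.sum(brain_mask))}}

    def series_bdi(s: ASLTimeseries) -> dict:
        out = {}
        ctrl = s.control_indices()
        plds = protocol.volume_plds()
        for p, pld in enumerate(protocol.plds):
            sel = [i for i in ctrl if plds[i] == pld]
            img = s.data[..., sel].mean(axis=-1)
            out[f"pld_{pld:g}"] = band_discontinuity_index(
                img, protocol.band_size, mask=brain_mask
            )
        return out

    qc["bdi"] = {"raw": series_bdi(series)}
    qc["bdi_calibration"] = {
        "raw": band_discontinuity_index(calib[..., 0], protocol.band_size, brain_mask)
    }

    # --- banding model -----------------------------------------------------
    # The satrecov model is fitted on the raw (acquisition-space) controls;
    # corrections are applied after motion correction with motion-resolved
    # factors, i.e. evaluated at the slice each voxel occupied at
    # acquisition, so they track anatomy rather than grid position.
    model = None
    corrected = subtraction.motion_correct(series)
    calib_corr = calib.copy()
    if opt.satrecov:
        model = debanding.fit_satrecov(series, mask=brain_mask)
        qc["satrecov_invalid_fits"] = int(np.sum(brain_mask & ~model.fit_mask))
        corrected = debanding.satrecov_correct(corrected, model)
        qc["bdi"]["after_satrecov"] = series_bdi(corrected)
        # calibration image is fully relaxed: no satrecov correction applied

    if opt.empirical:
        g = opt.empirical_gradient
        if g is None:
            imgs = [calib_corr[..., k] for k in range(calib_corr.shape[-1])]
            g = debanding.fit_empirical_banding(
                imgs, pv_gm, pv_wm, protocol.band_size
            )
        if model is not None:
            model.empirical_gradient = g
        corrected = debanding.empirical_correct(corrected, g)
        calib_corr = debanding.empirical_correct(calib_corr, g, protocol.band_size)
        results["empirical_gradient"] = g
        qc["bdi"]["after_empirical"] = series_bdi(corrected)

    if opt.bias and bias_field is not None:
        corrected = corrected.with_data(
            corrected.data / bias_field[..., None], extra_correction="bias"
        )
        calib_corr = calib_corr / bias_field[..., None]
        qc["bdi"]["after_bias"] = series_bdi(corrected)

    qc["bdi_calibration"]["corrected"] = band_discontinuity_index(
        calib_corr[..., 0], protocol.band_size, brain_mask
    )
    results["banding_model"] = model
    results["corrected_series"] = corrected
    results["corrected_calibration"] = calib_corr

    if not opt.glm:
        results["qc"] = qc
        return results

    # --- subtraction -------------------------------------------------------
    dm = subtraction.subtract_glm(corrected, banding_model=model, mask=brain_mask)
    results["difference"] = dm
    qc["n_valid_voxels"] = int(np.sum(dm.valid_mask))

    # --- calibration constant (needed by the fit's flow-term refinement) ---
    m0a = None
    if opt.calibrate:
        m0a = calibration.estimate_m0_blood(
            calib_corr[..., 0], csf_mask, opt.calib_params
        )
        results["m0_blood"] = m0a

    if not opt.fit:
        results["qc"] = qc
        return results

    # --- kinetic fit (non-PVEc path: no spatial regularisation) ------------
    if model is not None:
        t1_map = model.t1_filled()
    else:
        t1_map = np.full(series.shape, 1.3)
    fit_mask = dm.valid_mask & brain_mask & ((pv_gm + pv_wm) > 0.05)
    maps = kinetic.fit_voxelwise(
        dm,
        t1_map,
        protocol,
        priors=opt.kinetic_priors,
        fit_arterial=opt.fit_arterial,
        m0a=m0a,
        mask=fit_mask,
    )
    qc["kinetic_nonconverged"] = int(np.sum(fit_mask & ~maps.converged))
    if opt.calibrate:
        maps = calibration.calibrate(maps, m0a)
    results["perfusion"] = maps

    # --- PVEc ---------------------------------------------------------------
    if opt.pvec:
        res = pvec_mod.fit_pvec(
            dm,
            pv_gm,
            pv_wm,
            protocol,
            priors=opt.pvec_priors,
            smoothness=opt.smoothness,
            m0a=m0a,
        )
        if opt.calibrate:
            res.f_gm = res.f_gm * calibration.C.CBF_UNIT_SCALE / m0a
            res.f_wm = res.f_wm * calibration.C.CBF_UNIT_SCALE / m0a
            res.calibrated = True
        results["pvec"] = res
        qc["pvec_sweeps"] = len(res.objective_trace)

    results["qc"] = qc
    return results


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """File-level configuration for ``run_pipeline`` (YAML-serialisable)."""

    asl: str
    calibration: str
    pv_gm: str
    pv_wm: str
    csf_mask: str
    out_dir: str
    bias_field: str | None = None
    parcels: str | None = None
    motion: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def to_dict(self) -> dict:
        return {
            "asl": self.asl,
            "calibration": self.calibration,
            "pv_gm": self.pv_gm,
            "pv_wm": self.pv_wm,
            "csf_mask": self.csf_mask,
            "out_dir": self.out_dir,
            "bias_field": self.bias_field,
            "parcels": self.parcels,
            "motion": self.motion,
            "seed": self.seed,
            "log_level": self.log_level,
            "stages": self.stages,
            "constants": self.constants,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run ``process_dataset``, write outputs and provenance.

    Deterministic: re-running with the same configuration and inputs
    produces byte-identical result arrays.  Any stage failure raises with
    the stage name; outputs written before the failure are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series = io.load_timeseries(Path(config.asl).with_suffix("").with_suffix(""))
    if config.motion:
        series.motion_trace = np.loadtxt(config.motion, delimiter="\t").reshape(-1, 3)
    calib = io.load_nifti(config.calibration)
    pv_gm = io.load_nifti(config.pv_gm)
    pv_wm = io.load_nifti(config.pv_wm)
    csf = io.load_nifti(config.csf_mask) > 0.5
    bias = io.load_nifti(config.bias_field) if config.bias_field else None

    opt = ProcessOptions(**config.stages)
    for k, v in config.constants.items():
        setattr(opt, k, v)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    provenance = {
        "package": "hcpasl-lite",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
    }
    io.save_json(provenance, out / "provenance.json")

    stage = "process"
    try:
        results = process_dataset(
            series, calib, pv_gm, pv_wm, csf, bias_field=bias, options=opt
        )
        stage = "write"
        paths = {"provenance": out / "provenance.json"}
        if "corrected_series" in results:
            io.save_timeseries(results["corrected_series"], out / "asl_corrected")
            paths["asl_corrected"] = out / "asl_corrected.nii.gz"
        if "corrected_calibration" in results:
            io.save_nifti(results["corrected_calibration"], out / "calib_corrected.nii.gz")
        if "difference" in results:
            io.save_nifti(np.moveaxis(results["difference"].dm, 0, -1), out / "dm.nii.gz")
            io.save_nifti(
                np.moveaxis(results["difference"].effective_pld, 0, -1),
                out / "effective_pld.nii.gz",
            )
        if "perfusion" in results:
            maps: PerfusionMaps = results["perfusion"]
            io.save_nifti(maps.clipped_perfusion(), out / "cbf.nii.gz")
            io.save_nifti(maps.att, out / "att.nii.gz")
            if maps.abv is not None:
                io.save_nifti(maps.abv, out / "abv.nii.gz")
        if "pvec" in results:
            res = results["pvec"]
            for name in ("f_gm", "f_wm", "att_gm", "att_wm"):
                io.save_nifti(getattr(res, name), out / f"pvec_{name}.nii.gz")
        if config.parcels and "perfusion" in results:
            labels = io.load_nifti(config.parcels).astype(int)
            maps = results["perfusion"]
            tables = [
                compute_idps(maps.clipped_perfusion(), labels, maps.mask, "cbf"),
                compute_idps(maps.att, labels, maps.mask, "att"),
            ]
            if "pvec" in results:
                tables.append(
                    compute_idps(results["pvec"].f_gm, labels, results["pvec"].mask, "cbf_pvec_gm")
                )
                tables.append(
                    compute_idps(results["pvec"].att_gm, labels, results["pvec"].mask, "att_pvec_gm")
                )
            idps = pd.concat(tables, ignore_index=True)
            idps.to_csv(out / "idps.tsv", sep="\t", index=False)
            paths["idps"] = out / "idps.tsv"
        if "qc" in results:
            io.save_json(_jsonable(results["qc"]), out / "qc.json")
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc
    results["output_dir"] = out
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
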