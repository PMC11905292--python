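"""Motion-aware GLM label-control subtraction.

Label-control differencing is cast per PLD as a two-regressor ordinary
least squares problem — a static column of ones and a perfusion column of
+1/2 (control) / -1/2 (label) — so the perfusion coefficient equals the
control-minus-label difference dM.  With balanced volumes and no motion
this is identical to the difference of group means; the GLM form exists so
that per-voxel volume exclusion (motion outside the field of view) and the
residual-based standard error fall out naturally.

Motion handling: the per-volume rigid translation trace (an input, not
estimated here) is used to (a) resample each volume back to the reference
grid, (b) evaluate banding corrections at the slice each voxel actually
occupied at acquisition (see ``motion_resolved_correction_factors``), and
(c) exclude voxels that left the acquisition field of view in any volume.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import ASLTimeseries, DifferenceData
from .debanding import BandingModel, empirical_factors, satrecov_factor
from .protocol import AcquisitionProtocol


def build_design(annotations, pld_index: int):
    """Design matrix for one PLD: columns (static, perfusion).

    Returns ``(X, volume_indices)``.  The perfusion column is +1/2 for
    control and -1/2 for label volumes, so the fitted coefficient is the
    control-minus-label difference.
    """
    idx = [i for i, (p, _) in enumerate(annotations) if p == pld_index]
    if not idx:
        raise ValueError(f"no volumes for PLD index {pld_index}")
    labels = [annotations[i][1] for i in idx]
    if all(labels) or not any(labels):
        raise ValueError("need at least one label and one control volume")
    col = np.where(labels, -0.5, 0.5)
    X = np.column_stack([np.ones(len(idx)), col])
    return X, np.array(idx)


def motion_correct(series: ASLTimeseries) -> ASLTimeseries:
    """Resample each volume back to the reference grid (inverse translation).

    Trilinear interpolation; voxels pulled from outside the field of view
    are filled with zeros and must be excluded downstream via the FOV rule.
    """
    if series.motion_trace is None or not np.any(series.motion_trace):
        return series.with_data(series.data, extra_correction="moco")
    out = np.empty_like(series.data)
    for v in range(series.data.shape[3]):
        d = series.motion_trace[v]
        if np.any(d != 0):
            out[..., v] = ndimage.shift(
                series.data[..., v], -d, order=1, mode="constant", cval=0.0
            )
        else:
            out[..., v] = series.data[..., v]
    return series.with_data(out, extra_correction="moco")


def fov_valid_mask(shape, motion_trace: np.ndarray | None) -> np.ndarray:
    """Voxels whose anatomy stayed inside the acquisition FOV in every volume.

    A reference voxel at index ``y`` was acquired at ``y + d_v``; it is
    excluded if that position falls outside ``[0, dim - 1]`` for any
    volume; a voxel missing even a single timepoint is excluded entirely.
    """
    mask = np.ones(shape, dtype=bool)
    if motion_trace is None or not np.any(motion_trace):
        return mask
    lo = np.ceil(np.maximum(0.0, -motion_trace.min(axis=0))).astype(int)
    hi_excl = np.asarray(shape) - np.ceil(
        np.maximum(0.0, motion_trace.max(axis=0))
    ).astype(int)
    box = np.zeros(shape, dtype=bool)
    box[lo[0] : hi_excl[0], lo[1] : hi_excl[1], lo[2] : hi_excl[2]] = True
    return mask & box


def motion_resolved_correction_factors(
    model: BandingModel,
    motion_trace: np.ndarray | None,
    protocol: AcquisitionProtocol,
    include_satrecov: bool = True,
    include_empirical: bool = True,
) -> np.ndarray:
    """Per-volume banding correction factor fields in reference space.

    For each volume the factors (saturation recovery and/or empirical) are
    evaluated at the slice each voxel occupied at acquisition, i.e. the
    slice-index field shifted by the volume's Z translation, with
    sub-voxel shifts interpolating between adjacent slice factors.  The
    returned array has shape (X, Y, Z, T); the data should be *multiplied*
    by the satrecov part and *divided* by the empirical part — here both
    are combined into a single multiplicative correction field
    ``C_satrecov / f_empirical``.
    """
    t1 = model.t1_filled()
    X, Y, Z = t1.shape
    ann = protocol.volume_annotations()
    zgrid = np.arange(Z, dtype=float)[None, None, :]
    out = np.empty((X, Y, Z, len(ann)))
    cache: dict[tuple[int, float], np.ndarray] = {}
    for v, (p, _) in enumerate(ann):
        dz = 0.0
        if motion_trace is not None:
            dz = float(motion_trace[v, 2])
        key = (p, round(dz, 6))
        if key not in cache:
            s = np.clip(zgrid + dz, 0, Z - 1)
            fac = np.ones((X, Y, Z))
            if include_satrecov:
                fac = fac * satrecov_factor(t1, protocol, protocol.plds[p], s)
            if include_empirical:
                if model.empirical_gradient is None:
                    raise ValueError("model has no empirical gradient")
                fac = fac / empirical_factors(
                    model.empirical_gradient, model.band_size, s
                )
            cache[key] = fac
        out[..., v] = cache[key]
    return out


def subtract_glm(
    series: ASLTimeseries,
    banding_model: BandingModel | None = None,
    mask: np.ndarray | None = None,
) -> DifferenceData:
    """Per-PLD, per-voxel OLS label-control subtraction.

    The series must already be intensity-corrected and motion-corrected
    (or motion-free).  Voxels whose anatomy left the acquisition FOV at
    any timepoint are excluded from ``valid_mask``.  The effective PLD per
    voxel is the nominal PLD plus the slice-timing offset of the slice the
    voxel occupies in the reference geometry.

    If the series has been saturation-recovery corrected, that
    normalisation scaled the label-control difference by the same factor C
    as the static signal; the fitted dM (and its standard error) are
    divided by C — computed from ``banding_model``, which is then required
    — so the result is the physically sampled difference at the effective
    PLD.
    """
    protocol = series.protocol
    ann = protocol.volume_annotations()
    X, Y, Z = series.shape
    valid = fov_valid_mask((X, Y, Z), series.motion_trace)
    if mask is not None:
        valid = valid & mask.astype(bool)
    if not np.any(valid):
        raise ValueError("empty valid mask after FOV exclusion")
    if "satrecov" in series.corrections and banding_model is None:
        raise ValueError(
            "series is satrecov-corrected: banding_model required to rescale dM"
        )

    n_pld = len(protocol.plds)
    offsets = protocol.slice_offsets()
    dm = np.zeros((n_pld, X, Y, Z))
    dm_se = np.zeros((n_pld, X, Y, Z))
    eff_pld = np.zeros((n_pld, X, Y, Z))
    n_used = np.zeros((n_pld, X, Y, Z), dtype=int)

    for p, pld in enumerate(protocol.plds):
        Xd, idx = build_design(ann, p)
        Yv = series.data[..., idx]
        n = len(idx)
        # closed-form OLS for the (intercept, +-1/2 contrast) design
        is_ctrl = Xd[:, 1] > 0
        nc, nl = int(is_ctrl.sum()), int((~is_ctrl).sum())
        mean_c = Yv[..., is_ctrl].mean(axis=-1)
        mean_l = Yv[..., ~is_ctrl].mean(axis=-1)
        beta = mean_c - mean_l
        fitted = np.where(
            is_ctrl.reshape(1, 1, 1, -1), mean_c[..., None], mean_l[..., None]
        )
        dof = max(n - 2, 1)
        sse = np.sum((Yv - fitted) ** 2, axis=-1)
        sigma2 = sse / dof
        se = np.sqrt(sigma2 * (1.0 / nc + 1.0 / nl))

        dm[p] = beta
        dm_se[p] = se
        eff_pld[p] = pld + offsets[None, None, :]
        n_used[p][valid] = n

    if "satrecov" in series.corrections:
        t1 = banding_model.t1_filled()
        zgrid = np.arange(Z, dtype=float)[None, None, :]
        for p, pld in enumerate(protocol.plds):
            Cf = satrecov_factor(t1, protocol, pld, zgrid)
            dm[p] /= Cf
            dm_se[p] /= Cf

    dm[:, ~valid] = 0.0
    dm_se[:, ~valid] = 0.0
    return DifferenceData(
        dm=dm,
        dm_se=dm_se,
        effective_pld=eff_pld,
        n_used=n_used,
        valid_mask=valid,
        plds=protocol.plds,
    )
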