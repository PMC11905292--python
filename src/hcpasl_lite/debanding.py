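"""Correction of the two SMS slice-banding mechanisms.

Mechanism 1 — saturation recovery: a pre-saturation pulse precedes
labelling, so the static tissue signal at excitation is
``S = M0t (1 - exp(-t_sat / T1t))`` with ``t_sat = tau + PLD + delta(s)``.
Later-excited slices within a band have recovered longer and appear
brighter, with a discontinuity at every band boundary.  The model is
fitted voxelwise to the control images (all slice-specific saturation
times of all PLDs jointly) and the series is normalised to the intensity
each slice would have had at the nominal PLD.

Mechanism 2 — residual "empirical" banding: an approximately linear
within-band intensity gradient that survives saturation-recovery
correction (visible on the long-TR calibration image where saturation
recovery is negligible).  It is estimated as a single relative slope per
within-band position from satrecov-corrected, grey+white-masked
calibration images, averaged over bands and subjects, and removed by
dividing by ``1 + g (p - (band_size - 1)/2)`` — a factor that averages to
one over each band so band-mean intensity is preserved to first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ASLTimeseries
from .protocol import AcquisitionProtocol

T1_BOUNDS = (0.1, 5.0)


@dataclass
class BandingModel:
    """Voxelwise saturation-recovery fit plus the scalar empirical gradient."""

    m0t_map: np.ndarray
    t1t_map: np.ndarray
    fit_mask: np.ndarray  # True where the fit converged inside bounds
    band_size: int
    empirical_gradient: float | None = None

    def __post_init__(self):
        if np.any(self.t1t_map[self.fit_mask] <= 0):
            raise ValueError("t1t_map must be positive wherever the fit succeeded")

    def t1_fallback(self) -> float:
        """Mask-median T1 used for voxels where the fit failed."""
        if not np.any(self.fit_mask):
            raise ValueError("no valid saturation-recovery fits")
        return float(np.median(self.t1t_map[self.fit_mask]))

    def t1_filled(self) -> np.ndarray:
        return np.where(self.fit_mask, self.t1t_map, self.t1_fallback())


def satrecov_signal(m0, t1, t_sat):
    """Saturation-recovery signal m0 (1 - exp(-t_sat / t1))."""
    t1 = np.asarray(t1, dtype=float)
    t_sat = np.asarray(t_sat, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if np.any(t_sat < 0):
        raise ValueError("t_sat must be non-negative")
    return np.asarray(m0, dtype=float) * (1.0 - np.exp(-t_sat / t1))


def sat_time(protocol: AcquisitionProtocol, pld: float, slice_idx):
    """Pre-saturation interval tau + PLD + delta(slice)."""
    return protocol.sat_time(pld, slice_idx)


def fit_satrecov(
    series: ASLTimeseries,
    mask: np.ndarray | None = None,
    t1_grid_step: float = 0.005,
) -> BandingModel:
    """Voxelwise (M0t, T1t) fit to the control images.

    Profiled least squares: for each candidate T1 the optimal M0 is closed
    form, so the 2-parameter fit reduces to a 1-D search over T1 in
    [0.1, 5] s (grid + parabolic refinement), vectorised over all voxels of
    a slice, which share saturation times.  Voxels outside the mask, with
    degenerate (constant) signal, non-positive amplitude, or with the
    optimum pinned at a bound are flagged invalid.
    """
    protocol = series.protocol
    X, Y, Z = series.shape
    mask = np.ones((X, Y, Z), dtype=bool) if mask is None else mask.astype(bool)
    if not np.any(mask):
        raise ValueError("empty fit mask")

    ctrl_idx = series.control_indices()
    ctrl = series.data[..., ctrl_idx]
    ctrl_plds = protocol.volume_plds()[ctrl_idx]
    if len(np.unique(ctrl_plds)) < 2:
        raise ValueError("need >= 2 distinct saturation times per voxel")

    lo, hi = T1_BOUNDS
    grid = np.arange(lo, hi + 1e-9, t1_grid_step)
    m0_map = np.zeros((X, Y, Z))
    t1_map = np.zeros((X, Y, Z))
    valid = np.zeros((X, Y, Z), dtype=bool)

    for z in range(Z):
        sl = mask[:, :, z]
        if not np.any(sl):
            continue
        vx, vy = np.nonzero(sl)
        t_sat = protocol.label_duration + ctrl_plds + protocol.slice_offset(z)
        y = ctrl[vx, vy, z, :]  # (V, N)
        a = 1.0 - np.exp(-t_sat[None, :] / grid[:, None])  # (G, N)
        num = y @ a.T  # (V, G)
        den = np.sum(a**2, axis=1)[None, :]  # (1, G)
        yy = np.sum(y**2, axis=1, keepdims=True)
        sse = yy - num**2 / den  # (V, G)
        idx = np.argmin(sse, axis=1)

        # parabolic refinement of T1 between grid neighbours
        vr = np.arange(len(vx))
        li = np.clip(idx - 1, 0, len(grid) - 1)
        hi_i = np.clip(idx + 1, 0, len(grid) - 1)
        y0, y1, y2 = sse[vr, li], sse[vr, idx], sse[vr, hi_i]
        denom = y0 - 2 * y1 + y2
        interior = (idx > 0) & (idx < len(grid) - 1) & (denom > 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (y0 - y2) / denom
        delta = np.where(interior, np.clip(delta, -1.0, 1.0), 0.0)
        t1 = grid[idx] + delta * t1_grid_step

        a_ref = 1.0 - np.exp(-t_sat[None, :] / t1[:, None])  # (V, N)
        m0 = np.sum(y * a_ref, axis=1) / np.maximum(np.sum(a_ref**2, axis=1), 1e-300)
        spread = np.ptp(y, axis=1)
        ok = interior & (m0 > 0) & (spread > 1e-12 * np.maximum(np.abs(m0), 1.0))

        t1_map[vx, vy, z] = np.where(ok, t1, 0.0)
        m0_map[vx, vy, z] = np.where(ok, m0, 0.0)
        valid[vx, vy, z] = ok

    if not np.any(valid):
        raise ValueError("saturation-recovery fit failed in every voxel")
    return BandingModel(
        m0t_map=m0_map, t1t_map=t1_map, fit_mask=valid, band_size=protocol.band_size
    )


def satrecov_factor(
    t1,
    protocol: AcquisitionProtocol,
    pld: float,
    slice_idx,
):
    """Normalisation factor C(s, pld) mapping actual to nominal-PLD intensity.

    ``C = (1 - exp(-(tau+pld)/t1)) / (1 - exp(-(tau+pld+delta(s))/t1))``;
    equals 1 at the first slice of each band and is < 1 (never 0) for later
    within-band positions.  Fractional slice indices interpolate linearly
    between the factors of the neighbouring integer slices (what a voxel
    that moved between slices experiences).
    """
    t1 = np.asarray(t1, dtype=float)
    s = np.asarray(slice_idx, dtype=float)
    s = np.clip(s, 0, protocol.n_slices - 1)
    nominal = 1.0 - np.exp(-(protocol.label_duration + pld) / t1)

    s0 = np.floor(s).astype(int)
    s1 = np.minimum(s0 + 1, protocol.n_slices - 1)
    w = s - s0
    offsets = protocol.slice_offsets()

    def factor_at(si):
        t_sat = protocol.label_duration + pld + offsets[si]
        return nominal / (1.0 - np.exp(-t_sat / t1))

    return (1.0 - w) * factor_at(s0) + w * factor_at(s1)


def satrecov_correct(
    series: ASLTimeseries,
    model: BandingModel,
    motion_resolved: bool = True,
) -> ASLTimeseries:
    """Normalise every ASL volume (label and control) to the nominal PLD.

    Each voxel is multiplied by C(s, pld) computed with its fitted T1
    (mask-median T1 where the fit failed).  With ``motion_resolved`` and a
    motion trace present, the factor is evaluated at the slice each voxel
    occupied at acquisition (slice index shifted by the per-volume Z
    translation); the data are assumed already motion-corrected in that
    case.  Refuses to run twice on the same series.
    """
    if "satrecov" in series.corrections:
        raise ValueError("series is already saturation-recovery corrected")
    protocol = series.protocol
    if model.t1t_map.shape != series.shape:
        raise ValueError("banding model grid does not match series")
    t1 = model.t1_filled()
    X, Y, Z = series.shape
    zgrid = np.arange(Z, dtype=float)[None, None, :]

    out = np.empty_like(series.data)
    ann = protocol.volume_annotations()
    trace = series.motion_trace
    factors_cache: dict[tuple[int, float], np.ndarray] = {}
    for v, (p, _) in enumerate(ann):
        dz = 0.0
        if motion_resolved and trace is not None:
            dz = float(trace[v, 2])
        key = (p, round(dz, 6))
        if key not in factors_cache:
            factors_cache[key] = satrecov_factor(
                t1, protocol, protocol.plds[p], zgrid + dz
            )
        out[..., v] = series.data[..., v] * factors_cache[key]
    return series.with_data(out, extra_correction="satrecov")


def empirical_factors(g, band_size: int, slice_idx):
    """Within-band factor 1 + g (p - (band_size-1)/2), linearly interpolated
    at fractional slice indices.

    ``g`` is the single shared relative slope, or a sequence of per-band
    slopes (one per band, indexed by ``slice // band_size``).
    """
    s = np.asarray(slice_idx, dtype=float)
    s0 = np.floor(s).astype(int)
    w = s - s0
    p0 = s0 % band_size
    p1 = (s0 + 1) % band_size
    centre = (band_size - 1) / 2.0
    if np.ndim(g) == 0:
        g0 = g1 = g
    else:
        g = np.asarray(g, dtype=float)
        g0 = g[s0 // band_size]
        g1 = g[np.minimum((s0 + 1) // band_size, len(g) - 1)]
    f0 = 1.0 + g0 * (p0 - centre)
    f1 = 1.0 + g1 * (p1 - centre)
    return (1.0 - w) * f0 + w * f1


def fit_empirical_banding(
    images: list[np.ndarray],
    pv_gm: list[np.ndarray] | np.ndarray,
    pv_wm: list[np.ndarray] | np.ndarray,
    band_size: int,
    threshold: float = 0.7,
    per_band: bool = False,
):
    """Estimate the relative within-band gradient g.

    Per subject and band: OLS of mean grey+white-masked slice intensity on
    within-band position; the slope divided by the band-mean intensity
    gives a relative gradient, averaged over bands and then subjects.
    Bands with fewer than two populated slices are skipped; it is an error
    if every band of every subject is skipped.

    With ``per_band`` the band average is skipped and an array of one
    slope per band (averaged over subjects) is returned instead of the
    single shared scalar.
    """
    if isinstance(pv_gm, np.ndarray):
        pv_gm = [pv_gm] * len(images)
    if isinstance(pv_wm, np.ndarray):
        pv_wm = [pv_wm] * len(images)
    if not (len(images) == len(pv_gm) == len(pv_wm)):
        raise ValueError("one PV map pair required per calibration image")

    subject_gs = []
    subject_band_gs = []
    for img, gm, wm in zip(images, pv_gm, pv_wm):
        mask = (gm + wm) > threshold
        n_slices = img.shape[2]
        band_gs = []
        for b0 in range(0, n_slices, band_size):
            ps, means = [], []
            for p in range(band_size):
                sl_mask = mask[:, :, b0 + p]
                if np.any(sl_mask):
                    ps.append(p)
                    means.append(float(np.mean(img[:, :, b0 + p][sl_mask])))
            if len(ps) < 2:
                band_gs.append(np.nan)
                continue
            slope, _ = np.polyfit(ps, means, 1)
            band_mean = float(np.mean(means))
            band_gs.append(slope / band_mean if band_mean != 0 else np.nan)
        band_gs = np.asarray(band_gs)
        if np.any(np.isfinite(band_gs)):
            subject_band_gs.append(band_gs)
            subject_gs.append(float(np.nanmean(band_gs)))
    if not subject_gs:
        raise ValueError("no band had enough masked slices to fit")
    if per_band:
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.stack(subject_band_gs), axis=0)
    return float(np.mean(subject_gs))


def empirical_correct(
    data: np.ndarray | ASLTimeseries,
    g,
    band_size: int | None = None,
    motion_resolved: bool = True,
):
    """Divide out the empirical within-band gradient.

    Accepts a bare 3D/4D array (e.g. a calibration image) or an
    ``ASLTimeseries`` (all volumes corrected identically apart from the
    motion-resolved slice shift).  ``g`` is a scalar or per-band slopes.
    Raises if the correction factor is not strictly positive anywhere, or
    if the series was already corrected.
    """
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient must be finite")

    if isinstance(data, ASLTimeseries):
        series = data
        if "empirical" in series.corrections:
            raise ValueError("series is already empirically corrected")
        bs = series.protocol.band_size
        Z = series.shape[2]
        zgrid = np.arange(Z, dtype=float)[None, None, :]
        out = np.empty_like(series.data)
        trace = series.motion_trace
        for v in range(series.data.shape[3]):
            dz = 0.0
            if motion_resolved and trace is not None:
                dz = float(trace[v, 2])
            fac = empirical_factors(g, bs, np.clip(zgrid + dz, 0, Z - 1))
            if np.any(fac <= 0):
                raise ValueError("empirical factor not positive; |g| too large")
            out[..., v] = series.data[..., v] / fac
        return series.with_data(out, extra_correction="empirical")

    arr = np.asarray(data, dtype=float)
    if band_size is None:
        raise ValueError("band_size required for bare arrays")
    zgrid = np.arange(arr.shape[2], dtype=float)
    fac = empirical_factors(g, band_size, zgrid)
    if np.any(fac <= 0):
        raise ValueError("empirical factor not positive; |g| too large")
    shape = [1, 1, len(fac)] + [1] * (arr.ndim - 3)
    return arr / fac.reshape(shape)
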