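"""Synthetic SMS multi-delay PCASL phantom with known ground truth.

The phantom is a set of nested tissue compartments extruded along the
slice axis: a CSF core (standing in for the lateral ventricles), a WM
annulus, and an outer GM ribbon, with linear partial-volume transitions a
voxel or so wide.  Extrusion keeps the slice composition stationary along
Z, so slice-wise statistics (the empirical banding fit, the band
discontinuity index) are not confounded by anatomy.

``simulate_dataset`` renders the full acquisition: per-slice saturation
recovery of the static signal, label volumes carrying the kinetic-model
perfusion difference evaluated at the slice-adjusted time, the residual
within-band "empirical" intensity gradient, a smooth in-plane bias field,
per-volume rigid translations, homoscedastic Gaussian noise, and two
fully-relaxed long-TR calibration images.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from . import constants as C
from .containers import ASLTimeseries
from .kinetic import buxton_arterial, buxton_tissue, t1_apparent
from .protocol import AcquisitionProtocol, default_protocol

# Default empirical within-band gradient: negative so that the mechanism
# opposes saturation recovery (later-excited slices are brighter under
# satrecov, dimmer under the empirical effect), with magnitude chosen so
# the two nearly cancel at the shortest PLD.  The magnitude is a package
# choice; see docs/methods.md.
DEFAULT_EMPIRICAL_GRADIENT = -0.012
DEFAULT_NOISE_SD = 0.5


def m0_csf_value(
    m0_blood: float,
    te: float,
    lam_csf: float = C.LAMBDA_CSF,
    t2_csf: float = C.T2_CSF,
    t2_blood: float = C.T2_BLOOD,
) -> float:
    """Fully-relaxed CSF signal consistent with a given blood M0 at this TE.

    Inverse of the reference-region calibration formula, so that a
    noiseless phantom calibrates exactly.
    """
    return m0_blood * lam_csf * np.exp(te / t2_blood - te / t2_csf)


@dataclass
class PhantomTruth:
    """Ground-truth maps and scalars for one synthetic subject."""

    shape: tuple[int, int, int]
    pv_gm: np.ndarray
    pv_wm: np.ndarray
    pv_csf: np.ndarray
    f_gm: float  # ml/100g/min
    f_wm: float
    att_gm: float  # s
    att_wm: float
    abv: np.ndarray  # arterial blood volume fraction per voxel
    att_arterial: float
    t1_tissue: np.ndarray  # s per voxel
    m0_tissue: np.ndarray  # a.u. per voxel, fully relaxed
    m0_blood: float
    bias_field: np.ndarray
    empirical_gradient: float
    motion_trace: np.ndarray  # (n_volumes, 3) voxel translations
    noise_sd: float
    seed: int

    def __post_init__(self):
        pv_sum = self.pv_gm + self.pv_wm + self.pv_csf
        for name, arr in (("pv_gm", self.pv_gm), ("pv_wm", self.pv_wm), ("pv_csf", self.pv_csf)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(pv_sum > 1 + 1e-9):
            raise ValueError("partial volumes sum above 1")
        if self.att_gm <= 0 or self.att_wm <= 0 or self.att_arterial <= 0:
            raise ValueError("transit times must be positive")
        if self.f_gm < 0 or self.f_wm < 0:
            raise ValueError("perfusion must be non-negative")
        if np.any(self.abv < 0) or np.any(self.abv > 0.2):
            raise ValueError("abv must lie in [0, 0.2]")

    @property
    def support(self) -> np.ndarray:
        return (self.pv_gm + self.pv_wm + self.pv_csf) > 0

    def brain_mask(self, threshold: float = 0.5) -> np.ndarray:
        return (self.pv_gm + self.pv_wm + self.pv_csf) >= threshold

    def gm_mask(self, threshold: float = 0.9) -> np.ndarray:
        return self.pv_gm >= threshold

    def wm_mask(self, threshold: float = 0.9) -> np.ndarray:
        return self.pv_wm >= threshold

    def csf_mask(self, threshold: float = 0.95) -> np.ndarray:
        return self.pv_csf >= threshold


def _inside(r: np.ndarray, edge: float, width: float) -> np.ndarray:
    """Linear ramp from 1 (well inside ``edge``) to 0 (outside)."""
    return np.clip((edge + width / 2.0 - r) / width, 0.0, 1.0)


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 60),
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
    motion_sd: float = 0.0,
    n_arterial_rods: int = 0,
    abv_peak: float = 0.02,
    bias_amplitude: float = 0.1,
    **overrides,
) -> PhantomTruth:
    """Build a geometric phantom with smooth partial-volume transitions.

    Scalar overrides for array-valued truth fields (e.g. ``t1_tissue=1.3``)
    are broadcast over the tissue support; array overrides are used as-is.
    Deterministic for identical arguments.
    """
    protocol = protocol or default_protocol()
    X, Y, Z = shape
    if Z != protocol.n_slices:
        raise ValueError(
            f"phantom Z dimension ({Z}) must equal protocol n_slices ({protocol.n_slices})"
        )
    rng = np.random.default_rng(seed)

    x, y = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    cx, cy = (X - 1) / 2.0, (Y - 1) / 2.0
    r = np.sqrt(((x - cx) / (0.5 * X)) ** 2 + ((y - cy) / (0.5 * Y)) ** 2)
    width = 2.0 / min(X, Y)  # ~1 voxel transition
    r1, r2, r3 = 0.25, 0.62, 0.92  # CSF | WM | GM outer edges (normalised radius)
    in1, in2, in3 = (_inside(r, e, width) for e in (r1, r2, r3))
    pv_csf2d = in1
    pv_wm2d = in2 - in1
    pv_gm2d = in3 - in2

    def extrude(a2d):
        return np.repeat(a2d[:, :, None], Z, axis=2)

    pv_csf, pv_wm, pv_gm = extrude(pv_csf2d), extrude(pv_wm2d), extrude(pv_gm2d)
    pv_sum = pv_gm + pv_wm + pv_csf

    te = protocol.te
    m0_blood = C.M0_GM / C.LAMBDA
    m0_csf = m0_csf_value(m0_blood, te)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(
            pv_sum > 0,
            (pv_gm * C.T1_GM + pv_wm * C.T1_WM + pv_csf * C.T1_CSF)
            / np.maximum(pv_sum, 1e-12),
            0.0,
        )
    m0 = pv_gm * C.M0_GM + pv_wm * C.M0_WM + pv_csf * m0_csf

    abv = np.zeros(shape)
    if n_arterial_rods > 0:
        rod_r = (r1 + r2) / 2.0
        angles = 2 * np.pi * np.arange(n_arterial_rods) / n_arterial_rods
        for a in angles:
            ix = int(round(cx + rod_r * 0.5 * X * np.cos(a)))
            iy = int(round(cy + rod_r * 0.5 * Y * np.sin(a)))
            abv[ix, iy, :] = abv_peak

    bias2d = 1.0 + bias_amplitude * np.exp(
        -(((x - 0.35 * X) ** 2) + ((y - 0.4 * Y) ** 2)) / (2 * (0.35 * min(X, Y)) ** 2)
    )
    bias = extrude(bias2d)

    motion = np.zeros((protocol.n_volumes, 3))
    if motion_sd > 0:
        motion = rng.normal(0.0, motion_sd, size=(protocol.n_volumes, 3))
        motion[0] = 0.0  # reference volume

    truth = PhantomTruth(
        shape=(X, Y, Z),
        pv_gm=pv_gm,
        pv_wm=pv_wm,
        pv_csf=pv_csf,
        f_gm=60.0,
        f_wm=20.0,
        att_gm=1.2,
        att_wm=1.5,
        abv=abv,
        # chosen so the macrovascular bolus is still present during the
        # earliest readout for every slice (bolus spans 0.8-2.3 s, first
        # readout samples 1.7-2.23 s) -- an artery that had fully emptied
        # before any readout would contribute no signal at all
        att_arterial=0.8,
        t1_tissue=t1,
        m0_tissue=m0,
        m0_blood=m0_blood,
        bias_field=bias,
        empirical_gradient=DEFAULT_EMPIRICAL_GRADIENT,
        motion_trace=motion,
        noise_sd=DEFAULT_NOISE_SD,
        seed=seed,
    )

    array_fields = {"pv_gm", "pv_wm", "pv_csf", "abv", "t1_tissue", "m0_tissue", "bias_field"}
    valid = {f.name for f in fields(PhantomTruth)}
    for key, val in overrides.items():
        if key not in valid:
            raise TypeError(f"unknown truth field {key!r}")
        if key in array_fields and np.isscalar(val):
            background = 1.0 if key == "bias_field" else 0.0
            setattr(truth, key, np.where(truth.support, float(val), background))
        else:
            setattr(truth, key, val)
    truth.__post_init__()
    return truth


def empirical_factor_profile(g: float, band_size: int, n_slices: int) -> np.ndarray:
    """Multiplicative within-band factor 1 + g (p - (band_size-1)/2) per slice."""
    p = np.arange(n_slices) % band_size
    return 1.0 + g * (p - (band_size - 1) / 2.0)


def _delta_m_profiles(truth: PhantomTruth, protocol: AcquisitionProtocol, pld: float):
    """Per-slice unit-PV tissue dM and unit-abv arterial dM at this PLD."""
    t = protocol.label_duration + pld + protocol.slice_offsets()
    tau = protocol.label_duration
    f_gm_si = truth.f_gm / C.CBF_UNIT_SCALE
    f_wm_si = truth.f_wm / C.CBF_UNIT_SCALE
    dm_gm = buxton_tissue(
        t, f_gm_si, truth.att_gm, tau,
        t1app=t1_apparent(C.T1_GM, f_gm_si), m0a=truth.m0_blood,
    )
    dm_wm = buxton_tissue(
        t, f_wm_si, truth.att_wm, tau,
        t1app=t1_apparent(C.T1_WM, f_wm_si), m0a=truth.m0_blood,
    )
    dm_art = buxton_arterial(t, 1.0, truth.att_arterial, tau, m0a=truth.m0_blood)
    return dm_gm, dm_wm, dm_art


def simulate_dataset(
    truth: PhantomTruth,
    protocol: AcquisitionProtocol | None = None,
    apply_satrecov: bool = True,
):
    """Render the phantom into an ASL timeseries, calibration pair and sidecar.

    Returns ``(series, calib, sidecar)`` where ``calib`` has shape
    (X, Y, Z, 2).  Deterministic for identical truth and protocol (the
    noise stream is seeded from ``truth.seed``).
    """
    protocol = protocol or default_protocol()
    if truth.shape[2] != protocol.n_slices:
        raise ValueError("truth Z dimension must equal protocol n_slices")
    rng = np.random.default_rng(truth.seed)
    X, Y, Z = truth.shape
    ann = protocol.volume_annotations()
    offsets = protocol.slice_offsets() if apply_satrecov else np.zeros(Z)
    emp = empirical_factor_profile(
        truth.empirical_gradient, protocol.band_size, protocol.n_slices
    )[None, None, :]

    # The slice-timing physics (saturation recovery, kinetic sampling time)
    # and the banding/bias fields are properties of the scanner, locked to
    # the acquisition grid; motion moves the anatomy underneath them.  Each
    # volume is therefore rendered from the anatomy fields shifted by that
    # volume's translation, with all grid-locked effects applied afterwards.
    per_slice = {
        pld: _delta_m_profiles(truth, protocol, pld) for pld in protocol.plds
    }

    def render(fields, pld, is_label):
        m0, t1, pv_gm, pv_wm, abv = fields
        t_sat = protocol.label_duration + pld + offsets  # (Z,)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_t1 = np.where(t1 > 1e-6, 1.0 / np.maximum(t1, 1e-12), 0.0)
        recovery = 1.0 - np.exp(-t_sat[None, None, :] * inv_t1)
        recovery[t1 <= 1e-6] = 0.0
        vol = m0 * recovery
        if is_label:
            dm_gm, dm_wm, dm_art = per_slice[pld]
            vol = vol - (
                pv_gm * dm_gm[None, None, :]
                + pv_wm * dm_wm[None, None, :]
                + abv * dm_art[None, None, :]
            )
        return vol

    base_fields = (truth.m0_tissue, truth.t1_tissue, truth.pv_gm, truth.pv_wm, truth.abv)
    shifted_cache: dict[tuple, tuple] = {}

    def fields_for(v):
        d = truth.motion_trace[v]
        if not np.any(d != 0):
            return base_fields
        key = tuple(np.round(d, 9))
        if key not in shifted_cache:
            shifted_cache[key] = tuple(
                ndimage.shift(f, d, order=1, mode="constant", cval=0.0)
                for f in base_fields
            )
        return shifted_cache[key]

    data = np.empty((X, Y, Z, len(ann)))
    for v, (p, is_label) in enumerate(ann):
        vol = render(fields_for(v), protocol.plds[p], is_label)
        data[..., v] = vol * emp * truth.bias_field
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, size=data.shape)

    # long-TR calibration images: fully relaxed, empirical banding + bias only
    calib = np.empty((X, Y, Z, 2))
    for k in range(2):
        img = truth.m0_tissue * emp * truth.bias_field
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
        calib[..., k] = img

    sidecar = protocol.to_sidecar(
        Seed=int(truth.seed),
        NoiseSD=float(truth.noise_sd),
        EmpiricalGradient=float(truth.empirical_gradient),
    )
    series = ASLTimeseries(
        data=data, protocol=protocol, motion_trace=truth.motion_trace.copy()
    )
    return series, calib, sidecar
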