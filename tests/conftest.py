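"""Shared fixtures: phantoms and processing chains reused across tests.

The expensive objects (simulated datasets and fitted chains) are
session-scoped; tests must treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import hcpasl_lite as h
from hcpasl_lite import constants as C
from hcpasl_lite import debanding, kinetic, subtraction
from hcpasl_lite.kinetic import buxton_tissue, t1_apparent

# 10% of the peak GM difference signal under the default phantom kinetics
PEAK_GM_DM = 0.806
NOISE_10PCT = 0.0806


@pytest.fixture(scope="session")
def protocol():
    return h.default_protocol()


def run_chain(truth, protocol, fit_arterial=True):
    """Full correction + subtraction + kinetic fit on a phantom, returning
    every intermediate (the canonical processing chain used by many tests)."""
    series, calib, _ = h.simulate_dataset(truth, protocol)
    mask = truth.brain_mask()
    model = debanding.fit_satrecov(series, mask=mask)
    model.empirical_gradient = truth.empirical_gradient
    aligned = subtraction.motion_correct(series)
    corrected = debanding.satrecov_correct(aligned, model)
    corrected = debanding.empirical_correct(corrected, truth.empirical_gradient)
    corrected = corrected.with_data(
        corrected.data / truth.bias_field[..., None], extra_correction="bias"
    )
    dm = subtraction.subtract_glm(corrected, banding_model=model, mask=mask)
    fit_mask = mask & ((truth.pv_gm + truth.pv_wm) > 0.05)
    maps = kinetic.fit_voxelwise(
        dm,
        model.t1_filled(),
        protocol,
        fit_arterial=fit_arterial,
        m0a=truth.m0_blood,
        mask=fit_mask,
    )
    return dict(
        truth=truth,
        series=series,
        calib=calib,
        mask=mask,
        model=model,
        corrected=corrected,
        dm=dm,
        fit_mask=fit_mask,
        maps=maps,
    )


def forward_dm(truth, dm, protocol):
    """Ground-truth tissue difference signal at the effective PLDs."""
    tau = protocol.label_duration
    fg = truth.f_gm / C.CBF_UNIT_SCALE
    fw = truth.f_wm / C.CBF_UNIT_SCALE
    out = np.zeros_like(dm.dm)
    for p in range(dm.n_plds):
        t = tau + dm.effective_pld[p]
        tg = buxton_tissue(
            t, fg, truth.att_gm, tau, t1app=t1_apparent(C.T1_GM, fg), m0a=truth.m0_blood
        )
        tw = buxton_tissue(
            t, fw, truth.att_wm, tau, t1app=t1_apparent(C.T1_WM, fw), m0a=truth.m0_blood
        )
        out[p] = truth.pv_gm * tg + truth.pv_wm * tw
    return out


@pytest.fixture(scope="session")
def noiseless_chain(protocol):
    """Default banded, biased, noise-free, motionless phantom, fully processed."""
    truth = h.make_phantom((24, 24, 60), protocol, seed=1, noise_sd=0.0)
    return run_chain(truth, protocol)


@pytest.fixture(scope="session")
def noisy_mixed_chain(protocol):
    """Phantom with arterial rods at 10%-of-peak-signal noise, fully processed."""
    truth = h.make_phantom(
        (24, 24, 60), protocol, seed=7, noise_sd=NOISE_10PCT, n_arterial_rods=8
    )
    return run_chain(truth, protocol)


@pytest.fixture(scope="session")
def default_noisy_phantom(protocol):
    """Default study conditions: banding, bias and the default noise level."""
    truth = h.make_phantom((24, 24, 60), protocol, seed=2)
    series, calib, _ = h.simulate_dataset(truth, protocol)
    return dict(truth=truth, series=series, calib=calib)
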