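"""Shared fixtures: pulse pair, Bloch profiles and desk-scale recon studies.

The expensive objects (steady-state Bloch profiles, the 48x48x74
phantom study reconstructed with WA/PEN/NPEN at three TRs) are built once
per session and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mslab.bloch import TISSUES, SlabAcquisition, normalize_profile, simulate_all_profiles
from mslab.evaluate import evaluate_rmse
from mslab.forward import integrate_profiles, simulate_multislab_study
from mslab.phantom import make_synthetic_phantom
from mslab.pulses import design_slr_pulse
from mslab.recon import (
    estimate_profiles_sos,
    initial_profile_guess,
    recon_npen,
    recon_pen,
    recon_wa,
)

PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def pulses():
    """The protocol pulse pair: TBW 20 excitation (7.18 ms), TBW 8 refocusing (10.24 ms)."""
    ex = design_slr_pulse(20, 7.18, 256, "excitation", 90.0)
    ref = design_slr_pulse(8, 10.24, 256, "refocusing", 180.0)
    return ex, ref


@pytest.fixture(scope="session")
def acq11_tr2():
    return SlabAcquisition(n_slabs=11, TR=2000.0)


@pytest.fixture(scope="session")
def wm_profiles_tr2(pulses, acq11_tr2):
    """All 11 WM slab profiles at TR = 2 s, interleaved."""
    ex, ref = pulses
    return simulate_all_profiles(acq11_tr2, TISSUES["WM"], ex, ref)


@pytest.fixture(scope="session")
def study_results(pulses):
    """Desk-scale phantom study (9 slabs, 48x48x74) reconstructed at three TRs.

    Returns {TR_ms: {"wa"/"pen"/"npen": report, "npen_result": NPENResult,
    "truth": ..., "pv": ...}}; reports are EvaluationReports.
    """
    ex, ref = pulses
    out = {}
    vol = pv = None
    for tr in (2000.0, 4000.0, 7000.0):
        acq = SlabAcquisition(n_slabs=9, TR=tr)
        if vol is None:
            vol, pv = make_synthetic_phantom((48, 48, acq.total_slices), seed=PHANTOM_SEED)
        tp = {
            name: [normalize_profile(p) for p in simulate_all_profiles(acq, t, ex, ref)]
            for name, t in TISSUES.items()
        }
        S = integrate_profiles(pv, tp, acq)
        d, calib = simulate_multislab_study(vol, S)
        u_wa = recon_wa(d)
        S_sos = estimate_profiles_sos(calib, acq)
        u_pen, pen_info = recon_pen(d, S_sos)
        S0 = initial_profile_guess(calib, acq, pv.brain_mask())
        res = recon_npen(d, S0=S0, keep_iterates=(tr == 2000.0))
        entry = {
            "acq": acq,
            "truth": vol,
            "pv": pv,
            "pen_info": pen_info,
            "npen_result": res,
            "wa": evaluate_rmse(u_wa, vol.data, pv),
            "pen": evaluate_rmse(u_pen, vol.data, pv),
            "npen": evaluate_rmse(res.u, vol.data, pv),
        }
        if tr == 2000.0:
            entry["rmse_per_iter"] = [
                evaluate_rmse(ui, vol.data, pv).rmse for ui in res.u_iterates
            ]
        out[tr] = entry
    return out
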