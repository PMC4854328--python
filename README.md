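# mslab — slab-boundary artifacts in 3D multislab diffusion MRI

3D multislab acquisition tiles the brain into thick slabs, each excited as
a unit and resolved into thin slices by k<sub>z</sub> phase encoding. It is the
standard route to high-resolution diffusion MRI at SNR-optimal repetition
times (TR ≈ 1–2 s), but it suffers from **slab boundary artifacts**:
periodic signal modulation along the slice direction caused by

* **aliasing** — the RF slab profile extends beyond the phase-encoded slab
  FOV, so its transition bands and side lobes fold back into the slab; and
* **crosstalk** — where adjacent slab profiles overlap, magnetization is
  excited roughly twice per TR at irregular intervals, producing
  T1-dependent saturation dips at slab boundaries.

`mslab` implements the full simulation-and-correction chain for this
problem, aimed at MR physicists studying or correcting these artifacts:

* **`mslab.pulses`** — Shinnar–Le Roux design of the selective excitation /
  refocusing pulses (equiripple β filter, minimum-phase α, inverse SLR
  recursion) and their Cayley–Klein frequency responses.
* **`mslab.bloch`** — isochromat Bloch simulation of the steady-state
  multislab spin-echo signal profile per tissue (WM/GM/CSF), including
  firing schedules (sequential/interleaved), off-resonance, and the
  crosstalk saturation physics.
* **`mslab.diffusion`** — the two-compartment partial-volume signal model
  `M(b,v) = Σᵢ M0ᵢ fᵢ exp(−b vᵀ Dᵢ v)`, log-linear diffusion-tensor
  fitting, and FA/MD bias surfaces between slab center and boundary.
* **`mslab.phantom` / `mslab.forward`** — a synthetic brain phantom with
  WM/GM/CSF partial-volume maps, and the linear encoding model
  `P F C S u = d` (profile weighting, coil maps, Fourier transform, kz
  undersampling as a periodic fold).
* **`mslab.recon`** — the three reconstructions:
  **WA** (Fermi-windowed weighted slab averaging), **PEN** (linear
  inversion of `P F C S u = d` by conjugate gradients, profiles measured
  from 2×-FOV calibration data by sum-of-squares division), and **NPEN**
  (iteratively regularized Gauss–Newton joint estimation of image *u* and
  profiles *S*, with an in-plane Sobolev smoothness preconditioner on the
  profiles and a Gaussian k<sub>z</sub> penalty at the harmonics of the slab
  separation, stopping at the post-burn-in minimum of ‖Δu‖).
* **`mslab.evaluate` / `mslab.pipeline` / `mslab.cli`** — tissue-masked
  RMSE evaluation, a resumable end-to-end pipeline, and the `mslab` CLI
  (`simulate-profile`, `bias-surface`, `simulate-study`, `recon`,
  `evaluate`, `run-all`).

## Worked example

```python
import numpy as np
from mslab import (SlabAcquisition, TISSUES, design_slr_pulse,
                   simulate_all_profiles, normalize_profile,
                   make_synthetic_phantom, integrate_profiles,
                   simulate_multislab_study, evaluate_rmse)
from mslab.recon import (recon_wa, recon_pen, recon_npen,
                         estimate_profiles_sos, initial_profile_guess)

acq = SlabAcquisition(n_slabs=9, TR=2000.0)          # 9 slabs -> 74 slices
ex  = design_slr_pulse(20, 7.18, 256, "excitation", 90.0)
ref = design_slr_pulse(8, 10.24, 256, "refocusing", 180.0)

profiles = {name: [normalize_profile(p)
                   for p in simulate_all_profiles(acq, t, ex, ref)]
            for name, t in TISSUES.items()}
truth, pv = make_synthetic_phantom((48, 48, acq.total_slices), seed=7)
S = integrate_profiles(pv, profiles, acq)
d, calib = simulate_multislab_study(truth, S)

u_wa = recon_wa(d)
u_pen, _ = recon_pen(d, estimate_profiles_sos(calib, acq))
res = recon_npen(d, S0=initial_profile_guess(calib, acq, pv.brain_mask()))

for name, u in [("WA", u_wa), ("PEN", u_pen), ("NPEN", res.u)]:
    rep = evaluate_rmse(u, truth.data, pv)
    print(name, round(rep.rmse_tissue["WM"], 4))
```

prints

```
WA 0.1127
PEN 0.0501
NPEN 0.0267
```

i.e. at TR = 2 s the white-matter RMSE (fraction of the mean brain signal,
on voxels with WM fraction > 0.8) is more than four times lower for NPEN
than for WA, and roughly half of PEN's — the short-TR regime is exactly
where calibrated linear inversion still carries the residual
sum-of-squares modulation of the saturated profiles, while the joint
nonlinear estimate removes it. Rerunning at TR = 4 s and 7 s shows PEN
recovering (0.029, 0.018) while NPEN stays low throughout.

The same comparison from the shell:

```bash
mslab run-all --out-dir out/            # defaults: 9 slabs, TR 2 s, 48x48
mslab bias-surface --pair wm-csf --tr 2000 --out wmcsf.csv
```

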