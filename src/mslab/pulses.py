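"""RF pulse design via the Shinnar-Le Roux (SLR) transform.

Selective excitation/refocusing pulses are designed by choosing the
Cayley-Klein ``beta`` polynomial as an equiripple FIR filter (Parks-
McClellan), completing it with a minimum-phase ``alpha`` polynomial and
inverting the SLR recursion to obtain the RF waveform.  The same hard-pulse
model is used to evaluate frequency responses, so design and simulation are
mutually consistent.

Conventions: waveform samples are complex flip angles in radians per sample;
``dt`` is in ms; frequencies in Hz.  The transverse magnetization created
from equilibrium is ``Mxy = 2 conj(alpha) beta`` and the crushed spin-echo
refocusing efficiency is ``|beta^2|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RFPulse",
    "design_slr_pulse",
    "pulse_response",
    "excitation_profile",
    "refocusing_efficiency",
    "saturation_factor",
    "passband_fwhm_hz",
    "save_pulse_txt",
    "load_pulse_txt",
]


@dataclass(frozen=True)
class RFPulse:
    """A sampled RF pulse.

    Parameters
    ----------
    samples : complex ndarray
        Flip angle per sample in radians (hard-pulse approximation).
    dt : float
        Sample spacing in ms.
    tbw : float
        Time-bandwidth product of the design.
    nominal_flip : float
        Nominal on-resonance flip angle in degrees.
    role : str
        ``"excitation"`` or ``"refocusing"``.
    """

    samples: np.ndarray
    dt: float
    tbw: float
    nominal_flip: float
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=complex))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tbw <= 0:
            raise ValueError("time-bandwidth product must be positive")
        if self.role not in ("excitation", "refocusing"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total pulse length in ms (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def bandwidth_hz(self) -> float:
        """Design bandwidth tbw / duration, in Hz."""
        return self.tbw / (self.duration * 1e-3)

    @property
    def flip_integral_deg(self) -> float:
        """Small-tip flip angle implied by the waveform area, degrees."""
        return float(np.degrees(np.abs(self.samples.sum())))


# --- SLR machinery ----------------------------------------------------------


def _dinf(d1: float, d2: float) -> float:
    """Empirical transition-width factor for equiripple lowpass design."""
    a = (5.309e-3, 7.114e-2, -4.761e-1, -2.66e-3, -5.941e-1, -4.278e-1)
    l1, l2 = np.log10(d1), np.log10(d2)
    return (a[0] * l1**2 + a[1] * l1 + a[2]) * l2 + (a[3] * l1**2 + a[4] * l1 + a[5])


def _mag2mp(mag: np.ndarray) -> np.ndarray:
    """Minimum-phase frequency response with the given magnitude (cepstral)."""
    n = mag.size
    xl = np.log(np.maximum(mag, 1e-16))
    cep = np.fft.ifft(xl)
    w = np.zeros(n)
    w[0] = 1.0
    w[1 : (n + 1) // 2] = 2.0
    if n % 2 == 0:
        w[n // 2] = 1.0
    return np.exp(np.fft.fft(cep * w))


def _b2a(b: np.ndarray) -> np.ndarray:
    """Minimum-phase alpha polynomial for a given beta polynomial."""
    n = b.size
    npad = 1 << int(np.ceil(np.log2(16 * n)))
    bf = np.fft.fft(b, npad)
    bmax = np.abs(bf).max()
    if bmax >= 1.0:
        bf *= (1.0 - 1e-7) / bmax
    amag = np.sqrt(1.0 - np.abs(bf) ** 2)
    af = _mag2mp(amag)
    a = np.fft.ifft(af)[:n]
    return a


def _ab2rf(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inverse SLR recursion: recover the hard-pulse flip sequence."""
    a = np.asarray(a, dtype=complex).copy()
    b = np.asarray(b, dtype=complex).copy()
    n = a.size
    rf = np.zeros(n, dtype=complex)
    for j in range(n - 1, -1, -1):
        r = b[0] / a[0]
        theta = 2.0 * np.arctan(np.abs(r))
        phi = np.angle(r) - np.pi / 2
        rf[j] = theta * np.exp(1j * phi)
        if j == 0:
            break
        c = np.cos(theta / 2.0)
        s = 1j * np.exp(1j * phi) * np.sin(theta / 2.0)
        a_new = c * a + np.conj(s) * b
        b_new = -s * a + c * b
        a = a_new[:j]
        b = b_new[1 : j + 1]
    return rf


def design_slr_pulse(
    tbw: float,
    duration: float,
    n_samples: int = 256,
    role: str = "excitation",
    nominal_flip: float = 90.0,
    d1: float = 0.01,
    d2: float = 0.01,
) -> RFPulse:
    """Design a linear-phase selective SLR pulse.

    Parameters
    ----------
    tbw : float
        Time-bandwidth product (>= 2); controls edge sharpness.
    duration : float
        Pulse duration in ms.
    n_samples : int
        Number of hard-pulse samples (>= 64).
    role : str
        ``"excitation"`` or ``"refocusing"``; selects the ripple mapping
        between the beta filter and the magnetization profile.
    nominal_flip : float
        Flip angle in degrees, in (0, 180].
    d1, d2 : float
        Passband / stopband ripple of the magnetization profile.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if tbw < 2:
        raise ValueError("time-bandwidth product must be >= 2")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    if not 0.0 < nominal_flip <= 180.0:
        raise ValueError("nominal_flip must be in (0, 180] degrees")
    if role not in ("excitation", "refocusing"):
        raise ValueError(f"unknown role {role!r}")
    if tbw >= n_samples / 2:
        raise ValueError("n_samples too small for requested tbw")

    flip_rad = np.radians(nominal_flip)
    bsf = np.sin(flip_rad / 2.0)
    if role == "excitation":
        d1e, d2e = np.sqrt(d1 / 2.0), d2 / np.sqrt(2.0)
    else:
        d1e, d2e = d1 / 4.0, np.sqrt(d2)

    w = _dinf(d1e, d2e) / tbw  # fractional transition width
    fp = (1.0 - w) * tbw / (2.0 * n_samples)  # cycles/sample
    fs = (1.0 + w) * tbw / (2.0 * n_samples)
    b = signal.remez(n_samples, [0.0, fp, fs, 0.5], [1.0, 0.0], weight=[1.0, d1e / d2e], fs=1.0)
    b = b * bsf
    a = _b2a(b)
    rf = _ab2rf(a, b)
    dt = duration / n_samples
    return RFPulse(samples=rf, dt=dt, tbw=tbw, nominal_flip=nominal_flip, role=role)


# --- frequency responses ----------------------------------------------------


def pulse_response(pulse: RFPulse, freqs_hz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cayley-Klein (alpha, beta) of the pulse over off-resonance frequency.

    Hard-pulse propagation: free precession by ``2*pi*f*dt`` between
    instantaneous rotations given by the waveform samples.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    phase = np.exp(-1j * 2.0 * np.pi * freqs_hz * pulse.dt * 1e-3)
    a = np.ones_like(phase)
    b = np.zeros_like(phase)
    for rfj in pulse.samples:
        b = b * phase
        theta = np.abs(rfj)
        c = np.cos(theta / 2.0)
        s = 1j * np.exp(1j * np.angle(rfj)) * np.sin(theta / 2.0)
        a, b = c * a - np.conj(s) * b, s * a + c * b
    return a, b


def excitation_profile(pulse: RFPulse, freqs_hz: np.ndarray, rewind: bool = True) -> np.ndarray:
    """Transverse magnetization ``Mxy(f)`` created from equilibrium Mz=1.

    With ``rewind`` the linear phase of the slab-select gradient is
    compensated by the standard half-area rewinder lobe, making the
    passband response approximately real.
    """
    a, b = pulse_response(pulse, freqs_hz)
    mxy = 2.0 * np.conj(a) * b
    if rewind:
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        t_half = (pulse.n_samples - 1) / 2.0 * pulse.dt * 1e-3
        mxy = mxy * np.exp(1j * 2.0 * np.pi * freqs_hz * t_half)
    return mxy


def refocusing_efficiency(pulse: RFPulse, freqs_hz: np.ndarray) -> np.ndarray:
    """Crushed spin-echo refocusing profile ``beta^2(f)`` (complex).

    The linear phase across the band (slab-select gradient) is compensated,
    as done in the sequence by the symmetric crusher/select gradient timing.
    """
    _, b = pulse_response(pulse, freqs_hz)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    t_full = (pulse.n_samples - 1) * pulse.dt * 1e-3
    return b * b * np.exp(1j * 2.0 * np.pi * freqs_hz * t_full)


def saturation_factor(pulse: RFPulse, freqs_hz: np.ndarray) -> np.ndarray:
    """Longitudinal scaling ``Mz -> Mz * (1 - 2|beta|^2)`` under ideal crushing."""
    _, b = pulse_response(pulse, freqs_hz)
    return 1.0 - 2.0 * np.abs(b) ** 2


def passband_fwhm_hz(pulse: RFPulse, n_freq: int = 4096) -> float:
    """Measured full width at half maximum of the pulse's |Mxy| profile."""
    span = 4.0 * pulse.bandwidth_hz
    freqs = np.linspace(-span, span, n_freq)
    prof = np.abs(excitation_profile(pulse, freqs))
    half = prof.max() / 2.0
    above = prof >= half
    idx = np.flatnonzero(above)
    if idx.size < 2:
        return 0.0
    # linear interpolation at the two half-maximum crossings
    lo, hi = idx[0], idx[-1]
    f_lo = np.interp(half, [prof[lo - 1], prof[lo]], [freqs[lo - 1], freqs[lo]])
    f_hi = np.interp(half, [prof[hi + 1], prof[hi]], [freqs[hi + 1], freqs[hi]])
    return float(f_hi - f_lo)


# --- I/O --------------------------------------------------------------------


def save_pulse_txt(pulse: RFPulse, path) -> None:
    """Write the waveform as two-column text: time (ms), complex amplitude."""
    t = np.arange(pulse.n_samples) * pulse.dt
    with open(path, "w") as fh:
        fh.write(f"# role={pulse.role} tbw={pulse.tbw} flip={pulse.nominal_flip} dt={pulse.dt}\n")
        for ti, si in zip(t, pulse.samples):
            fh.write(f"{ti:.9g}\t{si.real:+.12e}{si.imag:+.12e}j\n")


def load_pulse_txt(path) -> RFPulse:
    """Read a pulse written by :func:`save_pulse_txt`."""
    meta = {}
    times, samples = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            tcol, scol = line.split("\t")
            times.append(float(tcol))
            samples.append(complex(scol))
    if not samples:
        raise ValueError(f"no waveform samples found in {path}")
    return RFPulse(
        samples=np.asarray(samples),
        dt=float(meta["dt"]),
        tbw=float(meta["tbw"]),
        nominal_flip=float(meta["flip"]),
        role=meta["role"],
    )
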