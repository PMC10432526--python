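"""Anti-aliasing sideband demodulation of sub-wavelength vibration.

A scatterer vibrating at f_m imprints first-order sidebands on its depth
carrier, offset by z_m = w_m / (2 k1).  When f_m exceeds half the A-line rate
the sideband phasor is aliased: writing f_m = f_bar + 0.5 n f_A with
0 <= f_bar < 0.5 f_A, the phasor observed across consecutive A-lines rotates
at the *apparent* frequency f_bar (n even) or f_bar - 0.5 f_A (n odd).  The
demodulator

  1. evaluates the tomogram on a grid shifted by exactly z_m (a fractional-
     pixel frequency shift of the raw samples) so each depth pixel reads its
     own sideband at the sideband's true center,
  2. subtracts the static DC background over the N A-lines,
  3. normalizes by the carrier DC at the scatterer depth, and
  4. locks in on the apparent frequency over the A-line index, which also
     rejects the counter-rotating sideband of the scatterer 2 z_m away.

Locking against the recorded stimulus phase instead of the nominal A-line
clock removes the sweep-period jitter that otherwise dominates the phase
noise at ultrasonic modulation frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import MScanCube
from .config import SweepConfig

WINDOWS = {
    "rect": lambda n: np.ones(n),
    "hann": lambda n: np.hanning(n),
}


@dataclass
class ComplexTomogram:
    """Per-A-line complex depth signals F[b, m, z] (one-sided, Z = S/2)."""

    F: np.ndarray  # (B, N, Z) complex
    delta_z: float
    delta_f: float
    sweep: SweepConfig
    window: str = "rect"
    samples: np.ndarray | None = None  # windowed real samples, for shifts
    x: np.ndarray | None = None
    stimulus_phase: np.ndarray | None = None
    f_m: float | None = None

    @property
    def n_alines(self) -> int:
        return self.F.shape[1]

    @property
    def carrier_dc(self) -> np.ndarray:
        """Time-averaged (static) tomogram <F>, shape (B, Z)."""
        return self.F.mean(axis=1)


@dataclass(frozen=True)
class SidebandPlan:
    """Aliasing bookkeeping for one modulation frequency."""

    f_m: float
    f_A: float
    n: int  # integer in f_m = f_folded + 0.5 n f_A
    f_folded: float  # 0 <= f_folded < 0.5 f_A
    f_apparent: float  # signed apparent frequency after the parity rule
    z_m: float  # sideband depth offset w_m / (2 k1), meters
    z_m_pixels: float
    lobe: str = "left"


def aline_transform(cube: MScanCube, window: str = "rect") -> ComplexTomogram:
    """Fourier transform each A-line into a one-sided complex tomogram."""
    try:
        w = WINDOWS[window](cube.sweep.n_samples)
    except KeyError:
        raise ValueError(f"unknown window {window!r}; options: {sorted(WINDOWS)}")
    samples = cube.data * w
    z = cube.sweep.n_depth
    F = np.fft.rfft(samples, axis=-1)[..., :z]
    return ComplexTomogram(
        F=F,
        delta_z=cube.sweep.delta_z,
        delta_f=cube.sweep.delta_f,
        sweep=cube.sweep,
        window=window,
        samples=samples,
        x=cube.x,
        stimulus_phase=cube.stimulus_phase,
        f_m=cube.f_m,
    )


def plan_sidebands(f_m: float, sweep: SweepConfig, lobe: str = "left") -> SidebandPlan:
    """Fold f_m into the sub-Nyquist band of the A-line rate (parity rule)."""
    if f_m <= 0:
        raise ValueError("f_m must be positive")
    if lobe not in ("left", "right"):
        raise ValueError("lobe must be 'left' or 'right'")
    half = 0.5 * sweep.f_A
    n = int(np.floor(f_m / half))
    f_folded = f_m - n * half
    # guard against float round-off putting f_folded at the band edge
    if f_folded >= half:
        n += 1
        f_folded -= half
    f_apparent = f_folded if n % 2 == 0 else f_folded - half
    if f_apparent == 0.0 and n > 0:
        raise ValueError(
            f"f_m = {f_m} Hz folds onto DC; vibration indistinguishable from "
            "static background at this A-line rate"
        )
    z_m = 2 * np.pi * f_m / (2 * sweep.k1)
    z_m_pixels = f_m / sweep.delta_f
    if z_m_pixels >= sweep.n_depth:
        raise ValueError(
            f"sideband offset {z_m_pixels:.1f} px exceeds the depth range "
            f"({sweep.n_depth} px)"
        )
    return SidebandPlan(
        f_m=f_m,
        f_A=sweep.f_A,
        n=n,
        f_folded=f_folded,
        f_apparent=f_apparent,
        z_m=z_m,
        z_m_pixels=z_m_pixels,
        lobe=lobe,
    )


@dataclass
class VibrationMap:
    """Recovered complex vibration amplitude per depth pixel.

    ``k0_delta[b, z]`` is the dimensionless complex amplitude k0 * delta of
    the scatterer at depth pixel z (phase = local vibration phase);
    ``mask`` is False where the carrier DC is below the validity threshold.
    """

    k0_delta: np.ndarray
    mask: np.ndarray
    plan: SidebandPlan
    k0: float
    x: np.ndarray | None = None
    delta_z: float | None = None
    jitter_corrected: bool = False

    @property
    def delta(self) -> np.ndarray:
        """Vibration amplitude in meters."""
        return np.abs(self.k0_delta) / self.k0

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.k0_delta)


def _sideband_tomogram(tom: ComplexTomogram, shift_px: float) -> np.ndarray:
    """Evaluate the spectrum on a grid shifted by ``shift_px`` pixels.

    Returns G[b, m, p] = F_cont(p - shift_px), computed exactly by modulating
    the time samples before the FFT, so fractional sideband offsets introduce
    no interpolation error.
    """
    if tom.samples is None:
        raise ValueError("tomogram lacks raw samples; rebuild with aline_transform")
    s = tom.samples.shape[-1]
    j = np.arange(s)
    carrier = np.exp(2j * np.pi * shift_px * j / s)
    return np.fft.fft(tom.samples * carrier, axis=-1)[..., : s // 2]


def carrier_mask(carrier_dc: np.ndarray, threshold_db: float = 6.0) -> np.ndarray:
    """Validity mask: carrier DC above ``threshold_db`` over the median floor."""
    mag = np.abs(carrier_dc)
    floor = np.median(mag, axis=-1, keepdims=True)
    return mag > 10 ** (threshold_db / 20) * floor


def demodulate(
    tom: ComplexTomogram,
    plan: SidebandPlan,
    stimulus_phase: np.ndarray | None = None,
    time_window: str | None = None,
    bin_tol: float = 0.25,
    threshold_db: float = 6.0,
) -> VibrationMap:
    """Recover the complex vibration amplitude k0*delta at every depth pixel.

    With ``stimulus_phase`` (shape (B, N), the recorded drive phase at each
    A-line) the temporal lock-in uses the measured phasor and thereby corrects
    sweep-period jitter; otherwise the nominal A-line clock is used.  Without
    a window over the A-line index, N * f_m / f_A must be integer so the
    static background cancels exactly and the apparent frequency falls on a
    DFT bin.
    """
    n = tom.n_alines
    nu = plan.f_apparent / plan.f_A  # cycles per A-line, in [-0.5, 0.5)
    cycles = n * plan.f_m / plan.f_A
    if time_window is None:
        if abs(cycles - round(cycles)) > bin_tol:
            raise ValueError(
                f"N*f_m/f_A = {cycles:.3f} is not integer: apparent frequency "
                "falls between DFT bins; pass time_window='hann' or change N"
            )
        w = np.ones(n)
    else:
        w = WINDOWS[time_window](n)

    sign = +1.0 if plan.lobe == "left" else -1.0
    g = _sideband_tomogram(tom, sign * plan.z_m_pixels)
    d = g - g.mean(axis=1, keepdims=True)
    c_dc = tom.carrier_dc  # (B, Z)
    mask = carrier_mask(c_dc, threshold_db)
    safe = np.where(mask, c_dc, 1.0)
    r = d / safe[:, None, :]

    m = np.arange(1, n + 1)  # sweeps are indexed 1..N
    if stimulus_phase is not None:
        theta = np.asarray(stimulus_phase)  # (B, N): w_m t_m + phi measured
        corrected = True
    else:
        theta = np.broadcast_to(2 * np.pi * nu * m, r.shape[:2])
        corrected = False
    # in the one-sided FFT spectrum the left sidelobe carries -k0 d e^{-i theta}
    # and the right sidelobe +k0 d e^{+i theta}
    lock = np.exp(1j * sign * theta) * w  # (B, N)
    amp = (lock[:, :, None] * r).sum(axis=1) / w.sum()
    if plan.lobe == "left":
        k0_delta = -np.conj(amp)
    else:
        k0_delta = amp
    # re-reference the vibration phase from sample 0 to the sweep center
    s, f_s = tom.sweep.n_samples, tom.sweep.f_s
    k0_delta = k0_delta * np.exp(2j * np.pi * plan.f_m * (s / 2) / f_s)
    k0_delta = np.where(mask, k0_delta, 0.0)
    return VibrationMap(
        k0_delta=k0_delta,
        mask=mask,
        plan=plan,
        k0=tom.sweep.k0,
        x=tom.x,
        delta_z=tom.delta_z,
        jitter_corrected=corrected,
    )


def jitter_correct(
    tom: ComplexTomogram, plan: SidebandPlan, **kwargs
) -> VibrationMap:
    """Demodulate locked to the recorded stimulus phase.

    The stimulus waveform is recorded with the same sweep-period jitter as
    the acquisition; its per-A-line phase replaces the nominal modulation
    phase in the lock-in.  Falls back to the uncorrected demodulation with a
    warning when no stimulus record is available.
    """
    if tom.stimulus_phase is None:
        warnings.warn("no stimulus record on tomogram: jitter correction skipped")
        return demodulate(tom, plan, **kwargs)
    return demodulate(tom, plan, stimulus_phase=tom.stimulus_phase, **kwargs)


def envelope_washout(sweep: SweepConfig, f_m: float) -> float:
    """Amplitude attenuation of an intra-sweep modulation at f_m.

    The phase of the carrier pixel averages the vibration over the sweep,
    weighted by the power envelope; the measured oscillation amplitude is
    reduced by W = |sum_j P_j e^{i w_m t_j}| / sum_j P_j.
    """
    from .acquisition import power_envelope, sample_times

    t = sample_times(sweep)
    p = power_envelope(sweep, t)
    return np.abs(np.sum(p * np.exp(2j * np.pi * f_m * t))) / np.sum(p)


def conventional_phase_demod(
    tom: ComplexTomogram, f_m: float, threshold_db: float = 6.0
) -> VibrationMap:
    """Classical sub-Nyquist (f_m < 0.5 f_A) phase-oscillation demodulation.

    The carrier-pixel phase oscillates as 2 k0 delta * g(t); delta is read
    from the magnitude of the temporal DFT of the unwrapped phase at f_m,
    divided by the sweep-envelope washout factor.  Serves as the independent
    oracle for the sideband demodulator in the non-aliased regime.
    """
    sweep = tom.sweep
    if f_m >= 0.5 * sweep.f_A:
        raise ValueError("conventional demodulation requires f_m < 0.5 f_A")
    n = tom.n_alines
    nu = f_m / sweep.f_A
    phase = np.unwrap(np.angle(tom.F), axis=1)
    phase = phase - phase.mean(axis=1, keepdims=True)
    m = np.arange(1, n + 1)
    coeff = (phase * np.exp(-2j * np.pi * nu * m)[None, :, None]).sum(axis=1)
    osc_amp = 2.0 * np.abs(coeff) / n  # amplitude of the phase oscillation
    w = envelope_washout(sweep, f_m)
    k0_delta_mag = osc_amp / (2.0 * w)
    phase_out = np.angle(1j * coeff)  # sin-referenced, matches sideband output
    mask = carrier_mask(tom.carrier_dc, threshold_db)
    k0_delta = np.where(mask, k0_delta_mag * np.exp(1j * phase_out), 0.0)
    plan = plan_sidebands(f_m, sweep)
    return VibrationMap(
        k0_delta=k0_delta,
        mask=mask,
        plan=plan,
        k0=sweep.k0,
        x=tom.x,
        delta_z=tom.delta_z,
    )
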