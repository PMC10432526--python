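"""Forward model of a swept-source interferometer observing vibrating scatterers.

The detector current for the m-th sweep of a scatterer at depth ``z0`` with
axial displacement ``delta * g_m(t)`` is

    I_m(t) = r P(t) cos(2 k0 z0 + 2 k1 t z0 + (2 k0 + 2 k1 t) delta g_m(t))

with the full cosine retained (no small-amplitude truncation), a Gaussian
sweep power envelope ``P``, and for harmonic drive
``g_m(t) = sin(w_m (t + t_m) + phi)`` where ``t_m`` is the (possibly
jittered) start time of sweep m.  Sweep-period jitter is modeled as i.i.d.
Gaussian deviations of the period that accumulate into the A-line start
times; the stimulus waveform is "recorded" with the identical jitter so the
demodulator can correct it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import ScanProtocol, SweepConfig

ComplexAmplitude = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class VibrationField:
    """Harmonic vibration field delta(x, z) * sin(w_m t + phi + arg delta).

    ``delta`` is either a scalar amplitude (m) or a callable ``delta(x, z)``
    returning a complex amplitude whose argument encodes the local phase of a
    traveling wave (e.g. ``delta0 * exp(-i k x)``).
    """

    f_m: float
    delta: float | ComplexAmplitude = 0.0
    phi: float = 0.0

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.f_m

    def amplitude(self, x: float, z: np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if callable(self.delta):
            amp = np.asarray(self.delta(np.full_like(z, x), z), dtype=complex)
        else:
            amp = np.full(z.shape, complex(self.delta))
        return amp


@dataclass(frozen=True)
class ScattererScene:
    """Discrete scatterers per lateral position.

    ``x``: lateral positions (m), shape (B,).
    ``scatterers``: for each position, an (n_s, 2) array of (depth z0 [m],
    reflectance amplitude r >= 0).
    """

    x: np.ndarray
    scatterers: Sequence[np.ndarray]

    def __post_init__(self):
        if len(self.x) != len(self.scatterers):
            raise ValueError("one scatterer list per lateral position required")
        for s in self.scatterers:
            if s.size and (not np.all(np.isfinite(s)) or np.any(s[:, 1] < 0)):
                raise ValueError("reflectance amplitudes must be finite and >= 0")


@dataclass(frozen=True)
class JitterRealization:
    """Per-sweep period deviations tau_i and cumulative A-line start times.

    Sweeps are indexed m = 1..N: ``t[m-1] = m T + sum_{i<=m} tau_i``.
    """

    tau: np.ndarray
    T: float
    t: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.tau)
        object.__setattr__(
            self, "t", np.arange(1, n + 1) * self.T + np.cumsum(self.tau)
        )


@dataclass
class MScanCube:
    """Raw M-B scan: real detector samples of shape (B, N, S).

    ``stimulus_phase[b, m]`` is the phase of the recorded stimulus waveform at
    the start of A-line m (= w_m t_m + phi, sampled with the same jitter that
    affected the acquisition), wrapped to (-pi, pi].
    """

    data: np.ndarray
    x: np.ndarray
    stimulus_phase: np.ndarray | None
    sweep: SweepConfig
    f_m: float
    phi: float = 0.0
    snr_db: float | None = None
    seed: int | None = None

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]

    @property
    def n_alines(self) -> int:
        return self.data.shape[1]

    @property
    def mscan_duration(self) -> float:
        """Duration of one M-scan, N / f_A (s)."""
        return self.n_alines / self.sweep.f_A

    @property
    def duration(self) -> float:
        """Total acquisition time per frequency, B * N / f_A (s)."""
        return self.n_positions * self.n_alines / self.sweep.f_A


def sample_times(sweep: SweepConfig) -> np.ndarray:
    """Intra-sweep sample times t_hat (s), centered on the sweep."""
    s = sweep.n_samples
    return (np.arange(s) - s / 2) / sweep.f_s


def power_envelope(sweep: SweepConfig, t_hat: np.ndarray | None = None) -> np.ndarray:
    """Gaussian sweep power envelope P(t_hat), FWHM = sigma_env * T."""
    if t_hat is None:
        t_hat = sample_times(sweep)
    fwhm = sweep.sigma_env * sweep.T
    return np.exp(-4 * np.log(2) * t_hat**2 / fwhm**2)


def draw_jitter(
    n: int, sigma_t: float, seed: int | np.random.Generator | None = None, T: float = 1 / 43.2e3
) -> JitterRealization:
    """Draw i.i.d. Gaussian period deviations tau_i ~ N(0, sigma_t^2)."""
    if sigma_t < 0:
        raise ValueError("sigma_t must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tau = rng.normal(0.0, sigma_t, n) if sigma_t > 0 else np.zeros(n)
    return JitterRealization(tau=tau, T=T)


def simulate_aline(
    scatterers: np.ndarray,
    sweep: SweepConfig,
    vib: VibrationField,
    t_m: float | np.ndarray,
    x: float = 0.0,
) -> np.ndarray:
    """Simulate detector samples for one (or a stack of) A-line sweep(s).

    ``scatterers`` is an (n_s, 2) array of (z0, r); ``t_m`` may be an array of
    start times, in which case the returned array has shape (len(t_m), S).
    Deterministic; detector noise is added by :func:`simulate_mscan`.
    """
    t_m = np.atleast_1d(np.asarray(t_m, dtype=float))
    t_hat = sample_times(sweep)
    env = power_envelope(sweep, t_hat)
    out = np.zeros((len(t_m), sweep.n_samples))
    if scatterers.size == 0:
        return out[0] if t_m.size == 1 else out
    z0 = scatterers[:, 0]
    if np.any(z0 >= sweep.z_nyquist) or np.any(z0 < 0):
        raise ValueError(
            f"scatterer depth outside unambiguous range [0, {sweep.z_nyquist:.4g} m)"
        )
    r = scatterers[:, 1]
    amp = vib.amplitude(x, z0)
    mod_mag = np.abs(amp)
    mod_phase = np.angle(amp)
    k0, k1 = sweep.k0, sweep.k1
    # phase (n_s, n_t, S): static fringe + vibration term, full cosine
    tt = t_hat[None, None, :] + t_m[None, :, None]
    g = np.sin(vib.omega * tt + vib.phi + mod_phase[:, None, None])
    phase = (
        2 * k0 * z0[:, None, None]
        + 2 * k1 * t_hat[None, None, :] * z0[:, None, None]
        + (2 * k0 + 2 * k1 * t_hat[None, None, :]) * mod_mag[:, None, None] * g
    )
    out = (r[:, None, None] * np.cos(phase)).sum(axis=0) * env[None, :]
    return out[0] if t_m.size == 1 else out


def simulate_mscan(
    scene: ScattererScene,
    sweep: SweepConfig,
    vib: VibrationField,
    protocol: ScanProtocol,
    snr_db: float | None = None,
    seed: int | None = 0,
) -> MScanCube:
    """Simulate a full M-B scan cube with period jitter and detector noise.

    ``snr_db`` sets the A-line power SNR of the brightest scatterer (peak FFT
    power over mean noise-floor power); ``None`` or ``inf`` disables noise.
    Jitter and detector noise use independent child streams of ``seed`` so
    either can be switched off without shifting the other.
    """
    n, b = protocol.n_alines, protocol.n_positions
    if n < 1 or b < 1:
        raise ValueError("protocol must have N, B >= 1")
    if len(scene.x) != b:
        raise ValueError(
            f"scene has {len(scene.x)} lateral positions but protocol expects {b}"
        )
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    jit_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    data = np.empty((b, n, sweep.n_samples))
    stim_phase = np.empty((b, n))
    for ib in range(b):
        jit = draw_jitter(n, sweep.sigma_T, jit_rng, T=sweep.T)
        data[ib] = simulate_aline(scene.scatterers[ib], sweep, vib, jit.t, x=scene.x[ib])
        stim_phase[ib] = np.angle(np.exp(1j * (vib.omega * jit.t + vib.phi)))

    if snr_db is not None and np.isfinite(snr_db):
        x_snr = 10 ** (snr_db / 10)
        peak = max(
            np.abs(np.fft.rfft(data[ib, 0])).max() for ib in range(b)
        )
        if peak == 0:
            warnings.warn("empty scene: SNR undefined, no noise added")
        else:
            sigma_n = peak / np.sqrt(sweep.n_samples * x_snr)
            data += noise_rng.normal(0.0, sigma_n, data.shape)

    return MScanCube(
        data=data,
        x=np.asarray(scene.x, dtype=float),
        stimulus_phase=stim_phase,
        sweep=sweep,
        f_m=vib.f_m,
        phi=vib.phi,
        snr_db=snr_db,
        seed=seed,
    )


# -- canonical scenes -------------------------------------------------------


def mirror_scene(
    sweep: SweepConfig, depth_px: float = 107.0, r: float = 1.0, n_positions: int = 1,
    dx: float = 15e-6,
) -> ScattererScene:
    """Single mirror-like reflector at ``depth_px`` pixels, every position."""
    z0 = depth_px * sweep.delta_z
    sc = np.array([[z0, r]])
    return ScattererScene(
        x=np.arange(n_positions) * dx, scatterers=[sc] * n_positions
    )


def three_scatterer_scene(
    sweep: SweepConfig,
    f_m: float = 688.8e3,
    depth_px: float = 107.0,
    deltas: tuple[float, float, float] = (20e-9, 0.0, 10e-9),
    r: tuple[float, float, float] = (1.0, 1.0, 1.0),
    phi: float = 0.0,
) -> tuple[ScattererScene, VibrationField]:
    """Canonical aliasing demonstration fixture.

    Three scatterers separated by the sideband depth offset z_m = w_m/(2 k1):
    scatterer 1 at ``depth_px`` (vibrating), scatterer 2 at z0 - z_m (static),
    scatterer 3 at z0 - 2 z_m (vibrating).  At the default 688.8 kHz drive
    (16 * f_A - 2.4 kHz for the default sweep) all three contributions meet in
    the same Fourier pixel, which is what the demodulator must untangle.
    """
    z_m = 2 * np.pi * f_m / (2 * sweep.k1)
    z0 = depth_px * sweep.delta_z
    depths = np.array([z0, z0 - z_m, z0 - 2 * z_m])
    if np.any(depths <= 0):
        raise ValueError("depth_px too shallow for this modulation frequency")
    sc = np.column_stack([depths, np.asarray(r, dtype=float)])
    amps = np.asarray(deltas, dtype=float)

    def delta_of(x, z):
        out = np.zeros(np.shape(z), dtype=complex)
        for zd, a in zip(depths, amps):
            out = np.where(np.abs(z - zd) < sweep.delta_z / 2, a, out)
        return out

    scene = ScattererScene(x=np.zeros(1), scatterers=[sc])
    return scene, VibrationField(f_m=f_m, delta=delta_of, phi=phi)


def traveling_wave_scene(
    sweep: SweepConfig,
    protocol: ScanProtocol,
    f_m: float,
    speed: float,
    amplitude: float,
    attenuation: float = 0.0,
    depth_px: float = 107.0,
    r: float = 1.0,
    phi: float = 0.0,
) -> tuple[ScattererScene, VibrationField]:
    """Surface reflector per position carrying delta0 e^{-(i k_r + k_i) x}."""
    k_r = 2 * np.pi * f_m / speed
    x = np.arange(protocol.n_positions) * protocol.dx
    z0 = depth_px * sweep.delta_z
    sc = np.array([[z0, r]])

    def delta_of(xx, zz):
        return amplitude * np.exp(-(1j * k_r + attenuation) * xx)

    scene = ScattererScene(x=x, scatterers=[sc] * protocol.n_positions)
    return scene, VibrationField(f_m=f_m, delta=delta_of, phi=phi)


def halfspace_wave_scene(
    sweep: SweepConfig,
    protocol: ScanProtocol,
    f_m: float,
    speed: float,
    amplitude: float,
    surface_px: float = 60.0,
    depth_extent_px: float = 100.0,
    depth_step_px: float = 2.0,
    attenuation: float = 0.0,
    r: float = 1.0,
) -> tuple[ScattererScene, VibrationField]:
    """Scattering half-space whose vibration follows a surface-wave mode.

    Scatterers populate depths below ``surface_px``; the vibration amplitude
    decays as the surface-wave eigenfunction |psi(z)| ~ e^{-k_z z} with
    k_z = 0.31 k, giving the canonical 1/e amplitude decay depth of about half
    a wavelength.
    """
    k_r = 2 * np.pi * f_m / speed
    k_z = 0.31 * k_r
    x = np.arange(protocol.n_positions) * protocol.dx
    z_surf = surface_px * sweep.delta_z
    depths = z_surf + np.arange(0, depth_extent_px, depth_step_px) * sweep.delta_z
    sc = np.column_stack([depths, np.full(depths.shape, r)])

    def delta_of(xx, zz):
        return (
            amplitude
            * np.exp(-k_z * np.maximum(zz - z_surf, 0.0))
            * np.exp(-(1j * k_r + attenuation) * xx)
        )

    scene = ScattererScene(x=x, scatterers=[sc] * protocol.n_positions)
    return scene, VibrationField(f_m=f_m, delta=delta_of)
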