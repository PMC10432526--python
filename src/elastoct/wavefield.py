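"""Surface-wave field analysis: k-domain spectra, mode picking, and fitting
of the analytic Rayleigh + supershear near-field model.

Convention: time dependence e^{+i w t}; an outgoing attenuated wave goes as
e^{-i K x} with K = k_r - i k_i (k_i >= 0), so |u| decays with distance.  The
surface displacement excited by a harmonically driven cylindrical contact of
radius ``a`` on an incompressible half-space is

    u(x) = i pi (a p0 K^4 / rho w^2) * sum over {R, SS} of
           J1(K_mode a) K_mode / F'(K_mode) * H0^(1)(-K_mode x)

where K_R and K_SS are the Rayleigh and supershear roots of the secular
equation F(kappa) = (2 kappa^2 - K^2)^2
- 4 kappa^2 sqrt(kappa^2) sqrt(kappa^2 - K^2) sign{Re(kappa^2 - K^2)}.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special


@dataclass(frozen=True)
class SurfaceProfile:
    """Complex surface displacement u(x) at a single frequency."""

    x: np.ndarray  # lateral positions (m), uniform grid
    u: np.ndarray  # complex displacement (m)
    f: float  # frequency (Hz)

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.size < 8:
            raise ValueError("need at least 8 lateral positions")
        dx = np.diff(x)
        if not np.allclose(dx, dx[0], rtol=1e-6):
            raise ValueError("lateral grid must be uniform")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "u", np.asarray(self.u, dtype=complex))

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass(frozen=True)
class ComplexWavenumber:
    """Complex wavenumber of the bulk shear wave at one frequency."""

    k_r: float  # rad/m
    k_i: float  # attenuation coefficient, rad/m (>= 0 for passive media)
    f: float  # Hz

    def __post_init__(self):
        if self.k_r <= 0:
            raise ValueError("k_r must be positive")

    @property
    def K(self) -> complex:
        return self.k_r - 1j * self.k_i

    @property
    def phase_velocity(self) -> float:
        return 2 * np.pi * self.f / self.k_r


# -- secular equation -------------------------------------------------------


def secular_function(kappa: complex | np.ndarray, K: complex = 1.0):
    """Rayleigh secular function for an incompressible half-space.

    Principal square roots of the two factors, with the sign{Re(kappa^2-K^2)}
    branch rule that places the Rayleigh root on the real axis and the leaky
    supershear root in the lower half plane.
    """
    kappa = np.asarray(kappa, dtype=complex)
    d = kappa**2 - K**2
    sgn = np.where(d.real >= 0, 1.0, -1.0)
    return (2 * kappa**2 - K**2) ** 2 - 4 * kappa**2 * sgn * np.sqrt(
        kappa**2
    ) * np.sqrt(d)


@lru_cache(maxsize=1)
def secular_roots() -> tuple[complex, complex]:
    """Roots (K_R/K, K_SS/K) of the secular equation, |F| < 1e-10.

    The Rayleigh root is real (~1.047); the supershear root is complex with a
    negative imaginary part (~0.4696 - 0.1355i).
    """
    f_real = lambda x: float(secular_function(x).real)
    k_r = optimize.brentq(f_real, 1.0 + 1e-9, 1.9, xtol=1e-15)

    def residual(p):
        v = secular_function(p[0] + 1j * p[1])
        return [float(v.real), float(v.imag)]

    sol = optimize.least_squares(
        residual, [0.5, -0.1], xtol=3e-16, ftol=3e-16, gtol=3e-16
    )
    k_ss = complex(sol.x[0], sol.x[1])
    for root in (k_r, k_ss):
        if abs(secular_function(root)) > 1e-10:
            raise RuntimeError("secular root refinement failed to converge")
    return complex(k_r), k_ss


def _secular_derivative(kappa: complex, K: complex, h: float = 1e-7) -> complex:
    step = h * abs(K)
    return (secular_function(kappa + step, K) - secular_function(kappa - step, K)) / (
        2 * step
    )


# -- analytic near-field model (forward) ------------------------------------


def surface_wave_displacement(
    x: np.ndarray,
    K: complex,
    a: float,
    rho: float,
    omega: float,
    p0: complex = 1.0,
) -> np.ndarray:
    """Analytic surface displacement of the Rayleigh + supershear near field.

    Valid outside the contact (|x| >= a).  ``K`` is the complex bulk shear
    wavenumber (k_r - i k_i); ``p0`` an arbitrary complex source strength.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) < a):
        raise ValueError("model is valid only outside the contact, |x| >= a")
    r_ratio, ss_ratio = secular_roots()
    out = np.zeros(x.shape, dtype=complex)
    pref = 1j * np.pi * a * p0 * K**4 / (rho * omega**2)
    for ratio in (r_ratio, ss_ratio):
        k_mode = ratio * K
        term = (
            special.jv(1, k_mode * a)
            * k_mode
            / _secular_derivative(k_mode, K)
            * special.hankel1(0, -k_mode * np.abs(x))
        )
        out += term
    return pref * out


# -- spatial spectra and mode picking ---------------------------------------


def spatial_spectrum(
    profile: SurfaceProfile, pad_factor: int = 8, window: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Wavenumber-domain spectrum of a surface profile.

    Returns (k, U) with k in rad/m (fftshifted, both signs) for the transform
    U(k) = sum_j u(x_j) e^{-i k x_j}; a plane wave e^{+i k0 x} peaks at +k0.
    Zero-padding by ``pad_factor`` refines the grid for peak interpolation.
    ``window="hann"`` suppresses the leakage pedestal of the abrupt near-field
    truncation, sharpening peak location at the cost of resolution.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    u = profile.u
    if window is not None:
        if window != "hann":
            raise ValueError("window must be None or 'hann'")
        u = u * np.hanning(len(u))
    n = len(profile.x) * pad_factor
    U = np.fft.fftshift(np.fft.fft(u, n=n))
    k = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(n, profile.dx))
    return k, U


@dataclass(frozen=True)
class ModePick:
    """Result of picking one propagating mode from a k-domain spectrum."""

    k_r: float  # |k| of the peak (rad/m), sub-bin interpolated
    k_signed: float  # signed peak location
    f: float
    amplitude: float

    @property
    def phase_velocity(self) -> float:
        """v = 2 pi f / k = omega / k (m/s)."""
        return 2 * np.pi * self.f / self.k_r


def pick_mode(
    k: np.ndarray,
    U: np.ndarray,
    expected_k_range: tuple[float, float],
    f: float,
    min_peak_ratio: float = 4.0,
) -> ModePick:
    """Pick the dominant mode with |k| inside ``expected_k_range``.

    Both propagation directions are searched; the peak is refined by 3-point
    quadratic interpolation on log magnitude (ties broken toward lower |k|).
    Raises when no peak stands ``min_peak_ratio`` above the in-band median.
    """
    lo, hi = expected_k_range
    if not 0 <= lo < hi:
        raise ValueError("expected_k_range must satisfy 0 <= lo < hi")
    mag = np.abs(U)
    band = (np.abs(k) >= max(lo, 1e-12)) & (np.abs(k) <= hi)
    if not np.any(band):
        raise ValueError("expected_k_range contains no spectral bins")
    floor = np.median(mag[band])
    idx_band = np.flatnonzero(band)
    order = np.lexsort((np.abs(k[idx_band]), -mag[idx_band]))
    i = idx_band[order[0]]
    if floor > 0 and mag[i] < min_peak_ratio * floor:
        raise ValueError(
            f"no peak above {min_peak_ratio}x the in-band median floor "
            f"(max/floor = {mag[i] / floor:.2f}); is a mode present in "
            f"[{lo:.3g}, {hi:.3g}] rad/m?"
        )
    # quadratic interpolation on log magnitude
    k_peak = k[i]
    if 0 < i < len(k) - 1 and mag[i - 1] > 0 and mag[i + 1] > 0:
        y0, y1, y2 = np.log(mag[i - 1 : i + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            k_peak = k[i] + shift * (k[1] - k[0])
    return ModePick(k_r=abs(k_peak), k_signed=float(k_peak), f=f, amplitude=float(mag[i]))


def filter_mode(
    profile: SurfaceProfile,
    k_center: float,
    rel_bandwidth: float = 0.35,
    pad_factor: int = 1,
) -> SurfaceProfile:
    """Band-pass the profile around one mode in the k domain.

    Retains a band of relative width ``rel_bandwidth`` around ``k_center``
    (signed); used to strip higher-order modes before velocity extraction.
    """
    n = len(profile.x)
    U = np.fft.fft(profile.u, n=n * pad_factor)
    k = 2 * np.pi * np.fft.fftfreq(n * pad_factor, profile.dx)
    keep = np.abs(k - k_center) <= rel_bandwidth * abs(k_center)
    u_f = np.fft.ifft(U * keep)[:n]
    return SurfaceProfile(x=profile.x, u=u_f, f=profile.f)


# -- model fitting ----------------------------------------------------------


@dataclass
class SurfaceWaveFit:
    """Least-squares fit of the analytic near-field model."""

    K: complex
    p0: complex
    residual: float  # RMS residual / RMS data
    n_iterations: int
    success: bool


def fit_surface_wave(
    profile: SurfaceProfile,
    a: float,
    rho: float,
    omega: float | None = None,
    K_init: complex | None = None,
) -> SurfaceWaveFit:
    """Fit the Rayleigh + supershear model to a complex displacement profile.

    Real and imaginary parts are fitted jointly.  The source strength enters
    linearly and is projected out at each iterate, leaving a 2-parameter
    trust-region search over complex K.  ``K_init`` defaults to the k-domain
    peak; it should be within about a factor 3 of the truth.
    """
    if omega is None:
        omega = 2 * np.pi * profile.f
    if np.any(np.abs(profile.x) < a):
        raise ValueError("fit requires |x| >= a for all samples")
    u = profile.u
    scale = np.sqrt(np.mean(np.abs(u) ** 2))
    if scale == 0:
        raise ValueError("zero displacement profile")

    if K_init is None:
        k, U = spatial_spectrum(profile, pad_factor=4)
        dk = abs(k[1] - k[0])
        pick = pick_mode(k, U, (2 * dk, abs(k).max()), profile.f, min_peak_ratio=1.0)
        r_ratio, _ = secular_roots()
        K_init = pick.k_r / r_ratio.real * (1 - 0.05j)

    def model_and_scale(K: complex):
        m = surface_wave_displacement(profile.x, K, a, rho, omega, p0=1.0)
        denom = np.vdot(m, m).real
        c = np.vdot(m, u) / denom if denom > 0 else 0.0
        return c * m, c

    def residuals(p):
        K = p[0] - 1j * abs(p[1])
        fit, _ = model_and_scale(K)
        r = (u - fit) / scale
        return np.concatenate([r.real, r.imag])

    # multi-start around K_init: the supershear mode creates a local minimum
    # that can trap the solver when the Rayleigh peak is not dominant
    sol = None
    for mult in (1.0, 0.5, 2.0):
        x0 = [mult * K_init.real, max(mult * abs(K_init.imag), 1e-3 * K_init.real)]
        trial = optimize.least_squares(x0=x0, fun=residuals, method="trf", xtol=1e-14)
        if sol is None or trial.cost < sol.cost:
            sol = trial
    K_hat = sol.x[0] - 1j * abs(sol.x[1])
    fit, c = model_and_scale(K_hat)
    res = float(np.sqrt(np.mean(np.abs(u - fit) ** 2)) / scale)
    if not sol.success:
        raise RuntimeError(
            f"surface-wave fit did not converge (best K = {K_hat:.1f}, "
            f"residual = {res:.3g})"
        )
    return SurfaceWaveFit(
        K=K_hat, p0=c, residual=res, n_iterations=sol.nfev, success=sol.success
    )


# -- cross-sectional displacement maps --------------------------------------


def rayleigh_depth_profile(z: np.ndarray, k: float) -> np.ndarray:
    """Surface-wave depth eigenfunction |psi(z)| = sqrt(2 k_z) e^{-k_z z}.

    k_z ~ 0.31 k, so the 1/e amplitude decay depth is about half a
    wavelength.
    """
    k_z = 0.31 * k
    return np.sqrt(2 * k_z) * np.exp(-k_z * np.asarray(z))


def cross_section_map(vib_map) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex displacement image u(x, z) in meters from a vibration map.

    Invalid pixels (carrier below the noise floor) are zeroed; the real part
    of the returned image is what is conventionally rendered.
    """
    u = vib_map.k0_delta / vib_map.k0
    u = np.where(vib_map.mask, u, 0.0)
    x = vib_map.x if vib_map.x is not None else np.arange(u.shape[0], dtype=float)
    dz = vib_map.delta_z if vib_map.delta_z is not None else 1.0
    z = np.arange(u.shape[1]) * dz
    return x, z, u
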