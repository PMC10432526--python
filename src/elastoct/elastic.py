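"""Elastodynamic inversion: wavenumbers and velocities to mechanical moduli.

Complex shear modulus from the complex shear wavenumber (k = k_r - i k_i for
a wave e^{i(wt - kx)}):

    mu' = rho w^2 (k_r^2 - k_i^2) / (k_r^2 + k_i^2)^2
    mu'' = 2 rho w^2 k_r k_i / (k_r^2 + k_i^2)^2

equivalently mu' + i mu'' = rho w^2 / (k_r - i k_i)^2.  Half-space Rayleigh
speeds convert through c_R = (0.862 + 1.14 nu) / (1 + nu) c_s with
mu = rho c_s^2; plate measurements go through the Rayleigh-Lamb fundamental
modes; and broadband Rayleigh-wave dispersion inverts to a depth profile of
shear modulus through a penetration-depth perturbation argument:

    k^2 ~ (rho w^2 / L_z) int_0^{L_z} dz / mu(z),  L_z = a_L * lambda

whose derivative with respect to frequency gives

    mu(z) ~ rho v^2 (v - f v') / (v + f v'),  z = a_L v / f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import UnivariateSpline

from .wavefield import ComplexWavenumber, secular_roots


def rayleigh_shear_ratio_incompressible() -> float:
    """c_s / c_R for an incompressible half-space, from the secular root.

    The same root renders as the familiar factors 1.047 (wavenumber ratio
    K_R/K) and ~1.048 (velocity conversion v = 1.048 v_R).
    """
    return secular_roots()[0].real


@dataclass(frozen=True)
class ComplexModulus:
    """Storage and loss shear moduli at one frequency."""

    mu_storage: float  # Pa
    mu_loss: float  # Pa
    f: float  # Hz
    rho: float  # kg/m^3

    @property
    def loss_tangent(self) -> float:
        return self.mu_loss / self.mu_storage


@dataclass(frozen=True)
class DispersionCurve:
    """Phase velocity (and optional attenuation) versus frequency."""

    f: np.ndarray  # Hz
    v: np.ndarray  # m/s
    k_i: np.ndarray | None = None  # rad/m

    def __post_init__(self):
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.k_i is not None:
            object.__setattr__(self, "k_i", np.asarray(self.k_i, dtype=float))

    @property
    def k_r(self) -> np.ndarray:
        return 2 * np.pi * self.f / self.v

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frequency_hz": self.f, "v_m_per_s": self.v})
        df["k_r_rad_per_m"] = self.k_r
        df["k_i_rad_per_m"] = self.k_i if self.k_i is not None else np.nan
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DispersionCurve":
        k_i = df["k_i_rad_per_m"].to_numpy() if "k_i_rad_per_m" in df else None
        if k_i is not None and np.all(np.isnan(k_i)):
            k_i = None
        return cls(f=df["frequency_hz"].to_numpy(), v=df["v_m_per_s"].to_numpy(), k_i=k_i)


def complex_modulus(k: ComplexWavenumber, rho: float) -> ComplexModulus:
    """Complex shear modulus from the complex shear wavenumber."""
    if k.k_i < 0:
        raise ValueError("attenuation k_i must be >= 0")
    w = 2 * np.pi * k.f
    denom = (k.k_r**2 + k.k_i**2) ** 2
    mu_s = rho * w**2 * (k.k_r**2 - k.k_i**2) / denom
    mu_l = 2 * rho * w**2 * k.k_r * k.k_i / denom
    return ComplexModulus(mu_storage=mu_s, mu_loss=mu_l, f=k.f, rho=rho)


def shear_wavenumber(mu: ComplexModulus) -> ComplexWavenumber:
    """Inverse of :func:`complex_modulus`: K = w sqrt(rho / (mu' + i mu''))."""
    w = 2 * np.pi * mu.f
    K = w * np.sqrt(mu.rho / (mu.mu_storage + 1j * mu.mu_loss))
    if K.real < 0:
        K = -K
    return ComplexWavenumber(k_r=K.real, k_i=-K.imag, f=mu.f)


def rayleigh_ratio(nu: float) -> float:
    """Rayleigh-to-shear speed ratio c_R/c_s = (0.862 + 1.14 nu)/(1 + nu)."""
    if not 0 <= nu <= 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5]")
    return (0.862 + 1.14 * nu) / (1 + nu)


def modulus_from_rayleigh(c_r: float, nu: float, rho: float) -> float:
    """Shear modulus mu = rho c_s^2 from a measured Rayleigh speed (Pa)."""
    if c_r <= 0 or rho <= 0:
        raise ValueError("c_R and rho must be positive")
    c_s = c_r / rayleigh_ratio(nu)
    return rho * c_s**2


# -- Rayleigh-Lamb plate dispersion -----------------------------------------


@dataclass(frozen=True)
class LambPlate:
    """Free elastic plate supporting the fundamental A0/S0 guided modes."""

    h: float  # thickness (m)
    rho: float
    nu: float
    c_s: float  # bulk shear speed (m/s)

    def __post_init__(self):
        if self.h <= 0 or self.c_s <= 0:
            raise ValueError("h and c_s must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def c_l(self) -> float:
        """Bulk longitudinal speed."""
        return self.c_s * np.sqrt(2 * (1 - self.nu) / (1 - 2 * self.nu))

    @property
    def c_plate(self) -> float:
        """Thin-plate (low f h) S0 limit c_s sqrt(2/(1 - nu))."""
        return self.c_s * np.sqrt(2 / (1 - self.nu))

    @property
    def c_rayleigh(self) -> float:
        """Half-space Rayleigh speed from the approximate ratio formula."""
        return rayleigh_ratio(self.nu) * self.c_s

    @property
    def c_rayleigh_exact(self) -> float:
        """Exact Rayleigh speed (root of the compressible secular equation).

        Differs from :attr:`c_rayleigh` by ~0.1%; the fundamental Lamb modes
        converge to this value, so it bounds the A0/S0 branches.
        """
        eta = self.c_s / self.c_l

        def det(xi):  # xi = v / c_s
            return (2 - xi**2) ** 2 - 4 * np.sqrt(1 - (xi * eta) ** 2) * np.sqrt(
                1 - xi**2
            )

        return self.c_s * optimize.brentq(det, 0.3, 1 - 1e-13, xtol=1e-15)


def _lamb_characteristic(v: float, f: float, plate: LambPlate, mode: str) -> float:
    """Real-valued Rayleigh-Lamb characteristic, conditioned for bracketing.

    Uses tanh-normalized real forms in each velocity regime (hyperbolic
    functions never overflow), continuous across the v = c_s boundary with
    the removable zero there divided out.
    """
    w = 2 * np.pi * f
    k = w / v
    hh = plate.h / 2
    kl2 = (w / plate.c_l) ** 2
    ks2 = (w / plate.c_s) ** 2
    alpha = np.sqrt(max(k**2 - kl2, 0.0))  # v < c_L always holds here
    scale = (k**2 + abs(ks2 - k**2)) ** 2
    if k**2 >= ks2:  # subsonic: v <= c_s
        beta = np.sqrt(k**2 - ks2)
        tb = np.tanh(beta * hh) / beta if beta > 0 else hh
        ta = np.tanh(alpha * hh)
        if mode == "S0":
            g = (beta**2 + k**2) ** 2 * tb - 4 * k**2 * alpha * ta
        else:  # A0
            g = (beta**2 + k**2) ** 2 * ta - 4 * k**2 * alpha * beta * np.tanh(
                beta * hh
            )
    else:  # mixed: c_s < v < c_L
        q = np.sqrt(ks2 - k**2)
        ta = np.tanh(alpha * hh)
        sq = np.sin(q * hh) / q if q > 0 else hh
        cq = np.cos(q * hh)
        if mode == "S0":
            g = (q**2 - k**2) ** 2 * sq - 4 * k**2 * alpha * ta * cq
        else:  # A0 (fundamental never enters this regime; kept for generality)
            g = (q**2 - k**2) ** 2 * ta * cq + 4 * k**2 * alpha * q * np.sin(q * hh)
    return float(g / scale)


def lamb_dispersion(plate: LambPlate, f: float, mode: Literal["A0", "S0"] = "A0") -> float:
    """Phase velocity (m/s) of a fundamental Lamb mode at frequency f.

    A0 is searched below the Rayleigh speed; S0 between the Rayleigh and
    longitudinal speeds (taking the lowest branch).  Roots are bracketed on a
    scan refined near the Rayleigh speed, then polished with Brent's method.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if mode not in ("A0", "S0"):
        raise ValueError("mode must be 'A0' or 'S0'")
    c_r = plate.c_rayleigh_exact
    if mode == "A0":
        # grid dense near c_R (deep-plate limit) and logarithmic at low v
        upper = c_r * (1 - 1e-12)
        grid = np.concatenate(
            [
                np.geomspace(1e-4 * plate.c_s, 0.9 * c_r, 600),
                c_r * (1 - np.geomspace(1e-15, 0.1, 700))[::-1],
            ]
        )
        grid = np.clip(np.sort(grid), None, upper)
    else:
        upper = plate.c_l * (1 - 1e-9)
        grid = np.concatenate(
            [
                c_r * (1 + np.geomspace(1e-12, 0.5, 600)),
                np.linspace(1.5 * c_r, upper, 600),
            ]
        )
        grid = np.sort(grid[grid <= upper])
    vals = np.array([_lamb_characteristic(v, f, plate, mode) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_change) == 0:
        raise ValueError(
            f"no {mode} root bracketed at f={f:.4g} Hz in "
            f"[{grid[0]:.4g}, {grid[-1]:.4g}] m/s; "
            f"char range [{vals.min():.3g}, {vals.max():.3g}]"
        )
    # fundamental branch: largest subsonic root for A0, lowest root for S0
    i = sign_change[-1] if mode == "A0" else sign_change[0]
    v = optimize.brentq(
        _lamb_characteristic, grid[i], grid[i + 1], args=(f, plate, mode), xtol=1e-10
    )
    return float(v)


# -- rheology fits ----------------------------------------------------------


def power_law_fit(
    f: np.ndarray,
    mu: np.ndarray,
    segments: int = 1,
    breakpoint: float | None = None,
) -> dict:
    """Power-law fit mu ~ f^alpha by log-log linear least squares.

    With ``segments=2`` a bilinear fit is performed on either side of the
    user-supplied ``breakpoint`` frequency; each segment needs >= 3 points.
    Returns a dict with exponents and prefactors.
    """
    f = np.asarray(f, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(f <= 0) or np.any(mu <= 0):
        raise ValueError("power-law fit requires positive frequencies and moduli")
    if segments == 1:
        alpha, loga = np.polyfit(np.log(f), np.log(mu), 1)
        return {"alpha": float(alpha), "prefactor": float(np.exp(loga))}
    if segments == 2:
        if breakpoint is None:
            raise ValueError("bilinear fit requires a breakpoint frequency")
        lo, hi = f <= breakpoint, f >= breakpoint
        if lo.sum() < 3 or hi.sum() < 3:
            raise ValueError("need >= 3 points per segment")
        a1, c1 = np.polyfit(np.log(f[lo]), np.log(mu[lo]), 1)
        a2, c2 = np.polyfit(np.log(f[hi]), np.log(mu[hi]), 1)
        return {
            "alpha_low": float(a1),
            "alpha_high": float(a2),
            "prefactor_low": float(np.exp(c1)),
            "prefactor_high": float(np.exp(c2)),
            "breakpoint": float(breakpoint),
        }
    raise ValueError("segments must be 1 or 2")


# -- empirical skin velocity model ------------------------------------------


@dataclass(frozen=True)
class SkinVelocityModel:
    """Empirical broadband surface-wave speed model for skin.

    v(f) = v0 + a f / sqrt(b^2 f^2 + 1) + c f / (d f + 1), f in kHz, v in m/s.
    """

    a: float
    b: float
    c: float
    d: float
    v0: float = 9.5

    @classmethod
    def normal(cls) -> "SkinVelocityModel":
        """Coefficients for normal (non-hydrated) fingertip skin."""
        return cls(a=0.44, b=0.0032, c=1.6, d=0.02)

    @classmethod
    def hydrated(cls) -> "SkinVelocityModel":
        """Coefficients after water immersion (third term absent)."""
        return cls(a=1.25, b=0.032, c=0.0, d=0.02)

    def __call__(self, f_khz: np.ndarray) -> np.ndarray:
        f = np.asarray(f_khz, dtype=float)
        if np.any(f < 0):
            raise ValueError("frequency must be >= 0")
        return (
            self.v0
            + self.a * f / np.sqrt(self.b**2 * f**2 + 1)
            + self.c * f / (self.d * f + 1)
        )

    def derivative(self, f_khz: np.ndarray) -> np.ndarray:
        """dv/df with f in kHz (m/s per kHz)."""
        f = np.asarray(f_khz, dtype=float)
        return self.a / (self.b**2 * f**2 + 1) ** 1.5 + self.c / (self.d * f + 1) ** 2


def skin_velocity(f_khz: np.ndarray, model: SkinVelocityModel) -> np.ndarray:
    """Evaluate the empirical skin dispersion model (f in kHz, v in m/s)."""
    return model(f_khz)


# -- depth-resolved modulus profiling ---------------------------------------


@dataclass(frozen=True)
class DepthProfile:
    """Depth-resolved shear modulus recovered from dispersion."""

    z: np.ndarray  # m, increasing
    mu: np.ndarray  # Pa
    f: np.ndarray  # probing frequency per depth (Hz)
    valid: np.ndarray  # False where v + f v' <= 0 (formula breakdown)
    a_l: float
    rho: float


def _fit_parametric_v(f_hz: np.ndarray, v: np.ndarray):
    """Fit the empirical skin functional form; returns (v(f), v'(f)) in SI."""
    f_khz = f_hz / 1e3

    def model(f, v0, a, b, c, d):
        return SkinVelocityModel(a=a, b=b, c=c, d=d, v0=v0)(f)

    p0 = [v.min(), 1.0, 1.0 / max(f_khz.max(), 1.0), 0.1, 0.01]
    popt, _ = optimize.curve_fit(model, f_khz, v, p0=p0, maxfev=20000)
    m = SkinVelocityModel(a=popt[1], b=popt[2], c=popt[3], d=popt[4], v0=popt[0])
    return lambda f: m(f / 1e3), lambda f: m.derivative(f / 1e3) / 1e3


def _fit_spline_v(f_hz: np.ndarray, v: np.ndarray, smoothing: float | None):
    s = smoothing if smoothing is not None else len(v) * (0.005 * np.ptp(v)) ** 2
    spl = UnivariateSpline(f_hz, v, k=3, s=s)
    return spl, spl.derivative()


def invert_depth_profile(
    disp: DispersionCurve,
    rho: float,
    a_l: float = 0.25,
    smoother: Literal["spline", "parametric"] = "spline",
    smoothing: float | None = None,
    rayleigh_factor: float | None = None,
) -> DepthProfile:
    """Depth-resolved shear modulus from Rayleigh-wave dispersion.

    The measured Rayleigh speed v_R(f) converts to the bulk shear speed
    v = (K_R/K) v_R; each frequency probes a depth z = a_L v / f and

        mu(z) = rho v^2 (v - f v') / (v + f v').

    ``smoother`` controls the estimate of v' = dv/df, the dominant numerical
    hazard: "parametric" fits the empirical skin functional form,
    "spline" a smoothing spline.  Points where v + f v' <= 0 are flagged
    invalid rather than propagated.
    """
    if rayleigh_factor is None:
        rayleigh_factor = rayleigh_shear_ratio_incompressible()
    order = np.argsort(disp.f)
    f = disp.f[order]
    v_bulk = rayleigh_factor * disp.v[order]
    if smoother == "parametric":
        v_fun, dv_fun = _fit_parametric_v(f, v_bulk)
    elif smoother == "spline":
        v_fun, dv_fun = _fit_spline_v(f, v_bulk, smoothing)
    else:
        raise ValueError("smoother must be 'spline' or 'parametric'")
    v_s = np.asarray(v_fun(f), dtype=float)
    dv = np.asarray(dv_fun(f), dtype=float)
    denom = v_s + f * dv
    numer = v_s - f * dv
    valid = denom > 0
    if not np.all(valid):
        import warnings

        warnings.warn("v + f v' <= 0 at some frequencies: masked (formula breakdown)")
    mu = np.where(valid, rho * v_s**2 * numer / np.where(valid, denom, 1.0), np.nan)
    z = a_l * v_s / f
    order_z = np.argsort(z)
    return DepthProfile(
        z=z[order_z], mu=mu[order_z], f=f[order_z], valid=valid[order_z],
        a_l=a_l, rho=rho,
    )


def forward_dispersion_from_profile(
    mu_of_z: Callable[[np.ndarray], np.ndarray],
    rho: float,
    f: Sequence[float],
    a_l: float = 0.25,
    as_rayleigh: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    n_quad: int = 512,
) -> DispersionCurve:
    """Rayleigh-wave dispersion predicted from a depth profile mu(z).

    Solves k^2 = (rho w^2 / L_z) int_0^{L_z} dz/mu(z) with the penetration
    depth L_z = a_L (2 pi / k) by fixed-point iteration.  With
    ``as_rayleigh`` the returned speeds are scaled to Rayleigh-wave speeds
    (v_R = v / (K_R/K)) so the curve feeds :func:`invert_depth_profile`
    directly.
    """
    ratio = rayleigh_shear_ratio_incompressible()
    f = np.asarray(f, dtype=float)
    v_out = np.empty(f.shape)
    for i, fi in enumerate(f):
        w = 2 * np.pi * fi

        def g(k: float) -> float:
            """Consistency map: wavenumber implied by the depth average at k."""
            l_z = a_l * 2 * np.pi / k
            zz = np.linspace(0.0, l_z, n_quad)
            integral = np.trapezoid(1.0 / mu_of_z(zz), zz)
            return float(np.sqrt(rho * w**2 / l_z * integral))

        # g is monotone decreasing in k, so g(k) = k has a unique root;
        # bracket it (plain fixed-point iteration 2-cycles on steep profiles)
        k1 = w * np.sqrt(rho / float(mu_of_z(np.zeros(1))[0]))
        lo, hi = min(k1, g(k1)) / 2, max(k1, g(k1)) * 2
        for _ in range(max_iter):
            if (g(lo) - lo) > 0 > (g(hi) - hi):
                break
            lo, hi = lo / 4, hi * 4
        else:
            raise RuntimeError(
                f"penetration-depth equation not bracketed at f = {fi:.4g} Hz"
            )
        k = optimize.brentq(lambda kk: g(kk) - kk, lo, hi, rtol=max(tol, 1e-14))
        v_out[i] = w / k
    if as_rayleigh:
        v_out = v_out / ratio
    return DispersionCurve(f=f, v=v_out)
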