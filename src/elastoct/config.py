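"""Instrument and run configuration models.

The default constants describe a polygon-scanner swept-source OCT engine:
1307 nm center wavelength, 43.2 kHz A-line rate, 2048 samples per sweep
digitized at 108 MS/s, giving a frequency-pixel spacing of f_s/S = 52.73 kHz
and a depth-pixel spacing of 21.5 um.  The wavenumber tuning rate ``k1`` is
tied to those two pixel spacings via ``delta_z = pi * delta_f / k1``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: depth-pixel spacing (m) used to derive the default tuning rate
DEFAULT_PIXEL_SPACING = 21.5e-6


class SweepConfig(BaseModel):
    """Swept-source laser / digitizer model.

    Parameters
    ----------
    lambda0 : center wavelength (m).
    f_A : A-line (sweep) rate (Hz).
    n_samples : samples digitized per A-line.
    f_s : digitizer sampling rate (samples/s).
    sigma_env : fractional FWHM of the Gaussian power envelope (0 < sigma < 1).
    sigma_T : standard deviation of the per-sweep period jitter (s).
    k1 : wavenumber tuning rate (rad m^-1 s^-1); when omitted it is derived so
        that one frequency pixel (f_s / n_samples) maps to 21.5 um of depth.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    lambda0: float = 1307e-9
    f_A: float = 43.2e3
    n_samples: int = 2048
    f_s: float = 108e6
    sigma_env: float = 0.8
    sigma_T: float = 4.9e-9
    k1: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self) -> "SweepConfig":
        if self.lambda0 <= 0 or self.f_A <= 0 or self.f_s <= 0:
            raise ValueError("lambda0, f_A and f_s must be positive")
        if not 0 < self.sigma_env < 1:
            raise ValueError("sigma_env must lie in (0, 1)")
        if self.sigma_T < 0:
            raise ValueError("sigma_T must be >= 0")
        if self.n_samples * self.f_A > self.f_s * (1 + 1e-9):
            raise ValueError(
                "acquisition window n_samples/f_s exceeds the sweep period 1/f_A"
            )
        if self.k1 is None:
            object.__setattr__(
                self, "k1", np.pi * self.delta_f / DEFAULT_PIXEL_SPACING
            )
        elif self.k1 <= 0:
            raise ValueError("k1 must be positive")
        return self

    # -- derived quantities -------------------------------------------------
    @property
    def k0(self) -> float:
        """Center wavenumber 2*pi/lambda0 (rad/m)."""
        return 2 * np.pi / self.lambda0

    @property
    def T(self) -> float:
        """Sweep period (s)."""
        return 1.0 / self.f_A

    @property
    def delta_f(self) -> float:
        """Frequency-pixel spacing f_s / n_samples (Hz)."""
        return self.f_s / self.n_samples

    @property
    def delta_z(self) -> float:
        """Depth-pixel spacing pi * delta_f / k1 (m)."""
        return np.pi * self.delta_f / self.k1

    @property
    def n_depth(self) -> int:
        """Number of one-sided depth pixels (n_samples / 2)."""
        return self.n_samples // 2

    @property
    def z_nyquist(self) -> float:
        """Maximum unambiguous depth (m)."""
        return self.n_depth * self.delta_z

    @property
    def axial_fwhm(self) -> float:
        """FWHM axial resolution 4 ln2 / (sigma * k1 * T) (m)."""
        return 4 * np.log(2) / (self.sigma_env * self.k1 * self.T)


class ScanProtocol(BaseModel):
    """M-B scan protocol: N A-lines per M-scan at each of B lateral positions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_alines: int = Field(108, gt=0)
    n_positions: int = Field(96, gt=0)
    dx: float = Field(15e-6, gt=0)


# -- scene specifications for the pipeline ----------------------------------


class MirrorSceneSpec(BaseModel):
    """Single mirror-like reflector at each lateral position."""

    model_config = ConfigDict(extra="forbid")
    kind: Literal["mirror"] = "mirror"
    depth_px: float = 107.0
    reflectance: float = 1.0


class SurfaceWaveSceneSpec(BaseModel):
    """Homogeneous half-space carrying a traveling harmonic surface wave.

    ``speed`` is the surface-wave phase speed (m/s); ``attenuation`` the
    spatial decay rate k_i (rad/m); ``amplitude`` the vibration amplitude at
    the source (m).
    """

    model_config = ConfigDict(extra="forbid")
    kind: Literal["surface_wave"] = "surface_wave"
    depth_px: float = 107.0
    reflectance: float = 1.0
    speed: float = Field(3.0, gt=0)
    attenuation: float = Field(0.0, ge=0)
    amplitude: float = Field(50e-9, ge=0)


SceneSpec = Union[MirrorSceneSpec, SurfaceWaveSceneSpec]


class RunConfig(BaseModel):
    """Complete configuration for the simulate -> demodulate -> invert pipeline."""

    model_config = ConfigDict(extra="forbid")

    sweep: SweepConfig = SweepConfig()
    protocol: ScanProtocol = ScanProtocol()
    scene: SceneSpec = Field(default_factory=SurfaceWaveSceneSpec, discriminator="kind")
    frequencies: list[float] = Field(default_factory=lambda: [10.8e3])
    phi: float = 0.0
    snr_db: Optional[float] = None  # None -> noise free
    rho: float = 1000.0
    seed: int = 0
    lobe: Literal["left", "right"] = "left"
    correct_jitter: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Instrument defaults are applied to any omitted field; unknown fields are
    rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2))
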