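"""End-to-end pipeline: simulate -> transform -> demodulate -> dispersion.

Stages run in acquisition order: A-line reconstruction, sideband (or
conventional) demodulation with jitter correction, surface-profile
extraction, x -> k transform, mode picking, phase velocity.  Everything is
deterministic given the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import acquisition as acq
from .config import MirrorSceneSpec, RunConfig, SurfaceWaveSceneSpec
from .demod import SidebandPlan, VibrationMap, aline_transform, demodulate, plan_sidebands
from .elastic import DispersionCurve, modulus_from_rayleigh, rayleigh_shear_ratio_incompressible
from .wavefield import SurfaceProfile, pick_mode, spatial_spectrum


@dataclass
class ResultBundle:
    """Pipeline outputs plus provenance."""

    dispersion: DispersionCurve | None
    moduli: np.ndarray | None  # Pa, per frequency (None for mirror scenes)
    vibration_maps: dict[float, VibrationMap] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    errors: dict[float, str] = field(default_factory=dict)


def _build_scene(cfg: RunConfig, f_m: float):
    if isinstance(cfg.scene, MirrorSceneSpec):
        scene = acq.mirror_scene(
            cfg.sweep,
            depth_px=cfg.scene.depth_px,
            r=cfg.scene.reflectance,
            n_positions=cfg.protocol.n_positions,
            dx=cfg.protocol.dx,
        )
        vib = acq.VibrationField(f_m=f_m, delta=0.0, phi=cfg.phi)
        return scene, vib
    if isinstance(cfg.scene, SurfaceWaveSceneSpec):
        return acq.traveling_wave_scene(
            cfg.sweep,
            cfg.protocol,
            f_m=f_m,
            speed=cfg.scene.speed,
            amplitude=cfg.scene.amplitude,
            attenuation=cfg.scene.attenuation,
            depth_px=cfg.scene.depth_px,
            r=cfg.scene.reflectance,
            phi=cfg.phi,
        )
    raise TypeError(f"unsupported scene spec {type(cfg.scene)!r}")


def demodulate_cube(
    cube: acq.MScanCube, lobe: str = "left", correct_jitter: bool = True,
) -> tuple[VibrationMap, SidebandPlan]:
    """Transform and demodulate one cube at its own modulation frequency."""
    tom = aline_transform(cube)
    plan = plan_sidebands(cube.f_m, cube.sweep, lobe=lobe)
    stim = cube.stimulus_phase if correct_jitter else None
    vib = demodulate(tom, plan, stimulus_phase=stim)
    return vib, plan


def surface_profile_from_map(
    vib: VibrationMap, surface_px: int, f: float
) -> SurfaceProfile:
    """Extract the complex surface displacement across lateral positions."""
    u = vib.k0_delta[:, surface_px] / vib.k0
    return SurfaceProfile(x=vib.x, u=u, f=f)


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Run simulate -> demod -> dispersion -> modulus for every frequency."""
    bundle = ResultBundle(
        dispersion=None,
        moduli=None,
        provenance={
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": _version(),
        },
    )
    rows_f, rows_v = [], []
    for i, f_m in enumerate(cfg.frequencies):
        try:
            scene, vib_field = _build_scene(cfg, f_m)
            cube = acq.simulate_mscan(
                scene,
                cfg.sweep,
                vib_field,
                cfg.protocol,
                snr_db=cfg.snr_db,
                seed=cfg.seed + i,
            )
            vib, plan = demodulate_cube(
                cube, lobe=cfg.lobe, correct_jitter=cfg.correct_jitter
            )
            bundle.vibration_maps[f_m] = vib
            if isinstance(cfg.scene, SurfaceWaveSceneSpec):
                surf_px = int(round(cfg.scene.depth_px))
                profile = surface_profile_from_map(vib, surf_px, f_m)
                k, U = spatial_spectrum(profile, pad_factor=8)
                dk = 2 * np.pi / (len(profile.x) * profile.dx)
                pick = pick_mode(k, U, (1.5 * dk, abs(k).max()), f_m)
                rows_f.append(f_m)
                rows_v.append(pick.phase_velocity)
        except (ValueError, RuntimeError) as exc:  # keep partial results
            bundle.errors[f_m] = str(exc)
    if rows_f:
        disp = DispersionCurve(f=np.array(rows_f), v=np.array(rows_v))
        bundle.dispersion = disp
        ratio = rayleigh_shear_ratio_incompressible()
        bundle.moduli = cfg.rho * (ratio * disp.v) ** 2
    return bundle


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("elastoct")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
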