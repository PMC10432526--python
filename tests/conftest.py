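import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elastoct as et

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sweep():
    """Default instrument, jitter disabled (deterministic timing)."""
    return et.SweepConfig(sigma_T=0.0)


@pytest.fixture(scope="session")
def sweep_jitter():
    """Default instrument with the nominal 4.9 ns period jitter."""
    return et.SweepConfig()


@pytest.fixture(scope="session")
def mirror_cube(sweep):
    """Noise-free single-mirror M-scan, 20 nm vibration at 688.8 kHz."""
    scene = et.mirror_scene(sweep, depth_px=107)
    vib = et.VibrationField(f_m=688.8e3, delta=20e-9)
    prot = et.ScanProtocol(n_alines=108, n_positions=1)
    return et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=1)


def demod_mirror(sweep, f_m, delta, n_alines=108, snr_db=None, seed=1, phi=0.0,
                 lobe="left", depth_px=107):
    """Simulate and demodulate a single-mirror M-scan; returns the map."""
    scene = et.mirror_scene(sweep, depth_px=depth_px)
    vib = et.VibrationField(f_m=f_m, delta=delta, phi=phi)
    prot = et.ScanProtocol(n_alines=n_alines, n_positions=1)
    cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=snr_db, seed=seed)
    tom = et.aline_transform(cube)
    plan = et.plan_sidebands(f_m, sweep, lobe=lobe)
    return et.demodulate(tom, plan)


@pytest.fixture(scope="session")
def eq23_field():
    """Noise-free analytic near-field profile with known complex K."""
    from elastoct.wavefield import SurfaceProfile, surface_wave_displacement

    K, a, rho, f = 3000 - 300j, 0.6e-3, 1000.0, 40e3
    x = np.linspace(3e-3, 18e-3, 512)
    u = surface_wave_displacement(x, K, a, rho, 2 * np.pi * f)
    return SurfaceProfile(x=x, u=u, f=f), K, a, rho
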