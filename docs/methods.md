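# Methods

`elastoct` implements the computational chain of an ultra-wideband
swept-source optical coherence elastography (OCE) system: a physical-optics
forward model of the interferograms, a demodulation algorithm that recovers
sub-wavelength harmonic vibration at modulation frequencies far above the
A-line rate by exploiting (rather than avoiding) aliasing, a closed-form
noise and sensitivity budget, and the elastodynamic inversions that turn
measured wavefields into complex shear moduli and depth-resolved stiffness
profiles.

## Forward model (acquisition)

The swept laser tunes its wavenumber linearly, k = k0 + k1*t_hat, over each
sweep of period T = 1/f_A. A scatterer of reflectance r at depth z0 whose
position is modulated by delta*g(t) produces the detector current

    I_m(t_hat) = r P(t_hat) cos( 2 k0 z0 + 2 k1 t_hat z0
                 + (2 k0 + 2 k1 t_hat) delta g_m(t_hat) ),

summed over scatterers, with g_m(t_hat) = sin(w_m (t_hat + t_m) + phi) for
harmonic drive and P a Gaussian power envelope of fractional FWHM
`sigma_env`. The full cosine is retained: at large k0*delta the simulator
produces the complete Bessel sideband ladder (carrier ~ J0(2 k0 d),
first-order sidebands ~ J1(2 k0 d)), which the first-order demodulation
theory then approximates. No commensurability between 2 k1 z0 T or w_m T and
2 pi is assumed anywhere.

Default instrument constants: lambda0 = 1307 nm, f_A = 43.2 kHz, S = 2048
samples at f_s = 108 MS/s. The tuning rate k1 is chosen so one FFT frequency
pixel (f_s/S = 52.73 kHz) corresponds to 21.5 um of depth
(k1 = pi * delta_f / delta_z ~ 7.71e9 rad m^-1 s^-1); neither k1 nor
sigma_env is an independently published instrument constant, so both are
tied to the printed pixel spacings, with sigma_env = 0.8 as the default
envelope width. The closed-form axial resolution
sigma_z = 4 ln2 / (sigma k1 T) holds when the envelope lies well inside the
acquisition window (sigma appreciably below the window duty S f_A / f_s ~
0.82); at the default sigma_env = 0.8 the window truncation dominates and
the realized point-spread FWHM is ~1.3 px rather than the formula's 0.9 px.
The unit tests probe the formula at sigma_env = 0.4 where it is valid.

Sweep-period jitter: each sweep's period deviates by tau_i ~ N(0, sigma_T^2)
(default sigma_T = 4.9 ns), i.i.d., and the start time of sweep m = 1..N is
t_m = m T + sum_{i<=m} tau_i. The stimulus waveform is "recorded" through
the same timeline, so its per-A-line phase w_m t_m + phi carries the
identical jitter — this is what makes in-situ correction possible.
Intra-sweep tuning-rate jitter is not modeled. Detector noise is additive
white Gaussian on the raw samples, scaled so the brightest scatterer's
A-line power SNR (FFT peak power over mean noise-floor power) equals the
requested figure; shot-noise statistics are not modeled, since everything
downstream depends only on the SNR X. Jitter and noise draw from
independent child streams of one master seed, so disabling either leaves
the other bit-identical.

## Demodulation

A scatterer vibrating at f_m puts first-order sidebands at depth offsets
+/- z_m = w_m/(2 k1) from its carrier. Across consecutive A-lines the
sideband phasor rotates at f_m, observed modulo the A-line rate: writing
f_m = f_bar + 0.5 n f_A with 0 <= f_bar < 0.5 f_A, the apparent rotation is
f_bar when n is even and f_bar - 0.5 f_A when n is odd. The demodulator,
per depth pixel z0:

1. evaluates the spectrum at the exact (generally fractional-pixel) shifted
   position z0 -/+ z_m by multiplying the time samples with a complex
   carrier before the FFT — an exact fractional shift. Because carrier and
   sideband share the same envelope transform, every envelope/leakage factor
   cancels in the later ratio, for any scatterer depth;
2. subtracts the N-A-line mean (static background), which is exact when
   N f_m / f_A is an integer;
3. normalizes by the carrier DC at the scatterer's own depth;
4. locks in on the apparent frequency over the A-line index. The
   counter-rotating term — the opposite sideband of the scatterer located
   2 z_m away — sums to zero over the integer number of cycles, which is
   how the two interleaved contributions are separated.

The recovered complex amplitude is k0*delta with the local vibration phase;
a final factor e^{i w_m S/(2 f_s)} re-references that phase from the first
digitized sample to the sweep center, so the output phase equals the drive
phase phi plus the propagation phase of the wave. In numpy's FFT sign
convention the left lobe carries -k0 d e^{-i theta} and the right lobe
+k0 d e^{+i theta} (the opposite of the analytic transform convention); the
lock-in and a final conjugation account for this, and left- and right-lobe
demodulation agree to numerical precision. The left lobe is the default.

Degenerate plans are refused: f_m folding exactly onto DC, sidebands beyond
the depth range, and non-integer N f_m / f_A without a window. A Hann window
over the A-line index (normalized by its coherent gain) relaxes the
integer-cycle requirement at some leakage cost. Pixels whose carrier DC is
less than 6 dB above the median spectral floor are masked rather than
propagated as quotient noise — the quotient at such pixels amplifies skirt
cross-talk and is not meaningful.

Known bias: the first-order theory reports J1(2 k0 d)/J0(2 k0 d) ~
k0 d (1 + (k0 d)^2/2), i.e. a relative bias bounded by (k0 d)^2/2 (0.5% at
k0 d = 0.1). Second-order sidebands are present in the simulation and
ignored in the inversion, as in the first-order theory.

The classical sub-Nyquist estimator (`conventional_phase_demod`, the oracle
for f_m < 0.5 f_A) reads the amplitude of the carrier-pixel phase
oscillation. Because the vibration advances during the sweep, that
amplitude is attenuated by the envelope washout factor
W = |sum_j P_j e^{i w_m t_j}| / sum_j P_j (~0.89 at 10 kHz for the default
envelope); the estimator divides it out, making the two demodulators agree
to better than 1% where both apply.

Jitter correction replaces the nominal lock-in phasor with the recorded
stimulus phasor. With the defaults at 679.6 kHz, the uncorrected
demodulated phase SD matches sigma_L below, and the corrected SD lands on
the SNR-limited floor 1/(sqrt(2 N X) k0 delta) to within a few percent.

## Noise budget

* Minimum detectable amplitude: k0 delta_min = X^{-1/2} N^{-1/2}, i.e.
  delta_min = lambda0/(2 pi sqrt(X N)); 200 pm at X = 1e4, N = 108,
  lambda0 = 1307 nm. The simulated demodulation noise floor reproduces this
  to a fraction of a percent.
* Jitter phase error: the lock-in phase carries the mean accumulated jitter,
  whose SD is sigma_L = w_m sigma_T sqrt((N+1)(2N+1)/(6N)) — exactly
  w_m sigma_T at N = 1 and sqrt(N/3) w_m sigma_T for N >> 1. (The exact and
  asymptotic forms must agree at large N; the implementation uses the form
  that satisfies both limits and the Monte-Carlo check.)
* Total phase noise: delta_phi = sqrt(1/(N X^2) + 0.58 N (w_m sigma_T)^2).
  The SNR term is implemented as printed; a `variance_nx` flag substitutes
  1/(N X), the form consistent with the delta_min derivation, because the
  printed term is typographically ambiguous. The jitter coefficient 0.58 is
  likewise kept as printed even though the sigma_L derivation suggests 1/3;
  tests pin the two limiting behaviours, not the coefficient.
* Velocity error: dv/v = (delta_phi / 2 pi)(lambda / L) with L the
  effective measurement length (a couple of wavelengths in lossy media).

## Wavefield analysis

Surface profiles u(x) at one frequency are transformed to the wavenumber
domain (optionally Hann-windowed — the abrupt near-field truncation
otherwise creates a leakage pedestal that biases peak positions by several
percent), and the Rayleigh mode is picked inside an expected-k band with
3-point quadratic interpolation on log magnitude (ties toward lower k).
Phase velocity is v = 2 pi f / k = omega/k (the dimensionally consistent
reading of the wavelength-like expression sometimes quoted for it).

For a harmonically driven cylindrical contact of radius a on an
incompressible half-space, the surface displacement is the two-mode sum

    u(x) = i pi (a p0 K^4 / rho w^2) * sum_{R,SS}
           J1(K_m a) K_m / F'(K_m) * H0^(1)(-K_m |x|),

where K_R = 1.0468 K and K_SS = (0.4696 - 0.1355 i) K are roots of the
secular equation

    F(kappa) = (2 kappa^2 - K^2)^2
               - 4 kappa^2 sqrt(kappa^2) sqrt(kappa^2 - K^2)
                 * sign{Re(kappa^2 - K^2)}.

Branch convention: the two square-root factors are taken on their principal
branches separately (taking the principal root of the product instead
annihilates the sign rule and misses the supershear root), and time goes as
e^{+i w t} with K = k_r - i k_i, which makes H0^(1)(-K x) outward-decaying
for k_i > 0 — verified by the decay of |u| with |x|. F' is a complex
central difference. Fitting minimizes the joint real/imaginary residuals
over complex K with the linear source strength p0 projected out at each
iterate (variable projection); a three-point multi-start guards against the
local minimum created by the supershear peak. K_init defaults to the
k-domain peak divided by the Rayleigh ratio.

Cross-sectional maps reuse the depth-resolved demodulation at every pixel;
a synthetic half-space scene ties the vibration amplitude to the
surface-wave eigenfunction |psi(z)| ~ e^{-k_z z}, k_z ~ 0.31 k, whose 1/e
decay depth is about half a wavelength.

## Elastodynamics

* Complex modulus: mu' + i mu'' = rho w^2/(k_r - i k_i)^2, expanded as
  mu' = rho w^2 (k_r^2 - k_i^2)/(k_r^2 + k_i^2)^2 and
  mu'' = 2 rho w^2 k_r k_i/(k_r^2 + k_i^2)^2; the loss/storage crossover
  sits at k_i/k_r = sqrt(2) - 1 = 0.414. The sign convention k = k_r - i k_i
  (wave ~ e^{i(wt - kx)}) makes mu'' >= 0 for passive media.
* Half-space conversion: c_R/c_s = (0.862 + 1.14 nu)/(1 + nu) and
  mu = rho c_s^2. The incompressible limit of this formula (0.9547) agrees
  with the reciprocal secular root (0.9553) to 0.07%; internally a single
  constant — the secular root, rendered variously as 1.047/1.048 in the
  literature — is used wherever the incompressible conversion is needed.
* Lamb plates: the fundamental A0/S0 phase velocities solve the classical
  Rayleigh-Lamb transcendental equations, evaluated in tanh-normalized real
  forms per velocity regime (no overflow at large f h), with the removable
  zero at v = c_s divided out so bracketing scans cannot lock onto it. A0 is
  searched below, S0 above, the *exact* compressible Rayleigh speed (the
  approximate ratio formula is ~0.1% off, enough to misplace the branch
  boundary at large f h). Beyond f h ~ 5 c_s the A0 root is within
  double-precision round-off of the Rayleigh speed and the solver reports a
  bracketing error rather than inventing digits.
* Rheology: power-law fits mu ~ f^alpha by log-log least squares, with a
  two-segment variant at a user-supplied breakpoint.
* Depth profiling: the penetration-depth approximation
  k^2 = (rho w^2/L_z) int_0^{L_z} dz/mu(z), L_z = a_L lambda (a_L = 0.25 by
  default, from L_z = 1/(2 k_z)). The forward map solves the implicit
  relation per frequency by bracketed root finding on the monotone
  consistency map (plain fixed-point iteration two-cycles on steep
  profiles, and for a discontinuous layer step the equation can have no
  solution at low frequency — profiles should be smooth on the scale of
  L_z). Differentiating gives the inverse,
  mu(z) = rho v^2 (v - f v')/(v + f v') at z = a_L v/f with
  v = 1.0468 v_R. The derivative v' is the dominant numerical hazard:
  the default estimator is a smoothing spline; alternatively the empirical
  skin dispersion form v = v0 + a f/sqrt(b^2 f^2 + 1) + c f/(d f + 1)
  (f in kHz) is fitted and differentiated analytically. Points with
  v + f v' <= 0 are masked (formula breakdown). Forward-then-inverse on a
  smooth two-decade exponential profile agrees within ~7% over the probed
  depth band (the first/last two frequencies are excluded — spline
  end-derivatives are unreliable there).

## Synthetic data: what it does and does not emulate

The generator reproduces the signal chain (fringe formation, envelope,
sidebands, aliasing, period jitter, detector noise at a set SNR) with
discrete specular scatterers and externally prescribed vibration fields.
It does not model speckle statistics of continuous scattering media,
depth-dependent SNR decay, galvanometer beam geometry, motion artifacts of
the sample itself, 1/f electrical noise, or the elastodynamics of wave
generation (vibration fields are imposed, not solved; the wavefield tests
therefore verify the measurement chain and the inversions, not continuum
mechanics). Passing tests demonstrate correctness of the algorithms under
the stated signal model, not instrument performance on tissue.

## Problem sizes in the test suite

Statistical checks use sizes chosen to keep sampling error a small
fraction of the tolerances: 500 noise realizations for the sensitivity
floor, 200 jittered M-scans for the phase-noise statistics, 1e4 analytic
M-scans for the sigma_L Monte-Carlo, 50 trials for the noisy model fit,
and 48-64 lateral positions for the end-to-end wave-speed round trips.
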