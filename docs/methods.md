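# Methods

This note records the models, numerical choices and study conditions behind
`voidlapse`, and what the synthetic experiments do and do not show.

## Object model

The phantom is a uniform cylinder (2D: disk) of background signal *B*
containing point-like signal voids:

    f(x, t) = B · 1_cyl(x) · (1 − Σ_i a_i s_i exp(−|x − x_i(t)|² / 2σ_i²)),

clipped at zero. Each void is a parametric Gaussian intensity dip with
amplitude `a` (fraction of background removed at the centre), width `σ` (mm)
and a per-sequence contrast scale `s`. It deliberately is *not* a
dipole-field/Bloch simulation: the observables of interest — signal loss,
void size in pixels, CNR — depend only on the rendered contrast, so a
calibrated dip reproduces them while keeping a closed-form spectrum. The
Fourier transform is analytic: a jinc-type disk term (times a slab sinc in
3D) minus one shifted-Gaussian term per particle,
`B a s (2πσ²)^{d/2} exp(−2π²σ²|k|²) e^{−2πi k·x_i(t)}`. Truncation of the
Gaussian tail by the cylinder edge is neglected (voids sit well inside and
σ ≪ R). Rigid rotation about the z axis through the origin moves particle
*i* at tangential speed 2π·ω·r_i mm/min (ω in rpm); the tube edge radius
default, 5.064 mm, is the value implied by the pairing "0.14 mm/min at
4.4×10⁻³ rpm", and at 4.7×10⁻² rpm it reproduces 1.5 mm/min.

Coordinates are physical millimetres with the origin on the rotation axis.
Image grids are centred with voxel centres at half-integer offsets (no voxel
sits exactly on the axis); k-space is in cycles/mm with DC at index n//2.
In 3D the standard scenes set the cylinder height equal to the z field of
view — the physical tube is longer than the imaging volume — which removes
end-face ringing from the reconstructions.

## Acquisition

The object is frozen within each readout (a readout lasts milliseconds,
motion is mm/min, so intra-readout displacement is ≪ one voxel) and evolves
between readouts; this is the entire mechanism of temporal blurring.
Complex Gaussian noise of SD `noise_sigma` per channel is added
independently to every sample. All randomness flows from a single seed.

*Cartesian*: one phase-encode line per TR, linear or centric ordering, all
averages of a line acquired back-to-back (switchable to frame-wise).
Frame duration = lines × averages × TR + overhead; the 4.546 s overhead that
reconciles 256×32×12 ms = 98.304 s with the printed 1:42.85 min is exposed
as a schedule parameter (dummy scans; inferred, not stated).

*3D radial dual-half-echo*: spoke directions from a deterministic spherical
phyllotaxis (Fibonacci) lattice; spoke j < f·⌊n/f⌋ joins interleave j mod f,
so every interleave inherits quasi-uniform sphere coverage, and the few
remainder spokes (id −1; 120188 − 20·6009 = 8 in the reference protocol)
are used only in fully sampled frames. Acquisition plays interleave 0
completely, then interleave 1, etc., enabling retrospective FS/US framing.
|k| along a spoke is quadratic over the gradient-ramp fraction of samples
and linear afterwards. The second (centre-in) half echo samples the same
k-space locations with independent noise and a deeper void contrast
(default scale 1.3), a phenomenological stand-in for the longer TE. The
(0, π) phase cycling of the sequence is a no-op in this signal model and is
recorded in metadata only.

## Reconstruction

*Cartesian*: inverse FFT in object units; retrospective contrast
enhancement zero-pads k-space by 4 per axis and takes the minimum of each
4×4 block of fine samples per native voxel, deepening voids whose true
minimum falls between voxel centres.

*Gridding*: Kaiser–Bessel convolution gridding, oversampling 2, kernel
width 4, Beatty shape parameter, analytic deapodization. The half-voxel
grid offset is applied as an exact per-sample phase (a grid-side ramp would
break the circular wrap of Nyquist-edge samples); both operators agree with
direct discrete Fourier sums to ~6×10⁻⁴ relative error. Density
compensation starts from quadrature weights |k|^{d−1}·(d|k|/ds)·Ω_d/n_spokes
(ramp filter plus gradient-ramp correction, DC floored at its half-cell
volume) and is refined by a few Pipe–Menon iterations with a unit-gain
normalisation, so the adjoint reconstructs in object units (a background-1
phantom comes back at ≈1).

*Echo combination*: `(I1^(1+p) + I2^(1+p))^(1/(1+p))` taken literally at
its printed normalisation; with the default p = −0.5 this is
(√I1 + √I2)², which preserves voids that are deep in either echo better
than sum-of-squares.

*Compressed sensing*: temporal total variation across the subframe stack,
weight λ = `lambda_percent`/100 × max |adjoint recon| (1% for phantom-like
data, 5% for noisier in-vivo-like data). The quadratic data term is applied
in its **density-compensated image-domain (preconditioned) form**
Σ_s ‖x_s − A_s^H W_s y_s‖²: because the density-compensated normal operator
is close to the identity, this agrees with the k-space residual form to
within the gridding accuracy, and it makes the λ → 0 limit coincide
*exactly* with the gridded reconstruction — the property the reconstruction
modes are validated against. The solution is then the exact temporal-TV
proximal map of the subframe recon stack, computed by projected dual ascent
(Chambolle), default 60 iterations, relative-change tolerance 10⁻⁴, applied
to real and imaginary parts; non-convergence is reported and the last
iterate returned. The trade-off versus a fully data-consistent iteration is
documented honestly: artifacts correlated with the object are not re-fitted
against k-space, and a moving void's temporal differences are shrunk by up
to ~2λ, a small contrast cost visible for the slowest movers. Magnitude is
taken last, so background noise is Rayleigh, consistent with the
quantification's correction factor.

## Quantification

Signal loss, void size (threshold = (minimum + background)/2, connected
pixels including diagonals), SNR (mean ROI / corrected noise SD, plus
SNR per scan time), CNR (|min − enclosing mean| / enclosing SD) and the
contrast changes are implemented exactly as defined. The Rayleigh
correction is read as √(2/(4−π)) ≈ 1.5264 — the standard magnitude-noise
factor — rather than (√2)/(4−π); the printed typography is ambiguous, but
only the former recovers the underlying complex-channel noise SD
(verified by Monte Carlo).

The "enclosing area", unspecified in the source procedure, is an
annulus/shell extending 2–5 voxels beyond the void's bounding radius
(estimated by a provisional threshold pass from a generous 4–8 voxel
shell), configurable. The spot minimum is searched in a 5^d neighbourhood
of the nominal coordinate to tolerate sub-voxel drift. Note a consequence
used in the analyses: the extreme value of pure noise over such a window is
≈3σ, so an automated "visible" call at CNR ≥ 2 will occasionally tag a
noise dip; the analyses that depend on visibility therefore either pool
enough particles for the misclassification rate to average out or restrict
to spots visible in both conditions being compared.

## Velocity detection limit

Records (velocity, SL_stat, SL_rot, visible) enter a bin
SL_stat ∈ [S̄ − 0.05, S̄ + 0.05] (closed interval). ΔSL = SL_stat − SL_rot,
with SL_rot ≡ 0 for non-visible spots. Ordinary least squares per group
(visible / strictly non-visible; zero-velocity visible spots are not mixed
into the non-visible fit), intersection
v_max = (b_nv − b_v)/(m_v − m_nv), first-order error propagation.
**Default error propagation includes each fit's internal slope–intercept
covariance**: the intersection typically lies far from the visible group's
mean velocity, where slope and intercept errors anti-correlate, and
ignoring the covariance (available via `use_covariance=False`) inflates σ
by a factor ≈2–3. With covariance the estimate is well calibrated: over
100 synthetic replicates with a planted limit of 0.8 mm/min, the mean
propagated σ matches the Monte-Carlo SD within ~10% and the ±2σ interval
covers the truth ~95–98% of the time. Velocities of non-visible particles
come from the rotation geometry (they cannot be measured from a blurred
image). The estimator is invariant under velocity unit rescaling.

The synthetic record generator plants the intersection exactly: visible
ΔSL grows as (S̄/v_max)·v with Gaussian scatter (SD 0.02), non-visible
ΔSL scatters flatly around S̄; group sizes 40/40 with velocities spanning
[0, 1.05·v_max] and [0.5, 1.8]·v_max respectively.

## Tracking

Greedy globally-shortest-link matching per consecutive frame pair
(candidates sorted by distance, mutual exclusion, links > `max_disp`
forbidden, no gap closing); adequate and deterministic for sparse slow
spots, and checked against brute-force assignment on tiny sets. Velocity =
total inter-frame path length / elapsed time. Stationary features present
in every frame (small vessels mimicking cells) can be filtered by a
net-displacement tolerance; trajectories spanning at least two consecutive
frames are the default unit of analysis.

## Desk-scale study conditions

The presets keep the reference protocols' *temporal* structure exactly and
shrink the matrices:

| preset | matrix | frame | notes |
|---|---|---|---|
| `cartesian_bssfp` | 64², 0.2 mm | 102.85 s | 32 averages |
| `cartesian_gre` | 64², 0.2 mm | 495.3 s | 4 averages, long TR |
| `radial_bssfp` | 32³, 0.4 mm | 480.752 s | 3200 spokes ≈ π·32² (Nyquist), f = 20; subframes 96.15 / 48.075 / 24.038 s |

Spoke counts follow the same Nyquist rule as the reference protocol
(120 188 ≈ π·196²). Rotation rates and particle speeds are used at their
physical values, so blurring develops on the real time scale. Void
contrast is calibrated per grid so a static reconstructed void lands at
SL ≈ 0.21–0.24 and ~2–4 pixels (2D: a = 0.32, σ = 0.12 mm; 3D preset:
a = 0.5, σ = 0.2 mm), and k-space noise presets reproduce the printed
image-quality figures (2D bSSFP SNR ≈ 70, GRE ≈ 85, 3D radial FS
population CNR ≈ 5–7). The FS↔CS blur comparison runs on a 48³ grid
(0.27 mm voxels, 7200 spokes) because the criterion of interest lives in
voxel-normalised units: there a 0.1 mm/min particle moves ≈3 voxels during
the fully sampled frame but <1 voxel during a five-subframe window — the
same sub-voxel regime as the reference protocol — and it pools three
seeded replicates (60 particles) since the per-replicate win fraction has
sampling noise of roughly ±0.15 at n ≈ 7 visible pairs.

The reported 10-subframe duration follows n_spokes·TR/n_subframes
(48.0752 s), which differs in the last digit from the printed 00:48.075
rounding.

## What the synthetic experiments do and do not show

The generator emulates: sparse point voids with sub-voxel motion, rigid
in-plane rotation, complex Gaussian k-space noise, retrospective FS/US/CS
framing, and dual-echo contrast asymmetry. It does **not** emulate
susceptibility dipole fields or bSSFP banding, partial-volume iron-load
variation, eddy currents, coil sensitivities, through-plane motion of real
cells, or physiological background texture. Passing tests therefore
demonstrate that the *measurement and estimation pipeline* behaves as
described (blur grows with speed, noise scales as √f under undersampling,
CS denoises and restores subframe contrast, the detection-limit estimator
is unbiased and calibrated) — not that absolute in-vivo detection limits
transfer; on real data they are expected to be lower, as noisier
backgrounds and 3D motion reduce contrast further.

## Known limitations

* The CS data term is preconditioned/image-domain (see above); highly
  structured undersampling artifacts are denoised, not inverted.
* The Gaussian void has no phase structure; effects that depend on the
  complex point-spread of a dipole (e.g. echo-time-dependent void shapes)
  are only captured through the per-echo contrast scale.
* Automated visibility (CNR threshold) is a proxy for the visual
  identification used in practice and misclassifies near the noise floor.
* The linker has no gap closing or motion model; crossing trajectories
  closer than `max_disp` can swap.
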