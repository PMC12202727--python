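# voidlapse

Desk-scale simulation, reconstruction and quantification toolkit for
single-cell **time-lapse MRI**.

Iron-labeled cells (or micron-sized iron-oxide particles, MPIOs, embedded in
an agar cylinder) appear in T2\*-weighted images as small hypointense spots —
signal voids a few pixels in size. Repeated imaging of the same volume lets
one follow individual cells over time, but spatial encoding takes minutes:
a cell that moves during the acquisition of one k-space frame is *temporally
blurred* — its void loses contrast, elongates, and above some speed
disappears entirely. `voidlapse` models this chain end to end:

* an **analytic rotating-cylinder phantom** with point-like Gaussian signal
  voids, evaluable in image space and in closed form in k-space at any time
  instant (each particle at radius *r* moves at tangential speed
  2π·ω·*r* mm/min for rotation rate ω in rpm);
* **time-stamped acquisition schedules** — 2D Cartesian bSSFP/GRE (one
  phase-encode line per TR) and interleaved 3D radial dual-half-echo bSSFP
  (deterministic spherical-phyllotaxis spoke directions, interleave factor
  *f*, each interleave covering the sphere quasi-uniformly) — with complex
  Gaussian k-space noise, the object frozen within each readout but moving
  between readouts;
* **reconstruction**: Cartesian FFT with retrospective zero-fill minimum
  projection; density-compensated Kaiser–Bessel gridding (ramp filter
  |k|^(d−1) plus gradient-ramp correction, iteratively refined weights);
  retrospective fully sampled (FS) / undersampled (US) framing from the
  interleaves; weighted dual-echo combination
  `I = (I1^(1+p) + I2^(1+p))^(1/(1+p))` with p = −0.5; temporal-total-variation
  compressed sensing (CS) of the subframe stack; inverted-image maximum
  intensity projections;
* **quantification**: signal loss
  `SL = (mean_enclosing − min_spot) / mean_enclosing`, threshold-and-count
  void size, SNR and SNR per unit time, CNR with the Rayleigh
  magnitude-noise correction √(2/(4−π)) ≈ 1.5264, the contrast change
  ΔSL = SL_stat − SL_rot, and the FS↔CS relative change
  `(SL_CS − SL_FS) / ((SL_CS + SL_FS)/2)`;
* the **velocity detection limit** v_max: per-particle (velocity, ΔSL,
  visibility) records are binned by static signal loss (±0.05), visible and
  non-visible groups are fitted by independent least-squares lines, and the
  intersection of the two fits — with first-order error propagation — is the
  maximum speed at which a void of that contrast remains detectable;
* simple **nearest-neighbour trajectory linking** with per-track velocities.

## Worked example

A single void 3 mm from the rotation axis, imaged with the 64×64 Cartesian
bSSFP preset (102.85 s per frame), static versus rotating at 4.7×10⁻² rpm:

```python
import numpy as np
from voidlapse import (Scene, Particle, ImageGrid, CartesianSchedule, acquire,
                       cartesian_recon, measure_spot, delta_sl,
                       particle_speed, particle_position)

particle = Particle(0, position0=np.array([3.0, 0.0]))
schedule = CartesianSchedule(matrix=(64, 64), fov=(12.8, 12.8),
                             tr_ms=50.22, averages=32)
grid = ImageGrid(schedule.matrix, schedule.fov)

static   = Scene(particles=[particle], omega_rpm=0.0,    noise_sigma=0.2)
rotating = Scene(particles=[particle], omega_rpm=4.7e-2, noise_sigma=0.2)

img_stat = cartesian_recon(acquire(static,   schedule, seed=7))
img_rot  = cartesian_recon(acquire(rotating, schedule, seed=8))

mid = particle_position(rotating, 0, 102.85 / 2)   # void position mid-frame
m_stat = measure_spot(img_stat, grid.index_of(particle.position0))
m_rot  = measure_spot(img_rot,  grid.index_of(mid))
print(f"tangential speed : {particle_speed(rotating, 0):.2f} mm/min")
print(f"static   SL {m_stat.sl:.3f}   void {m_stat.void_px} px   CNR {m_stat.cnr:.1f}")
print(f"rotating SL {m_rot.sl:.3f}   void {m_rot.void_px} px   CNR {m_rot.cnr:.1f}")
print(f"delta SL  {delta_sl(m_stat.sl, m_rot.sl):.3f}")
```

prints

```
tangential speed : 0.89 mm/min
static   SL 0.190   void 4 px   CNR 10.5
rotating SL 0.106   void 8 px   CNR 5.3
delta SL  0.084
```

— the moving void doubles in size and loses nearly half its contrast within
one frame: temporal blurring, the quantity the ΔSL-versus-velocity
regressions turn into a detection limit. Collections of such records feed
`voidlapse.vmax.estimate_vmax` (or `voidlapse vmax --sl-center 0.25
spots.csv` from the shell).

There is also a CLI for the common workflows:

```bash
voidlapse pipeline --config cfg.yaml --seed 3 --out run1   # simulate→recon→quantify
voidlapse recon kspace.h5 --mode cs --subframes 5 --lambda-pct 1 --out frames.nii.gz
voidlapse fixture rotating_fast --seed 0 --out fixtures/
```

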