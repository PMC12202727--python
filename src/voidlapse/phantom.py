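"""Analytic digital phantom: a rotating agar cylinder containing point-like signal voids.

The phantom stands in for the rotating-phantom rig used to characterise the
velocity detection limit of time-lapse MRI: micron-sized iron-oxide particles
suspended in agar produce small hypointense spots, and slow rigid rotation of
the tube moves each particle at a tangential speed proportional to its radius.

The object is modelled analytically so that its Fourier transform is available
in closed form at any time instant.  The image-space object is

    f(x, t) = B * 1_cylinder(x) * (1 - sum_i a_i * s_i * g(x - x_i(t); sigma_i))

with background ``B``, per-particle void amplitude ``a_i`` (fraction of the
background removed at the void centre), per-sequence contrast scale ``s_i``
and an isotropic Gaussian dip profile ``g`` of width ``sigma_i``.  The void is
a parametric intensity dip, not a dipole-field simulation: the quantities of
interest (signal loss, void size in pixels, CNR) depend only on the rendered
contrast, so a calibrated dip reproduces them at desk scale.

Units: positions and lengths in mm, time in seconds, rotation rate in rpm,
spatial frequency k in cycles/mm.  The origin sits on the rotation axis;
image grids are centred with voxel centres at half-integer offsets, so no
voxel lies exactly on the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.special import j1

__all__ = [
    "Particle",
    "Scene",
    "ImageGrid",
    "particle_position",
    "particle_speed",
    "render_image",
    "analytic_kspace",
    "bandlimited_render",
]

# Edge radius (mm) of the phantom tube, inferred from the printed pairing of
# rotation rate and maximal particle speed: 0.14 mm/min at 4.4e-3 rpm.
DEFAULT_CYLINDER_RADIUS_MM = 0.14 / (2.0 * np.pi * 4.4e-3)


@dataclass
class Particle:
    """A point-like signal void (an iron-labeled cell / MPIO surrogate)."""

    id: int
    position0: np.ndarray  # mm, phantom frame at t = 0; length 2 or 3
    void_amplitude: float = 0.32  # fraction of background removed at centre
    void_sigma: float = 0.12  # mm, Gaussian width of the dip
    sequence_contrast_scale: float = 1.0  # e.g. deeper dephasing in GRE

    def __post_init__(self) -> None:
        self.position0 = np.asarray(self.position0, dtype=float)
        if not 0.0 < self.void_amplitude <= 1.0:
            raise ValueError("void_amplitude must be in (0, 1]")
        if self.void_sigma <= 0:
            raise ValueError("void_sigma must be positive")


@dataclass
class Scene:
    """Ground-truth description of the rotating cylinder phantom.

    ``omega_rpm`` is the constant rotation rate about the z axis (through the
    origin).  A particle at radius r moves at tangential speed
    ``2*pi*omega_rpm*r`` mm/min.
    """

    cylinder_radius: float = DEFAULT_CYLINDER_RADIUS_MM
    background_signal: float = 1.0
    particles: list = field(default_factory=list)
    omega_rpm: float = 0.0
    noise_sigma: float = 0.0  # complex-Gaussian k-space noise SD per channel
    cylinder_height: float | None = None  # mm; None -> 2D disk object

    def __post_init__(self) -> None:
        if self.omega_rpm < 0:
            raise ValueError("omega_rpm must be >= 0")
        for p in self.particles:
            if np.hypot(*p.position0[:2]) > self.cylinder_radius:
                raise ValueError(f"particle {p.id} lies outside the cylinder")

    @property
    def dim(self) -> int:
        return 2 if self.cylinder_height is None else 3

    def particle(self, particle_id: int) -> Particle:
        for p in self.particles:
            if p.id == particle_id:
                return p
        raise KeyError(f"unknown particle id {particle_id}")

    # ---- YAML serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for p in d["particles"]:
            p["position0"] = [float(v) for v in p["position0"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scene":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["particles"] = [Particle(**p) for p in d.get("particles", [])]
        return cls(**d)


@dataclass
class ImageGrid:
    """Centred image grid: voxel centres at (j - n/2 + 0.5) * fov/n per axis."""

    shape: tuple
    fov: tuple  # mm per axis

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.fov = tuple(float(f) for f in self.fov)
        if len(self.shape) != len(self.fov):
            raise ValueError("shape and fov must have the same length")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid resolution must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_size(self) -> tuple:
        return tuple(f / n for f, n in zip(self.fov, self.shape))

    def axis_coords(self, ax: int) -> np.ndarray:
        n, d = self.shape[ax], self.voxel_size[ax]
        return (np.arange(n) - n / 2 + 0.5) * d

    def coords(self) -> list:
        """Meshgrid ('ij') of voxel-centre coordinates, one array per axis."""
        return np.meshgrid(*[self.axis_coords(a) for a in range(self.ndim)], indexing="ij")

    def axis_kcoords(self, ax: int) -> np.ndarray:
        n = self.shape[ax]
        return (np.arange(n) - n // 2) / self.fov[ax]

    def kmax(self, ax: int = 0) -> float:
        """Nyquist radius (cycles/mm) along ``ax``."""
        return self.shape[ax] / (2.0 * self.fov[ax])

    def index_of(self, position) -> tuple:
        """Voxel index whose centre is nearest to a physical position (mm)."""
        position = np.asarray(position, dtype=float)
        idx = []
        for ax in range(self.ndim):
            n, d = self.shape[ax], self.voxel_size[ax]
            j = int(round(position[ax] / d + n / 2 - 0.5))
            idx.append(min(max(j, 0), n - 1))
        return tuple(idx)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _rotation_angle(omega_rpm: float, t: float) -> float:
    return 2.0 * np.pi * omega_rpm * np.asarray(t, dtype=float) / 60.0


def particle_position(scene: Scene, particle_id: int, t: float) -> np.ndarray:
    """Lab-frame position (mm) of a particle at time ``t`` (s).

    Rigid rotation of ``position0`` about the z axis by ``2*pi*omega*t``;
    the distance to the axis is conserved.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    p = scene.particle(particle_id)
    return _rotate(p.position0, _rotation_angle(scene.omega_rpm, t))


def _rotate(pos: np.ndarray, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    x, y = pos[0], pos[1]
    out = np.empty(np.shape(theta) + pos.shape, dtype=float)
    out[..., 0] = c * x - s * y
    out[..., 1] = s * x + c * y
    if pos.shape[0] == 3:
        out[..., 2] = pos[2]
    return out


def particle_speed(scene: Scene, particle_id: int) -> float:
    """Tangential speed in mm/min: 2*pi*omega[rpm]*r[mm]."""
    p = scene.particle(particle_id)
    r = float(np.hypot(p.position0[0], p.position0[1]))
    return 2.0 * np.pi * scene.omega_rpm * r


def positions_at(scene: Scene, t: float) -> np.ndarray:
    """Stacked lab-frame positions of all particles at time ``t`` (s)."""
    theta = _rotation_angle(scene.omega_rpm, t)
    return np.stack([_rotate(p.position0, theta) for p in scene.particles])


# ---------------------------------------------------------------------------
# Image-space rendering
# ---------------------------------------------------------------------------

def render_image(scene: Scene, t: float, grid: ImageGrid) -> np.ndarray:
    """Evaluate the analytic object at the voxel centres of ``grid``.

    Produces the sharp (non-band-limited) ground-truth image: a uniform disk
    (2D) or cylinder cross-section stack (3D) with Gaussian hypointense dips
    at the instantaneous particle positions, clipped at zero.
    """
    xs = grid.coords()
    r2 = xs[0] ** 2 + xs[1] ** 2
    support = (r2 <= scene.cylinder_radius ** 2).astype(float)
    if grid.ndim == 3 and scene.cylinder_height is not None:
        support = support * (np.abs(xs[2]) <= scene.cylinder_height / 2)
    dip = np.zeros(grid.shape)
    if scene.particles:
        for p, pos in zip(scene.particles, positions_at(scene, t)):
            d2 = sum((xs[a] - pos[a]) ** 2 for a in range(grid.ndim))
            dip += p.void_amplitude * p.sequence_contrast_scale * np.exp(
                -d2 / (2.0 * p.void_sigma ** 2)
            )
    img = scene.background_signal * support * (1.0 - dip)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# Closed-form k-space
# ---------------------------------------------------------------------------

def _disk_ft(radius: float, kr: np.ndarray) -> np.ndarray:
    """2D FT of the unit-height disk of ``radius``: R*J1(2*pi*R*|k|)/|k|."""
    out = np.full(kr.shape, np.pi * radius ** 2, dtype=float)
    nz = kr > 0
    out[nz] = radius * j1(2.0 * np.pi * radius * kr[nz]) / kr[nz]
    return out


def analytic_kspace(
    scene: Scene,
    t,
    k: np.ndarray,
    echo_contrast_scale: float = 1.0,
) -> np.ndarray:
    """Closed-form Fourier transform of the object at time ``t``.

    ``k``: array of shape (..., d) in cycles/mm.  ``t`` may be a scalar or an
    array of shape ``k.shape[:-1]`` (one time stamp per sample).
    ``echo_contrast_scale`` multiplies every void amplitude; it models the
    deeper voids of a later echo time.

    The transform is linear in the particles: the support term (disk jinc in
    2D, disk jinc x slab sinc in 3D) minus one shifted-Gaussian term
    ``B*a*s*(2*pi*sigma^2)^(d/2) * exp(-2*pi^2*sigma^2|k|^2) * e^(-2*pi*i*k.x_i(t))``
    per particle.  Because voids sit well inside the cylinder and sigma is
    small, truncation of the Gaussian tail by the support edge is neglected.
    """
    k = np.asarray(k, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("k must be finite")
    d = k.shape[-1]
    kr2d = np.hypot(k[..., 0], k[..., 1])
    support = _disk_ft(scene.cylinder_radius, kr2d)
    if d == 3:
        if scene.cylinder_height is None:
            raise ValueError("3D k requested for a 2D scene")
        h = scene.cylinder_height
        support = support * h * np.sinc(h * k[..., 2])
    out = np.asarray(support, dtype=complex) * scene.background_signal
    if not scene.particles:
        return out
    k2 = np.sum(k * k, axis=-1)
    theta = _rotation_angle(scene.omega_rpm, t)
    for p in scene.particles:
        pos = _rotate(p.position0, theta)  # shape = np.shape(t) + (d,)
        phase = np.einsum("...i,...i->...", k, pos)
        amp = (
            scene.background_signal
            * p.void_amplitude
            * p.sequence_contrast_scale
            * echo_contrast_scale
            * (2.0 * np.pi * p.void_sigma ** 2) ** (d / 2.0)
        )
        out = out - amp * np.exp(-2.0 * np.pi ** 2 * p.void_sigma ** 2 * k2) * np.exp(
            -2j * np.pi * phase
        )
    return out


def bandlimited_render(scene: Scene, t: float, grid: ImageGrid) -> np.ndarray:
    """Reference rendering via dense inverse FFT of the closed-form spectrum.

    Samples ``analytic_kspace`` on the full Cartesian k-grid of ``grid`` and
    inverts it; this is the band-limited image an ideal fully sampled
    acquisition of the frozen object would produce (complex, before taking
    the magnitude).  Serves as the oracle for gridding reconstructions.
    """
    kaxes = [grid.axis_kcoords(a) for a in range(grid.ndim)]
    kmesh = np.stack(np.meshgrid(*kaxes, indexing="ij"), axis=-1)
    spec = analytic_kspace(scene, t, kmesh)
    return inverse_fft_image(spec, grid)


def inverse_fft_image(spec: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Invert a centred Cartesian k-grid to the half-offset image grid.

    Computes I(x_m) = sum_k S(k) e^{2 pi i k.x_m} dk^d with the DC sample at
    index n//2 per axis and voxel centres at half-integer offsets.
    """
    arr = np.asarray(spec, dtype=complex)
    dk = 1.0
    for ax in range(grid.ndim):
        kax = grid.axis_kcoords(ax)
        ramp = np.exp(2j * np.pi * kax * (0.5 * grid.voxel_size[ax]))
        arr = arr * ramp.reshape([-1 if a == ax else 1 for a in range(grid.ndim)])
        dk *= 1.0 / grid.fov[ax]
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(arr)))
    return img * np.prod(grid.shape) * dk
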