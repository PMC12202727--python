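"""Time-stamped k-space sampling schedules and simulated acquisition.

Two sequence families are modelled:

* 2D Cartesian bSSFP/GRE: one phase-encode line per TR, all averages of a
  line acquired back to back (configurable to frame-wise averaging).
* 3D radial dual-half-echo bSSFP: one spoke per TR, two half echoes
  (centre-out at TE1, centre-in at TE2), directions distributed by a
  deterministic spherical (generalized spiral/phyllotaxis) scheme and played
  in an interleaved order of ``f`` quasi-uniform subsets, which permits
  retrospective reconstruction of fully sampled and undersampled frames.

The object is frozen within each readout (a readout lasts milliseconds while
the particles move mm/min, so the intra-readout displacement is far below a
voxel) but evolves from readout to readout — the mechanism that produces
temporal blurring of moving voids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from voidlapse.phantom import Scene, analytic_kspace

__all__ = [
    "CartesianSchedule",
    "RadialSchedule",
    "KSpaceData",
    "generate_spoke_directions",
    "interleave_order",
    "cartesian_frame_duration",
    "radial_frame_duration",
    "acquire",
]


@dataclass
class CartesianSchedule:
    """2D Cartesian acquisition: ``matrix = (read, phase)``, times in ms."""

    matrix: tuple = (64, 64)
    fov: tuple = (12.8, 12.8)  # mm
    tr_ms: float = 12.0
    te_ms: float = 6.0
    averages: int = 1
    line_order: str = "linear"  # or "centric"
    overhead_s: float = 0.0  # dummy scans etc. before the first line
    frame_index: int = 0
    linewise_averaging: bool = True

    def __post_init__(self) -> None:
        if self.line_order not in ("linear", "centric"):
            raise ValueError("line_order must be 'linear' or 'centric'")

    @property
    def n_read(self) -> int:
        return self.matrix[0]

    @property
    def n_phase(self) -> int:
        return self.matrix[1]

    def phase_line_sequence(self) -> np.ndarray:
        """Order in which phase-encode indices are acquired."""
        idx = np.arange(self.n_phase)
        if self.line_order == "centric":
            centre = self.n_phase // 2
            return idx[np.argsort(np.abs(idx - centre), kind="stable")]
        return idx


def cartesian_frame_duration(schedule: CartesianSchedule) -> float:
    """Seconds per timeframe: phase lines x averages x TR, plus overhead."""
    return (
        schedule.n_phase * schedule.averages * schedule.tr_ms / 1000.0
        + schedule.overhead_s
    )


@dataclass
class RadialSchedule:
    """3D radial dual-half-echo acquisition with interleaved spoke ordering."""

    n_spokes: int = 2000
    interleave_factor: int = 20
    samples_per_spoke: int = 33
    matrix: tuple = (32, 32, 32)
    fov: tuple = (12.8, 12.8, 12.8)  # mm
    tr_ms: float = 4.0
    te1_ms: float = 0.65
    te2_ms: float = 3.33
    ramp_fraction: float = 0.2  # fraction of samples acquired on the gradient ramp
    dual_echo: bool = True
    echo2_contrast_scale: float = 1.3  # longer TE deepens iron voids

    directions: np.ndarray = field(init=False, repr=False)
    acquisition_order: np.ndarray = field(init=False, repr=False)
    interleave_id: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_spokes < 1:
            raise ValueError("n_spokes must be >= 1")
        if not 1 <= self.interleave_factor <= self.n_spokes:
            raise ValueError("interleave factor must satisfy 1 <= f <= n_spokes")
        self.directions = generate_spoke_directions(self.n_spokes)
        self.acquisition_order, self.interleave_id = interleave_order(
            self.n_spokes, self.interleave_factor
        )

    @property
    def spokes_per_interleave(self) -> int:
        return self.n_spokes // self.interleave_factor

    def kmax(self) -> float:
        return self.matrix[0] / (2.0 * self.fov[0])

    def spoke_radii(self) -> np.ndarray:
        """|k| (cycles/mm) along one spoke, centre-out.

        During the gradient ramp the k-space speed grows linearly, so |k| is
        quadratic in the sample index over the first ``ramp_fraction`` of the
        readout and linear afterwards; normalized to end at Nyquist.
        """
        s = np.linspace(0.0, 1.0, self.samples_per_spoke)
        rho = self.ramp_fraction
        if rho > 0:
            r = np.where(s < rho, s**2 / (2 * rho), s - rho / 2)
            r = r / (1.0 - rho / 2)
        else:
            r = s
        return r * self.kmax()

    def trajectory(self, spoke_indices=None) -> np.ndarray:
        """Sample coordinates (n_spokes_sel, samples_per_spoke, 3) in cycles/mm."""
        dirs = self.directions if spoke_indices is None else self.directions[spoke_indices]
        return dirs[:, None, :] * self.spoke_radii()[None, :, None]

    def spokes_for_subframes(self, n_subframes: int, subframe: int | None = None):
        """Spoke indices per subframe (or for one subframe).

        ``n_subframes`` must divide the interleave factor; each subframe is a
        block of ``f / n_subframes`` consecutive interleaves.  Remainder
        spokes (interleave id -1) belong to no subframe but are included in
        the fully sampled frame.
        """
        f = self.interleave_factor
        if n_subframes < 1 or f % n_subframes != 0:
            raise ValueError(
                f"n_subframes={n_subframes} must divide the interleave factor {f}"
            )
        per = f // n_subframes
        groups = []
        for s in range(n_subframes):
            ids = range(s * per, (s + 1) * per)
            mask = np.isin(self.interleave_id, list(ids))
            groups.append(np.nonzero(mask)[0])
        if subframe is not None:
            return groups[subframe]
        return groups


def radial_frame_duration(schedule: RadialSchedule, n_subframes: int = 1) -> float:
    """Seconds per (sub)frame: n_spokes * TR / n_subframes.

    Valid ``n_subframes`` must divide the interleave factor so that each
    subframe combines whole interleaves.
    """
    f = schedule.interleave_factor
    if n_subframes < 1 or f % n_subframes != 0:
        raise ValueError(
            f"n_subframes={n_subframes} not achievable from interleave factor {f}"
        )
    return schedule.n_spokes * schedule.tr_ms / 1000.0 / n_subframes


# ---------------------------------------------------------------------------
# Spoke directions and interleaving
# ---------------------------------------------------------------------------

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def generate_spoke_directions(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the full sphere (deterministic).

    Generalized spiral phyllotaxis (spherical Fibonacci lattice): points
    descend uniformly in z while advancing by the golden angle in azimuth.
    Consecutive points are neighbours along the spiral, so a stride-``f``
    subsampling again covers the sphere quasi-uniformly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def interleave_order(n: int, f: int):
    """Partition ``n`` spokes into ``f`` interleaves and give the play order.

    Spokes follow the phyllotaxis path; spoke ``j`` (for ``j < f*floor(n/f)``)
    joins interleave ``j mod f``, so every interleave inherits quasi-uniform
    sphere coverage.  The ``n - f*floor(n/f)`` remainder spokes get
    interleave id -1: they are acquired last and used only in fully sampled
    reconstructions.  Acquisition order plays interleave 0 completely, then
    interleave 1, and so on.
    """
    if not 1 <= f <= n:
        raise ValueError("require 1 <= f <= n")
    m = n // f
    ids = np.full(n, -1, dtype=int)
    j = np.arange(f * m)
    ids[: f * m] = j % f
    order = np.concatenate(
        [np.nonzero(ids == i)[0] for i in range(f)] + [np.arange(f * m, n)]
    )
    return order, ids


# ---------------------------------------------------------------------------
# k-space container
# ---------------------------------------------------------------------------


@dataclass
class KSpaceData:
    """Complex k-space samples with trajectory, timing and noise provenance.

    ``samples`` has shape (n_echoes, n_readouts, n_samples_per_readout) and
    ``trajectory`` (n_readouts, n_samples_per_readout, d) in cycles/mm;
    ``timestamps`` (seconds, one per readout) increase strictly in
    acquisition order.  Readouts are stored in logical order (Cartesian: phase
    line index; radial: spoke index), not acquisition order.
    """

    samples: np.ndarray
    trajectory: np.ndarray
    timestamps: np.ndarray
    noise_sigma: float
    schedule: object
    meta: dict = field(default_factory=dict)

    @property
    def n_echoes(self) -> int:
        return self.samples.shape[0]

    @property
    def is_radial(self) -> bool:
        return isinstance(self.schedule, RadialSchedule)

    # ---- HDF5 persistence ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("samples", data=self.samples)
            fh.create_dataset("trajectory", data=self.trajectory)
            fh.create_dataset("timestamps", data=self.timestamps)
            fh.attrs["noise_sigma"] = self.noise_sigma
            fh.attrs["meta"] = json.dumps(self.meta)
            sched = {"type": type(self.schedule).__name__}
            for key, val in vars(self.schedule).items():
                if isinstance(val, np.ndarray):
                    continue
                sched[key] = list(val) if isinstance(val, tuple) else val
            fh.attrs["schedule"] = json.dumps(sched)

    @classmethod
    def from_hdf5(cls, path) -> "KSpaceData":
        with h5py.File(path, "r") as fh:
            sched = json.loads(fh.attrs["schedule"])
            kind = sched.pop("type")
            klass = {"CartesianSchedule": CartesianSchedule, "RadialSchedule": RadialSchedule}[kind]
            for key in ("matrix", "fov"):
                if key in sched:
                    sched[key] = tuple(sched[key])
            return cls(
                samples=fh["samples"][...],
                trajectory=fh["trajectory"][...],
                timestamps=fh["timestamps"][...],
                noise_sigma=float(fh.attrs["noise_sigma"]),
                schedule=klass(**sched),
                meta=json.loads(fh.attrs["meta"]),
            )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def acquire(scene: Scene, schedule, seed: int | None = 0, frame_start_s: float = 0.0) -> KSpaceData:
    """Simulate acquisition of ``scene`` under ``schedule``.

    Each readout samples the closed-form spectrum at that readout's time
    stamp; independent complex Gaussian noise of SD ``scene.noise_sigma``
    (per real/imaginary channel) is added to every sample.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(schedule, CartesianSchedule):
        return _acquire_cartesian(scene, schedule, rng, frame_start_s)
    if isinstance(schedule, RadialSchedule):
        return _acquire_radial(scene, schedule, rng, frame_start_s)
    raise TypeError(f"unsupported schedule type {type(schedule)!r}")


def _add_noise(rng, arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return arr
    noise = rng.normal(size=arr.shape) + 1j * rng.normal(size=arr.shape)
    return arr + sigma * noise


def _acquire_cartesian(scene, sched: CartesianSchedule, rng, t0: float) -> KSpaceData:
    if scene.dim != 2:
        raise ValueError("Cartesian schedule expects a 2D scene")
    nr, nph = sched.n_read, sched.n_phase
    kx = (np.arange(nr) - nr // 2) / sched.fov[0]
    ky = (np.arange(nph) - nph // 2) / sched.fov[1]
    traj = np.empty((nph, nr, 2))
    traj[:, :, 0] = kx[None, :]
    traj[:, :, 1] = ky[:, None]

    tr = sched.tr_ms / 1000.0
    seq = sched.phase_line_sequence()
    timestamps = np.empty(nph)
    samples = np.zeros((nph, nr), dtype=complex)
    for acq_idx, line in enumerate(seq):
        if sched.linewise_averaging:
            # all averages of this line back to back
            t_avgs = t0 + sched.overhead_s + (acq_idx * sched.averages + np.arange(sched.averages)) * tr
        else:
            t_avgs = t0 + sched.overhead_s + (acq_idx + np.arange(sched.averages) * nph) * tr
        acc = np.zeros(nr, dtype=complex)
        for t_line in t_avgs:
            vals = analytic_kspace(scene, t_line, traj[line])
            acc += _add_noise(rng, vals, scene.noise_sigma)
        samples[line] = acc / sched.averages
        timestamps[line] = t_avgs[0]
    return KSpaceData(
        samples=samples[None, ...],
        trajectory=traj,
        timestamps=timestamps,
        noise_sigma=scene.noise_sigma,
        schedule=sched,
        meta={"frame_start_s": t0, "sequence": "cartesian"},
    )


def _acquire_radial(scene, sched: RadialSchedule, rng, t0: float) -> KSpaceData:
    if scene.dim != 3:
        raise ValueError("Radial schedule expects a 3D scene")
    traj = sched.trajectory()
    tr = sched.tr_ms / 1000.0
    timestamps = np.empty(sched.n_spokes)
    timestamps[sched.acquisition_order] = t0 + np.arange(sched.n_spokes) * tr
    tgrid = np.broadcast_to(timestamps[:, None], traj.shape[:2])
    echoes = [_add_noise(rng, analytic_kspace(scene, tgrid, traj), scene.noise_sigma)]
    if sched.dual_echo:
        # centre-in half echo: same sample locations, deeper void contrast,
        # independent noise realisation
        e2 = analytic_kspace(scene, tgrid, traj, echo_contrast_scale=sched.echo2_contrast_scale)
        echoes.append(_add_noise(rng, e2, scene.noise_sigma))
    return KSpaceData(
        samples=np.stack(echoes),
        trajectory=traj,
        timestamps=timestamps,
        noise_sigma=scene.noise_sigma,
        schedule=sched,
        meta={"frame_start_s": t0, "sequence": "radial", "phase_cycling": "0,pi"},
    )
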