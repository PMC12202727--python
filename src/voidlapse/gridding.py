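"""Kaiser-Bessel gridding NUFFT (adjoint and forward) for 2D/3D trajectories.

Community-standard convolution gridding: oversampling factor 2, kernel width
4 grid cells, Kaiser-Bessel shape parameter from the Beatty formula, and
analytic deapodization.  The adjoint computes

    I(x_m) = sum_i q_i exp(+2 pi i k_i . x_m)

for arbitrary sample coordinates ``k_i`` (cycles/mm) and pre-weighted data
``q_i`` on a centred image grid with voxel centres at half-integer offsets;
with proper density-compensation quadrature weights folded into ``q`` this
approximates the continuous inverse Fourier integral in object units.
The forward operator is its exact conjugate-transpose counterpart
``y_i = sum_m I_m exp(-2 pi i k_i . x_m)`` up to the usual kernel
approximation error.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import i0

from voidlapse.phantom import ImageGrid

__all__ = ["GriddingOperator"]

OVERSAMPLING = 2.0
KERNEL_WIDTH = 4


def _beatty_beta(width: int = KERNEL_WIDTH, os: float = OVERSAMPLING) -> float:
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel on offsets ``u`` (oversampled-grid cells)."""
    inside = np.abs(u) <= width / 2.0
    arg = np.zeros_like(u, dtype=float)
    arg[inside] = 1.0 - (2.0 * u[inside] / width) ** 2
    out = np.zeros_like(u, dtype=float)
    out[inside] = i0(beta * np.sqrt(arg[inside]))
    return out


def _kb_apodization(xi: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous FT of the KB kernel at frequency ``xi`` (cycles/grid cell)."""
    t = (np.pi * width * xi) ** 2 - beta ** 2
    out = np.empty_like(t)
    pos = t > 0
    sq = np.sqrt(np.abs(t))
    out[pos] = np.sin(sq[pos]) / sq[pos]
    out[~pos] = np.sinh(sq[~pos]) / np.where(sq[~pos] == 0, 1.0, sq[~pos])
    out[(~pos) & (sq == 0)] = 1.0
    return out * width


class GriddingOperator:
    """Adjoint/forward NUFFT between an ``ImageGrid`` and arbitrary k samples."""

    def __init__(self, grid: ImageGrid, coords: np.ndarray,
                 width: int = KERNEL_WIDTH, os: float = OVERSAMPLING):
        self.grid = grid
        self.coords = coords.reshape(-1, grid.ndim)
        self.width = width
        self.beta = _beatty_beta(width, os)
        self.os_shape = tuple(int(round(n * os)) for n in grid.shape)
        # fractional index of each sample on the oversampled k grid
        self._idx = np.empty_like(self.coords)
        for ax in range(grid.ndim):
            dk_os = 1.0 / (os * grid.fov[ax])
            self._idx[:, ax] = self.coords[:, ax] / dk_os + self.os_shape[ax] / 2.0
        self._base = np.floor(self._idx - width / 2.0 + 1.0).astype(np.int64)
        # per-axis kernel values for each of the `width` neighbour offsets
        self._kern = []
        for off in range(width):
            u = self._base + off - self._idx
            self._kern.append(_kb_kernel(u, width, self.beta))
        self._apod = self._apodization_image()
        # half-voxel offset of the image grid, applied exactly at each
        # sample's true coordinates (a grid-side phase ramp would break the
        # circular wrap of edge samples)
        phase = np.zeros(self.coords.shape[0])
        for ax in range(grid.ndim):
            phase += self.coords[:, ax] * (0.5 * grid.voxel_size[ax])
        self._prephase = np.exp(2j * np.pi * phase)

    # -- precomputations ------------------------------------------------------
    def _apodization_image(self) -> np.ndarray:
        axes = []
        for ax in range(self.grid.ndim):
            n, G = self.grid.shape[ax], self.os_shape[ax]
            xi = (np.arange(n) - n // 2) / G
            axes.append(_kb_apodization(xi, self.width, self.beta))
        out = axes[0]
        for a in axes[1:]:
            out = np.multiply.outer(out, a)
        return out

    def _crop_slices(self):
        return tuple(
            slice(G // 2 - n // 2, G // 2 - n // 2 + n)
            for G, n in zip(self.os_shape, self.grid.shape)
        )

    def _neighbour_indices(self):
        strides = np.array(
            [int(np.prod(self.os_shape[a + 1:])) for a in range(self.grid.ndim)]
        )
        G = np.array(self.os_shape)
        for offs in product(range(self.width), repeat=self.grid.ndim):
            w = np.ones(self.coords.shape[0])
            flat = np.zeros(self.coords.shape[0], dtype=np.int64)
            for ax, off in enumerate(offs):
                w = w * self._kern[off][:, ax]
                flat = flat + np.mod(self._base[:, ax] + off, G[ax]) * strides[ax]
            yield flat, w

    def _spread(self, values: np.ndarray) -> np.ndarray:
        """Convolve point samples onto the oversampled grid (flat output)."""
        out = np.zeros(int(np.prod(self.os_shape)), dtype=complex)
        for flat, w in self._neighbour_indices():
            np.add.at(out, flat, values * w)
        return out

    def _interp(self, gridded_flat: np.ndarray) -> np.ndarray:
        """Convolution-interpolate an oversampled k grid at the samples."""
        out = np.zeros(self.coords.shape[0], dtype=complex)
        for flat, w in self._neighbour_indices():
            out += gridded_flat[flat] * w
        return out

    # -- adjoint: samples -> image -------------------------------------------
    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Spread samples onto the oversampled grid, invert, deapodize, crop."""
        q = np.asarray(data, dtype=complex).reshape(-1) * self._prephase
        gridded = self._spread(q).reshape(self.os_shape)
        img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(gridded)))
        img = img * np.prod(self.os_shape)
        img = img[self._crop_slices()]
        return img / self._apod

    # -- forward: image -> samples ---------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate the DTFT of ``image`` at the sample coordinates."""
        img = np.asarray(image, dtype=complex) / self._apod
        padded = np.zeros(self.os_shape, dtype=complex)
        padded[self._crop_slices()] = img
        spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
        return self._interp(spec.reshape(-1)) * np.conj(self._prephase)

    def sample_density(self, weights: np.ndarray) -> np.ndarray:
        """Kernel-smoothed sampling density seen at each sample location."""
        return np.real(self._interp(self._spread(weights.astype(complex))))

    def refine_weights(self, w0: np.ndarray, n_iter: int = 8) -> np.ndarray:
        """Pipe-Menon iterative density compensation seeded with ``w0``.

        Repeatedly divides the weights by their kernel-smoothed density so
        that the weighted sampling cloud convolved with the gridding kernel
        becomes flat, then rescales so that forward-then-adjoint has unit
        gain on a smooth reference image.  Sharpens the adjoint towards the
        true (least-squares) inverse beyond the analytic ramp weights.
        """
        w = np.asarray(w0, dtype=float).copy()
        for _ in range(n_iter):
            d = self.sample_density(w)
            w = w / np.maximum(d, 1e-12 * d.max())
        # unit-gain normalisation in object units
        xs = np.meshgrid(
            *[self.grid.axis_coords(a) for a in range(self.grid.ndim)], indexing="ij"
        )
        r2 = sum(x**2 for x in xs)
        ref = np.exp(-r2 / (2.0 * (min(self.grid.fov) / 6.0) ** 2))
        dtft_scale = float(np.prod(self.grid.voxel_size))
        back = self.adjoint(w * self.forward(ref) * dtft_scale)
        gain = float(np.real(np.vdot(back.reshape(-1), ref.reshape(-1))) / np.sum(ref**2))
        return w / gain
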