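"""Non-uniform Fourier transforms for non-Cartesian k-space.

Conventions
-----------
Image voxels live at world positions ``r(x) = (x - n//2) * voxel`` mm per
axis; k-space coordinates are in cycles/mm.  The forward (type-2) model is

    s_j = sum_x f(x) exp(-2 pi i k_j . r(x))

and the adjoint (type-1) maps weighted samples back:

    f(x) = sum_j w_j s_j exp(+2 pi i k_j . r(x)).

Two code paths:

* exact FFT path when every coordinate falls on the grid lattice
  (Cartesian trajectories) -- bitwise-deterministic and used as its own
  oracle target;
* Kaiser-Bessel gridding (oversampled FFT + deapodisation) for arbitrary
  coordinates, with the kernel shape parameter from the Beatty formula.

Density compensation for irregular trajectories uses the Pipe-Menon fixed
point ``w <- w / (C C^T w)`` evaluated with the same gridding kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0

_OVERSAMPLING = 2.0
_KERNEL_WIDTH = 6  # grid cells on the oversampled grid

__all__ = ["nufft_forward", "nufft_adjoint", "pipe_menon_weights"]


def _normalized_coords(coords: np.ndarray, grid_shape, voxel_size: float) -> np.ndarray:
    """k (cycles/mm) -> continuous index on the (non-oversampled) grid."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = np.asarray(grid_shape)
    u = coords * voxel_size * n  # in grid-frequency units, |u| <= n/2
    if np.any(np.abs(u) > n / 2 + 1e-9):
        raise ValueError("k-space coordinates exceed the grid Nyquist radius")
    return u


def _on_grid(u: np.ndarray) -> bool:
    return bool(np.all(np.abs(u - np.round(u)) < 1e-9))


def _kb_beta(width: int, os: float) -> float:
    # Beatty et al. optimal Kaiser-Bessel shape parameter
    return float(np.pi * np.sqrt((width / os * (os - 0.5)) ** 2 - 0.8))


def _kb_kernel(x: np.ndarray, width: int, beta: float) -> np.ndarray:
    arg = 1.0 - (2.0 * x / width) ** 2
    out = np.zeros_like(x, dtype=float)
    ok = arg > 0
    out[ok] = i0(beta * np.sqrt(arg[ok]))
    return out / i0(beta)

def _deapodization(n_os: int, n: int, width: int, beta: float) -> np.ndarray:
    """Image-domain response of the sampled KB kernel (central ``n`` points).

    Computed as the inverse DFT of the kernel samples themselves, so it is
    exact for the discrete spreading operator (no continuous-FT scale
    approximation).
    """
    half = width // 2
    j = np.arange(-half, half + 1)
    arr = np.zeros(n_os, dtype=float)
    arr[np.mod(j, n_os)] = _kb_kernel(j.astype(float), width, beta)
    c_full = np.real(np.fft.fftshift(np.fft.ifft(arr))) * n_os
    start = n_os // 2 - n // 2
    return c_full[start:start + n]


class _Gridder:
    """Shared geometry for spreading/interpolation on the oversampled grid."""

    def __init__(self, grid_shape, voxel_size: float, coords: np.ndarray):
        self.n = tuple(int(v) for v in grid_shape)
        self.voxel = float(voxel_size)
        self.u = _normalized_coords(coords, self.n, voxel_size)
        self.n_os = tuple(int(round(_OVERSAMPLING * v)) for v in self.n)
        self.width = _KERNEL_WIDTH
        self.beta = _kb_beta(self.width, _OVERSAMPLING)
        # continuous position on each oversampled axis (DC at index 0, wrap)
        self.pos = [
            self.u[:, ax] * self.n_os[ax] / self.n[ax] for ax in range(3)
        ]
        self.base = [np.floor(p).astype(np.int64) - self.width // 2 + 1
                     for p in self.pos]
        offs = np.arange(self.width)
        self.kern = []
        for ax in range(3):
            dist = self.base[ax][:, None] + offs[None, :] - self.pos[ax][:, None]
            self.kern.append(_kb_kernel(dist, self.width, self.beta))
        self.idx = [
            np.mod(self.base[ax][:, None] + offs[None, :], self.n_os[ax])
            for ax in range(3)
        ]

    def spread(self, values: np.ndarray) -> np.ndarray:
        """Samples -> oversampled k-space grid (adjoint interpolation)."""
        flat = np.zeros(int(np.prod(self.n_os)), dtype=complex)
        sx, sy, sz = self.n_os
        w = self.width
        for a in range(w):
            ia = self.idx[0][:, a]
            ka = self.kern[0][:, a]
            for b in range(w):
                iab = (ia * sy + self.idx[1][:, b]) * sz
                kab = ka * self.kern[1][:, b]
                for c in range(w):
                    lin = iab + self.idx[2][:, c]
                    v = values * (kab * self.kern[2][:, c])
                    flat += np.bincount(lin, weights=v.real, minlength=flat.size)
                    flat += 1j * np.bincount(lin, weights=v.imag, minlength=flat.size)
        grid = flat.reshape(self.n_os)
        return grid

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Oversampled k-space grid -> samples."""
        flat = grid.ravel()
        sx, sy, sz = self.n_os
        out = np.zeros(self.u.shape[0], dtype=complex)
        w = self.width
        for a in range(w):
            ia = self.idx[0][:, a]
            ka = self.kern[0][:, a]
            for b in range(w):
                iab = (ia * sy + self.idx[1][:, b]) * sz
                kab = ka * self.kern[1][:, b]
                for c in range(w):
                    out += flat[iab + self.idx[2][:, c]] * (kab * self.kern[2][:, c])
        return out

    def deapod(self) -> np.ndarray:
        cs = [
            _deapodization(self.n_os[ax], self.n[ax], self.width, self.beta)
            for ax in range(3)
        ]
        return cs[0][:, None, None] * cs[1][None, :, None] * cs[2][None, None, :]


_gridder_cache: dict[tuple, _Gridder] = {}


def _get_gridder(grid_shape, voxel_size: float, coords: np.ndarray) -> _Gridder:
    import hashlib

    key = (
        tuple(int(v) for v in grid_shape),
        float(voxel_size),
        hashlib.sha1(np.ascontiguousarray(coords).tobytes()).hexdigest(),
    )
    if key not in _gridder_cache:
        if len(_gridder_cache) > 24:
            _gridder_cache.clear()
        _gridder_cache[key] = _Gridder(grid_shape, voxel_size, coords)
    return _gridder_cache[key]


def nufft_forward(image: np.ndarray, coords: np.ndarray, voxel_size: float) -> np.ndarray:
    """Type-2 NUFFT: centred image -> complex samples at ``coords`` (cycles/mm)."""
    image = np.asarray(image)
    n = image.shape
    u = _normalized_coords(coords, n, voxel_size)
    if _on_grid(u):
        m = np.round(u).astype(np.int64)
        spec = np.fft.fftn(np.fft.ifftshift(image))
        idx = [np.mod(m[:, ax], n[ax]) for ax in range(3)]
        return spec[idx[0], idx[1], idx[2]].astype(complex)

    g = _get_gridder(n, voxel_size, coords)
    padded = np.zeros(g.n_os, dtype=complex)
    sl = tuple(
        slice(g.n_os[ax] // 2 - n[ax] // 2, g.n_os[ax] // 2 - n[ax] // 2 + n[ax])
        for ax in range(3)
    )
    padded[sl] = image / g.deapod()
    spec = np.fft.fftn(np.fft.ifftshift(padded))
    return g.interpolate(spec)


def nufft_adjoint(
    samples: np.ndarray,
    coords: np.ndarray,
    weights: np.ndarray,
    grid_shape,
    voxel_size: float,
) -> np.ndarray:
    """Type-1 NUFFT: density-weighted samples -> centred complex image."""
    samples = np.asarray(samples, dtype=complex)
    weights = np.asarray(weights, dtype=float)
    n = tuple(int(v) for v in grid_shape)
    u = _normalized_coords(coords, n, voxel_size)
    if _on_grid(u):
        m = np.round(u).astype(np.int64)
        grid = np.zeros(n, dtype=complex)
        idx = [np.mod(m[:, ax], n[ax]) for ax in range(3)]
        np.add.at(grid, (idx[0], idx[1], idx[2]), samples * weights)
        return np.fft.fftshift(np.fft.ifftn(grid)) * np.prod(n)

    g = _get_gridder(n, voxel_size, coords)
    grid = g.spread(samples * weights)
    img = np.fft.fftshift(np.fft.ifftn(grid)) * np.prod(g.n_os)
    sl = tuple(
        slice(g.n_os[ax] // 2 - n[ax] // 2, g.n_os[ax] // 2 - n[ax] // 2 + n[ax])
        for ax in range(3)
    )
    return img[sl] / g.deapod()


def pipe_menon_weights(
    coords: np.ndarray, grid_shape, voxel_size: float, n_iter: int = 12
) -> np.ndarray:
    """Iterative density compensation: w <- w / C(C^T w), normalised to sum 1."""
    g = _get_gridder(grid_shape, voxel_size, coords)
    w = np.ones(g.u.shape[0])
    for _ in range(n_iter):
        dens = g.interpolate(g.spread(w.astype(complex))).real
        w = w / np.maximum(dens, 1e-12 * dens.max())
    return w / w.sum()
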