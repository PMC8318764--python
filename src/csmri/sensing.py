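"""Measurement model: sampling masks, Fourier sensing operators, explicit systems.

The measurement vector ``B`` is obtained from a signal through a composed
sensing matrix ``Theta = Pi @ Omega`` (explicit mode, small instances) or
through a masked unitary 2-D Fourier transform (operator mode, images).
Both modes expose the same ``forward`` / ``adjoint`` contract so solvers
and theory code are mode-agnostic.

Conventions
-----------
* Image index (0, 0) is the top-left pixel.
* k-space arrays are stored with the zero frequency at the grid centre
  (``fftshift`` layout); :func:`fft2c` / :func:`ifft2c` implement the
  unitary (``norm="ortho"``) transform in that layout, so Parseval
  identities and adjoint tests are exact.
* Measurement vectors enumerate sampled k-space positions in row-major
  order over the centred grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from csmri._rng import substream

MaskDialect = Literal["vd-random", "radial", "cartesian-lines", "full"]

_MASK_DIALECTS = ("vd-random", "radial", "cartesian-lines", "full")

#: Largest explicit-matrix column count; theory ops need small N anyway.
MAX_EXPLICIT_COLUMNS = 1024

#: Largest grid side that :func:`materialize` will densify (N = side**2).
MAX_MATERIALIZE_GRID = 32


# --------------------------------------------------------------------------
# unitary centred Fourier transform
# --------------------------------------------------------------------------

def fft2c(image: np.ndarray) -> np.ndarray:
    """Unitary FFT with the zero frequency moved to the grid centre."""
    axes = tuple(range(image.ndim))
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image, axes=axes), norm="ortho"), axes=axes)


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    axes = tuple(range(kspace.ndim))
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kspace, axes=axes), norm="ortho"), axes=axes)


# --------------------------------------------------------------------------
# sampling masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space selection pattern (zero-frequency-centred layout).

    Attributes
    ----------
    grid : ndarray of bool, shape (n, n)
        True where the k-space coefficient is acquired.
    dialect : str
        One of ``vd-random``, ``radial``, ``cartesian-lines``, ``full``.
    fraction : float
        Requested sampling fraction in (0, 1].
    seed : int
        Seed that generated the pattern (ignored by ``full``).
    """

    grid: np.ndarray
    dialect: str
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.grid.dtype != bool or self.grid.ndim != 2:
            raise ValueError("mask grid must be a 2-D boolean array")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.dialect not in _MASK_DIALECTS:
            raise ValueError(f"unknown mask dialect {self.dialect!r}")

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())

    @property
    def achieved_fraction(self) -> float:
        return self.n_sampled / self.grid.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _radial_coordinates(grid_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # centre pixel index grid_size // 2 matches the fftshift zero-frequency bin
    c = grid_size // 2
    ky, kx = np.mgrid[0:grid_size, 0:grid_size]
    dy = ky - c
    dx = kx - c
    r = np.hypot(dx, dy) / (grid_size / 2.0)
    return dx, dy, r


def _vd_random_mask(grid_size: int, fraction: float, seed: int) -> np.ndarray:
    """Variable-density random pattern, denser toward the k-space centre.

    Cells are ranked by ``u / p(r)`` with u uniform and p a decreasing
    radial profile; taking the smallest ranks yields weighted sampling
    without replacement at an exact target count.  The central 4 % of the
    radius is always fully sampled.
    """
    _, _, r = _radial_coordinates(grid_size)
    target = max(1, round(fraction * grid_size * grid_size))
    centre = r <= 0.04
    # gentle decay: steep profiles starve the high frequencies and hurt
    # TV recovery on piecewise-constant scenes
    profile = np.power(np.maximum(1.0 - np.minimum(r, 1.0), 1e-3), 0.5) + 1e-3
    rng = substream(seed, "mask:vd-random")
    u = rng.random((grid_size, grid_size))
    score = u / profile
    score[centre] = -1.0  # guarantee inclusion
    flat_order = np.argsort(score, axis=None, kind="stable")
    mask = np.zeros(grid_size * grid_size, dtype=bool)
    mask[flat_order[: max(target, int(centre.sum()))]] = True
    return mask.reshape(grid_size, grid_size)


def _radial_mask(grid_size: int, fraction: float, seed: int) -> np.ndarray:
    """Golden-angle spokes through the centre, truncated to the exact count."""
    target = max(1, round(fraction * grid_size * grid_size))
    rng = substream(seed, "mask:radial")
    angle0 = rng.uniform(0, np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    c = grid_size // 2
    half = grid_size // 2
    chosen: list[int] = []
    seen = np.zeros(grid_size * grid_size, dtype=bool)
    spoke = 0
    # worst case ~4*grid_size spokes fills the grid
    while len(chosen) < target and spoke < 8 * grid_size:
        theta = angle0 + spoke * golden
        ct, st = np.cos(theta), np.sin(theta)
        for t in range(-half, half + 1):
            x = int(round(c + t * ct))
            y = int(round(c + t * st))
            if 0 <= x < grid_size and 0 <= y < grid_size:
                idx = y * grid_size + x
                if not seen[idx]:
                    seen[idx] = True
                    chosen.append(idx)
                    if len(chosen) >= target:
                        break
        spoke += 1
    mask = np.zeros(grid_size * grid_size, dtype=bool)
    mask[np.asarray(chosen, dtype=int)] = True
    return mask.reshape(grid_size, grid_size)


def _cartesian_lines_mask(grid_size: int, fraction: float, seed: int) -> np.ndarray:
    """Full phase-encode rows; density of retained rows decays off-centre.

    The achieved fraction is quantised to whole lines (1/grid_size), so the
    2-percentage-point fraction invariant holds for grids of 32 and above.
    """
    n_lines = int(np.clip(round(fraction * grid_size), 1, grid_size))
    c = grid_size // 2
    rows = np.arange(grid_size)
    rdist = np.abs(rows - c) / (grid_size / 2.0)
    profile = np.power(np.maximum(1.0 - np.minimum(rdist, 1.0), 1e-3), 2.0) + 1e-3
    rng = substream(seed, "mask:cartesian-lines")
    score = rng.random(grid_size) / profile
    score[c] = -1.0  # always keep the DC line
    keep = np.argsort(score, kind="stable")[:n_lines]
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    mask[keep, :] = True
    return mask


def generate_mask(grid_size: int, dialect: MaskDialect, fraction: float, seed: int = 0) -> SamplingMask:
    """Generate a deterministic sampling mask.

    Parameters
    ----------
    grid_size : int
        Side length of the square k-space grid.
    dialect : {"vd-random", "radial", "cartesian-lines", "full"}
        Sampling pattern family.
    fraction : float
        Target fraction of acquired coefficients, in (0, 1].
    seed : int
        Seed for the stochastic dialects.

    Returns
    -------
    SamplingMask
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if dialect == "full" or fraction == 1.0:
        grid = np.ones((grid_size, grid_size), dtype=bool)
        return SamplingMask(grid=grid, dialect=dialect, fraction=fraction, seed=seed)
    if dialect == "vd-random":
        grid = _vd_random_mask(grid_size, fraction, seed)
    elif dialect == "radial":
        grid = _radial_mask(grid_size, fraction, seed)
    elif dialect == "cartesian-lines":
        grid = _cartesian_lines_mask(grid_size, fraction, seed)
    else:
        raise ValueError(f"unknown mask dialect {dialect!r}")
    return SamplingMask(grid=grid, dialect=dialect, fraction=fraction, seed=seed)


# --------------------------------------------------------------------------
# sensing systems
# --------------------------------------------------------------------------

@dataclass
class SensingSystem:
    """Explicit measurement model ``B = Theta @ a`` with ``Theta = Pi @ Omega``.

    ``Pi`` is the M-by-N measurement matrix, ``Omega`` the N-by-N sparse
    mapping (identity by default), and ``Theta`` their product.  Explicit
    systems are capped at ``MAX_EXPLICIT_COLUMNS`` columns because the
    uniqueness theory enumerates column subsets.
    """

    Pi: np.ndarray
    Omega: np.ndarray | None = None
    Theta: np.ndarray = field(init=False)
    mode: str = field(default="explicit", init=False)

    def __post_init__(self) -> None:
        Pi = np.atleast_2d(np.asarray(self.Pi))
        m, n = Pi.shape
        if m > n:
            raise ValueError(f"measurement matrix must have M <= N, got {m}x{n}")
        if n > MAX_EXPLICIT_COLUMNS:
            raise ValueError(f"explicit systems are capped at N={MAX_EXPLICIT_COLUMNS} columns")
        self.Pi = Pi
        if self.Omega is None:
            self.Omega = np.eye(n)
        else:
            self.Omega = np.asarray(self.Omega)
            if self.Omega.shape != (n, n):
                raise ValueError("Omega must be N x N")
        self.Theta = self.Pi @ self.Omega

    @property
    def m(self) -> int:
        return self.Theta.shape[0]

    @property
    def n(self) -> int:
        return self.Theta.shape[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Measure sparse coefficients: ``Theta @ x``."""
        x = np.asarray(x).ravel()
        if x.size != self.n:
            raise ValueError(f"signal length {x.size} does not match N={self.n}")
        return self.Theta @ x

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Conjugate-transpose action ``Theta^* @ y``."""
        y = np.asarray(y).ravel()
        if y.size != self.m:
            raise ValueError(f"measurement length {y.size} does not match M={self.m}")
        return self.Theta.conj().T @ y

    def lipschitz(self) -> float:
        """Squared spectral norm of Theta (gradient Lipschitz constant)."""
        return float(np.linalg.norm(self.Theta, 2) ** 2)


class FourierSensingOperator:
    """Masked unitary Fourier measurement operator for 2-D images.

    ``forward`` returns the length-M vector of sampled (centred) k-space
    coefficients in row-major order; ``adjoint`` is the exact adjoint,
    i.e. the zero-filled inverse transform.  Rows are orthonormal, so the
    gradient of the data-fidelity term has Lipschitz constant 1.
    """

    mode = "operator"

    def __init__(self, mask: SamplingMask):
        self.mask = mask
        self._flat_index = np.flatnonzero(mask.grid.ravel())

    @property
    def m(self) -> int:
        return self._flat_index.size

    @property
    def n(self) -> int:
        return self.mask.grid.size

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.mask.shape

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape != self.image_shape:
            raise ValueError(f"image shape {image.shape} does not match mask {self.image_shape}")
        return fft2c(image).ravel()[self._flat_index]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y).ravel()
        if y.size != self.m:
            raise ValueError(f"measurement length {y.size} does not match M={self.m}")
        k = np.zeros(self.n, dtype=complex)
        k[self._flat_index] = y
        return ifft2c(k.reshape(self.image_shape))

    def lipschitz(self) -> float:
        return 1.0

    def embed(self, y: np.ndarray) -> np.ndarray:
        """Scatter a measurement vector back onto the full k-space grid."""
        k = np.zeros(self.n, dtype=complex)
        k[np.asarray(self._flat_index)] = np.asarray(y).ravel()
        return k.reshape(self.image_shape)

    def extract(self, kspace: np.ndarray) -> np.ndarray:
        """Gather the sampled coefficients of a full k-space grid."""
        return np.asarray(kspace).ravel()[self._flat_index]


def materialize(operator: FourierSensingOperator) -> SensingSystem:
    """Densify an operator into an explicit M-by-N system.

    Applies the operator to every coordinate vector; guarded to grids of
    side <= ``MAX_MATERIALIZE_GRID`` to avoid a quadratic blow-up.
    """
    side = operator.image_shape[0]
    if side > MAX_MATERIALIZE_GRID:
        raise ValueError(f"materialize is limited to grids of side <= {MAX_MATERIALIZE_GRID}")
    n = operator.n
    theta = np.empty((operator.m, n), dtype=complex)
    e = np.zeros(operator.image_shape)
    for j in range(n):
        e.ravel()[j] = 1.0
        theta[:, j] = operator.forward(e)
        e.ravel()[j] = 0.0
    return SensingSystem(Pi=theta)


def forward(system, x: np.ndarray) -> np.ndarray:
    """Dispatch ``forward`` for either system flavour."""
    return system.forward(x)


def adjoint(system, y: np.ndarray) -> np.ndarray:
    """Dispatch ``adjoint`` for either system flavour."""
    return system.adjoint(y)
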