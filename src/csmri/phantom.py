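"""Synthetic brain-like phantoms and simulated undersampled acquisitions.

Phantoms are piecewise-constant ellipse scenes (sparse spatial gradients),
optionally carrying a bright disk lesion; acquisitions apply the unitary
centred Fourier transform, keep the masked coefficients and add circular
complex Gaussian noise in k-space only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from csmri._rng import substream
from csmri.sensing import SamplingMask, fft2c


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: centre in [-1, 1]^2, semi-axes, rotation, intensity."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float
    intensity: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.cx <= 1.0 and -1.0 <= self.cy <= 1.0):
            raise ValueError("ellipse centre must lie in [-1, 1]^2")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class Lesion:
    """Disk-shaped intensity bump: centre, radius as a fraction of half-width, delta."""

    cx: float
    cy: float
    radius: float
    delta: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")
        if self.delta <= 0:
            raise ValueError("lesion delta must be positive (lesions brighten)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a renderable phantom.

    Rendering is deterministic: the seed is carried only so downstream
    noise streams can be derived from one place.
    """

    grid_size: int
    ellipses: tuple[Ellipse, ...]
    lesion: Lesion | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        object.__setattr__(self, "ellipses", tuple(self.ellipses))

    def with_lesion(self, lesion: Lesion) -> "PhantomSpec":
        return replace(self, lesion=lesion)


# Head-like scene: skull ring, brain matter, ventricles, a few small
# internal structures.  Intensities are additive and clipped to [0, 1].
_DEFAULT_ELLIPSES: tuple[Ellipse, ...] = (
    Ellipse(0.0, 0.0, 0.92, 0.76, 0.0, 0.8),
    Ellipse(0.0, 0.0, 0.87, 0.71, 0.0, -0.6),
    Ellipse(0.0, 0.02, 0.80, 0.64, 0.0, 0.4),
    Ellipse(-0.22, 0.0, 0.14, 0.28, 0.25, -0.18),
    Ellipse(0.22, 0.0, 0.14, 0.28, -0.25, -0.18),
    Ellipse(0.0, 0.38, 0.16, 0.10, 0.0, 0.18),
    Ellipse(0.0, -0.38, 0.20, 0.12, 0.0, 0.12),
    Ellipse(-0.08, -0.06, 0.046, 0.046, 0.0, 0.12),
    Ellipse(0.06, 0.065, 0.046, 0.030, 0.0, 0.12),
    Ellipse(0.42, -0.35, 0.08, 0.05, 0.6, 0.10),
)

DEFAULT_LESION = Lesion(cx=0.35, cy=0.25, radius=0.12, delta=0.35)


def default_head_spec(grid_size: int = 64, lesion: bool = False, seed: int = 0) -> PhantomSpec:
    """Ten-ellipse head phantom, optionally with the default stroke-like lesion."""
    return PhantomSpec(
        grid_size=grid_size,
        ellipses=_DEFAULT_ELLIPSES,
        lesion=DEFAULT_LESION if lesion else None,
        seed=seed,
    )


def _pixel_coordinates(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    # index (0, 0) is the top-left pixel; x grows rightward, y grows upward
    step = 2.0 / grid_size
    xs = -1.0 + step * (np.arange(grid_size) + 0.5)
    ys = 1.0 - step * (np.arange(grid_size) + 0.5)
    return np.meshgrid(xs, ys)


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean support of the lesion disk (all-False when absent)."""
    if spec.lesion is None:
        return np.zeros((spec.grid_size, spec.grid_size), dtype=bool)
    x, y = _pixel_coordinates(spec.grid_size)
    les = spec.lesion
    return (x - les.cx) ** 2 + (y - les.cy) ** 2 <= les.radius**2


def render_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the piecewise-constant phantom image in [0, 1].

    Deterministic for a fixed spec; the seed is never consulted.
    """
    x, y = _pixel_coordinates(spec.grid_size)
    image = np.zeros((spec.grid_size, spec.grid_size))
    for ell in spec.ellipses:
        ct, st = np.cos(ell.theta), np.sin(ell.theta)
        xr = (x - ell.cx) * ct + (y - ell.cy) * st
        yr = -(x - ell.cx) * st + (y - ell.cy) * ct
        inside = (xr / ell.a) ** 2 + (yr / ell.b) ** 2 <= 1.0
        image[inside] += ell.intensity
    if spec.lesion is not None:
        image[lesion_mask(spec)] += spec.lesion.delta
    return np.clip(image, 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticAcquisition:
    """An observed undersampled k-space together with its ground truth.

    ``kspace_observed`` lives on the full centred grid with exact zeros at
    unsampled positions; ``noise_level`` is the per-coefficient standard
    deviation of the circular complex noise added to sampled coefficients.
    """

    true_image: np.ndarray
    mask: SamplingMask
    kspace_observed: np.ndarray
    noise_level: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.kspace_observed.shape != self.mask.shape:
            raise ValueError("kspace grid does not match mask grid")

    @property
    def measurements(self) -> np.ndarray:
        """Sampled coefficients as a length-M vector (row-major order)."""
        return self.kspace_observed.ravel()[np.flatnonzero(self.mask.grid.ravel())]


def simulate_acquisition(
    true_image: np.ndarray,
    mask: SamplingMask,
    noise_level: float = 0.0,
    seed: int = 0,
) -> SyntheticAcquisition:
    """Simulate a noisy, undersampled k-space acquisition of ``true_image``.

    Noise is circular complex Gaussian with standard deviation
    ``noise_level`` per sampled coefficient (real and imaginary parts each
    have standard deviation ``noise_level / sqrt(2)``), added in k-space
    only.  With ``noise_level=0`` the sampled coefficients equal the
    unitary transform of the image exactly.
    """
    true_image = np.asarray(true_image, dtype=float)
    if true_image.shape != mask.shape:
        raise ValueError(f"image shape {true_image.shape} does not match mask {mask.shape}")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    kfull = fft2c(true_image)
    observed = np.where(mask.grid, kfull, 0.0 + 0.0j)
    if noise_level > 0:
        rng = substream(seed, "acquisition:noise")
        m = mask.n_sampled
        noise = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) * (noise_level / np.sqrt(2.0))
        flat = observed.ravel()
        flat[np.flatnonzero(mask.grid.ravel())] += noise
        observed = flat.reshape(mask.shape)
    return SyntheticAcquisition(
        true_image=true_image,
        mask=mask,
        kspace_observed=observed,
        noise_level=float(noise_level),
        seed=int(seed),
    )


def generate_sparse_signal(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Exactly k-sparse length-n vector with entries bounded away from zero.

    Nonzero positions are uniform without replacement; values are signed
    uniforms with magnitude in [0.5, 1.5] so supports are unambiguous.
    """
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    x = np.zeros(n)
    if k == 0:
        return x
    rng = substream(seed, "sparse-signal")
    support = rng.choice(n, size=k, replace=False)
    signs = rng.choice((-1.0, 1.0), size=k)
    x[support] = signs * rng.uniform(0.5, 1.5, size=k)
    return x
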