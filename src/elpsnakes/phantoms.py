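"""Synthetic phantom images and volumes for exercising the snake pipeline.

Each phantom is a binary shape (disk, ellipse, or harmonic "blob") rendered
at pixel centers, blurred by a Gaussian of scale ``blur`` to give the edge a
finite-width intensity ramp, then corrupted with additive Gaussian noise and
clipped to [0, 1].  The seed governs only the noise draw, so geometry is
fully determined by the explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .curves import ClosedCurve
from .errors import InvalidInputError, StencilWidthError
from .potential import ScalarField

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_volume",
    "cylinder_specs",
    "cone_specs",
    "make_initial_circle",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic image.

    ``shape`` is one of ``disk``, ``ellipse``, ``blob``; ``radii`` is a
    scalar radius for disks/blobs or an (rx, ry) pair for ellipses.  Blobs
    perturb the disk radius with low-frequency harmonics
    ``r(θ) = R(1 + Σ amp·cos(k·θ + phase))`` given as ``blob_harmonics``
    tuples ``(k, amp, phase)``.
    """

    shape: str = "disk"
    size: tuple[int, int] = (128, 128)
    center: tuple[float, float] = (64.0, 64.0)
    radii: float | tuple[float, float] = 30.0
    blur: float = 2.0
    noise: float = 0.0
    seed: int = 0
    blob_harmonics: tuple = ((3, 0.12, 0.0), (5, 0.05, 1.0))

    def __post_init__(self):
        if self.shape not in ("disk", "ellipse", "blob"):
            raise InvalidInputError(f"unknown phantom shape {self.shape!r}")
        if self.noise < 0:
            raise InvalidInputError("noise level must be >= 0")
        if self.blur < 0:
            raise InvalidInputError("edge blur must be >= 0")
        rx, ry = self._radii_xy()
        if self.shape == "blob":
            amp = sum(abs(a) for _, a, _ in self.blob_harmonics)
            rx = ry = rx * (1.0 + amp)
        h, w = self.size
        cx, cy = self.center
        if cx - rx < 0 or cx + rx > w - 1 or cy - ry < 0 or cy + ry > h - 1:
            raise InvalidInputError("phantom geometry does not fit inside the image")

    def _radii_xy(self) -> tuple[float, float]:
        if isinstance(self.radii, (tuple, list)):
            return float(self.radii[0]), float(self.radii[1])
        return float(self.radii), float(self.radii)

    def with_radius(self, radius) -> "PhantomSpec":
        return PhantomSpec(
            shape=self.shape, size=self.size, center=self.center, radii=radius,
            blur=self.blur, noise=self.noise, seed=self.seed,
            blob_harmonics=self.blob_harmonics,
        )


def make_phantom(spec: PhantomSpec) -> ScalarField:
    """Render, blur, and corrupt one phantom image."""
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = spec.center
    rx, ry = spec._radii_xy()
    dx, dy = xx - cx, yy - cy
    if spec.shape == "disk":
        inside = dx * dx + dy * dy <= rx * rx
    elif spec.shape == "ellipse":
        inside = (dx / rx) ** 2 + (dy / ry) ** 2 <= 1.0
    else:  # blob
        theta = np.arctan2(dy, dx)
        r_theta = rx * (
            1.0 + sum(a * np.cos(k * theta + ph) for k, a, ph in spec.blob_harmonics)
        )
        inside = np.hypot(dx, dy) <= r_theta
    img = inside.astype(float)
    if spec.blur > 0:
        img = ndimage.gaussian_filter(img, spec.blur, mode="reflect")
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise, size=img.shape)
    return ScalarField(np.clip(img, 0.0, 1.0))


def make_volume(specs) -> list[ScalarField]:
    """Render a stack of phantom slices (one spec per slice)."""
    specs = list(specs)
    if len(specs) < 1:
        raise InvalidInputError("a volume needs at least one slice")
    sizes = {s.size for s in specs}
    if len(sizes) != 1:
        raise InvalidInputError(f"inconsistent slice shapes: {sorted(sizes)}")
    return [make_phantom(s) for s in specs]


def cylinder_specs(base: PhantomSpec, m: int) -> list[PhantomSpec]:
    """M identical slices (a cylinder when stacked)."""
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return [base] * m


def cone_specs(base: PhantomSpec, r_first: float, r_last: float, m: int) -> list[PhantomSpec]:
    """M slices whose radius interpolates linearly between the endpoints."""
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    radii = np.linspace(r_first, r_last, m)
    return [base.with_radius(float(r)) for r in radii]


def make_initial_circle(center, radius: float, n_points: int) -> ClosedCurve:
    """Counter-clockwise circle sampled at s_i = i/N, the usual rough prior."""
    if n_points < 5:
        raise StencilWidthError(f"n_points must be >= 5, got {n_points}")
    s = 2.0 * np.pi * np.arange(n_points) / n_points
    cx, cy = center
    pts = np.column_stack([cx + radius * np.cos(s), cy + radius * np.sin(s)])
    return ClosedCurve(pts)
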