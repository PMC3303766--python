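"""External potential P = -λ|∇I|² built from a grayscale image.

Coordinate convention: pixel centers sit at integer coordinates with
``x = column index`` and ``y = row index``, both 0-based.  A ``ScalarField``
is any H×W grid of reals under this convention; the snake is attracted to
strong intensity edges because P is most negative where |∇I| is largest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = [
    "ScalarField",
    "PotentialField",
    "gaussian_smooth",
    "potential_from_image",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class ScalarField:
    """H×W grid of reals with unit pixel spacing."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InvalidInputError(f"scalar field must be 2D, got shape {vals.shape}")
        if vals.shape[0] < 3 or vals.shape[1] < 3:
            raise InvalidInputError(
                f"scalar field must be at least 3x3 (central differences), got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("scalar field values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, points, strict: bool = False) -> np.ndarray:
        """Bilinear interpolation at (x, y) points.

        Out-of-domain points are clamped to the field rectangle (edge
        replication) unless ``strict`` is set, in which case they raise.
        """
        return _bilinear(self.values, points, strict=strict)


def _bilinear(values: np.ndarray, points, strict: bool = False) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0)
    pts = np.atleast_2d(pts)
    if strict:
        h, w = values.shape
        if (
            np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1)
            or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h - 1)
        ):
            raise InvalidInputError("sample point outside the field domain (strict mode)")
    # map_coordinates takes (row, col) = (y, x); mode="nearest" clamps
    coords = np.vstack([pts[:, 1], pts[:, 0]])
    return ndimage.map_coordinates(values, coords, order=1, mode="nearest")


def gaussian_smooth(field: ScalarField, sigma: float) -> ScalarField:
    """Discrete Gaussian convolution with reflective boundary handling.

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    if sigma == 0:
        return field
    return ScalarField(ndimage.gaussian_filter(field.values, sigma, mode="reflect"))


def _gradient(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences in the interior, one-sided at the edges.

    Returns (d/dx, d/dy) = (column derivative, row derivative).
    """
    gy, gx = np.gradient(values)
    return gx, gy


@dataclass(frozen=True)
class PotentialField:
    """P = -λ|∇I|² with precomputed gradient grids ∂P/∂x, ∂P/∂y."""

    p: ScalarField
    grad_px: ScalarField
    grad_py: ScalarField
    lam: float
    sigma: float

    def __post_init__(self):
        if not (self.p.shape == self.grad_px.shape == self.grad_py.shape):
            raise InvalidInputError("potential and gradient grids must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape

    def sample_p(self, points, strict: bool = False) -> np.ndarray:
        return self.p.sample(points, strict=strict)

    def sample_grad(self, points, strict: bool = False) -> np.ndarray:
        """∇P at off-grid points; shape (n, 2) with columns (∂P/∂x, ∂P/∂y)."""
        gx = self.grad_px.sample(points, strict=strict)
        gy = self.grad_py.sample(points, strict=strict)
        return np.column_stack([gx, gy])


def potential_from_image(image: ScalarField, lam: float, sigma: float = 0.0) -> PotentialField:
    """Build the edge-attraction potential from an intensity image.

    The image is Gaussian-smoothed at scale ``sigma``, its central-difference
    gradient squared and scaled: ``P = -λ(I_x² + I_y²) <= 0``.  The gradient
    grids of P are computed from the P grid itself (not analytically from I),
    so the force field is exactly consistent with the discrete potential.
    """
    if lam <= 0:
        raise InvalidInputError("lam must be > 0")
    smoothed = gaussian_smooth(image, sigma)
    ix, iy = _gradient(smoothed.values)
    p = -lam * (ix * ix + iy * iy)
    px, py = _gradient(p)
    return PotentialField(
        p=ScalarField(p),
        grad_px=ScalarField(px),
        grad_py=ScalarField(py),
        lam=lam,
        sigma=sigma,
    )


def read_image(path) -> ScalarField:
    """Read an 8/16-bit grayscale PNG or single-page TIFF as floats in [0, 1].

    Multi-page TIFFs are read with :func:`read_volume`; float inputs are
    passed through unchanged.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise InvalidInputError("color images are not supported; provide grayscale")
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a single 2D image, got shape {arr.shape}")
    return ScalarField(_normalize(arr))


def read_volume(path) -> list[ScalarField]:
    """Read a multi-page TIFF as a list of slices, floats in [0, 1]."""
    import tifffile

    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError(f"expected a 2D/3D grayscale stack, got shape {arr.shape}")
    return [ScalarField(_normalize(page)) for page in arr]


def _normalize(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_image(field: ScalarField, path) -> None:
    """Write a field to PNG (16-bit, values clipped to [0,1]) or float TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, field.values.astype(np.float32))
    else:
        import imageio.v3 as iio

        scaled = np.clip(field.values, 0.0, 1.0)
        iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))


def write_volume(fields: list[ScalarField], path) -> None:
    import tifffile

    stack = np.stack([f.values for f in fields]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
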