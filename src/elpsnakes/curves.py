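"""Closed parametric curves and snake model parameters.

A snake is a closed curve ``v(s) = (x(s), y(s))``, ``0 <= s <= 1``, sampled at
``N`` uniformly spaced parameter values ``s_i = i*h`` with ``h = 1/N``.  All
index arithmetic is modulo ``N`` (the curve is closed), and coordinates are in
image pixels with ``x`` the column and ``y`` the row.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, StencilWidthError

__all__ = ["ClosedCurve", "SnakeParams"]

#: Minimum node count: the fourth-difference stencil spans five distinct nodes.
MIN_POINTS = 5


@dataclass(frozen=True)
class ClosedCurve:
    """N uniformly parameterized points of a closed snake.

    Parameters
    ----------
    points
        Array of shape ``(N, 2)`` holding ``(x_i, y_i)`` in pixel coordinates.
        The polygon closes implicitly: point ``N-1`` connects back to point 0.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError(f"curve points must have shape (N, 2), got {pts.shape}")
        if pts.shape[0] < MIN_POINTS:
            raise StencilWidthError(
                f"a closed snake needs at least {MIN_POINTS} nodes "
                f"(pentadiagonal stencil), got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("curve coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def spacing(self) -> float:
        """Parameter step h = 1/N."""
        return 1.0 / self.n_points

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def signed_area(self) -> float:
        """Shoelace signed area; positive for the canonical orientation."""
        x, y = self.x, self.y
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def rolled(self, shift: int) -> "ClosedCurve":
        """Cyclically move the index origin; same geometric curve."""
        return ClosedCurve(np.roll(self.points, shift, axis=0))

    def translated(self, offset) -> "ClosedCurve":
        return ClosedCurve(self.points + np.asarray(offset, dtype=float))

    def scaled(self, factor: float) -> "ClosedCurve":
        return ClosedCurve(self.points * float(factor))

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path=None) -> str | None:
        """Write ``index,x,y`` rows (closure implicit).

        Coordinates are formatted with 9 significant digits so identical
        curves serialize to identical bytes.
        """
        buf = io.StringIO()
        buf.write("index,x,y\n")
        for i, (px, py) in enumerate(self.points):
            buf.write(f"{i},{px:.9g},{py:.9g}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", newline="") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_csv(cls, path_or_text) -> "ClosedCurve":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            fh = io.StringIO(path_or_text)
            return cls._read_csv(fh)
        with open(path_or_text, newline="") as fh:
            return cls._read_csv(fh)

    @classmethod
    def _read_csv(cls, fh) -> "ClosedCurve":
        reader = csv.DictReader(fh)
        rows = sorted(reader, key=lambda r: int(r["index"]))
        pts = np.array([[float(r["x"]), float(r["y"])] for r in rows])
        return cls(pts)

    def to_json(self) -> str:
        return json.dumps({"n": self.n_points, "points": self.points.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ClosedCurve":
        obj = json.loads(text)
        pts = np.asarray(obj["points"], dtype=float)
        if "n" in obj and obj["n"] != len(pts):
            raise InvalidInputError(
                f"declared point count {obj['n']} != actual {len(pts)}"
            )
        return cls(pts)


@dataclass(frozen=True)
class SnakeParams:
    """Model weights and discretization for the explicit snake evolution.

    Attributes
    ----------
    w1 : float
        Elasticity weight (first-derivative penalty), >= 0.
    w2 : float
        Rigidity (bending) weight, > 0 -- the Legendre condition for the
        energy minimum requires strictly positive rigidity.
    c0 : float
        Balloon scalar in ``k(v) = c0 * v``; 0 disables the balloon term.
    lam : float
        Potential weight λ in ``P = -λ|∇I|²``.
    sigma : float
        Gaussian pre-smoothing scale of the image, in pixels.
    delta : float
        Explicit time step δ.
    n_points : int
        Number of snake nodes N; parameter spacing is ``h = 1/N``.

    Derived quantities (``alpha = w1/h²``, ``beta = w2/h⁴``, ``gamma = c0/h``,
    ``r1 = alpha*delta``, ``r2 = beta*delta``, ``eps = delta/h⁴``) are computed
    on access and never stored, so they cannot go stale.
    """

    w1: float
    w2: float
    c0: float = 0.0
    lam: float = 1.0
    sigma: float = 0.0
    delta: float = field(default=0.0)
    n_points: int = 100

    def __post_init__(self):
        if self.w1 < 0:
            raise InvalidInputError("elasticity weight w1 must be >= 0")
        if self.w2 <= 0:
            raise InvalidInputError(
                "rigidity weight w2 must be > 0 (Legendre condition); "
                "w2 = 0 is allowed only in diagnostic operators"
            )
        if self.c0 < 0:
            raise InvalidInputError("balloon scalar c0 must be >= 0")
        if self.sigma < 0:
            raise InvalidInputError("smoothing scale sigma must be >= 0")
        if self.n_points < MIN_POINTS:
            raise StencilWidthError(f"n_points must be >= {MIN_POINTS}")
        if self.delta == 0.0:
            # auto step: half the largest von Neumann-stable δ
            object.__setattr__(self, "delta", self.auto_delta())
        if self.delta <= 0:
            raise InvalidInputError("time step delta must be > 0")

    # -------------------------------------------------------------- derived
    @property
    def h(self) -> float:
        return 1.0 / self.n_points

    @property
    def alpha(self) -> float:
        return self.w1 / self.h**2

    @property
    def beta(self) -> float:
        return self.w2 / self.h**4

    @property
    def gamma(self) -> float:
        # c0/h: the scaling under which γ(V_{i+1}-V_i) approximates c0·v′
        return self.c0 / self.h

    @property
    def r1(self) -> float:
        return self.alpha * self.delta

    @property
    def r2(self) -> float:
        return self.beta * self.delta

    @property
    def eps(self) -> float:
        return self.delta / self.h**4

    def auto_delta(self, safety_factor: float = 0.5) -> float:
        """δ = safety_factor / (2α + 8β): a guaranteed-stable explicit step."""
        return safety_factor / (2.0 * self.alpha + 8.0 * self.beta)

    def with_delta(self, delta: float) -> "SnakeParams":
        return SnakeParams(
            w1=self.w1, w2=self.w2, c0=self.c0, lam=self.lam,
            sigma=self.sigma, delta=delta, n_points=self.n_points,
        )
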