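"""Slice-by-slice 2.5D surface reconstruction.

A 3D surface is represented as a stack of planar closed snakes, one per
image slice, with the third coordinate constrained to the slice parameter:
``z(s, r) = r``.  Each slice is segmented independently by the 2D explicit
scheme; the converged curves are then stitched into a triangle mesh wrapping
periodically in the angular index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curves import ClosedCurve, SnakeParams
from .errors import DegenerateSurfaceError, DivergenceError, InvalidInputError
from .potential import ScalarField, potential_from_image
from .scheme import evolve

__all__ = ["SliceStack", "SurfaceMesh", "evolve_slices", "assemble_surface",
           "write_mesh", "read_mesh"]


@dataclass(frozen=True)
class SliceStack:
    """Ordered closed curves, one per slice, sharing the node count N."""

    curves: tuple
    r_values: np.ndarray

    def __post_init__(self):
        curves = tuple(self.curves)
        if len(curves) == 0:
            raise InvalidInputError("a slice stack needs at least one curve")
        n = curves[0].n_points
        if any(c.n_points != n for c in curves):
            raise InvalidInputError("all slice curves must share the same N")
        r = np.asarray(self.r_values, dtype=float)
        if r.shape != (len(curves),):
            raise InvalidInputError("r_values length must match the curve count")
        if len(r) > 1 and not np.all(np.diff(r) > 0):
            raise InvalidInputError("r_values must be strictly increasing")
        object.__setattr__(self, "curves", curves)
        object.__setattr__(self, "r_values", r)

    @property
    def n_slices(self) -> int:
        return len(self.curves)

    @property
    def n_points(self) -> int:
        return self.curves[0].n_points


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated band surface over an M×N grid of slice-stack vertices."""

    vertices: np.ndarray  # (M*N, 3)
    faces: np.ndarray  # (F, 3) integer, 0-based
    n_slices: int
    n_points: int


def _default_r_values(m: int) -> np.ndarray:
    if m == 1:
        return np.array([0.0])
    return np.arange(m) / (m - 1)


def evolve_slices(
    volume: Sequence[ScalarField],
    init: ClosedCurve,
    params: SnakeParams,
    tol: float = 1e-3,
    max_iter: int = 100_000,
    mode: str = "propagate",
    r_values: Sequence[float] | None = None,
    allow_unstable: bool = False,
) -> SliceStack:
    """Segment every slice of a volume with the 2D explicit scheme.

    In ``propagate`` mode (default) the converged curve of slice m seeds
    slice m+1 — cheap and robust when adjacent slices are similar.  In
    ``independent`` mode every slice starts from ``init``.
    """
    volume = list(volume)
    if len(volume) == 0:
        raise InvalidInputError("empty volume")
    shape0 = volume[0].shape
    if any(f.shape != shape0 for f in volume):
        raise InvalidInputError("all slices must share the same shape")
    if mode not in ("propagate", "independent"):
        raise InvalidInputError(f"unknown mode {mode!r}")

    curves = []
    current_init = init
    for m, field in enumerate(volume):
        pot = potential_from_image(field, params.lam, params.sigma)
        try:
            state = evolve(
                current_init, pot, params, tol=tol, max_iter=max_iter,
                allow_unstable=allow_unstable, record_energy=False,
            )
        except DivergenceError as err:
            raise DivergenceError(
                f"slice {m} diverged: {err}", iteration=err.iteration
            ) from err
        curves.append(state.curve)
        if mode == "propagate":
            current_init = state.curve
    r = _default_r_values(len(curves)) if r_values is None else np.asarray(r_values, float)
    return SliceStack(curves=tuple(curves), r_values=r)


def assemble_surface(stack: SliceStack) -> SurfaceMesh:
    """Stitch the slice curves into a triangle mesh with z = r.

    Vertex (m, i) is ``(x_{m,i}, y_{m,i}, r_m)``; each band between
    consecutive slices contributes N quads (2N triangles) wrapping modulo N.
    """
    m, n = stack.n_slices, stack.n_points
    if m < 2:
        raise DegenerateSurfaceError("surface assembly needs at least 2 slices")
    vertices = np.empty((m * n, 3))
    for mi, (curve, r) in enumerate(zip(stack.curves, stack.r_values)):
        vertices[mi * n:(mi + 1) * n, :2] = curve.points
        vertices[mi * n:(mi + 1) * n, 2] = r
    faces = []
    for mi in range(m - 1):
        base, nxt = mi * n, (mi + 1) * n
        for i in range(n):
            j = (i + 1) % n
            # quad (mi,i)-(mi,j)-(mi+1,j)-(mi+1,i) split along one diagonal
            faces.append((base + i, base + j, nxt + j))
            faces.append((base + i, nxt + j, nxt + i))
    return SurfaceMesh(
        vertices=vertices, faces=np.asarray(faces, dtype=int),
        n_slices=m, n_points=n,
    )


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a Wavefront OBJ (``v x y z`` then 1-based ``f`` lines)."""
    with open(path, "w") as fh:
        for vx, vy, vz in mesh.vertices:
            fh.write(f"v {vx:.9g} {vy:.9g} {vz:.9g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back vertices and (0-based) triangle faces from an OBJ file."""
    vertices, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return np.asarray(vertices), np.asarray(faces, dtype=int)
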