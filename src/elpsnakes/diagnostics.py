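"""Numerical-analysis apparatus for the explicit snake scheme.

Applying the discrete spatial operator to samples of an exact smooth closed
curve measures the *residue* of the scheme; its decay as the grid is refined
gives the empirical consistency order, which is O(h²) without the balloon
term and O(h) with it (the balloon uses a one-sided difference).  The module
also reduces the general scalar Euler-Lagrange equations of the snake energy
to a normalized constant-coefficient ODE system for worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .curves import SnakeParams
from .errors import InvalidInputError, NonConstantCoefficientError
from .scheme import j2

__all__ = [
    "ResidueReport",
    "ReducedODE",
    "residue",
    "estimate_order",
    "truncature_error",
    "reduce_elp",
    "evaluate_example2",
    "periodic_derivative",
]


def periodic_derivative(samples: np.ndarray, order: int) -> np.ndarray:
    """Spectral derivative of uniformly sampled values of a 1-periodic map.

    Exact for trigonometric polynomials below the Nyquist frequency; the
    Nyquist mode is zeroed for odd orders (it has no well-defined odd
    derivative on the real grid).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    k = np.fft.fftfreq(n, d=1.0 / n)
    if order % 2 == 1 and n % 2 == 0:
        k = k.copy()
        k[n // 2] = 0.0
    mult = (2.0j * np.pi * k) ** order
    out = np.fft.ifft(np.fft.fft(samples, axis=0) * mult.reshape(-1, *([1] * (samples.ndim - 1))), axis=0)
    return out.real


@dataclass(frozen=True)
class ResidueReport:
    """Discrete spatial operator evaluated on an exact closed curve.

    ``residues`` holds the full per-node residue vectors (including the
    ½∇P term when a potential gradient is supplied); ``residues_no_potential``
    drops that term.  ``defect`` is the residue minus the analytic operator
    ``w2 v⁗ - w1 v″ - c0 J2 v′ (+ ½∇P)``, i.e. the pure truncation part whose
    max-norm decays at the consistency order.  ``term_defects`` resolves the
    defect by term ('rigid', 'elastic', 'balloon'): the one-sided balloon
    difference is first-order accurate while the centered elastic and rigid
    differences are second-order, so the terms decay at different rates.
    """

    residues: np.ndarray
    residues_no_potential: np.ndarray
    defect: np.ndarray
    term_defects: dict
    h: float
    delta: float
    c0: float
    includes_time_term: bool = False

    @property
    def max_norm(self) -> float:
        return float(np.max(np.linalg.norm(self.residues, axis=1)))

    @property
    def defect_max_norm(self) -> float:
        return float(np.max(np.linalg.norm(self.defect, axis=1)))

    def term_max_norms(self) -> dict:
        return {
            name: float(np.max(np.linalg.norm(d, axis=1)))
            for name, d in self.term_defects.items()
        }


def _sample_closed(curve_fn: Callable, n: int) -> np.ndarray:
    v0 = np.asarray(curve_fn(0.0), dtype=float)
    v1 = np.asarray(curve_fn(1.0), dtype=float)
    if np.max(np.abs(v0 - v1)) > 1e-8:
        raise InvalidInputError(
            f"curve function is not 1-periodic: |v(0) - v(1)| = {np.max(np.abs(v0 - v1)):.3g}"
        )
    s = np.arange(n) / n
    pts = np.asarray([curve_fn(si) for si in s], dtype=float)
    if pts.shape != (n, 2):
        raise InvalidInputError(f"curve function must return 2-vectors, got {pts.shape}")
    return pts


def residue(
    exact_curve_fn: Callable[[float], Sequence[float]],
    params: SnakeParams,
    potential_grad_fn: Callable | None = None,
    n: int | None = None,
) -> ResidueReport:
    """Per-node residue of the explicit scheme on a time-independent curve.

    For a curve that does not depend on time, the forward time difference
    vanishes and the residue reduces to its spatial part

        R_i = β Δ⁴V_i - α Δ²V_i - γ J2 (V_{i+1} - V_i) + ½∇P(V_i),

    with the undivided periodic differences Δ² and Δ⁴.  The analytic
    counterpart needed for the defect is computed by spectral (FFT)
    differentiation of the samples.
    """
    n = params.n_points if n is None else n
    pts = _sample_closed(exact_curve_fn, n)
    h = 1.0 / n
    alpha = params.w1 / h**2
    beta = params.w2 / h**4
    gamma = params.c0 / h

    d2 = np.roll(pts, -1, axis=0) - 2.0 * pts + np.roll(pts, 1, axis=0)
    d4 = (
        np.roll(pts, -2, axis=0)
        - 4.0 * np.roll(pts, -1, axis=0)
        + 6.0 * pts
        - 4.0 * np.roll(pts, 1, axis=0)
        + np.roll(pts, 2, axis=0)
    )
    fwd = np.roll(pts, -1, axis=0) - pts

    spatial = beta * d4 - alpha * d2 - gamma * j2(fwd)
    residues_no_p = spatial.copy()
    if potential_grad_fn is not None:
        grad = np.asarray([potential_grad_fn(p[0], p[1]) for p in pts], dtype=float)
        residues = spatial + 0.5 * grad
    else:
        grad = np.zeros_like(pts)
        residues = spatial

    # analytic operator via spectral derivatives (exact for trig polynomials)
    v1 = periodic_derivative(pts, 1)
    v2 = periodic_derivative(pts, 2)
    v4 = periodic_derivative(pts, 4)
    analytic = params.w2 * v4 - params.w1 * v2 - params.c0 * j2(v1) + 0.5 * grad
    defect = residues - analytic
    term_defects = {
        "rigid": beta * d4 - params.w2 * v4,
        "elastic": -(alpha * d2 - params.w1 * v2),
    }
    if params.c0 != 0.0:
        term_defects["balloon"] = -(gamma * j2(fwd) - params.c0 * j2(v1))

    return ResidueReport(
        residues=residues,
        residues_no_potential=residues_no_p,
        defect=defect,
        term_defects=term_defects,
        h=h,
        delta=params.delta,
        c0=params.c0,
        includes_time_term=False,
    )


def estimate_order(
    exact_curve_fn: Callable,
    params: SnakeParams,
    n_list: Sequence[int],
    potential_grad_fn: Callable | None = None,
) -> dict:
    """Empirical spatial consistency order from a grid refinement study.

    Fits, per operator term, the least-squares slope of log(defect max-norm)
    against log(h) over the supplied grid sizes; the time term is excluded by
    construction (time-independent test curves).  The overall order is the
    smallest per-term slope, since the slowest-decaying term sets the
    asymptotic rate: first order when the one-sided balloon difference is
    active (c0 > 0), second order otherwise.  The aggregate-defect slope and
    norms are also returned (at coarse grids the second-order terms can still
    dominate the aggregate even when a first-order term is present).

    If every norm is at numerical zero the order is undefined and reported
    as ``None``.
    """
    n_list = list(n_list)
    if len(n_list) < 2:
        raise InvalidInputError("order estimation needs at least two grid sizes")
    if any(n < 8 for n in n_list):
        raise InvalidInputError("grid sizes must be >= 8")
    total_norms, hs = [], []
    term_norms: dict[str, list] = {}
    for n in n_list:
        rep = residue(exact_curve_fn, params, potential_grad_fn, n=n)
        total_norms.append(rep.defect_max_norm)
        hs.append(rep.h)
        for name, norm in rep.term_max_norms().items():
            term_norms.setdefault(name, []).append(norm)
    total_norms = np.asarray(total_norms)
    hs = np.asarray(hs)

    def _fit(norms):
        norms = np.asarray(norms)
        if np.all(norms < 1e-12):
            return None, []
        slope = float(np.polyfit(np.log(hs), np.log(norms), 1)[0])
        ratios = [float(np.log2(norms[i] / norms[i + 1])) for i in range(len(norms) - 1)]
        return slope, ratios

    total_slope, total_ratios = _fit(total_norms)
    terms = {}
    for name, norms in term_norms.items():
        slope, ratios = _fit(norms)
        terms[name] = {"slope": slope, "ratios": ratios, "norms": list(norms)}
    active = [t["slope"] for t in terms.values() if t["slope"] is not None]
    overall = min(active) if active else None
    out = {
        "slope": overall,
        "terms": terms,
        "slope_total": total_slope,
        "ratios_total": total_ratios,
        "norms_total": total_norms.tolist(),
        "h": hs.tolist(),
        "n": n_list,
    }
    if overall is None:
        out["note"] = "residues identically zero"
    return out


def truncature_error(report: ResidueReport, delta: float) -> float:
    """δ × (residue max-norm): the per-step local error of the scheme."""
    return float(delta) * report.max_norm


# --------------------------------------------------------------------------
# Reduction of the general scalar Euler-Lagrange equations
# --------------------------------------------------------------------------

_FD_STEP = 1e-2


def _d1(f: Callable[[float], float], x: float, h: float = _FD_STEP) -> float:
    """Fourth-order central first derivative (five-point stencil)."""
    return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)


def _d2(f: Callable[[float], float], x: float, h: float = _FD_STEP) -> float:
    """Fourth-order central second derivative."""
    return (
        -f(x + 2 * h) + 16 * f(x + h) - 30 * f(x) + 16 * f(x - h) - f(x - 2 * h)
    ) / (12 * h * h)


@dataclass(frozen=True)
class ReducedODE:
    """Normalized constant-coefficient scalar system

        x⁗ + p3·x‴ + p2·x″ + p1·x′ + q·y′ + cx = 0
        y⁗ + p3·y‴ + p2·y″ + p1·y′ - q·x′ + cy = 0

    (fourth-derivative coefficient normalized to 1; with constant weights
    p3 = p1 = 0).  The cross-coupling coefficient q carries opposite signs
    in the two equations, mirroring the rotation structure of the balloon
    term.
    """

    p3: float
    p2: float
    p1: float
    q: float
    const_x: float
    const_y: float

    def x_coefficients(self) -> dict:
        return {"x4": 1.0, "x3": self.p3, "x2": self.p2, "x1": self.p1,
                "yprime": self.q, "const": self.const_x}

    def y_coefficients(self) -> dict:
        return {"y4": 1.0, "y3": self.p3, "y2": self.p2, "y1": self.p1,
                "xprime": -self.q, "const": self.const_y}


_DEFAULT_SAMPLE_POINTS = ((0.7, 0.6), (1.1, 1.3), (1.9, 2.4))


def reduce_elp(
    w1: float,
    w2: float,
    k_fn: Callable | None,
    I_fn: Callable | None,
    lam: float,
    sample_points: Sequence[tuple[float, float]] = _DEFAULT_SAMPLE_POINTS,
    tol: float = 1e-8,
) -> ReducedODE:
    """Reduce the scalar Euler-Lagrange equations to normalized form.

    With constant weights the x-equation reads

        2 w2 x⁗ - 2 w1 x″ - tr(∇k)·y′ + ∂P/∂x = 0,   P = -λ|∇I|²,

    and dividing by 2 w2 normalizes the fourth-derivative coefficient.
    ``tr(∇k) = ∂k1/∂x + ∂k2/∂y`` and ``∂P/∂x = -2λ(I_x I_xx + I_y I_xy)``
    are evaluated by high-order central differences at ``sample_points``;
    the reduction to a constant-coefficient system requires the computed
    values to agree across those points to relative spread ``tol``.

    ``k_fn`` maps (x, y) to the balloon field (k1, k2); ``I_fn`` is the
    image intensity surface.  Pass ``None`` to drop either term.
    """
    if w2 <= 0:
        raise InvalidInputError("reduction requires w2 > 0 for normalization")
    if len(sample_points) < 3:
        raise InvalidInputError("need at least 3 sample points to verify constancy")

    traces, px_vals, py_vals = [], [], []
    for (x0, y0) in sample_points:
        if k_fn is not None:
            tr = _d1(lambda t: k_fn(t, y0)[0], x0) + _d1(lambda t: k_fn(x0, t)[1], y0)
        else:
            tr = 0.0
        traces.append(tr)
        if I_fn is not None:
            ix = _d1(lambda t: I_fn(t, y0), x0)
            iy = _d1(lambda t: I_fn(x0, t), y0)
            ixx = _d2(lambda t: I_fn(t, y0), x0)
            iyy = _d2(lambda t: I_fn(x0, t), y0)
            ixy = _d1(lambda t: _d1(lambda u: I_fn(u, t), x0), y0)
            px_vals.append(-2.0 * lam * (ix * ixx + iy * ixy))
            py_vals.append(-2.0 * lam * (iy * iyy + ix * ixy))
        else:
            px_vals.append(0.0)
            py_vals.append(0.0)

    def _constant(vals, name):
        vals = np.asarray(vals)
        spread = np.max(vals) - np.min(vals)
        scale = max(np.max(np.abs(vals)), 1.0)
        if spread / scale > tol:
            raise NonConstantCoefficientError(
                f"{name} varies across sample points (relative spread "
                f"{spread / scale:.3g} > {tol:.1g}); the reduced system is "
                "not constant-coefficient"
            )
        return float(np.mean(vals))

    tr = _constant(traces, "trace of the balloon-field Jacobian")
    px = _constant(px_vals, "dP/dx")
    py = _constant(py_vals, "dP/dy")

    return ReducedODE(
        p3=0.0,
        p2=-w1 / w2,
        p1=0.0,
        q=-tr / (2.0 * w2),
        const_x=px / (2.0 * w2),
        const_y=py / (2.0 * w2),
    )


def evaluate_example2(s):
    """Closed-form curve used as a worked anchor for the scalar reduction:

        x(s) = sin 2s + cos 2s + sin(s) cosh(2s) + 0.1 s
        y(s) = -4 sin 2s + 4 cos 2s + 3 cos(s) cosh(2s) - 4 sinh(2s) sin(s)
               - 0.1 s - 6

    Returns ``((x, y), (x', y'))`` with exact derivatives; accepts scalar or
    array ``s``.
    """
    s = np.asarray(s, dtype=float)
    x = np.sin(2 * s) + np.cos(2 * s) + np.sin(s) * np.cosh(2 * s) + 0.1 * s
    y = (
        -4 * np.sin(2 * s)
        + 4 * np.cos(2 * s)
        + 3 * np.cos(s) * np.cosh(2 * s)
        - 4 * np.sinh(2 * s) * np.sin(s)
        - 0.1 * s
        - 6.0
    )
    dx = (
        2 * np.cos(2 * s)
        - 2 * np.sin(2 * s)
        + np.cos(s) * np.cosh(2 * s)
        + 2 * np.sin(s) * np.sinh(2 * s)
        + 0.1
    )
    dy = (
        -8 * np.cos(2 * s)
        - 8 * np.sin(2 * s)
        - 3 * np.sin(s) * np.cosh(2 * s)
        + 6 * np.cos(s) * np.sinh(2 * s)
        - 8 * np.cosh(2 * s) * np.sin(s)
        - 4 * np.sinh(2 * s) * np.cos(s)
        - 0.1
    )
    return (x, y), (dx, dy)
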