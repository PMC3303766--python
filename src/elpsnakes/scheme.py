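"""Explicit finite-difference evolution of a closed snake.

Discretizing the gradient-descent flow of the snake energy on a periodic
grid of N nodes (spacing ``h = 1/N``, time step ``δ``) gives the update

    V^{k+1} = (I_N - δK) V^k - γδ L (J2 V^k) + δ g^k

where K is the circulant pentadiagonal *stiffness matrix* with first row
``(a1, a2, a3, 0, ..., 0, a3, a2)``, ``a1 = 2α+6β``, ``a2 = -α-4β``,
``a3 = β`` (``α = w1/h²``, ``β = w2/h⁴``), L is the circulant forward
difference with first row ``(1, -1, 0, ..., 0)``, ``J2`` the rotation
``(x, y) -> (y, -x)``, ``γ = c0/h`` the balloon coefficient, and
``g^k = -½ ∇P`` sampled at the current nodes.

Von Neumann analysis of the scheme (no balloon term) gives the
amplification factor ``μ(η) = 1 - 4 r1 sin²η - 16 r2 sin⁴η`` with
``r1 = αδ``, ``r2 = βδ``; the error modes stay bounded iff ``|μ| <= 1``
for every frequency, i.e. iff ``2 r1 + 8 r2 <= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ClosedCurve, SnakeParams
from .energies import total_energy
from .errors import (
    DivergenceError,
    InvalidInputError,
    StabilityError,
    StencilWidthError,
)
from .potential import PotentialField

__all__ = [
    "StiffnessOperator",
    "StabilityReport",
    "EvolutionState",
    "build_stiffness",
    "explicit_step",
    "amplification_factor",
    "check_stability",
    "stability_from_rates",
    "criterion_supremum",
    "evolve",
    "apply_forward_difference",
    "j2",
]


def j2(points: np.ndarray) -> np.ndarray:
    """Apply the rotation J2 = [[0, 1], [-1, 0]]: (x, y) -> (y, -x)."""
    return np.column_stack([points[:, 1], -points[:, 0]])


def apply_forward_difference(points: np.ndarray) -> np.ndarray:
    """(LV)_i = V_i - V_{i+1}, the circulant with first row (1, -1, 0, ...)."""
    return points - np.roll(points, -1, axis=0)


@dataclass(frozen=True)
class StiffnessOperator:
    """Circulant pentadiagonal operator K applied by its periodic stencil."""

    n: int
    a1: float
    a2: float
    a3: float

    @property
    def first_row(self) -> np.ndarray:
        row = np.zeros(self.n)
        row[0] = self.a1
        row[1] = self.a2
        row[2] = self.a3
        row[-2] = self.a3
        row[-1] = self.a2
        return row

    def apply(self, points: np.ndarray) -> np.ndarray:
        """(KV)_i = a1 V_i + a2 (V_{i+1} + V_{i-1}) + a3 (V_{i+2} + V_{i-2})."""
        return (
            self.a1 * points
            + self.a2 * (np.roll(points, -1, axis=0) + np.roll(points, 1, axis=0))
            + self.a3 * (np.roll(points, -2, axis=0) + np.roll(points, 2, axis=0))
        )

    def dense(self) -> np.ndarray:
        from scipy.linalg import circulant

        # scipy's circulant builds from the first column; K is symmetric so
        # first column == first row
        return circulant(self.first_row)

    def symbol(self, m) -> np.ndarray:
        """Eigenvalue of K at integer frequency m (DFT diagonalization):

        4α sin²(πm/N) + 16β sin⁴(πm/N), written via the stencil weights.
        """
        theta = 2.0 * np.pi * np.asarray(m, dtype=float) / self.n
        return self.a1 + 2.0 * self.a2 * np.cos(theta) + 2.0 * self.a3 * np.cos(2.0 * theta)


def build_stiffness(n: int, alpha: float, beta: float) -> StiffnessOperator:
    """Stiffness operator with weights a1 = 2α+6β, a2 = -α-4β, a3 = β."""
    if n < 5:
        raise StencilWidthError(f"stiffness stencil needs n >= 5, got {n}")
    if alpha < 0 or beta < 0:
        raise InvalidInputError("alpha and beta must be >= 0")
    return StiffnessOperator(
        n=n,
        a1=2.0 * alpha + 6.0 * beta,
        a2=-alpha - 4.0 * beta,
        a3=beta,
    )


def explicit_step(
    curve: ClosedCurve,
    op: StiffnessOperator,
    params: SnakeParams,
    potential: PotentialField | None = None,
) -> ClosedCurve:
    """One explicit update V^{k+1} = (I - δK)V^k - γδ L(J2 V^k) + δ g^k.

    ``g^k = -½∇P`` at the current nodes (zero without a potential).  Note
    ``-γδ (L(J2 V))_i = +γδ J2(V_{i+1} - V_i)``: the balloon term pushes
    along the (one-sided) tangent normal.
    """
    if op.n != curve.n_points:
        raise InvalidInputError(
            f"operator size {op.n} != curve size {curve.n_points}"
        )
    if params.delta <= 0:
        raise InvalidInputError("time step delta must be > 0")
    v = curve.points
    new = v - params.delta * op.apply(v)
    if params.gamma != 0.0:
        new = new - params.gamma * params.delta * apply_forward_difference(j2(v))
    if potential is not None:
        g = -0.5 * potential.sample_grad(v)
        new = new + params.delta * g
    if not np.all(np.isfinite(new)):
        raise DivergenceError("explicit step produced non-finite coordinates")
    return ClosedCurve(new)


def amplification_factor(r1, r2, eta):
    """μ(η) = 1 - 4 r1 sin²η - 16 r2 sin⁴η."""
    s2 = np.sin(eta) ** 2
    return 1.0 - 4.0 * r1 * s2 - 16.0 * r2 * s2 * s2


@dataclass(frozen=True)
class StabilityReport:
    """Von Neumann stability assessment of an explicit parameter set."""

    r1: float
    r2: float
    criterion_value: float  # 2 r1 + 8 r2
    satisfied: bool
    delta_max: float  # largest stable time step, 1/(2α + 8β)
    bound_iterations: int  # largest k+1 with 6 ε w2 (k+1) <= 1
    mu_min: float  # min over the frequency grid of μ(η)

    def to_dict(self) -> dict:
        return {
            "r1": self.r1,
            "r2": self.r2,
            "criterion_value": self.criterion_value,
            "satisfied": self.satisfied,
            "delta_max": self.delta_max,
            "bound_iterations": self.bound_iterations,
            "mu_min": self.mu_min,
        }


def check_stability(params: SnakeParams, n_eta: int = 2049) -> StabilityReport:
    """Evaluate the von Neumann criterion 2 r1 + 8 r2 <= 1.

    The equivalent printed form 2ε(4 w2 + w1 h²) <= 1 (ε = δ/h⁴) is the same
    inequality after substituting α = w1/h², β = w2/h⁴.  ``mu_min`` is the
    worst amplification factor over a uniform frequency grid on [0, π]; the
    criterion holds iff ``mu_min >= -1``.
    """
    r1, r2 = params.r1, params.r2
    criterion = 2.0 * r1 + 8.0 * r2
    eta = np.linspace(0.0, np.pi, n_eta)
    mu_min = float(np.min(amplification_factor(r1, r2, eta)))
    denom = 2.0 * params.alpha + 8.0 * params.beta
    delta_max = np.inf if denom == 0 else 1.0 / denom
    six_eps_w2 = 6.0 * params.eps * params.w2
    bound_iter = int(np.floor(1.0 / six_eps_w2)) if six_eps_w2 > 0 else np.iinfo(np.int64).max
    return StabilityReport(
        r1=r1,
        r2=r2,
        criterion_value=criterion,
        satisfied=criterion <= 1.0,
        delta_max=delta_max,
        bound_iterations=bound_iter,
        mu_min=mu_min,
    )


def stability_from_rates(r1: float, r2: float, n_eta: int = 2049) -> dict:
    """Criterion arithmetic directly from the rates r1 = αδ, r2 = βδ."""
    eta = np.linspace(0.0, np.pi, n_eta)
    mu = amplification_factor(r1, r2, eta)
    criterion = 2.0 * r1 + 8.0 * r2
    return {
        "criterion_value": criterion,
        "satisfied": criterion <= 1.0,
        "mu_min": float(np.min(mu)),
        "mu_max": float(np.max(mu)),
    }


def criterion_supremum(
    n_r2: int = 101, r2_max: float = 0.2, n_eta: int = 4097, tol: float = 1e-10
) -> float:
    """Supremum of 2 r1 + 8 r2 over nonnegative rates keeping |μ(η)| <= 1.

    For each r2 on a grid the largest admissible r1 is found by bisection on
    ``min_η μ(r1, r2, η) >= -1`` (μ <= 1 holds automatically for nonnegative
    rates); the supremum of the objective over the grid is returned.
    """
    eta = np.linspace(0.0, np.pi, n_eta)
    s2 = np.sin(eta) ** 2
    s4 = s2 * s2

    def admissible(r1, r2):
        return np.min(1.0 - 4.0 * r1 * s2 - 16.0 * r2 * s4) >= -1.0

    best = 0.0
    for r2 in np.linspace(0.0, r2_max, n_r2):
        if not admissible(0.0, r2):
            continue
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if admissible(mid, r2):
                lo = mid
            else:
                hi = mid
        best = max(best, 2.0 * lo + 8.0 * r2)
    return best


@dataclass
class EvolutionState:
    """Trajectory record of one snake evolution."""

    k: int
    curve: ClosedCurve
    energy_history: list = field(default_factory=list)
    displacement_rate_history: list = field(default_factory=list)
    converged: bool = False
    stability: StabilityReport | None = None


def evolve(
    curve0: ClosedCurve,
    potential: PotentialField | None,
    params: SnakeParams,
    tol: float = 1e-3,
    max_iter: int = 100_000,
    allow_unstable: bool = False,
    record_energy: bool = True,
) -> EvolutionState:
    """Iterate the explicit scheme until the snake is stationary.

    Stationarity is the discrete analogue of the time derivative vanishing:
    iteration stops once ``max_i |V_i^{k+1} - V_i^k| / δ < tol``.  With
    ``c0 = 0`` the update is an explicit gradient descent on the energy, so
    under the stability condition the internal energy is non-increasing.

    Raises
    ------
    StabilityError
        if the von Neumann criterion fails and ``allow_unstable`` is not set.
    DivergenceError
        if an iterate becomes non-finite or runs away (displacement beyond
        10x the domain diagonal).
    """
    report = check_stability(params)
    if not report.satisfied and not allow_unstable:
        raise StabilityError(
            f"2*r1 + 8*r2 = {report.criterion_value:.4g} > 1; "
            f"largest stable delta is {report.delta_max:.4g} "
            "(pass allow_unstable=True to override)"
        )
    op = build_stiffness(curve0.n_points, params.alpha, params.beta)
    if potential is not None:
        hdom, wdom = potential.shape
        diag = float(np.hypot(hdom, wdom))
    else:
        span = curve0.points.max(axis=0) - curve0.points.min(axis=0)
        diag = max(float(np.hypot(*span)), 1.0)
    start = curve0.points.mean(axis=0)

    state = EvolutionState(k=0, curve=curve0, stability=report)
    curve = curve0
    for k in range(max_iter):
        try:
            new = explicit_step(curve, op, params, potential)
        except DivergenceError as err:
            raise DivergenceError(
                f"evolution diverged at iteration {k}: {err}", iteration=k
            ) from err
        disp = float(np.max(np.abs(new.points - curve.points)))
        rate = disp / params.delta
        state.displacement_rate_history.append(rate)
        if record_energy:
            state.energy_history.append(total_energy(new, params, potential))
        if float(np.max(np.abs(new.points - start))) > 10.0 * diag:
            raise DivergenceError(
                f"evolution diverged at iteration {k}: iterate left the domain",
                iteration=k,
            )
        curve = new
        state.k = k + 1
        state.curve = curve
        if rate < tol:
            state.converged = True
            break
    return state
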