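"""Five-parameter logistic (5PL) fitting and second-derivative-maximum Ct.

Model::

    F(x) = F_b + (F_max - F_b) / (1 + exp(-(x - x0)/k))**s

with baseline ``F_b``, plateau ``F_max``, midpoint ``x0`` (cycles), slope
scale ``k`` (cycles, > 0) and asymmetry ``s`` (dimensionless, > 0).

The fit is a hand-rolled Gauss-Newton iteration on the analytic Jacobian;
Levenberg-style diagonal damping kicks in only when an undamped step fails
(ill-conditioned normal equations or an SSR increase). Ct is the abscissa of
the maximum of the analytic second derivative over the measured cycle domain
(the SDM method): a dense grid locates the maximum, Newton steps on the third
derivative refine it, and boundary maxima are rejected rather than
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simgen import FluorescenceCurve

__all__ = [
    "FivePLParams",
    "FitResult",
    "CtResult",
    "model_eval",
    "d1",
    "d2",
    "jacobian",
    "init_guess",
    "gauss_newton_fit",
    "ct_from_fit",
    "call_ct",
    "NotAmplifyingError",
    "FitFailureError",
    "CtUndefinedError",
    "UncallableError",
]

_MIN_SCALE = 1e-6  # projection floor for k and s


class NotAmplifyingError(ValueError):
    """Curve has no usable dynamic range (flat trace)."""


class FitFailureError(RuntimeError):
    """Normal equations singular with damping exhausted."""


class CtUndefinedError(RuntimeError):
    """Second-derivative maximum on the domain boundary or fit unusable."""


class UncallableError(RuntimeError):
    """Positive curve for which no Ct could be produced."""


@dataclass(frozen=True)
class FivePLParams:
    """Parameters of the asymmetric five-parameter logistic."""

    f_b: float
    f_max: float
    x0: float
    k: float
    s: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError("slope scale k must be > 0")
        if not (self.s > 0):
            raise ValueError("asymmetry s must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_b, self.f_max, self.x0, self.k, self.s])

    @classmethod
    def from_array(cls, beta: np.ndarray) -> "FivePLParams":
        return cls(*(float(v) for v in beta))


@dataclass(frozen=True)
class FitResult:
    params: FivePLParams
    residual_norm: float  # sum of squared residuals
    iterations: int
    converged: bool
    damping_used: bool = False


@dataclass(frozen=True)
class CtResult:
    ct: float
    fit: FitResult
    method: str = "SDM"


def _core(p: FivePLParams, x: np.ndarray):
    """Shared pieces: u = exp(-(x-x0)/k) and g = (1+u)^(-s)."""
    x = np.asarray(x, dtype=float)
    # clip the exponent so extreme cycles saturate instead of overflowing
    z = np.clip(-(x - p.x0) / p.k, -700.0, 700.0)
    u = np.exp(z)
    g = (1.0 + u) ** (-p.s)
    return u, g


def model_eval(p: FivePLParams, x) -> np.ndarray:
    """5PL value at cycle positions ``x``."""
    _, g = _core(p, np.asarray(x, dtype=float))
    return p.f_b + (p.f_max - p.f_b) * g


def d1(p: FivePLParams, x) -> np.ndarray:
    """Analytic first derivative dF/dx."""
    u, _ = _core(p, np.asarray(x, dtype=float))
    amp = p.f_max - p.f_b
    return amp * p.s * u / p.k * (1.0 + u) ** (-p.s - 1.0)


def d2(p: FivePLParams, x) -> np.ndarray:
    """Analytic second derivative d2F/dx2."""
    u, _ = _core(p, np.asarray(x, dtype=float))
    amp = p.f_max - p.f_b
    return amp * p.s * u / p.k**2 * (1.0 + u) ** (-p.s - 2.0) * (p.s * u - 1.0)


def jacobian(p: FivePLParams, x: np.ndarray) -> np.ndarray:
    """Jacobian of the model w.r.t. (f_b, f_max, x0, k, s), shape (n, 5)."""
    x = np.asarray(x, dtype=float)
    u, g = _core(p, x)
    amp = p.f_max - p.f_b
    gp = (1.0 + u) ** (-p.s - 1.0)
    J = np.empty((len(x), 5))
    J[:, 0] = 1.0 - g
    J[:, 1] = g
    J[:, 2] = -amp * p.s * u / p.k * gp
    J[:, 3] = -amp * p.s * u * (x - p.x0) / p.k**2 * gp
    J[:, 4] = -amp * g * np.log1p(u)
    return J


def init_guess(curve: FluorescenceCurve, noise_factor: float = 10.0) -> FivePLParams:
    """Heuristic starting point for the Gauss-Newton fit.

    Baseline from the first five cycles, plateau from the trace maximum,
    midpoint from the half-rise crossing (linearly interpolated), unit slope
    scale and symmetry. Raises :class:`NotAmplifyingError` when the dynamic
    range does not exceed ``noise_factor`` times the early-cycle noise level
    (affine-invariant: no dependence on absolute fluorescence units).
    """
    y = curve.rfu
    x = curve.cycles.astype(float)
    f_b = float(np.mean(y[:5]))
    f_max = float(np.max(y))
    span = f_max - f_b
    noise = float(np.std(y[:5], ddof=0))
    if span <= noise_factor * noise or span <= 0:
        raise NotAmplifyingError(
            f"dynamic range {span:.4g} within noise; curve is not amplifying"
        )
    half = (f_b + f_max) / 2.0
    above = np.nonzero(y >= half)[0]
    idx = int(above[0]) if len(above) else len(y) - 1
    if idx == 0:
        x0 = x[0]
    else:
        y0, y1 = y[idx - 1], y[idx]
        frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.5
        x0 = float(x[idx - 1] + frac * (x[idx] - x[idx - 1]))
    return FivePLParams(f_b=f_b, f_max=f_max, x0=x0, k=1.0, s=1.0)


def _project(beta: np.ndarray) -> np.ndarray:
    beta = beta.copy()
    beta[3] = max(beta[3], _MIN_SCALE)
    beta[4] = max(beta[4], _MIN_SCALE)
    return beta


def gauss_newton_fit(
    curve: FluorescenceCurve,
    init: FivePLParams,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Fit the 5PL to a curve by damped Gauss-Newton iteration.

    Each iteration solves the normal equations ``(J'J) step = J'r`` on the
    analytic Jacobian. An undamped step is attempted first; if the system is
    ill-conditioned or the step increases the SSR, Levenberg diagonal damping
    is escalated until the step is accepted. Convergence is declared when the
    accepted step's infinity norm or the relative SSR change falls below
    ``tol``. Accepted iterations never increase the SSR.
    """
    x = curve.cycles.astype(float)
    y = curve.rfu
    beta = _project(init.as_array())
    damping_used = False

    def ssr_of(b: np.ndarray) -> float:
        return float(np.sum((y - model_eval(FivePLParams.from_array(b), x)) ** 2))

    ssr = ssr_of(beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = FivePLParams.from_array(beta)
        r = y - model_eval(p, x)
        J = jacobian(p, x)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = None
        lam = 0.0
        scale = float(np.mean(np.diag(JtJ))) or 1.0
        for _ in range(25):
            A = JtJ + lam * np.diag(np.diag(JtJ) + 1e-12 * scale)
            try:
                step = np.linalg.solve(A, Jtr)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and np.all(np.isfinite(step)):
                cand = _project(beta + step)
                cand_ssr = ssr_of(cand)
                if np.isfinite(cand_ssr) and cand_ssr <= ssr * (1 + 1e-15):
                    accepted = (cand, cand_ssr, step)
                    break
            # escalate damping and retry
            lam = 1e-4 if lam == 0.0 else lam * 10.0
            damping_used = True
        if accepted is None:
            raise FitFailureError(
                f"singular normal equations with damping exhausted at iteration {iterations}"
            )
        new_beta, new_ssr, step = accepted
        step_norm = float(np.max(np.abs(step)))
        rel_change = abs(ssr - new_ssr) / max(ssr, 1e-300)
        beta, ssr = new_beta, new_ssr
        if step_norm < tol or rel_change < tol:
            converged = True
            break

    return FitResult(
        params=FivePLParams.from_array(beta),
        residual_norm=ssr,
        iterations=iterations,
        converged=converged,
        damping_used=damping_used,
    )


def ct_from_fit(
    fit: FitResult,
    domain: tuple[float, float] = (1.0, 40.0),
    grid_step: float = 0.01,
) -> CtResult:
    """Ct as the abscissa of the second-derivative maximum over ``domain``.

    Dense-grid argmax followed by Newton refinement on the third derivative
    (finite difference of the analytic second derivative). Raises
    :class:`CtUndefinedError` for non-converged fits, non-positive amplitude,
    or a maximum on the domain boundary.
    """
    if not fit.converged:
        raise CtUndefinedError("fit did not converge; Ct undefined")
    p = fit.params
    if not (p.f_max > p.f_b):
        raise CtUndefinedError("plateau not above baseline; Ct undefined")
    lo, hi = float(domain[0]), float(domain[1])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = d2(p, grid)
    i = int(np.argmax(vals))
    if i == 0 or i == len(grid) - 1:
        raise CtUndefinedError(
            "second-derivative maximum lies on the domain boundary"
        )
    ct = float(grid[i])
    # Newton refinement: find the zero of d3 near the grid argmax
    h = 1e-5
    for _ in range(30):
        d3 = (d2(p, ct + h) - d2(p, ct - h)) / (2 * h)
        d4 = (d2(p, ct + h) - 2 * d2(p, ct) + d2(p, ct - h)) / h**2
        if d4 == 0:
            break
        new_ct = ct - float(d3 / d4)
        if not (lo < new_ct < hi) or abs(new_ct - ct) > 2 * grid_step:
            break  # keep the grid estimate if Newton wanders
        if abs(new_ct - ct) < 1e-10:
            ct = new_ct
            break
        ct = new_ct
    if not (lo < ct < hi):
        raise CtUndefinedError("refined Ct left the measured domain")
    return CtResult(ct=ct, fit=fit)


def call_ct(curve: FluorescenceCurve) -> CtResult:
    """Full Ct pipeline for a positive curve: init -> fit -> SDM.

    Raises :class:`UncallableError` (with the underlying cause chained) when
    any stage fails; the caller maps this to a positive-but-uncallable status.
    """
    try:
        init = init_guess(curve)
        fit = gauss_newton_fit(curve, init)
        domain = (float(curve.cycles[0]), float(curve.cycles[-1]))
        return ct_from_fit(fit, domain=domain)
    except (NotAmplifyingError, FitFailureError, CtUndefinedError) as exc:
        raise UncallableError(f"positive curve but Ct uncallable: {exc}") from exc
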