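"""Nonlinear phenotypic scale: power-transform estimation and linearization.

Many genotype-phenotype maps relate additively combined mutational effects
to the measured phenotype through a monotone nonlinear function (the map's
*scale*). Analyzing such a map with a linear epistasis model partitions the
curvature into spurious high-order interaction terms. This module models the
scale with a power transform

    tau(p; lambda, A, B) = ((p + A)^lambda − 1) / (lambda · GM^(lambda−1)) + B,

where A and B are translation constants, lambda is the shape parameter and
GM is the geometric mean of (p + A) over the fitting data (a deterministic
function of A, not a free parameter). The transform is fit by nonlinear
least squares of the observed phenotypes on the additive predictions, and
its exact inverse (``linearize``) places observed phenotypes back on the
additive scale, where the Walsh decomposition measures genuine epistasis.

The saturating benchmark scale (1+K)p / (1+Kp) used for simulation studies
also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PowerTransform",
    "PowerTransformError",
    "ScaleDomainError",
    "fit_power_transform",
    "transform",
    "linearize",
    "saturating_scale",
]

# Below this |lambda| the analytic log-limit branch of the transform is used.
_LAMBDA_SMALL = 1e-5


class PowerTransformError(RuntimeError):
    """Power-transform regression failed to converge.

    Carries the best parameters seen so far in ``best_params``.
    """

    def __init__(self, message: str, best_params: tuple | None = None):
        super().__init__(message)
        self.best_params = best_params


class ScaleDomainError(ValueError):
    """Input falls outside the domain of the fitted scale."""


@dataclass
class PowerTransform:
    """Fitted power-transform scale parameters.

    ``GM`` is the geometric mean of (p_add + A) over the fitting data and is
    stored for reuse so that :func:`transform` and :func:`linearize` are
    exact inverses on any input, not only the fitting set.
    """

    lam: float
    A: float
    B: float
    GM: float
    residuals: np.ndarray
    objective: float
    n_points: int

    @property
    def pearson_r2(self) -> float:
        """Squared Pearson correlation of the fitted curve with the data."""
        return self._r2

    def __post_init__(self) -> None:
        self._r2 = float("nan")

    def transform(self, p: np.ndarray) -> np.ndarray:
        return transform(p, self)

    def linearize(self, p_obs: np.ndarray) -> np.ndarray:
        return linearize(p_obs, self)

    def report(self) -> dict:
        return {
            "lambda": self.lam,
            "A": self.A,
            "B": self.B,
            "GM": self.GM,
            "objective": self.objective,
            "n_points": self.n_points,
            "pearson_r2_fit": self.pearson_r2,
        }


def _tau(p: np.ndarray, lam: float, A: float, B: float, GM: float) -> np.ndarray:
    s = p + A
    if abs(lam) < _LAMBDA_SMALL:
        return GM * np.log(s) + B
    return (np.power(s, lam) - 1.0) / (lam * GM ** (lam - 1.0)) + B


def _geometric_mean(p: np.ndarray, A: float) -> float:
    return float(np.exp(np.mean(np.log(p + A))))


def transform(p: np.ndarray, pt: PowerTransform) -> np.ndarray:
    """Evaluate the power transform at ``p``; requires p + A > 0.

    Continuous in lambda: for |lambda| below 1e-5 the removable singularity
    is replaced by its limit GM·log(p + A) + B.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p + pt.A <= 0):
        bad = np.nonzero(p + pt.A <= 0)[0]
        raise ScaleDomainError(
            f"p + A <= 0 at indices {bad.tolist()}; outside transform domain"
        )
    return _tau(p, pt.lam, pt.A, pt.B, pt.GM)


def linearize(p_obs: np.ndarray, pt: PowerTransform) -> np.ndarray:
    """Exact inverse of :func:`transform`: map observed phenotypes onto the
    additive (linear) scale.

    Raises :class:`ScaleDomainError`, listing the offending indices, when
    lambda·GM^(lambda−1)·(p_obs − B) + 1 <= 0 for some genotype — i.e. the
    observation lies outside the representable range of the fitted scale.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    if abs(pt.lam) < _LAMBDA_SMALL:
        return np.exp((p_obs - pt.B) / pt.GM) - pt.A
    bracket = pt.lam * pt.GM ** (pt.lam - 1.0) * (p_obs - pt.B) + 1.0
    if np.any(bracket <= 0):
        bad = np.nonzero(bracket <= 0)[0]
        raise ScaleDomainError(
            f"phenotypes at indices {bad.tolist()} are outside the "
            "representable range of the fitted scale (bracket <= 0)"
        )
    return np.power(bracket, 1.0 / pt.lam) - pt.A


def fit_power_transform(
    p_add: np.ndarray,
    p_obs: np.ndarray,
    n_starts: tuple[float, ...] = (0.3, 1.0, 3.0),
    init: tuple[float, float, float] | None = None,
) -> PowerTransform:
    """Fit (lambda, A, B) by nonlinear least squares of p_obs on p_add.

    The shift A is bounded below so that min(p_add) + A stays positive
    (delta = 1e-6 of the p_add range), GM is recomputed from A inside the
    objective, and the fit is multi-started over lambda in ``n_starts``
    (A initialized so min(p_add) + A = 1, B = 0), keeping the lowest
    objective. (lambda, A, B) are only weakly jointly identifiable near
    lambda = 1, where A and B trade off; the returned *curve* is what is
    well determined.

    ``init`` optionally warm-starts the solver from known-good parameters
    (e.g. a previous fit on nearby data); if that single start converges to
    an invertible scale it is used directly, skipping the multistart.
    """
    p_add = np.asarray(p_add, dtype=float)
    p_obs = np.asarray(p_obs, dtype=float)
    if p_add.shape != p_obs.shape:
        raise ValueError("p_add and p_obs must be the same length")
    if p_add.size < 4:
        raise ValueError(f"need >= 4 points to fit 3 parameters; got {p_add.size}")

    pmin = float(p_add.min())
    span = float(np.ptp(p_add))
    delta = 1e-6 * (span if span > 0 else 1.0)
    a_lower = -pmin + delta

    def residual(theta: np.ndarray) -> np.ndarray:
        lam, A, B = theta
        GM = _geometric_mean(p_add, A)
        return _tau(p_add, lam, A, B, GM) - p_obs

    obs_span_pen = float(np.ptp(p_obs)) or 1.0

    def bracket_of(theta: np.ndarray) -> np.ndarray:
        lam, A, B = theta
        if abs(lam) < _LAMBDA_SMALL:
            return np.ones_like(p_obs)
        GM = _geometric_mean(p_add, A)
        return lam * GM ** (lam - 1.0) * (p_obs - B) + 1.0

    def penalized_residual(theta: np.ndarray) -> np.ndarray:
        # hinge penalty keeping every observation inside the invertible range
        pen = 10.0 * obs_span_pen * np.maximum(0.0, 1e-3 - bracket_of(theta))
        return np.concatenate([residual(theta), pen])

    def solve_from(x0: np.ndarray, lam_lower: float, fun=None):
        # optimizer excursions can overflow the power harmlessly (the huge
        # residual steers the step back); keep them out of user warnings
        with np.errstate(over="ignore", invalid="ignore"):
            return _solve_from(x0, lam_lower, fun)

    def _solve_from(x0: np.ndarray, lam_lower: float, fun=None):
        return least_squares(
            fun if fun is not None else residual,
            x0,
            bounds=([lam_lower, a_lower, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf",
            x_scale="jac",
            max_nfev=2000,
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
        )

    def invertible(theta: np.ndarray) -> bool:
        lam, A, B = theta
        if abs(lam) < _LAMBDA_SMALL:
            return True  # log-limit branch inverts every real value
        GM = _geometric_mean(p_add, A)
        return bool(np.all(lam * GM ** (lam - 1.0) * (p_obs - B) + 1.0 > 0))

    # On some maps the objective has no interior minimum: its infimum lies on
    # an unbounded ridge along which the fitted curve converges while the
    # parameters drift without bound. A start therefore also counts as
    # converged when the fitted curve stabilizes — maximum change below
    # 1e-4 of the observed range — across chained restarts; the curve, not
    # the (weakly identified) parameter triple, is what linearization uses.
    obs_span = float(np.ptp(p_obs)) or 1.0

    def run_start(x0: np.ndarray, lam_lower: float, fun=None):
        """Chained solves from one start; True when curve/solver converged."""
        sol = None
        prev_curve = None
        for _ in range(6):
            sol = solve_from(x0 if sol is None else sol.x, lam_lower, fun)
            curve = residual(sol.x) + p_obs
            if sol.success:
                return sol, True
            if prev_curve is not None and (
                np.max(np.abs(curve - prev_curve)) < 1e-4 * obs_span
            ):
                return sol, True
            prev_curve = curve
        return sol, False

    def multistart(lam_lower: float, fun=None):
        best = None  # best converged start whose scale inverts the data
        best_any = None  # best-so-far including unconverged starts
        failures = []
        for lam0 in n_starts:
            x0 = np.array(
                [max(lam0, lam_lower), max(1.0 - pmin, a_lower + delta), 0.0]
            )
            try:
                sol, start_converged = run_start(x0, lam_lower, fun)
            except Exception as exc:  # numerical failure of one start
                failures.append(str(exc))
                continue
            if best_any is None or sol.cost < best_any.cost:
                best_any = sol
            if (
                start_converged
                and invertible(sol.x)
                and (best is None or sol.cost < best.cost)
            ):
                best = sol
        return best, best_any, failures

    best = None
    best_any = None
    failures: list[str] = []
    if init is not None:
        lam0, A0, B0 = init
        x0 = np.array([lam0, max(A0, a_lower + delta), B0])
        try:
            sol, conv = run_start(x0, -np.inf)
            if conv and invertible(sol.x):
                best = sol
            best_any = sol
        except Exception as exc:
            failures.append(str(exc))
    if best is None:
        best, best_any, failures2 = multistart(-np.inf)
        failures += failures2
    if best is None:
        # No unconstrained start yielded a scale that can back-transform the
        # data (typically a runaway negative lambda whose curve has a finite
        # asymptote inside the observed range). Refit with lambda >= 0: the
        # lambda -> 0 log-limit is invertible everywhere.
        best, best_any2, failures2 = multistart(0.0)
        failures += failures2
        if best_any2 is not None and (
            best_any is None or best_any2.cost < best_any.cost
        ):
            best_any = best_any2
    if best is None:
        # Last resort: refit with a hinge penalty that pushes the curve's
        # representable range to cover every observation.
        best, best_any3, failures3 = multistart(-np.inf, penalized_residual)
        failures += failures3
        if best_any3 is not None and best_any is None:
            best_any = best_any3
    if best is None:
        raise PowerTransformError(
            "no start converged to an invertible scale"
            f" ({len(failures)} raised: {failures})",
            best_params=None if best_any is None else tuple(best_any.x),
        )

    lam, A, B = (float(v) for v in best.x)
    GM = _geometric_mean(p_add, A)
    residuals = _tau(p_add, lam, A, B, GM) - p_obs
    pt = PowerTransform(
        lam=lam,
        A=A,
        B=B,
        GM=GM,
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        n_points=int(p_add.size),
    )
    fitted = p_obs + residuals
    if np.ptp(fitted) > 0 and np.ptp(p_obs) > 0:
        pt._r2 = float(np.corrcoef(fitted, p_obs)[0, 1] ** 2)
    return pt


def saturating_scale(p: np.ndarray | float, K: float) -> np.ndarray | float:
    """Diminishing-returns benchmark scale (1+K)·p / (1+K·p).

    K = 0 is the identity; p = 0 and p = 1 are fixed points for every K.
    Used to place simulated linear phenotypes on a saturating scale.
    """
    if K < 0:
        raise ValueError(f"K must be >= 0; got {K}")
    p_arr = np.asarray(p, dtype=float)
    denom = 1.0 + K * p_arr
    if np.any(np.isclose(denom, 0.0)):
        raise ScaleDomainError("input hits the pole 1 + K·p = 0")
    out = (1.0 + K) * p_arr / denom
    return float(out) if np.isscalar(p) else out
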