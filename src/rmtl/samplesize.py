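"""Sample-size calculation for the RMTLd tests.

For the basic difference test the total sample size is closed-form:

    n = (1 + r) * (z_{1-beta} + z_{1-alpha/2})^2 / (Delta^2 / (sigma1^2 +
        r^{-1} sigma2^2)),

with ``r = n2/n1`` the allocation ratio and ``sigma_k^2`` the per-observation
RMTL variances. For the supremum test the size inflates by a factor
``xi = eta^2 / eta_tilde^2`` that depends only on (alpha, power):
``eta_tilde = z_{1-alpha/2} + z_{1-beta}`` is the drift a normal test needs,
while ``eta`` is the drift a Brownian motion must carry for its supremum to
cross the two-sided critical value ``V_{1-alpha/2}`` with the target
probability. ``eta`` solves the boundary-crossing power equation

    Y(eta) = PhiBar(V - eta) + exp(2 V eta) PhiBar(V + eta) = 1 - beta,

by safeguarded Newton-Raphson started at ``eta_tilde`` (the exact derivative
``Y'(x) = phi(V - x) + 2 V exp(2Vx) PhiBar(V + x) - exp(2Vx) phi(V + x)`` is
used, with a bisection fallback inside ``[eta_tilde, eta_tilde + 5]``).
``V_{1-alpha/2}`` itself is found by inverting the sup-|BM| tail series.
Per-group sizes are rounded up individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.optimize import brentq

from .compare import sup_bm_tail
from .restricted import Tau, rmtl_from_sample
from .sample import CompetingRisksSample

__all__ = [
    "DesignParams",
    "SampleSizeResult",
    "samplesize_diff",
    "samplesize_sdiff",
    "sup_bm_critical_value",
    "solve_eta",
    "pilot_design_from_data",
]


@dataclass(frozen=True)
class DesignParams:
    """Design inputs for a two-arm RMTLd trial.

    ``delta`` is the assumed RMTL difference (group 2 minus group 1) and
    ``var1``/``var2`` the per-observation RMTL variances, all on the time
    scale of the study; ``r = n2/n1``.
    """

    delta: float
    var1: float
    var2: float
    alpha: float = 0.05
    power: float = 0.8
    r: float = 1.0
    epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if self.r <= 0:
            raise ValueError(f"allocation ratio r must be positive, got {self.r}")
        if self.delta == 0:
            raise ValueError("delta = 0 implies an infinite sample size")
        if self.var1 <= 0 or self.var2 <= 0:
            raise ValueError("per-observation variances must be positive")


@dataclass(frozen=True)
class SampleSizeResult:
    n1: int
    n2: int
    n_total: int
    method: str
    n_raw: float  # real-valued n before rounding
    xi: float = 1.0
    eta: float = float("nan")
    eta_tilde: float = float("nan")
    V: float = float("nan")


def _round_groups(n_raw: float, r: float) -> tuple[int, int]:
    n1 = math.ceil(n_raw / (1.0 + r))
    n2 = math.ceil(r * n_raw / (1.0 + r))
    return n1, n2


def samplesize_diff(params: DesignParams) -> SampleSizeResult:
    """Closed-form total sample size for the basic difference test."""
    z_b = stats.norm.ppf(params.power)
    z_a = stats.norm.ppf(1.0 - params.alpha / 2.0)
    n_raw = (1.0 + params.r) * (z_b + z_a) ** 2 / (
        params.delta**2 / (params.var1 + params.var2 / params.r)
    )
    n1, n2 = _round_groups(n_raw, params.r)
    return SampleSizeResult(n1=n1, n2=n2, n_total=n1 + n2, method="diff",
                            n_raw=n_raw)


def sup_bm_critical_value(alpha: float, epsilon: float = 1e-10) -> float:
    """x such that P[sup_{[0,1]} |M(t)| > x] = alpha (two-sided critical
    value of the supremum of absolute standard Brownian motion)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return brentq(
        lambda x: sup_bm_tail(x, epsilon).probability - alpha,
        1e-3, 10.0, xtol=max(epsilon, 1e-12),
    )


def solve_eta(
    alpha: float, power: float, epsilon: float = 1e-10, max_iter: int = 100
) -> tuple[float, float, float]:
    """Solve the drifted-Brownian power equation Y(eta) = power.

    Returns ``(eta, eta_tilde, V)`` where ``eta_tilde`` is the normal-test
    drift and ``V`` the sup-|BM| critical value at ``alpha``.
    """
    V = sup_bm_critical_value(alpha, epsilon)
    eta_tilde = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)

    def Y(x: float) -> float:
        return stats.norm.sf(V - x) + math.exp(2.0 * V * x) * stats.norm.sf(V + x)

    def Yp(x: float) -> float:
        return (stats.norm.pdf(V - x)
                + 2.0 * V * math.exp(2.0 * V * x) * stats.norm.sf(V + x)
                - math.exp(2.0 * V * x) * stats.norm.pdf(V + x))

    lo, hi = eta_tilde, eta_tilde + 5.0
    x = eta_tilde
    for _ in range(max_iter):
        step = (power - Y(x)) / Yp(x)
        x_new = x + step
        if not (lo <= x_new <= hi):  # safeguard: bisect within the bracket
            if Y(x) < power:
                lo = x
            else:
                hi = x
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) <= epsilon:
            return x_new, eta_tilde, V
        x = x_new
    raise RuntimeError(
        f"eta iteration did not converge (alpha={alpha}, power={power}, "
        f"last eta={x}, residual={Y(x) - power})"
    )


def samplesize_sdiff(params: DesignParams) -> SampleSizeResult:
    """Sample size for the supremum test: xi * (Diff sample size)."""
    base = samplesize_diff(params)
    eta, eta_tilde, V = solve_eta(params.alpha, params.power, params.epsilon)
    xi = (eta / eta_tilde) ** 2
    n_raw = xi * base.n_raw
    n1, n2 = _round_groups(n_raw, params.r)
    return SampleSizeResult(n1=n1, n2=n2, n_total=n1 + n2, method="sdiff",
                            n_raw=n_raw, xi=xi, eta=eta, eta_tilde=eta_tilde, V=V)


def pilot_design_from_data(
    sample1: CompetingRisksSample,
    sample2: CompetingRisksSample,
    tau: Tau | float,
    alpha: float = 0.05,
    power: float = 0.8,
    r: float = 1.0,
) -> DesignParams:
    """Design parameters (delta, var1, var2) estimated from pilot data at tau."""
    r1 = rmtl_from_sample(sample1, tau)
    r2 = rmtl_from_sample(sample2, tau)
    delta = r2.value - r1.value
    if delta == 0.0:
        raise ValueError("pilot RMTL difference is exactly zero; cannot size")
    return DesignParams(delta=delta, var1=r1.var_perobs, var2=r2.var_perobs,
                        alpha=alpha, power=power, r=r)
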