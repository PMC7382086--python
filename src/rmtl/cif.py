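"""Nonparametric estimation for competing risks: all-cause Kaplan-Meier
survival and the cumulative incidence function (CIF) with pointwise variance.

The CIF of cause *j* is estimated by the Aalen-Johansen form

    I_j(t) = sum_{t_i <= t} (d_ij / n_i) * S(t_{i-1}),

where the sum runs over the distinct times with at least one event of any
cause, ``d_ij`` counts cause-*j* events at ``t_i``, ``n_i`` is the number at
risk, and ``S`` is the Kaplan-Meier estimate treating every event type as a
failure. Censoring tied with an event time is processed after the events
(subjects censored at ``t_i`` are still at risk at ``t_i``).

The pointwise variance attached to the CIF is the counting-process (Aalen-type)
estimator in its standard textbook form,

    V[I_j(t)] = sum_{t_i<=t} [I_j(t) - I_j(t_i)]^2 d_i / (n_i (n_i - d_i))
              + sum_{t_i<=t} S(t_{i-1})^2 (n_i - d_ij) d_ij / n_i^3
              - 2 sum_{t_i<=t} [I_j(t) - I_j(t_i)] S(t_{i-1}) d_ij / n_i^2,

with ``d_i`` the all-cause event count at ``t_i``; terms with ``n_i = d_i``
contribute zero to the first sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample import CompetingRisksSample

__all__ = [
    "SurvivalCurve",
    "CIFCurve",
    "estimate_overall_survival",
    "estimate_cif",
]


def _step_eval(
    knots: np.ndarray, values: np.ndarray, t: np.ndarray | float, baseline: float
) -> np.ndarray | float:
    """Right-continuous step evaluation with a pre-first-knot baseline."""
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(knots, t_arr, side="right") - 1
    out = np.where(idx >= 0, np.concatenate(([baseline], values))[idx + 1], baseline)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous all-cause Kaplan-Meier estimate.

    ``survival[i]`` is the value on ``[event_times[i], event_times[i+1])``;
    the curve equals 1 before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray  # all-cause event counts d_i
    n: int
    max_time: float

    def __call__(self, t):
        return _step_eval(self.event_times, self.survival, t, baseline=1.0)


@dataclass(frozen=True)
class CIFCurve:
    """Aalen-Johansen cumulative incidence for one cause with pointwise variance.

    The grid holds every distinct time with at least one event of any cause,
    so curves for different causes from the same sample share their grid.
    """

    event_times: np.ndarray
    cif: np.ndarray
    variance: np.ndarray
    cause: int
    at_risk: np.ndarray
    n_events: np.ndarray  # cause-specific counts d_ij
    n: int
    max_time: float

    def __call__(self, t):
        return _step_eval(self.event_times, self.cif, t, baseline=0.0)

    def variance_at(self, t):
        return _step_eval(self.event_times, self.variance, t, baseline=0.0)


def _event_table(sample: CompetingRisksSample):
    """Distinct all-cause event times with at-risk and per-cause counts."""
    event_mask = sample.causes > 0
    times = np.unique(sample.times[event_mask])
    # at risk: subjects whose observed time is >= t_i (ties censored at t_i count)
    sorted_all = np.sort(sample.times)
    at_risk = sample.n - np.searchsorted(sorted_all, times, side="left")
    d_all = np.zeros(times.size, dtype=int)
    per_cause: dict[int, np.ndarray] = {}
    for cause in np.unique(sample.causes[event_mask]):
        idx = np.searchsorted(times, sample.times[sample.causes == cause])
        counts = np.bincount(idx, minlength=times.size)
        per_cause[int(cause)] = counts
        d_all += counts
    return times, at_risk, d_all, per_cause


def estimate_overall_survival(sample: CompetingRisksSample) -> SurvivalCurve:
    """Kaplan-Meier estimate treating every event type as a failure."""
    times, at_risk, d_all, _ = _event_table(sample)
    surv = np.cumprod(1.0 - d_all / at_risk) if times.size else np.array([])
    return SurvivalCurve(
        event_times=times,
        survival=surv,
        at_risk=at_risk,
        n_events=d_all,
        n=sample.n,
        max_time=sample.max_time,
    )


def estimate_cif(sample: CompetingRisksSample, cause: int = 1) -> CIFCurve:
    """Aalen-Johansen CIF for one cause, with the Aalen pointwise variance."""
    if cause <= 0:
        raise ValueError(f"cause must be a positive event code, got {cause}")
    times, at_risk, d_all, per_cause = _event_table(sample)
    d_j = per_cause.get(int(cause), np.zeros(times.size, dtype=int))

    if times.size == 0:
        empty = np.array([])
        return CIFCurve(empty, empty, empty, int(cause), empty.astype(int),
                        empty.astype(int), sample.n, sample.max_time)

    surv = np.cumprod(1.0 - d_all / at_risk)
    s_prev = np.concatenate(([1.0], surv[:-1]))  # S(t_{i-1})
    incr = (d_j / at_risk) * s_prev
    cif = np.cumsum(incr)

    # Aalen-type variance via prefix sums: V(t_k) =
    #   I_k^2 A_k - 2 I_k P_k + Q_k + B_k - 2 I_k C_k + 2 R_k
    # with a_i = d_i/(n_i(n_i-d_i)) (0 when n_i=d_i), b_i, c_i as in the
    # module docstring, and prefix sums of a, I*a, I^2*a, b, c, I*c.
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(at_risk > d_all, d_all / (at_risk * (at_risk - d_all)), 0.0)
    b = s_prev**2 * (at_risk - d_j) * d_j / at_risk**3
    c = s_prev * d_j / at_risk**2
    A = np.cumsum(a)
    P = np.cumsum(cif * a)
    Q = np.cumsum(cif**2 * a)
    B = np.cumsum(b)
    C = np.cumsum(c)
    R = np.cumsum(cif * c)
    var = cif**2 * A - 2.0 * cif * P + Q + B - 2.0 * cif * C + 2.0 * R
    var = np.maximum(var, 0.0)  # guard tiny negative round-off

    return CIFCurve(
        event_times=times,
        cif=cif,
        variance=var,
        cause=int(cause),
        at_risk=at_risk,
        n_events=d_j,
        n=sample.n,
        max_time=sample.max_time,
    )
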