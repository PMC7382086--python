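"""Competing-risks data simulator and Monte-Carlo studies of the RMTLd tests.

Data generation is two-stage, mirroring how the cause-specific CIFs are
specified: for each subject the cause of failure is drawn first —
Bernoulli(p1) for the event of interest, where ``p1 = I1(inf)`` is the
plateau of the event-of-interest CIF — and the latent failure time is then
drawn from that cause's conditional distribution, a piecewise Weibull sampled
by closed-form inverse transform on the cumulative hazard (continuity is
enforced at the breakpoints). An independent Uniform(0, c) censoring time is
applied identically in both groups; ``c`` can be calibrated by root search to
hit a target censoring proportion.

Six stock scenarios (A-F, loaded from ``scenarios.yaml``) cover the standard
qualitative shapes for two-sample CIF comparisons: null, proportional-type,
non-proportional, early, late and crossing differences.

Replication studies draw both groups per replicate from a dedicated child
stream of one seeded root generator, set ``tau`` to the default rule
(minimum over groups of the last event-of-interest time), run the requested
tests on the same data (paired comparison), and tabulate rejection rates
with binomial Monte-Carlo standard errors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.optimize import brentq

from .compare import diff_test, sdiff_test
from .restricted import default_tau
from .sample import CompetingRisksSample

__all__ = [
    "PiecewiseWeibull",
    "ScenarioConfig",
    "RejectionStudyResult",
    "load_scenario",
    "available_scenarios",
    "sample_group",
    "sample_pair",
    "calibrate_censoring",
    "rejection_study",
    "observed_power_at_n",
]


@dataclass(frozen=True)
class PiecewiseWeibull:
    """Piecewise Weibull distribution on [0, inf).

    ``breaks`` are the interior breakpoints (strictly increasing); segment
    ``s`` covers ``[breaks[s-1], breaks[s])`` and carries Weibull cumulative
    hazard ``(t/scale_s)^shape_s``, shifted so the total cumulative hazard is
    continuous.
    """

    shapes: tuple[float, ...]
    scales: tuple[float, ...]
    breaks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.shapes) != len(self.scales):
            raise ValueError("one (shape, scale) pair per segment required")
        if len(self.breaks) != len(self.shapes) - 1:
            raise ValueError("need exactly one more segment than breakpoints")
        if any(s <= 0 for s in self.shapes) or any(s <= 0 for s in self.scales):
            raise ValueError("shapes and scales must be positive")
        b = np.asarray(self.breaks, dtype=float)
        if b.size and (np.any(b <= 0) or np.any(np.diff(b) <= 0)):
            raise ValueError("breakpoints must be positive and increasing")

    def _segment_hazards(self) -> tuple[np.ndarray, np.ndarray]:
        """Left edges of the segments and the cumulative hazard there."""
        lefts = np.concatenate(([0.0], np.asarray(self.breaks, dtype=float)))
        H = np.zeros(len(lefts))
        for s in range(1, len(lefts)):
            k, lam = self.shapes[s - 1], self.scales[s - 1]
            H[s] = H[s - 1] + (lefts[s] / lam) ** k - (lefts[s - 1] / lam) ** k
        return lefts, H

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lefts, H0 = self._segment_hazards()
        seg = np.clip(np.searchsorted(lefts, t, side="right") - 1, 0, None)
        k = np.asarray(self.shapes)[seg]
        lam = np.asarray(self.scales)[seg]
        return H0[seg] + (t / lam) ** k - (lefts[seg] / lam) ** k

    def cdf(self, t: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-self.cumhaz(t))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse transform via segment-wise inversion of the cumulative
        hazard H* = -log(1 - u)."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u >= 1)):
            raise ValueError("u must lie in [0, 1)")
        lefts, H0 = self._segment_hazards()
        h_star = -np.log1p(-u)
        seg = np.clip(np.searchsorted(H0, h_star, side="right") - 1, 0, None)
        k = np.asarray(self.shapes)[seg]
        lam = np.asarray(self.scales)[seg]
        return lam * (h_star - H0[seg] + (lefts[seg] / lam) ** k) ** (1.0 / k)


def _pw_from_spec(spec: dict) -> PiecewiseWeibull:
    segs = spec["segments"]
    return PiecewiseWeibull(
        shapes=tuple(float(s[0]) for s in segs),
        scales=tuple(float(s[1]) for s in segs),
        breaks=tuple(float(b) for b in spec.get("breaks", [])),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generating configuration for one two-group simulation setting."""

    scenario: str
    cause1: tuple[PiecewiseWeibull, PiecewiseWeibull]  # per group
    cause2: tuple[PiecewiseWeibull, PiecewiseWeibull]
    p1: float | tuple[float, float] = 0.7
    censor_upper: float | None = None
    n1: int = 100
    n2: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        # p1 is the plateau I1(inf) of the event-of-interest CIF; scenarios
        # with a proportional sub-distribution-hazard difference need it to
        # differ between groups, so a per-group pair is accepted.
        p1 = self.p1 if isinstance(self.p1, tuple) else (self.p1, self.p1)
        object.__setattr__(self, "p1", (float(p1[0]), float(p1[1])))
        if any(not (0.0 < p <= 1.0) for p in self.p1):
            raise ValueError(f"p1 must be in (0, 1], got {self.p1}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if self.censor_upper is not None and self.censor_upper <= 0:
            raise ValueError("censor_upper must be positive or None")


def _registry() -> dict:
    text = (importlib.resources.files("rmtl") / "scenarios.yaml").read_text()
    return yaml.safe_load(text)


def available_scenarios() -> list[str]:
    return sorted(_registry()["scenarios"])


def load_scenario(
    name: str,
    n1: int = 100,
    n2: int = 100,
    censor_upper: float | None = None,
    seed: int | None = None,
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from the packaged registry."""
    reg = _registry()
    try:
        sc = reg["scenarios"][name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {available_scenarios()}"
        ) from None
    cause2_default = _pw_from_spec(reg["defaults"]["cause2"])
    c1 = tuple(
        _pw_from_spec(sc[g]["cause1"]) for g in ("group1", "group2")
    )
    c2 = tuple(
        _pw_from_spec(sc[g]["cause2"]) if "cause2" in sc[g] else cause2_default
        for g in ("group1", "group2")
    )
    p1_default = float(reg["defaults"]["p1"])
    p1 = tuple(
        float(sc[g].get("p1", p1_default)) for g in ("group1", "group2")
    )
    return ScenarioConfig(
        scenario=name.upper(), cause1=c1, cause2=c2,
        p1=p1, censor_upper=censor_upper,
        n1=n1, n2=n2, seed=seed,
    )


def sample_group(
    config: ScenarioConfig, group: int, rng: np.random.Generator
) -> CompetingRisksSample:
    """Draw one group's records under the configuration."""
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    n = config.n1 if group == 1 else config.n2
    g = group - 1
    is_cause1 = rng.random(n) < config.p1[g]
    t = np.empty(n)
    u = rng.random(n)
    if is_cause1.any():
        t[is_cause1] = config.cause1[g].ppf(u[is_cause1])
    if (~is_cause1).any():
        t[~is_cause1] = config.cause2[g].ppf(u[~is_cause1])
    cause = np.where(is_cause1, 1, 2)
    if config.censor_upper is not None:
        c = rng.uniform(0.0, config.censor_upper, n)
        censored = c < t
        t = np.minimum(t, c)
        cause = np.where(censored, 0, cause)
    return CompetingRisksSample(t, cause, group=str(group))


def sample_pair(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[CompetingRisksSample, CompetingRisksSample]:
    return sample_group(config, 1, rng), sample_group(config, 2, rng)


def calibrate_censoring(
    config: ScenarioConfig,
    target_rate: float,
    tol: float = 0.005,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float | None:
    """Uniform-censoring upper bound hitting a target censoring proportion.

    Uses common random numbers: one large set of latent failure times and
    censoring uniforms is drawn once, making the realized censoring rate a
    monotone function of the upper bound that a bracketed root search can
    invert. Returns ``None`` for a zero target (no censoring).
    """
    if not (0.0 <= target_rate <= 0.9):
        raise ValueError("target censoring rate must lie in [0, 0.9]")
    if target_rate == 0.0:
        return None
    rng = np.random.default_rng(seed)
    big = replace(config, n1=n_draws // 2, n2=n_draws - n_draws // 2,
                  censor_upper=None)
    s1, s2 = sample_pair(big, rng)
    t = np.concatenate([s1.times, s2.times])
    u = rng.random(t.size)

    def realized(upper: float) -> float:
        return float(np.mean(upper * u < t))

    # realized rate decreases with upper; bracket it
    lo, hi = 1e-6, 10.0
    while realized(hi) > target_rate:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"censoring target {target_rate} unattainable")
    upper = brentq(lambda x: realized(x) - target_rate, lo, hi, xtol=1e-6)
    if abs(realized(upper) - target_rate) > tol:
        raise ValueError(
            f"calibration missed target {target_rate} "
            f"(got {realized(upper):.4f}); increase n_draws"
        )
    return float(upper)


@dataclass(frozen=True)
class RejectionStudyResult:
    """Monte-Carlo rejection rates for a set of tests on one configuration."""

    scenario: str
    rates: dict[str, float]
    se: dict[str, float]
    reps: int
    alpha: float
    n1: int
    n2: int
    censor_upper: float | None = None

    def rate(self, method: str) -> float:
        return self.rates[method]


_METHODS = ("diff", "sdiff")


def rejection_study(
    config: ScenarioConfig,
    methods: tuple[str, ...] = ("diff", "sdiff"),
    reps: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    rho: float = 0.5,
    tau: float | None = None,
) -> RejectionStudyResult:
    """Rejection rate of each test over ``reps`` paired replicates.

    Each replicate draws both groups from its own child stream and runs every
    requested method on the same data. ``tau=None`` applies the default rule
    (minimum over groups of the last event-of-interest time) per replicate; a
    fixed ``tau`` emulates a design with a prescribed follow-up window.
    """
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {_METHODS}")
    root_seed = seed if seed is not None else config.seed
    ss = np.random.SeedSequence(root_seed)
    rejections = {m: 0 for m in methods}
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        s1, s2 = sample_pair(config, rng)
        rep_tau = default_tau(s1, s2) if tau is None else tau
        if "diff" in methods:
            rejections["diff"] += diff_test(s1, s2, rep_tau).p_value < alpha
        if "sdiff" in methods:
            rejections["sdiff"] += (
                sdiff_test(s1, s2, rep_tau, rho=rho).p_value < alpha
            )
    rates = {m: rejections[m] / reps for m in methods}
    se = {m: float(np.sqrt(r * (1.0 - r) / reps)) for m, r in rates.items()}
    return RejectionStudyResult(
        scenario=config.scenario, rates=rates, se=se, reps=reps, alpha=alpha,
        n1=config.n1, n2=config.n2, censor_upper=config.censor_upper,
    )


def observed_power_at_n(
    config: ScenarioConfig,
    method: str,
    n_total: int,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    tau: float | None = None,
) -> float:
    """Rejection rate at a prescribed total sample size (equal allocation)."""
    n1 = n_total // 2 + n_total % 2
    n2 = n_total - n1
    sized = replace(config, n1=n1, n2=max(n2, 1))
    study = rejection_study(sized, methods=(method,), reps=reps, alpha=alpha,
                            seed=seed, tau=tau)
    return study.rate(method)
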