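"""Seeded noise standards and a synthetic hospital-census generator.

The calibration noises are the classical standards used to anchor finite-length
fractal-dimension estimates: uniform deviates, Gaussian deviates obtained with
the Box–Muller transform (both the sine and the cosine branch are consumed, in
order), the Gaussian random walk (first value 0, independent normal
increments), and Cauchy deviates by inverse-CDF sampling (the heavy-tailed
stress case for nonparametric estimators).

The hospital simulator is a minimal conserved-refill model of a long-stay
hospital: each day a Poisson number of patients is discharged, and every
discharged bed schedules exactly one replacement admission after a random lag.
The lag pool is the model's only source of low-frequency census variance: with
lag 0 the census is constant, and as the mean lag grows the in-patient series
meanders like a Brownian random walk while the daily admissions-minus-
discharges difference stays white.  Recording artifacts (impossible New-Year
spikes, a contiguous gap of missing days) can be injected so the cleaning
stage is testable.

All randomness flows from a single integer seed through numpy's seeded PCG64
generator; one generator instance is drawn from sequentially per call, so a
given (spec, seed) pair is byte-reproducible.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import PanelSeries

__all__ = [
    "NoiseSpec",
    "HospitalSimConfig",
    "SimulatedPanel",
    "box_muller",
    "gen_uniform",
    "gen_gaussian",
    "gen_brownian",
    "gen_cauchy",
    "generate",
    "simulate_hospital",
]

NOISE_KINDS = ("uniform", "gaussian", "brownian", "cauchy")
LAG_DISTRIBUTIONS = ("geometric", "fixed", "uniform")


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of a calibration-noise draw.

    ``params`` hold the distribution parameters: ``a``/``b`` for uniform,
    ``mu``/``sigma`` for gaussian and brownian (sigma is the increment scale),
    ``mu``/``lam`` for cauchy.
    """

    kind: str
    length: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        p = self.params
        if self.kind == "uniform":
            a, b = p.get("a", 0.0), p.get("b", 1.0)
            if not a < b:
                raise ValueError("uniform noise requires a < b")
        elif self.kind == "gaussian":
            if p.get("sigma", 1.0) <= 0:
                raise ValueError("gaussian noise requires sigma > 0")
        elif self.kind == "brownian":
            if p.get("sigma", 1.0) < 0:
                raise ValueError("brownian noise requires sigma >= 0")
        elif self.kind == "cauchy":
            if p.get("lam", 1.0) <= 0:
                raise ValueError("cauchy noise requires lam > 0")


def box_muller(r1: np.ndarray, r2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both branches of the Box–Muller transform of paired uniform deviates.

    Returns ``(sin branch, cos branch)``:
    ``sin(2π r1)·√(−2 ln r2)`` and ``cos(2π r1)·√(−2 ln r2)``.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    radius = np.sqrt(-2.0 * np.log(r2))
    angle = 2.0 * np.pi * r1
    return np.sin(angle) * radius, np.cos(angle) * radius


def _gaussian_stream(rng: np.random.Generator, n: int) -> np.ndarray:
    """n standard-normal deviates: Box–Muller pairs consumed in order."""
    pairs = (n + 1) // 2
    r1 = rng.random(pairs)
    r2 = 1.0 - rng.random(pairs)  # in (0, 1]; keeps log() finite
    z_sin, z_cos = box_muller(r1, r2)
    out = np.empty(2 * pairs)
    out[0::2] = z_sin
    out[1::2] = z_cos
    return out[:n]


def gen_uniform(spec: NoiseSpec) -> np.ndarray:
    if spec.kind != "uniform":
        raise ValueError("spec.kind must be 'uniform'")
    a = spec.params.get("a", 0.0)
    b = spec.params.get("b", 1.0)
    rng = np.random.default_rng(spec.seed)
    return a + (b - a) * rng.random(spec.length)


def gen_gaussian(spec: NoiseSpec) -> np.ndarray:
    if spec.kind != "gaussian":
        raise ValueError("spec.kind must be 'gaussian'")
    mu = spec.params.get("mu", 0.0)
    sigma = spec.params.get("sigma", 1.0)
    rng = np.random.default_rng(spec.seed)
    return mu + sigma * _gaussian_stream(rng, spec.length)


def gen_brownian(spec: NoiseSpec) -> np.ndarray:
    """Gaussian random walk: b₀ = 0, bᵢ = bᵢ₋₁ + gᵢ₋₁ with gᵢ ~ N(0, σ²)."""
    if spec.kind != "brownian":
        raise ValueError("spec.kind must be 'brownian'")
    sigma = spec.params.get("sigma", 1.0)
    rng = np.random.default_rng(spec.seed)
    increments = sigma * _gaussian_stream(rng, spec.length - 1)
    out = np.empty(spec.length)
    out[0] = 0.0
    np.cumsum(increments, out=out[1:])
    return out


def gen_cauchy(spec: NoiseSpec) -> np.ndarray:
    """Inverse-CDF Cauchy sampling: x = μ̂ + λ·tan(π(u − ½))."""
    if spec.kind != "cauchy":
        raise ValueError("spec.kind must be 'cauchy'")
    mu = spec.params.get("mu", 0.0)
    lam = spec.params.get("lam", 1.0)
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.length)
    return mu + lam * np.tan(np.pi * (u - 0.5))


_GENERATORS = {
    "uniform": gen_uniform,
    "gaussian": gen_gaussian,
    "brownian": gen_brownian,
    "cauchy": gen_cauchy,
}


def generate(spec: NoiseSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)


# ---------------------------------------------------------------------------
# Hospital census simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HospitalSimConfig:
    """Configuration of the conserved-refill census simulator.

    Defaults emulate the scale of the study system: a 192-bed long-stay
    hospital observed for 1329 consecutive days around a 150-bed census.
    ``mean_discharges_per_day`` = 3 corresponds to ~150 occupied beds turning
    over with a mean stay of ~50 days.  ``lag_param`` is the mean
    discharge-to-admission lag in days (for ``fixed`` it is the exact lag; for
    ``uniform`` the lag is drawn from 0..lag_param inclusive).  The default
    geometric lag with a 60-day mean represents a slow referral pipeline and
    is what makes the census Brownian-like at this observation length.
    """

    beds: int = 192
    days: int = 1329
    target_census: int = 150
    mean_discharges_per_day: float = 3.0
    lag_distribution: str = "geometric"
    lag_param: float = 60.0
    inject_newyear_spike: bool = False
    inject_gap: tuple[int, int] | None = None  # (start_day, length)

    def __post_init__(self) -> None:
        if self.beds <= 0 or self.days <= 0:
            raise ValueError("beds and days must be positive")
        if not 0 < self.target_census <= self.beds:
            raise ValueError("target_census must satisfy 0 < target_census <= beds")
        if self.mean_discharges_per_day <= 0:
            raise ValueError("mean_discharges_per_day must be positive")
        if self.lag_distribution not in LAG_DISTRIBUTIONS:
            raise ValueError(f"unknown lag_distribution {self.lag_distribution!r}")
        if self.lag_param < 0:
            raise ValueError("lag parameter must be >= 0")
        if self.inject_gap is not None:
            start, length = self.inject_gap
            if length <= 0 or start <= 0 or start + length >= self.days:
                raise ValueError("injected gap must lie strictly inside the series")


@dataclass(frozen=True)
class SimulatedPanel:
    """A simulated command panel plus the ground truth behind it."""

    series: PanelSeries
    true_lag_draws: np.ndarray
    seed: int
    newyear_days: tuple[int, ...] = ()
    gap: tuple[int, int] | None = None


def _draw_lags(rng: np.random.Generator, config: HospitalSimConfig, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0, dtype=int)
    if config.lag_distribution == "geometric":
        if config.lag_param == 0:
            return np.zeros(size, dtype=int)
        p = 1.0 / (1.0 + config.lag_param)
        return rng.geometric(p, size=size) - 1  # support 0, 1, 2, ...
    if config.lag_distribution == "fixed":
        return np.full(size, int(round(config.lag_param)), dtype=int)
    return rng.integers(0, int(round(config.lag_param)) + 1, size=size)


def _mean_lag(config: HospitalSimConfig) -> float:
    if config.lag_distribution == "uniform":
        return int(round(config.lag_param)) / 2.0
    if config.lag_distribution == "fixed":
        return float(int(round(config.lag_param)))
    return float(config.lag_param)


# Day offsets of January-1-equivalents for a series starting on a May 1
# (May 1 -> Dec 31 is 244 days, so day 245 is the first New Year).
_FIRST_NEWYEAR_OFFSET = 245
_YEAR = 365


def simulate_hospital(config: HospitalSimConfig, seed: int) -> SimulatedPanel:
    """Run the conserved-refill census model.

    Per day: a Poisson number of discharges (capped at the current census)
    leaves; each discharged bed schedules one admission after a random lag
    (lag 0 means same-day replacement); the census is updated by
    admissions − discharges and admissions that would exceed the bed capacity
    are deferred to the next day.  The in-transit pool is initialised at its
    stationary size so the census starts in (approximate) equilibrium at
    ``target_census``.
    """
    rng = np.random.default_rng(seed)
    mdis = config.mean_discharges_per_day
    census = config.target_census
    pending: dict[int, int] = defaultdict(int)

    # Stationary in-transit pool: Poisson(discharge rate × mean lag) patients
    # already on their way, with residual lags (exact for the memoryless
    # geometric family, a uniform-residual approximation otherwise).
    pool = int(rng.poisson(mdis * _mean_lag(config)))
    if pool:
        if config.lag_distribution == "geometric":
            residuals = _draw_lags(rng, config, pool)
        else:
            top = max(int(round(config.lag_param)), 1)
            residuals = rng.integers(0, top, size=pool)
        for lag in residuals:
            pending[int(lag)] += 1

    adm_out = np.zeros(config.days)
    dis_out = np.zeros(config.days)
    inp_out = np.zeros(config.days)
    lag_draws: list[int] = []

    for t in range(config.days):
        dis = min(int(rng.poisson(mdis)), census)
        lags = _draw_lags(rng, config, dis)
        lag_draws.extend(int(v) for v in lags)
        for lag in lags:
            pending[t + int(lag)] += 1
        adm = pending.pop(t, 0)
        census += adm - dis
        if census > config.beds:
            excess = census - config.beds
            pending[t + 1] += excess
            adm -= excess
            census = config.beds
        adm_out[t] = adm
        dis_out[t] = dis
        inp_out[t] = census

    newyear_days: tuple[int, ...] = ()
    if config.inject_newyear_spike:
        candidates = [
            d
            for d in range(_FIRST_NEWYEAR_OFFSET, config.days, _YEAR)
            if 0 < d < config.days - 1
        ][:2]
        # Year-rollover bug: a count far above capacity lands in one flow
        # column per affected New Year (admissions first, discharges second).
        for i, day in enumerate(candidates):
            spike = 900 + int(rng.integers(0, 100))
            if i % 2 == 0:
                adm_out[day] = spike
            else:
                dis_out[day] = spike
        newyear_days = tuple(candidates)

    gap = config.inject_gap
    if gap is not None:
        start, length = gap
        inp_out[start : start + length] = np.nan

    series = PanelSeries(
        adm=adm_out, dis=dis_out, inp=inp_out, beds=config.beds
    )
    return SimulatedPanel(
        series=series,
        true_lag_draws=np.array(lag_draws, dtype=int),
        seed=seed,
        newyear_days=newyear_days,
        gap=gap,
    )
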