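"""Distribution-free significance machinery for dimension comparisons.

The Vysochanskij–Petunin (V-P) inequality bounds the tails of any unimodal
distribution with finite variance:

    P(|X − μ| ≥ λσ) ≤ 4/(9λ²) = ε          for λ > √(8/3).

Inverting the bound gives distribution-free critical ratios: λ ≥ √(40/9)
(≈ 2.108) declares a one-tailed difference significant at α = 0.05, and
λ ≥ √(80/9) (≈ 2.981) the two-tailed analogue.  Below the applicability
threshold √(8/3) (≈ 1.633) the theorem gives no usable bound and the
probability is only known to lie in [1/6, 1]; a comparison landing there is
reported as that interval, never as a point p-value, and is never declared
significant.  The V-P verdict is deliberately conservative: for Gaussian data
the same α would need only λ ≈ 1.65 (one tail), so anything the V-P rule
flags is more significant than it appears.

Two fractal-dimension estimates are compared through the ratio of their
difference to its pooled standard error, λ = |ΔD̄s| / √(var_t,1 + var_t,2),
with the total (between + within) variances from the calibration ensembles.

The Cauchy closed forms live here because the Cauchy law (no mean, no
variance) is the canonical counterexample motivating the all-nonparametric
toolbox: quotients of random quantities such as the per-day mean length of
stay can behave this way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "THEOREM_THRESHOLD",
    "TailBound",
    "VPComparison",
    "CauchyParams",
    "critical_lambda",
    "vp_tail_bound",
    "compare_dimensions",
    "cauchy_pdf",
    "cauchy_cdf",
    "cauchy_quantile",
]

#: λ below which Theorem 1 ceases to apply (√(8/3)).
THEOREM_THRESHOLD = math.sqrt(8.0 / 3.0)

#: The [1/6, 1] probability interval of the corollary regime.
COROLLARY_BOUND = (1.0 / 6.0, 1.0)


def _epsilon(lam: float) -> float:
    """The two-sided V-P tail bound ε = 4/(9λ²)."""
    return 4.0 / (9.0 * lam * lam)


def critical_lambda(alpha: float = 0.05, tails: int = 1) -> float:
    """Invert the V-P tail bound: the smallest λ significant at level α.

    One-tailed: ε/2 ≤ α  ⟹  λ ≥ √(2/(9α)); two-tailed: ε ≤ α  ⟹
    λ ≥ √(4/(9α)).  The result is never below the theorem's applicability
    threshold √(8/3).
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if tails == 1:
        lam = math.sqrt(2.0 / (9.0 * alpha))
    elif tails == 2:
        lam = math.sqrt(4.0 / (9.0 * alpha))
    else:
        raise ValueError("tails must be 1 or 2")
    return max(lam, THEOREM_THRESHOLD)


@dataclass(frozen=True)
class TailBound:
    """The V-P bound evaluated at a ratio λ."""

    lam: float
    regime: str  # "theorem_applies" | "corollary"
    epsilon: float | None  # two-sided bound, None in the corollary regime
    p_one_sided: float | None
    interval: tuple[float, float] | None  # [1/6, 1] in the corollary regime


def vp_tail_bound(lam: float) -> TailBound:
    """Evaluate the V-P tail bound at λ.

    Above the threshold the two-sided bound is ε = 4/(9λ²) and, by the
    symmetry convention, the one-sided bound ε/2.  At or below the threshold
    only the corollary interval [1/6, 1] is available.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if lam > THEOREM_THRESHOLD:
        eps = _epsilon(lam)
        return TailBound(
            lam=lam,
            regime="theorem_applies",
            epsilon=eps,
            p_one_sided=eps / 2.0,
            interval=None,
        )
    return TailBound(
        lam=lam,
        regime="corollary",
        epsilon=None,
        p_one_sided=None,
        interval=COROLLARY_BOUND,
    )


@dataclass(frozen=True)
class VPComparison:
    """Outcome of a distribution-free dimension-difference test."""

    deltaD: float
    s_delta: float
    lam: float
    regime: str
    p_bound: float | tuple[float, float]
    significant: bool
    alpha: float
    tails: int

    def to_dict(self) -> dict:
        p = self.p_bound
        return {
            "deltaD": self.deltaD,
            "s_delta": self.s_delta,
            "lam": self.lam,
            "regime": self.regime,
            "p_bound": list(p) if isinstance(p, tuple) else p,
            "significant": self.significant,
            "alpha": self.alpha,
            "tails": self.tails,
        }


def _mean_var(obj) -> tuple[float, float]:
    """Coerce an ensemble, a single-trace result, or a (mean, var) pair."""
    if hasattr(obj, "Dbar"):
        return float(obj.Dbar), float(obj.var_total)
    if hasattr(obj, "Ds"):
        return float(obj.Ds), float(obj.varDs)
    mean, var = obj
    return float(mean), float(var)


def compare_dimensions(ens1, ens2, alpha: float = 0.05, two_tailed: bool = False) -> VPComparison:
    """Test whether two dimension estimates differ, without a known pdf.

    Accepts :class:`~censuswalk.fractal.CalibrationEnsemble` objects,
    :class:`~censuswalk.fractal.SevcikResult` objects, or plain
    ``(mean, variance)`` pairs.  The default decision rule is the one-tailed
    λ ≥ √(40/9) criterion at α = 0.05; ``two_tailed=True`` switches to the
    √(80/9) threshold.  In the corollary regime (λ ≤ √(8/3)) the p-bound is
    the interval [1/6, 1] and the difference is never significant.
    """
    mean1, var1 = _mean_var(ens1)
    mean2, var2 = _mean_var(ens2)
    if var1 <= 0 or var2 <= 0:
        raise ValueError("both variances must be positive")
    delta = mean1 - mean2
    s_delta = math.sqrt(var1 + var2)
    lam = abs(delta) / s_delta
    tails = 2 if two_tailed else 1

    if lam <= THEOREM_THRESHOLD:
        return VPComparison(
            deltaD=delta,
            s_delta=s_delta,
            lam=lam,
            regime="corollary",
            p_bound=COROLLARY_BOUND,
            significant=False,
            alpha=alpha,
            tails=tails,
        )
    eps = _epsilon(lam)
    p_bound = eps if two_tailed else eps / 2.0
    return VPComparison(
        deltaD=delta,
        s_delta=s_delta,
        lam=lam,
        regime="theorem_applies",
        p_bound=p_bound,
        significant=lam >= critical_lambda(alpha, tails),
        alpha=alpha,
        tails=tails,
    )


# ---------------------------------------------------------------------------
# Cauchy closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CauchyParams:
    """Location (median) and dispersion of a Cauchy law.

    The distribution has no mean and no variance; its 95% central interval is
    μ̂ ± tan(0.475π)·λ ≈ μ̂ ± 12.706·λ.
    """

    mu_hat: float = 0.0
    lam_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lam_scale <= 0:
            raise ValueError("lam_scale must be positive")


def cauchy_pdf(x, p: CauchyParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lam = p.lam_scale
    return (1.0 / math.pi) * lam / (lam * lam + (x - p.mu_hat) ** 2)


def cauchy_cdf(x, p: CauchyParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.arctan((x - p.mu_hat) / p.lam_scale) / math.pi + 0.5


def cauchy_quantile(q, p: CauchyParams) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("quantile levels must lie in (0, 1)")
    return p.mu_hat + p.lam_scale * np.tan(math.pi * (q - 0.5))
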