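"""Windowed spectral density and white-vs-Brownian classification.

The spectral density ψ_f = a_f² + b_f² is formed from the real and imaginary
FFT components of the mean-removed, windowed, zero-padded series.  On log-log
axes the density of white noise is flat while a Brownian random walk decays
like 1/f²; a robust (Theil) slope over the informative band therefore
separates the two.  The top decade of frequencies is excluded from slope fits
— discrete sampling contaminates it with rapid oscillations that carry no
information about the underlying process.  A series whose energy concentrates
in one dominant peak is periodic rather than a noise, and is reported as
indeterminate with a dominant-peak annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import fractal, nonparam

__all__ = [
    "Spectrum",
    "Classification",
    "spectral_density",
    "loglog_slope",
    "classify_series",
]

WINDOWS = ("hann", "hamming", "none")

#: slope above which the log-log spectral decay votes "white"
WHITE_SLOPE_CUT = -0.5
#: slope below which it votes "brownian" (1/f² decay is −2)
BROWNIAN_SLOPE_CUT = -1.2
#: peak-to-median ψ ratio flagging a dominant periodic component
DOMINANT_PEAK_RATIO = 100.0


@dataclass(frozen=True)
class Spectrum:
    """One-sided spectral density with window metadata.

    ``freqs`` are cycles per sample (equivalently per day for daily series),
    strictly increasing in (0, 0.5]; the zero-frequency term is excluded.
    """

    freqs: np.ndarray
    psi: np.ndarray
    window: str
    n_input: int
    n_padded: int


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def spectral_density(ys, window: str = "hann") -> Spectrum:
    """ψ_f from the FFT of the mean-removed, windowed, zero-padded series."""
    ys = np.asarray(ys, dtype=float)
    n = len(ys)
    if n < 16:
        raise ValueError("need at least 16 points")
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {WINDOWS}")
    y = ys - ys.mean()
    if np.all(y == 0):
        warnings.warn("constant input: spectrum is identically zero")
    if window == "hann":
        y = y * np.hanning(n)
    elif window == "hamming":
        y = y * np.hamming(n)
    npad = _next_pow2(n)
    coeffs = np.fft.rfft(y, npad)
    psi = coeffs.real**2 + coeffs.imag**2
    freqs = np.arange(1, npad // 2 + 1) / npad
    return Spectrum(
        freqs=freqs,
        psi=psi[1 : npad // 2 + 1],
        window=window,
        n_input=n,
        n_padded=npad,
    )


def loglog_slope(
    spec: Spectrum,
    fit_band: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Theil slope of log₁₀ ψ against log₁₀ f over the informative band.

    The default band spans all positive frequencies up to one tenth of the
    Nyquist frequency (excluding the artefact-contaminated top decade);
    zero-power bins are dropped before taking logs.
    """
    if fit_band is None:
        fit_band = (0.0, spec.freqs[-1] / 10.0)
    lo, hi = fit_band
    mask = (spec.freqs > lo) & (spec.freqs <= hi) & (spec.psi > 0)
    if mask.sum() < 16:
        raise ValueError("fewer than 16 usable frequencies in the fit band")
    fit = nonparam.theil_regression(
        np.log10(spec.freqs[mask]), np.log10(spec.psi[mask])
    )
    return fit.beta, fit.beta_ci


@dataclass(frozen=True)
class Classification:
    """Joint spectral-slope / dimension-band verdict for one series."""

    label: str  # "white_like" | "brownian_like" | "indeterminate"
    slope: float
    Ds: float
    slope_vote: str
    dimension_vote: str
    white_band: tuple[float, float]
    brownian_band: tuple[float, float]
    peak_ratio: float
    annotation: str = ""


@lru_cache(maxsize=32)
def _cached_ensemble(kind: str, n: int, m: int, seed: int):
    return fractal.calibrate(kind, n, m=m, seed=seed)


def _has_dominant_peak(psi: np.ndarray) -> bool:
    """A narrow spectral line: the peak towers over the median *and* over its
    own neighbourhood.  A 1/f² decay also spans orders of magnitude but is
    not isolated — bins a few steps from its maximum stay comparable."""
    peak = int(np.argmax(psi))
    if peak < 5:
        # a red spectrum's maximum sits at the lowest bins; a periodic line
        # this close to zero frequency is indistinguishable from a trend
        return False
    if psi[peak] <= DOMINANT_PEAK_RATIO * np.median(psi):
        return False
    ring = [
        psi[peak + off]
        for off in range(-10, 11)
        if abs(off) >= 3 and 0 <= peak + off < len(psi)
    ]
    # the median of the surrounding ring is robust to the exponential
    # scatter of individual periodogram ordinates
    return psi[peak] > 50.0 * np.median(ring)


def classify_series(
    ys,
    window: str = "hann",
    calib_m: int = 50,
    calib_seed: int = 0,
) -> Classification:
    """Label a series white-like or Brownian-like, or refuse to.

    Two independent votes are combined: the log-log spectral slope (flat vs
    1/f² decay) and the position of the series' dimension relative to
    matched-length calibration bands (D̄s ± 3·s_t).  The label is returned
    only when the votes agree; a dominant periodic peak short-circuits to
    indeterminate.
    """
    ys = np.asarray(ys, dtype=float)
    if len(ys) < 256:
        raise ValueError("need at least 256 points to classify")
    spec = spectral_density(ys, window=window)
    peak_ratio = float(spec.psi.max() / np.median(spec.psi))
    slope, _ = loglog_slope(spec)

    white = _cached_ensemble("white", len(ys), calib_m, calib_seed)
    brownian = _cached_ensemble("brownian", len(ys), calib_m, calib_seed)
    ds = fractal.sevcik_dimension(ys).Ds
    white_band = white.band()
    brownian_band = brownian.band()

    if slope > WHITE_SLOPE_CUT:
        slope_vote = "white_like"
    elif slope < BROWNIAN_SLOPE_CUT:
        slope_vote = "brownian_like"
    else:
        slope_vote = "none"

    if white_band[0] <= ds <= white_band[1]:
        dimension_vote = "white_like"
    elif brownian_band[0] <= ds <= brownian_band[1]:
        dimension_vote = "brownian_like"
    else:
        dimension_vote = "none"

    annotation = ""
    if _has_dominant_peak(spec.psi):
        label = "indeterminate"
        annotation = "dominant-peak"
    elif slope_vote == dimension_vote and slope_vote != "none":
        label = slope_vote
    else:
        label = "indeterminate"
    return Classification(
        label=label,
        slope=slope,
        Ds=ds,
        slope_vote=slope_vote,
        dimension_vote=dimension_vote,
        white_band=white_band,
        brownian_band=brownian_band,
        peak_ratio=peak_ratio,
        annotation=annotation,
    )
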