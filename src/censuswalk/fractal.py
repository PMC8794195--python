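"""Waveform fractal-dimension estimation with Monte Carlo calibration.

The estimator maps a uniformly sampled waveform into the unit square
(abscissa divided by its span, ordinate min-max normalised), measures the
embedded polyline length L over the N′ = N − 1 segments, and reports

    Ds = 1 + (ln L − ln 2) / ln(2·N′)

which converges to the Hausdorff–Besicovitch dimension only as N′ → ∞: at any
finite length it underestimates, so a Ds is only comparable against standards
of *matched length*.  The estimator's within-trace variance follows from the
dispersion of the embedded segment lengths Δyᵢ:

    var(Ds) = Σᵢ (Δyᵢ − Δȳ)² / (L · ln(2·N′))²

(the printed grouping with the N′ factors cancelled).  Calibration ensembles
run M seeded traces of a named standard noise (white: i.i.d. N(0,1) deviates;
brownian: the unit-Gaussian random walk) at the analysed series' exact length
and summarise the mean dimension together with the between-trace variance,
the mean within-trace variance, and their sum (the total variance used by the
distribution-free comparison in :mod:`censuswalk.vpstats`).

With N = 1329 the white standard sits near D̄s ≈ 1.60 and the Brownian
standard near D̄s ≈ 1.29, far below their infinite-length limits of 2 and 1.5.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthgen

__all__ = [
    "EmbeddedCurve",
    "SevcikResult",
    "CalibrationEnsemble",
    "embed_unit_square",
    "sevcik_dimension",
    "calibrate",
]

CALIBRATION_KINDS = ("white", "brownian")


@dataclass(frozen=True)
class EmbeddedCurve:
    """A waveform normalised into the unit square."""

    xstar: np.ndarray
    ystar: np.ndarray
    L: float
    N: int
    Nprime: int
    segment_lengths: np.ndarray


@dataclass(frozen=True)
class SevcikResult:
    """Fractal-dimension estimate of a single waveform."""

    Ds: float
    varDs: float
    L: float
    Nprime: int

    @property
    def sDs(self) -> float:
        return math.sqrt(self.varDs)


def embed_unit_square(ys, xs=None) -> EmbeddedCurve:
    """Normalise a uniformly sampled waveform into the unit square.

    The abscissa must start at 0 and increase with constant spacing (the
    default is 0..N−1), which makes the printed x/(x_max − x_min) transform
    identical to full min-max normalisation.  Flat waveforms (y_max = y_min)
    cannot be embedded and raise; callers wanting the degenerate convention
    should use :func:`sevcik_dimension`.
    """
    ys = np.asarray(ys, dtype=float)
    n = len(ys)
    if n < 2:
        raise ValueError("need at least 2 points to embed")
    if np.isnan(ys).any():
        raise ValueError("cannot embed a series with missing values")
    if xs is None:
        xs = np.arange(n, dtype=float)
    else:
        xs = np.asarray(xs, dtype=float)
        if len(xs) != n:
            raise ValueError("xs and ys must have equal length")
        steps = np.diff(xs)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("abscissa must be strictly increasing with constant spacing")
        if xs[0] != 0:
            raise ValueError("abscissa must start at 0")
    ymin, ymax = ys.min(), ys.max()
    if ymax == ymin:
        raise ValueError("flat waveform: y_max equals y_min")
    span = xs[-1] - xs[0]
    xstar = xs / span
    ystar = (ys - ymin) / (ymax - ymin)
    segments = np.hypot(np.diff(xstar), np.diff(ystar))
    return EmbeddedCurve(
        xstar=xstar,
        ystar=ystar,
        L=float(segments.sum()),
        N=n,
        Nprime=n - 1,
        segment_lengths=segments,
    )


def sevcik_dimension(ys, xs=None) -> SevcikResult:
    """Estimate the fractal dimension of a waveform.

    A constant waveform is topologically one-dimensional and returns
    Ds = 1 with zero variance (with a warning): the embedding itself is
    undefined there.
    """
    ys = np.asarray(ys, dtype=float)
    if len(ys) < 3:
        raise ValueError("need at least 3 points for a dimension estimate")
    if ys.max() == ys.min():
        warnings.warn("flat waveform: returning the topological dimension Ds = 1")
        return SevcikResult(Ds=1.0, varDs=0.0, L=1.0, Nprime=len(ys) - 1)
    curve = embed_unit_square(ys, xs=xs)
    log2n = math.log(2.0 * curve.Nprime)
    ds = 1.0 + (math.log(curve.L) - math.log(2.0)) / log2n
    seg = curve.segment_lengths
    var = float(np.sum((seg - seg.mean()) ** 2)) / (curve.L * log2n) ** 2
    return SevcikResult(Ds=ds, varDs=var, L=curve.L, Nprime=curve.Nprime)


@dataclass(frozen=True)
class CalibrationEnsemble:
    """Monte Carlo reference band for a standard noise at a fixed length.

    ``var_total = var_between + var_within_mean`` holds by construction; the
    square root of ``var_total`` is the spread attached to ``Dbar`` when the
    ensemble enters a dimension comparison.
    """

    kind: str
    M: int
    N: int
    Dbar: float
    var_between: float
    var_within_mean: float
    seed: int
    Ds_values: tuple[float, ...] = field(default=(), repr=False)

    @property
    def var_total(self) -> float:
        return self.var_between + self.var_within_mean

    @property
    def s_total(self) -> float:
        return math.sqrt(self.var_total)

    def band(self, width: float = 3.0) -> tuple[float, float]:
        """The D̄s ± width·s_t interval used for band-membership checks."""
        return (self.Dbar - width * self.s_total, self.Dbar + width * self.s_total)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "M": self.M,
            "N": self.N,
            "Dbar": self.Dbar,
            "var_between": self.var_between,
            "var_within_mean": self.var_within_mean,
            "var_total": self.var_total,
            "seed": self.seed,
            "Ds_values": list(self.Ds_values),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationEnsemble":
        return cls(
            kind=data["kind"],
            M=int(data["M"]),
            N=int(data["N"]),
            Dbar=float(data["Dbar"]),
            var_between=float(data["var_between"]),
            var_within_mean=float(data["var_within_mean"]),
            seed=int(data["seed"]),
            Ds_values=tuple(data.get("Ds_values", ())),
        )


def _standard_trace(kind: str, n: int, seed: int) -> np.ndarray:
    spec = synthgen.NoiseSpec(kind="gaussian" if kind == "white" else "brownian",
                              length=n, seed=seed)
    return synthgen.generate(spec)


def calibrate(
    kind: str,
    n: int,
    m: int = 100,
    seed: int = 0,
    cache_dir=None,
) -> CalibrationEnsemble:
    """Build (or load from cache) a calibration ensemble.

    M seeded traces of the named standard are generated (per-trace seeds are
    spawned from the master seed), each trace's dimension and within-trace
    variance computed, and the ensemble summarised by the mean dimension,
    the between-trace variance (denominator M − 1), the mean within-trace
    variance, and their sum.
    """
    if kind not in CALIBRATION_KINDS:
        raise ValueError(f"unknown calibration kind {kind!r}")
    if m < 2:
        raise ValueError("need at least 2 traces")
    if n < 3:
        raise ValueError("need at least 3 points per trace")

    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"{kind}_N{n}_M{m}_seed{seed}.json"
        if cache_path.exists():
            with open(cache_path) as fh:
                return CalibrationEnsemble.from_dict(json.load(fh))

    trace_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    ds_values = np.empty(m)
    var_within = np.empty(m)
    for j in range(m):
        result = sevcik_dimension(_standard_trace(kind, n, int(trace_seeds[j])))
        ds_values[j] = result.Ds
        var_within[j] = result.varDs

    ensemble = CalibrationEnsemble(
        kind=kind,
        M=m,
        N=n,
        Dbar=float(ds_values.mean()),
        var_between=float(ds_values.var(ddof=1)),
        var_within_mean=float(var_within.mean()),
        seed=seed,
        Ds_values=tuple(float(v) for v in ds_values),
    )
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        with open(cache_path, "w") as fh:
            json.dump(ensemble.to_dict(), fh)
    return ensemble
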