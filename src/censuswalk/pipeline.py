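"""End-to-end analysis: clean, derive, estimate, calibrate, compare, report.

The pipeline mirrors the study design: after cleaning, six series are
dimension-estimated (admissions, discharges, in-patients, the two daily
difference series, and the Ξ walk rebuilt from the admissions-minus-
discharges difference), calibration ensembles of white and Brownian standards
are run at the *exact* series length, and the full pairwise matrix of
distribution-free dimension comparisons is formed — never comparing
dimensions across different lengths, since the finite-length bias of the
estimator would otherwise masquerade as a real difference.  The headline
check the report surfaces is InP-vs-Ξ: when the two are statistically
indistinguishable, the census meandering is fully explained by the
discharge-to-admission lag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import fractal, ingest, nonparam, spectral, vpstats

__all__ = ["AnalysisConfig", "AnalysisReport", "PipelineError", "run_pipeline",
           "render_text"]

SERIES_ORDER = ("adm", "dis", "inp", "dinp", "ddiad", "xi")
MATRIX_ORDER = SERIES_ORDER + ("brownian", "white")


class PipelineError(RuntimeError):
    """A stage failure with the stage name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one full pipeline run."""

    input: str
    dialect: str = "csv"
    beds: int = 192
    calib_m: int = 100
    seed: int = 1
    alpha: float = 0.05
    window: str = "hann"
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.calib_m < 2:
            raise ValueError("calib_m must be >= 2")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisReport:
    """Serializable record of one pipeline run."""

    seed: int
    n_days: int
    cleaning_log: list
    dimensions: dict  # name -> {"Ds": ..., "varDs": ..., "L": ..., "Nprime": ...}
    ensembles: dict  # kind -> CalibrationEnsemble dict
    comparisons: dict  # "a|b" -> VPComparison dict
    runs: dict
    occupancy: dict
    smirnov: dict
    classifications: dict
    software: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _sevcik_dict(result: fractal.SevcikResult) -> dict:
    return {
        "Ds": result.Ds,
        "varDs": result.varDs,
        "sDs": result.sDs,
        "L": result.L,
        "Nprime": result.Nprime,
    }


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis on a command-panel file."""
    from . import __version__

    try:
        panel = ingest.load_panel(
            config.input,
            dialect=config.dialect,
            beds=config.beds,
            column_map=config.column_map,
        )
        if panel.n == 0:
            raise ingest.PanelLoadError("empty input")
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc

    try:
        panel, log = ingest.clean(panel)
    except ValueError as exc:
        raise PipelineError("clean", str(exc)) from exc

    try:
        dinp = ingest.daily_diff(panel.inp, parent="inp")
        dd = ingest.ddiad(panel)
        xi = ingest.reconstruct_walk(dd)
        series = {
            "adm": panel.adm,
            "dis": panel.dis,
            "inp": panel.inp,
            "dinp": dinp.values,
            "ddiad": dd.values,
            "xi": xi.values,
        }
    except ValueError as exc:
        raise PipelineError("derive", str(exc)) from exc

    try:
        dims = {name: fractal.sevcik_dimension(values)
                for name, values in series.items()}
    except ValueError as exc:
        raise PipelineError("estimate", str(exc)) from exc

    # Calibration at the analysed length, with child seeds spawned from the
    # master seed (kept below 2^31 for portability).
    child = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    ensembles = {
        "white": fractal.calibrate("white", panel.n, m=config.calib_m,
                                   seed=int(child[0])),
        "brownian": fractal.calibrate("brownian", panel.n, m=config.calib_m,
                                      seed=int(child[1])),
    }

    items: dict[str, object] = {name: dims[name] for name in SERIES_ORDER}
    items["brownian"] = ensembles["brownian"]
    items["white"] = ensembles["white"]
    comparisons = {}
    for i, a in enumerate(MATRIX_ORDER):
        for b in MATRIX_ORDER[i + 1 :]:
            comp = vpstats.compare_dimensions(items[a], items[b],
                                              alpha=config.alpha)
            comparisons[f"{a}|{b}"] = comp.to_dict()

    try:
        runs = dataclasses.asdict(nonparam.runs_test(panel.inp))
        occ = dataclasses.asdict(ingest.occupancy_stats(panel))
        occ["occupancy_median_pct"] = 100.0 * occ["median"] / occ["beds"]
        occ["occupancy_range_pct"] = [
            100.0 * occ["minimum"] / occ["beds"],
            100.0 * occ["maximum"] / occ["beds"],
        ]
        smirnov = {}
        d, p = nonparam.smirnov_two_sample(series["dinp"], series["ddiad"])
        smirnov["dinp|ddiad"] = {"D": d, "p": p}
        d, p = nonparam.smirnov_two_sample(panel.adm, panel.dis)
        smirnov["adm|dis"] = {"D": d, "p": p}
    except ValueError as exc:
        raise PipelineError("nonparam", str(exc)) from exc

    classifications = {}
    if panel.n >= 256:
        for name in ("inp", "ddiad"):
            cls = spectral.classify_series(
                series[name], window=config.window, calib_seed=int(child[0])
            )
            classifications[name] = {
                "label": cls.label,
                "slope": cls.slope,
                "Ds": cls.Ds,
                "annotation": cls.annotation,
            }

    return AnalysisReport(
        seed=config.seed,
        n_days=panel.n,
        cleaning_log=log,
        dimensions={k: _sevcik_dict(v) for k, v in dims.items()},
        ensembles={k: v.to_dict() for k, v in ensembles.items()},
        comparisons=comparisons,
        runs=runs,
        occupancy=occ,
        smirnov=smirnov,
        classifications=classifications,
        software={"package": "censuswalk", "version": __version__},
    )


def render_text(report: AnalysisReport) -> str:
    """Plain-text rendering: a dimension table and a significance matrix."""
    lines = [f"censuswalk report  (seed={report.seed}, n={report.n_days} days)", ""]
    lines.append(f"{'series':>10}  {'Ds':>8}  {'s(Ds)':>9}")
    for name in SERIES_ORDER:
        d = report.dimensions[name]
        lines.append(f"{name:>10}  {d['Ds']:8.5f}  {d['sDs']:9.2e}")
    for kind in ("brownian", "white"):
        e = report.ensembles[kind]
        lines.append(
            f"{kind:>10}  {e['Dbar']:8.5f}  {np.sqrt(e['var_total']):9.2e}"
            f"  (M={e['M']} ensemble)"
        )
    lines.append("")
    lines.append("pairwise dimension comparisons (one-tailed V-P bound):")
    header = " " * 10 + "".join(f"{b:>10}" for b in MATRIX_ORDER[1:])
    lines.append(header)
    for i, a in enumerate(MATRIX_ORDER[:-1]):
        row = [f"{a:>10}"]
        for b in MATRIX_ORDER[1:]:
            key = f"{a}|{b}"
            if key not in report.comparisons:
                row.append(f"{'...':>10}")
                continue
            comp = report.comparisons[key]
            if comp["regime"] == "corollary":
                cell = "[1/6,1]"
            else:
                cell = f"{comp['p_bound']:.2e}"
                if comp["significant"]:
                    cell += "*"
            row.append(f"{cell:>10}")
        lines.append("".join(row))
    lines.append("")
    occ = report.occupancy
    lines.append(
        "occupancy: median {median:.1f} beds ({ci_low:.0f}-{ci_high:.0f}), "
        "{pct:.1f}% of {beds} beds, range {lo:.1f}-{hi:.1f}%".format(
            median=occ["median"],
            ci_low=occ["ci_low"],
            ci_high=occ["ci_high"],
            pct=occ["occupancy_median_pct"],
            beds=occ["beds"],
            lo=occ["occupancy_range_pct"][0],
            hi=occ["occupancy_range_pct"][1],
        )
    )
    runs = report.runs
    lines.append(
        f"runs about the median (inp): {runs['n_runs']} runs over "
        f"{runs['n_used']} usable days, P(R<=obs) = {runs['p_lower']:.3g}"
    )
    for name, cls in report.classifications.items():
        lines.append(
            f"classification {name}: {cls['label']} "
            f"(slope {cls['slope']:.2f}, Ds {cls['Ds']:.4f})"
        )
    return "\n".join(lines) + "\n"
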