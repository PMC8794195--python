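"""Reading, cleaning and deriving daily hospital census series.

A command-panel export is three aligned daily integer series: admissions
(``adm``), discharges (``dis``) and in-patients (``inp``), indexed by a 0-based
day counter.  Raw exports contain two kinds of recording artifact that must be
repaired before any differencing: impossible New-Year spikes (a year-rollover
bug producing counts far above the bed capacity) and contiguous gaps of missing
days.  Cleaning replaces a spiked value by the mean of its flanking days and
bridges a gap with a constant daily change, flagging every touched day.

From a clean panel three derived series are formed: the one-day differences
``Δy_t`` (``Δy_0 = 0``), the daily admissions-minus-discharges difference
(DDiAd), and the random walk ``Ξ`` obtained by accumulating a difference series
from zero.  Accumulating DDiAd and adding the initial census reproduces the
in-patient series exactly on artifact-free data, which is the conservation
identity the rest of the pipeline leans on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelSeries",
    "DiffSeries",
    "WalkSeries",
    "UnitSeries",
    "OccupancySummary",
    "load_panel",
    "write_panel_csv",
    "fix_new_year",
    "fill_gap",
    "find_gaps",
    "clean",
    "daily_diff",
    "ddiad",
    "reconstruct_walk",
    "mean_los",
    "occupancy_stats",
]

COLUMNS = ("adm", "dis", "inp")

#: cleaning flags
NEWYEAR_CORRECTED = "newyear_corrected"
GAP_FILLED = "gap_filled"


class PanelLoadError(ValueError):
    """Raised when a panel file fails validation."""


@dataclass
class PanelSeries:
    """Aligned daily count series with a 0-based day index.

    Values are stored as float64 so that missing cells can be carried as NaN
    before cleaning and so that gap-filled values need not be integers.
    """

    adm: np.ndarray
    dis: np.ndarray
    inp: np.ndarray
    beds: int
    dates: pd.DatetimeIndex | None = None
    flags: dict[int, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adm = np.asarray(self.adm, dtype=float)
        self.dis = np.asarray(self.dis, dtype=float)
        self.inp = np.asarray(self.inp, dtype=float)
        n = len(self.adm)
        if len(self.dis) != n or len(self.inp) != n:
            raise ValueError("adm, dis and inp must have equal length")
        if self.beds <= 0:
            raise ValueError("beds must be a positive integer")
        if self.dates is not None and len(self.dates) != n:
            raise ValueError("dates must align with the series")

    @property
    def n(self) -> int:
        return len(self.adm)

    @property
    def day_index(self) -> np.ndarray:
        return np.arange(self.n)

    def column(self, name: str) -> np.ndarray:
        if name not in COLUMNS:
            raise KeyError(f"unknown column {name!r}; expected one of {COLUMNS}")
        return getattr(self, name)

    def copy(self) -> "PanelSeries":
        return PanelSeries(
            adm=self.adm.copy(),
            dis=self.dis.copy(),
            inp=self.inp.copy(),
            beds=self.beds,
            dates=self.dates,
            flags={d: set(f) for d, f in self.flags.items()},
        )

    def add_flag(self, day: int, flag: str) -> None:
        self.flags.setdefault(int(day), set()).add(flag)

    def has_missing(self) -> bool:
        return bool(
            np.isnan(self.adm).any()
            or np.isnan(self.dis).any()
            or np.isnan(self.inp).any()
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"day": self.day_index, "adm": self.adm, "dis": self.dis, "inp": self.inp}
        )
        if self.dates is not None:
            frame.insert(1, "date", self.dates.strftime("%Y-%m-%d"))
        return frame


@dataclass(frozen=True)
class DiffSeries:
    """A per-day difference series.

    ``convention`` records whether element 0 follows the Δy₀ = 0 rule
    (one-day differences) or is a raw same-day difference (DDiAd).
    """

    values: np.ndarray
    parent: str
    convention: str = "zero_origin"  # or "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WalkSeries:
    """A random walk accumulated from a difference series, starting at 0."""

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class UnitSeries:
    """Per-unit daily in-patient count and mean length of stay."""

    unit: str
    inp: np.ndarray
    mean_los: np.ndarray


# ---------------------------------------------------------------------------
# Loading / writing the canonical CSV dialect and workbook sheets
# ---------------------------------------------------------------------------


def _validate_counts(frame: pd.DataFrame, path: str, strict_integers: bool = True) -> None:
    if "day" not in frame.columns:
        raise PanelLoadError(f"{path}: missing required 'day' column")
    for col in COLUMNS:
        if col not in frame.columns:
            raise PanelLoadError(f"{path}: missing required column {col!r}")
    day = frame["day"].to_numpy()
    if np.any(np.diff(day) <= 0):
        bad = int(np.argmax(np.diff(day) <= 0)) + 1
        raise PanelLoadError(f"{path}: day index not strictly increasing at row {bad}")
    if len(np.unique(day)) != len(day):
        raise PanelLoadError(f"{path}: duplicate day indices")
    for col in COLUMNS:
        raw = frame[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise PanelLoadError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r} "
                f"at row {row}"
            )
        present = numeric.dropna()
        if strict_integers and not np.all(present == np.round(present)):
            row = int(present.index[present != np.round(present)][0])
            raise PanelLoadError(
                f"{path}: non-integer count in column {col!r} at row {row}"
            )
        frame[col] = numeric


def load_panel(
    path,
    dialect: str = "csv",
    beds: int = 192,
    column_map: dict | None = None,
    strict_integers: bool = True,
) -> PanelSeries:
    """Read a daily panel from the canonical CSV dialect or a workbook sheet.

    The canonical CSV has columns ``day`` (0-based integer), optional ``date``
    (ISO-8601) and integer ``adm``/``dis``/``inp`` with empty cells for missing
    values.  For ``dialect='workbook'`` a ``column_map`` must describe the
    sheet: ``{"sheet": name, "header_row": int, "columns": {"day": "A", ...}}``
    with spreadsheet column letters.  Raw series are returned as-is; missing
    cells stay missing and no cleaning is applied.  Raw exports must carry
    integer counts; ``strict_integers=False`` admits the real-valued cells a
    cleaned, gap-bridged series legitimately contains.
    """
    if dialect == "csv":
        frame = pd.read_csv(path, dtype={"day": int})
    elif dialect == "workbook":
        if column_map is None:
            raise PanelLoadError("workbook dialect requires a column_map")
        raw = pd.read_excel(
            path,
            sheet_name=column_map.get("sheet", 0),
            header=None,
            engine="openpyxl",
        )
        header_row = int(column_map.get("header_row", 0))
        body = raw.iloc[header_row + 1 :]
        data = {}
        for name, letter in column_map["columns"].items():
            idx = _column_letter_to_index(letter)
            if idx >= body.shape[1]:
                raise PanelLoadError(f"column letter {letter!r} outside sheet")
            data[name] = body.iloc[:, idx].reset_index(drop=True)
        frame = pd.DataFrame(data)
        frame["day"] = pd.to_numeric(frame["day"]).astype(int)
    else:
        raise PanelLoadError(f"unknown dialect {dialect!r}")

    _validate_counts(frame, str(path), strict_integers=strict_integers)
    dates = None
    if "date" in frame.columns and frame["date"].notna().any():
        dates = pd.DatetimeIndex(pd.to_datetime(frame["date"]))
        if dates.duplicated().any():
            raise PanelLoadError(f"{path}: duplicate dates")
        if not dates.is_monotonic_increasing:
            raise PanelLoadError(f"{path}: non-monotone dates")
    return PanelSeries(
        adm=frame["adm"].to_numpy(dtype=float),
        dis=frame["dis"].to_numpy(dtype=float),
        inp=frame["inp"].to_numpy(dtype=float),
        beds=beds,
        dates=dates,
    )


def _column_letter_to_index(letter: str) -> int:
    idx = 0
    for ch in letter.strip().upper():
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx - 1


def write_panel_csv(series: PanelSeries, path) -> None:
    """Write the canonical CSV dialect (integer cells, empty cell = missing)."""
    frame = series.to_frame()
    for col in COLUMNS:
        frame[col] = frame[col].map(
            lambda v: "" if np.isnan(v) else (str(int(v)) if v == int(v) else repr(v))
        )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning rules
# ---------------------------------------------------------------------------


def fix_new_year(
    series: PanelSeries,
    suspect_days: Sequence[int] | str | None = None,
    log: list | None = None,
) -> PanelSeries:
    """Repair impossible year-rollover spikes.

    A suspect day whose count in any column exceeds the bed capacity (the
    impossibility criterion for a hospital of ``beds`` beds) is replaced by
    the arithmetic mean of its flanking days.  Suspect days come from the
    date index (every January 1), from an explicit list, or — with
    ``suspect_days='auto'`` — from scanning for any value above capacity.
    """
    if suspect_days is None:
        if series.dates is None:
            raise ValueError(
                "fix_new_year needs dates, an explicit suspect-day list, "
                "or suspect_days='auto'"
            )
        suspects = [
            int(i)
            for i, d in enumerate(series.dates)
            if d.month == 1 and d.day == 1
        ]
    elif isinstance(suspect_days, str):
        if suspect_days != "auto":
            raise ValueError("suspect_days must be a list, 'auto', or None")
        with np.errstate(invalid="ignore"):
            mask = (
                (series.adm > series.beds)
                | (series.dis > series.beds)
                | (series.inp > series.beds)
            )
        suspects = [int(i) for i in np.nonzero(mask)[0]]
    else:
        suspects = [int(d) for d in suspect_days]

    out = series.copy()
    suspect_set = set(suspects)
    for day in suspects:
        for col in COLUMNS:
            values = out.column(col)
            value = values[day]
            if np.isnan(value) or value <= out.beds:
                continue
            if day == 0 or day == out.n - 1:
                raise ValueError(
                    f"suspect day {day} at series boundary: no flanking pair"
                )
            for flank in (day - 1, day + 1):
                flank_val = values[flank]
                if np.isnan(flank_val):
                    raise ValueError(
                        f"flank day {flank} of suspect day {day} is missing"
                    )
                if flank in suspect_set and flank_val > out.beds:
                    raise ValueError(
                        f"consecutive spike days {day} and {flank}: "
                        "flanking rule cannot apply"
                    )
            replacement = 0.5 * (values[day - 1] + values[day + 1])
            values[day] = replacement
            out.add_flag(day, NEWYEAR_CORRECTED)
            if log is not None:
                log.append(
                    {
                        "day": day,
                        "column": col,
                        "rule": NEWYEAR_CORRECTED,
                        "old": float(value),
                        "new": float(replacement),
                    }
                )
    return out


def find_gaps(series: PanelSeries) -> list[tuple[str, int, int]]:
    """Maximal runs of missing values, as (column, start_day, length)."""
    gaps = []
    for col in COLUMNS:
        missing = np.isnan(series.column(col))
        i = 0
        while i < series.n:
            if missing[i]:
                j = i
                while j < series.n and missing[j]:
                    j += 1
                gaps.append((col, i, j - i))
                i = j
            else:
                i += 1
    return gaps


def fill_gap(
    series: PanelSeries,
    gap_start: int,
    gap_len: int,
    columns: Iterable[str] | None = None,
    log: list | None = None,
) -> PanelSeries:
    """Bridge a contiguous gap with a constant daily change.

    The change per day is ``(y_after − y_before) / gap_len`` applied
    cumulatively from the flank before the gap, so the last filled day lands
    exactly on the after-flank value (a 9-day gap divides the flank-to-flank
    jump by 9).  Filled values are kept as reals so telescoping identities of
    the difference series hold exactly.
    """
    if gap_len <= 0:
        raise ValueError("gap_len must be positive")
    if gap_start <= 0 or gap_start + gap_len >= series.n:
        raise ValueError("gap touches the series boundary: no flanking pair")
    out = series.copy()
    cols = list(columns) if columns is not None else [
        c
        for c in COLUMNS
        if np.isnan(out.column(c)[gap_start : gap_start + gap_len]).all()
    ]
    if not cols:
        raise ValueError(
            f"no column is fully missing on days "
            f"[{gap_start}, {gap_start + gap_len - 1}]"
        )
    for col in cols:
        values = out.column(col)
        window = values[gap_start : gap_start + gap_len]
        if not np.isnan(window).all():
            raise ValueError(
                f"column {col!r} is not missing across the declared gap"
            )
        before = values[gap_start - 1]
        after = values[gap_start + gap_len]
        if np.isnan(before) or np.isnan(after):
            raise ValueError("flank of the gap is itself missing")
        step = (after - before) / gap_len
        for k in range(1, gap_len + 1):
            day = gap_start + k - 1
            values[day] = before + k * step
            out.add_flag(day, GAP_FILLED)
            if log is not None:
                log.append(
                    {
                        "day": day,
                        "column": col,
                        "rule": GAP_FILLED,
                        "old": None,
                        "new": float(values[day]),
                    }
                )
    return out


def clean(series: PanelSeries) -> tuple[PanelSeries, list[dict]]:
    """Apply both cleaning rules and return the cleaned panel plus a log.

    New-Year spikes are located by the impossibility criterion (value above
    bed capacity), then every maximal missing run is bridged.  The result has
    no missing values and satisfies ``0 <= inp <= beds``; only flagged days
    differ from the input.
    """
    log: list[dict] = []
    out = fix_new_year(series, suspect_days="auto", log=log)
    for col, start, length in find_gaps(out):
        out = fill_gap(out, start, length, columns=[col], log=log)
    return out, log


def write_cleaning_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1)


# ---------------------------------------------------------------------------
# Derived series
# ---------------------------------------------------------------------------


def daily_diff(values: np.ndarray | Sequence[float], parent: str = "") -> DiffSeries:
    """One-day differences with the Δy₀ = 0 convention."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("daily_diff requires a cleaned series without missing values")
    out = np.empty_like(values)
    out[0] = 0.0
    out[1:] = np.diff(values)
    return DiffSeries(values=out, parent=parent, convention="zero_origin")


def ddiad(series: PanelSeries) -> DiffSeries:
    """Daily admissions − discharges (the walk-generating difference)."""
    if np.isnan(series.adm).any() or np.isnan(series.dis).any():
        raise ValueError("ddiad requires a cleaned series without missing values")
    return DiffSeries(
        values=series.adm - series.dis, parent="adm-dis", convention="raw"
    )


def reconstruct_walk(diff: DiffSeries) -> WalkSeries:
    """Accumulate a difference series into a random walk starting at 0.

    Element 0 of the input is not accumulated (the walk's origin convention),
    so accumulating DDiAd and adding the day-0 census reproduces the
    in-patient series exactly on artifact-free data.
    """
    if len(diff) == 0:
        raise ValueError("cannot accumulate an empty difference series")
    values = diff.values.copy()
    values[0] = 0.0
    return WalkSeries(values=np.cumsum(values), source=diff.parent)


def mean_los(stays_per_day: Sequence[Sequence[float]], unit: str = "") -> UnitSeries:
    """Mean accumulated stay duration over the patients present each day.

    Days with no patients are undefined (NaN), not zero.
    """
    counts = []
    means = []
    for day_stays in stays_per_day:
        stays = np.asarray(list(day_stays), dtype=float)
        if (stays < 0).any():
            raise ValueError("negative stay duration")
        counts.append(len(stays))
        means.append(float(stays.mean()) if len(stays) else np.nan)
    return UnitSeries(unit=unit, inp=np.array(counts, dtype=float),
                      mean_los=np.array(means))


@dataclass(frozen=True)
class OccupancySummary:
    """Robust location summary of the in-patient census."""

    median: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float
    beds: int

    @property
    def occupancy_median_pct(self) -> float:
        return 100.0 * self.median / self.beds

    @property
    def occupancy_range_pct(self) -> tuple[float, float]:
        return (100.0 * self.minimum / self.beds, 100.0 * self.maximum / self.beds)


def occupancy_stats(series: PanelSeries, conf: float = 0.95) -> OccupancySummary:
    """Hodges–Lehmann median (with CI), range, and the same as % of beds."""
    from .nonparam import hl_median_ci

    inp = series.inp
    if np.isnan(inp).any():
        raise ValueError("occupancy_stats requires a cleaned series")
    estimate, lo, hi = hl_median_ci(inp, conf=conf)
    return OccupancySummary(
        median=estimate,
        ci_low=lo,
        ci_high=hi,
        minimum=float(inp.min()),
        maximum=float(inp.max()),
        beds=series.beds,
    )
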