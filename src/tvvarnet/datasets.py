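"""Daily-diary dataset container, screening rules, segment selection, standardization.

A participant's diary is held on a contiguous daily calendar grid: days the
participant never logged appear as all-missing rows, so row index differences
always equal calendar-day differences. Missing entries are NaN with a parallel
boolean mask (True = observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DiaryDataset",
    "InclusionReport",
    "ScalingParams",
    "load_diary_csv",
    "screen_inclusion",
    "select_longest_segment",
    "z_standardize",
]


@dataclass
class DiaryDataset:
    """Multivariate daily time series for one participant.

    Attributes
    ----------
    participant_id : str
    dates : pd.DatetimeIndex
        Strictly increasing, step exactly one day.
    values : (T, p) float array
        NaN where ``mask`` is False.
    mask : (T, p) bool array
        True where observed.
    var_names : list of str
    standardized : bool
        True once each variable's observed entries have mean 0, SD 1.
    """

    participant_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray
    var_names: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (T, p)")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("dates length does not match values")
        if len(self.var_names) != self.values.shape[1]:
            raise ValueError("var_names length does not match values")
        diffs = np.diff(self.dates.view("int64"))
        if len(diffs) and not np.all(diffs == 86_400_000_000_000):
            raise ValueError("dates must be strictly increasing with step 1 day")
        # missing sentinel is NaN, enforced
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates, columns=self.var_names)


@dataclass
class InclusionReport:
    """Outcome of the screening rules for one participant."""

    participant_id: str
    n_days: int
    missing_frac_per_var: np.ndarray
    included: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class ScalingParams:
    """Per-variable mean and SD used for z-standardization (sample SD, ddof=1)."""

    mean: np.ndarray
    sd: np.ndarray

    def inverse(self, ds: DiaryDataset) -> DiaryDataset:
        """Undo standardization, returning a raw-scale copy."""
        raw = ds.values * self.sd[None, :] + self.mean[None, :]
        return replace(ds, values=raw, mask=ds.mask.copy(), standardized=False)


def load_diary_csv(
    path,
    date_column: str = "date",
    var_columns: list[str] | None = None,
    participant_id: str | None = None,
) -> DiaryDataset:
    """Read a wide daily-diary CSV onto a contiguous daily grid.

    Empty cells are missing. Calendar days absent from the file become
    all-missing rows. Duplicate dates are an error.
    """
    df = pd.read_csv(path)
    if date_column not in df.columns:
        raise ValueError(f"date column {date_column!r} not found")
    try:
        dates = pd.to_datetime(df[date_column], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable dates in column {date_column!r}: {exc}") from exc
    if dates.duplicated().any():
        dupes = dates[dates.duplicated()].dt.date.unique()
        raise ValueError(f"duplicate dates: {list(dupes)}")
    if var_columns is None:
        var_columns = [c for c in df.columns if c != date_column]
    if not var_columns:
        raise ValueError("zero usable variables")
    vals = df[var_columns].apply(pd.to_numeric, errors="raise")
    vals.index = dates
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    vals = vals.reindex(full)
    values = vals.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    pid = participant_id if participant_id is not None else str(getattr(path, "stem", path))
    return DiaryDataset(pid, full, values, mask, list(var_columns))


def screen_inclusion(
    ds: DiaryDataset, min_days: int = 130, max_missing_frac: float = 0.30
) -> InclusionReport:
    """Apply the inclusion rules: at least ``min_days`` days of data and a
    missing fraction strictly below ``max_missing_frac`` for every variable.

    The fraction's denominator is the full span of the loaded series.
    Screening never raises on content.
    """
    miss = 1.0 - ds.mask.mean(axis=0)
    reasons = []
    if ds.T < min_days:
        reasons.append("min_days")
    if np.any(miss >= max_missing_frac):
        reasons.append("missingness")
    return InclusionReport(ds.participant_id, ds.T, miss, not reasons, reasons)


def _barrier_days(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Days belonging to any item-wise missing run strictly longer than max_gap.

    Such runs delimit the analyzable phases of the series: no phase may
    contain any part of one (the run would otherwise be imputed).
    """
    T, p = mask.shape
    barrier = np.zeros(T, dtype=bool)
    for j in range(p):
        miss = ~mask[:, j]
        t = 0
        while t < T:
            if miss[t]:
                s = t
                while t < T and miss[t]:
                    t += 1
                if t - s > max_gap:
                    barrier[s:t] = True
            else:
                t += 1
    return barrier


def select_longest_segment(ds: DiaryDataset, max_gap_days: int = 7) -> DiaryDataset:
    """Longest contiguous phase free of item-wise missing runs > ``max_gap_days``.

    Runs of more than ``max_gap_days`` consecutive missing days (for any
    variable, counted item-wise on the full series) split the series into
    phases; the longest phase wins, ties broken by earliest start, and
    everything outside it is discarded. A run of exactly ``max_gap_days``
    splits nothing (the rule is strict), so such gaps survive to be imputed.
    """
    T = ds.T
    barrier = _barrier_days(ds.mask, max_gap_days)
    best_start, best_len = 0, 0
    t = 0
    while t < T:
        if barrier[t]:
            t += 1
            continue
        s = t
        while t < T and not barrier[t]:
            t += 1
        if t - s > best_len:
            best_start, best_len = s, t - s
    if best_len < 2:
        raise ValueError("no analyzable segment of length >= 2 exists")
    sl = slice(best_start, best_start + best_len)
    return DiaryDataset(
        ds.participant_id,
        ds.dates[sl],
        ds.values[sl].copy(),
        ds.mask[sl].copy(),
        list(ds.var_names),
        ds.standardized,
    )


def z_standardize(ds: DiaryDataset) -> tuple[DiaryDataset, ScalingParams]:
    """Z-transform each variable over its observed entries (mean 0, sample SD 1).

    The lasso penalizes coefficients on a common scale, so unequal variances
    would distort shrinkage; estimation therefore consumes standardized data
    only. Constant variables are an error.
    """
    mean = np.nanmean(ds.values, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(ds.values, axis=0, ddof=1)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        bad = [ds.var_names[j] for j in np.flatnonzero(~(sd > 0))]
        raise ValueError(f"constant or empty variable(s): {bad}")
    z = (ds.values - mean[None, :]) / sd[None, :]
    out = DiaryDataset(
        ds.participant_id, ds.dates, z, ds.mask.copy(), list(ds.var_names), True
    )
    return out, ScalingParams(mean=mean, sd=sd)
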