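"""Temporal matrix container, replicate collapsing, and the fold-change pre-filter.

The central object is a variables-by-timepoints matrix of log occupancy
ratios (treated over control), e.g. protein oxidative-PTM sites measured on
days 1, 3, 5, 7, 10 and 14 of a treatment time course. Cells may be missing;
downstream preprocessing imputes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AllMissingRowError,
    DuplicateIdError,
    ParameterError,
    TimeAxisError,
)

#: Tokens read as missing cells (case-insensitive).
MISSING_TOKENS = ("", "na", "nan", "null")


@dataclass
class TemporalMatrix:
    """An m x n real matrix over an ordered time axis, missing cells allowed.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Log-ratio measurements; ``NaN`` marks a missing cell.
    time_points : ndarray of shape (n,)
        Strictly increasing sampling times (days).
    variable_ids : sequence of str
        Unique row identifiers (e.g. ``"ACTN2_C234_SO2H"``).
    meta : dict
        Free-form provenance (e.g. ``{"log_base": "2"}``).
    """

    values: np.ndarray
    time_points: np.ndarray
    variable_ids: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.variable_ids = [str(v) for v in self.variable_ids]
        if self.values.ndim != 2:
            raise ParameterError("values must be a 2-D array")
        m, n = self.values.shape
        if n < 2:
            raise TimeAxisError("at least 2 time points are required")
        if self.time_points.shape != (n,):
            raise TimeAxisError("time_points length must match the column count")
        if not np.all(np.diff(self.time_points) > 0):
            raise TimeAxisError("time_points must be strictly increasing")
        if len(self.variable_ids) != m:
            raise DuplicateIdError("variable_ids length must match the row count")
        if len(set(self.variable_ids)) != m:
            seen, dups = set(), []
            for v in self.variable_ids:
                if v in seen:
                    dups.append(v)
                seen.add(v)
            raise DuplicateIdError(f"duplicate variable ids: {sorted(set(dups))}")
        all_missing = np.all(np.isnan(self.values), axis=1)
        if np.any(all_missing):
            raise AllMissingRowError(
                [self.variable_ids[i] for i in np.flatnonzero(all_missing)]
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (m, n) array, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def log_base(self) -> float:
        return float(self.meta.get("log_base", 2.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.variable_ids, name="variable_id"),
            columns=self.time_points,
        )

    def subset(self, row_indices) -> "TemporalMatrix":
        row_indices = np.asarray(row_indices, dtype=int)
        return TemporalMatrix(
            self.values[row_indices],
            self.time_points,
            [self.variable_ids[i] for i in row_indices],
            dict(self.meta),
        )


@dataclass
class FilterReport:
    """Outcome of the fold-change pre-filter."""

    threshold: float
    n_input: int
    n_kept: int
    n_dropped: int
    dropped_ids: list

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "dropped_ids": list(self.dropped_ids),
        }

    def write_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# I/O


def _infer_delimiter(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_temporal_matrix(path, delimiter=None, missing_tokens=MISSING_TOKENS,
                         meta=None) -> TemporalMatrix:
    """Read a matrix from delimited text.

    The header row holds the time points (first column = variable id); missing
    cells may be encoded by any of `missing_tokens` (case-insensitive).
    """
    delimiter = delimiter or _infer_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise TimeAxisError("need an id column plus at least 2 time columns")
    ids = df.iloc[:, 0].tolist()
    try:
        time_points = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise TimeAxisError(f"time header is not numeric: {exc}") from None
    tokens = {t.lower() for t in missing_tokens}

    def _cell(tok: str) -> float:
        return np.nan if tok.strip().lower() in tokens else float(tok)

    values = np.array(
        [[_cell(tok) for tok in row] for row in df.iloc[:, 1:].to_numpy()]
    )
    return TemporalMatrix(values, time_points, ids, dict(meta or {}))


def write_temporal_matrix(matrix: TemporalMatrix, path, delimiter=None,
                          missing_token="NA"):
    """Write a matrix as delimited text (inverse of :func:`read_temporal_matrix`)."""
    delimiter = delimiter or _infer_delimiter(path)
    with open(path, "w") as fh:
        header = ["variable_id"] + [_fmt_time(t) for t in matrix.time_points]
        fh.write(delimiter.join(header) + "\n")
        for vid, row in zip(matrix.variable_ids, matrix.values):
            cells = [missing_token if np.isnan(x) else repr(float(x)) for x in row]
            fh.write(delimiter.join([vid] + cells) + "\n")


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


# ---------------------------------------------------------------------------
# Replicate collapsing

REPLICATE_COLUMNS = ("variable_id", "time", "condition", "replicate", "occupancy")


def read_replicate_table(path, delimiter=None) -> pd.DataFrame:
    delimiter = delimiter or _infer_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    missing = set(REPLICATE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"replicate table lacks columns: {sorted(missing)}")
    return df


def collapse_replicates(table: pd.DataFrame, log_base: float = 2.0,
                        meta=None) -> TemporalMatrix:
    """Collapse a replicate-level long table to a log-ratio matrix.

    Per (variable, time): treated and control occupancies are paired by
    replicate index, each matched pair contributes the ratio treated/control,
    and the cell is ``log_base`` of the mean ratio. Pairs whose control
    occupancy is zero are discarded rather than producing an infinite ratio;
    a (variable, time) with no usable pair becomes a missing cell.
    """
    if log_base <= 0 or log_base == 1:
        raise ParameterError("log_base must be positive and != 1")
    df = table.copy()
    missing_cols = set(REPLICATE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParameterError(f"replicate table lacks columns: {sorted(missing_cols)}")
    bad_cond = set(df["condition"].unique()) - {"treated", "control"}
    if bad_cond:
        raise ParameterError(f"unknown conditions: {sorted(bad_cond)}")
    if (df["occupancy"] < 0).any():
        raise ParameterError("occupancy must be non-negative")
    if (df["replicate"] < 1).any():
        raise ParameterError("replicate index must be >= 1")

    wide = df.pivot_table(
        index=["variable_id", "time", "replicate"], columns="condition",
        values="occupancy", aggfunc="mean",
    )
    for cond in ("treated", "control"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    usable = wide.dropna(subset=["treated", "control"])
    usable = usable[usable["control"] > 0]
    ratio = usable["treated"] / usable["control"]
    mean_ratio = ratio.groupby(level=["variable_id", "time"]).mean()

    # log of zero mean ratio (all treated occupancies zero) -> missing
    with np.errstate(divide="ignore"):
        cell = np.log(mean_ratio) / np.log(log_base)
    cell = cell.replace(-np.inf, np.nan)

    variable_ids = list(dict.fromkeys(df["variable_id"]))
    time_points = np.sort(df["time"].unique().astype(float))
    values = np.full((len(variable_ids), len(time_points)), np.nan)
    t_index = {t: j for j, t in enumerate(time_points)}
    v_index = {v: i for i, v in enumerate(variable_ids)}
    for (vid, t), x in cell.items():
        values[v_index[vid], t_index[float(t)]] = x

    meta = dict(meta or {})
    meta.setdefault("log_base", repr(float(log_base)))
    return TemporalMatrix(values, time_points, variable_ids, meta)


# ---------------------------------------------------------------------------
# Fold-change pre-filter


def fold_change_filter(matrix: TemporalMatrix, threshold: float = 1.2,
                       log_base: float | None = None):
    """Drop variables whose dynamics never reach `threshold`-fold in either direction.

    A variable is kept iff some observed cell satisfies
    ``|log-ratio| >= log(threshold)`` in the matrix's log base, i.e. at least
    one time point shows a `threshold`-fold change up or down.

    Returns
    -------
    (TemporalMatrix, FilterReport)
    """
    if threshold <= 1:
        raise ParameterError("fold-change threshold must exceed 1")
    base = float(log_base) if log_base is not None else matrix.log_base
    cutoff = np.log(threshold) / np.log(base)
    with np.errstate(invalid="ignore"):
        max_abs = np.nanmax(np.abs(matrix.values), axis=1)
    keep = max_abs >= cutoff
    kept_idx = np.flatnonzero(keep)
    dropped_ids = [matrix.variable_ids[i] for i in np.flatnonzero(~keep)]
    report = FilterReport(
        threshold=float(threshold),
        n_input=matrix.n_variables,
        n_kept=int(keep.sum()),
        n_dropped=int((~keep).sum()),
        dropped_ids=dropped_ids,
    )
    return matrix.subset(kept_idx), report
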