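"""Balanced panels of health-worker densities and their relative transition paths.

The central object is :class:`Panel`: a balanced unit x year matrix of strictly
positive densities (e.g. physicians per 10,000 population).  From it the
time-varying factor analysis derives, per unit, the *relative transition
parameter*

    h_it = X_it / (N^{-1} sum_i X_it),

each unit's path relative to the cross-sectional average, and the
cross-sectional transition variance

    H_t = N^{-1} sum_i (h_it - 1)^2,

which tends to zero exactly when all units converge to a common path.  These
two statistics are everything the log-t regression and the club-clustering
algorithm consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .exceptions import (
    DegenerateCrossSectionError,
    DuplicateRecordError,
    InsufficientSampleError,
    NonPositiveValueError,
    PanelError,
    UnbalancedPanelError,
)

__all__ = [
    "Panel",
    "TransitionPaths",
    "load_panel",
    "write_panel",
    "hp_smooth",
    "relative_transition",
    "transform_values",
]

#: cross-sectional variances below this are treated as exact zeros
#: (machine-noise floor: |h - 1| ~ 1e-12 squared)
ZERO_H_TOL = 1e-24


@dataclass(frozen=True)
class Panel:
    """A balanced unit x time panel of strictly positive densities.

    Parameters
    ----------
    unit_ids : tuple of str
        Ordered unit identifiers (e.g. country names), unique.
    years : ndarray of int
        Strictly increasing, consecutive (annual) time stamps.
    values : ndarray, shape (n_units, n_years)
        Strictly positive densities.
    """

    unit_ids: tuple
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "unit_ids", tuple(str(u) for u in self.unit_ids))
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise PanelError("duplicate unit identifiers")
        if len(self.unit_ids) < 2:
            raise PanelError("a panel needs at least 2 units")
        if years.ndim != 1 or years.size < 2:
            raise PanelError("a panel needs at least 2 years")
        if not np.all(np.diff(years) == 1):
            raise PanelError("years must be strictly increasing and consecutive")
        if values.shape != (len(self.unit_ids), years.size):
            raise PanelError(
                f"values shape {values.shape} does not match "
                f"({len(self.unit_ids)} units, {years.size} years)"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise UnbalancedPanelError([(self.unit_ids[bad[0]], int(years[bad[1]]))])
        if np.any(values <= 0):
            bad = np.argwhere(values <= 0)[0]
            raise NonPositiveValueError(
                self.unit_ids[bad[0]], int(years[bad[1]]), float(values[bad[0], bad[1]])
            )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def subset(self, units: Sequence[str]) -> "Panel":
        """Return the sub-panel restricted to ``units`` (in the given order)."""
        index = {u: i for i, u in enumerate(self.unit_ids)}
        rows = [index[u] for u in units]
        return Panel(tuple(units), self.years.copy(), self.values[rows].copy())

    def to_long_frame(
        self, location_col="location_name", year_col="year", value_col="value"
    ) -> pd.DataFrame:
        n, t = self.values.shape
        return pd.DataFrame(
            {
                location_col: np.repeat(self.unit_ids, t),
                year_col: np.tile(self.years, n),
                value_col: self.values.ravel(),
            }
        )

    def to_wide_frame(self, location_col="location_name") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.years.tolist())
        df.insert(0, location_col, list(self.unit_ids))
        return df


@dataclass(frozen=True)
class TransitionPaths:
    """Relative transition paths h_it and their cross-sectional variance H_t.

    ``source_transform`` records whether h was computed from levels or logs;
    note that in log mode h is *not* invariant to a change of measurement
    units (a scale shift adds a constant to every log series).
    """

    h: np.ndarray  # (n_units, n_years)
    H: np.ndarray  # (n_years,)
    source_transform: str  # "levels" | "log"


def _validate_years(years) -> np.ndarray:
    try:
        years = np.asarray([int(y) for y in years], dtype=int)
    except (TypeError, ValueError) as exc:
        raise PanelError(f"year headers must be integers: {exc}") from None
    return years


def load_panel(
    source,
    layout: str = "long",
    *,
    location_col: str = "location_name",
    year_col: str = "year",
    value_col: str = "value",
) -> Panel:
    """Read a panel from CSV and validate it into a balanced :class:`Panel`.

    ``layout="long"`` expects one row per (location, year) with a value
    column; ``layout="wide"`` expects one row per location with one column
    per year.  Units are sorted lexicographically for determinism.

    Raises
    ------
    DuplicateRecordError, UnbalancedPanelError, NonPositiveValueError
        On duplicate (unit, year) records, missing cells, or values <= 0.
    """
    df = pd.read_csv(source)
    if layout == "long":
        missing_cols = [c for c in (location_col, year_col, value_col) if c not in df.columns]
        if missing_cols:
            raise PanelError(f"missing columns in long CSV: {missing_cols}")
        df = df[[location_col, year_col, value_col]].copy()
        df[location_col] = df[location_col].astype(str)
        df[year_col] = df[year_col].astype(int)
        dup_mask = df.duplicated([location_col, year_col], keep=False)
        if dup_mask.any():
            dups = (
                df.loc[dup_mask, [location_col, year_col]]
                .drop_duplicates()
                .itertuples(index=False)
            )
            raise DuplicateRecordError([(u, int(y)) for u, y in dups])
        wide = df.pivot(index=location_col, columns=year_col, values=value_col)
    elif layout == "wide":
        if df.shape[1] < 3:
            raise PanelError("wide CSV needs a location column plus at least 2 year columns")
        loc = df.columns[0]
        df[loc] = df[loc].astype(str)
        if df[loc].duplicated().any():
            dups = df.loc[df[loc].duplicated(), loc].tolist()
            raise DuplicateRecordError([(u, "*") for u in dups])
        wide = df.set_index(loc)
        wide.columns = _validate_years(wide.columns)
    else:
        raise PanelError(f"unknown layout {layout!r}")

    wide = wide.sort_index()
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        rows, cols = np.nonzero(wide.isna().to_numpy())
        pairs = [(str(wide.index[r]), int(wide.columns[c])) for r, c in zip(rows, cols)]
        raise UnbalancedPanelError(pairs)
    return Panel(tuple(wide.index), np.asarray(wide.columns, int), wide.to_numpy(float))


def write_panel(
    panel: Panel,
    target,
    layout: str = "long",
    *,
    location_col: str = "location_name",
    year_col: str = "year",
    value_col: str = "value",
) -> None:
    """Write a panel back to CSV in the same dialects :func:`load_panel` reads.

    Values are written with full round-trip precision.
    """
    if layout == "long":
        df = panel.to_long_frame(location_col, year_col, value_col)
    elif layout == "wide":
        df = panel.to_wide_frame(location_col)
    else:
        raise PanelError(f"unknown layout {layout!r}")
    df.to_csv(target, index=False)


def hp_smooth(series, lam: float = 400.0):
    """Hodrick-Prescott trend of one series (1-D) or a bundle of series.

    Returns the trend tau minimizing

        sum_t (y_t - tau_t)^2 + lam * sum_t (Delta^2 tau_t)^2,

    i.e. the solution of (I + lam * D'D) tau = y with D the second-difference
    operator.  For 2-D input, time runs along the last axis and every row is
    smoothed with a single factorized solve.

    lam = 400 is a conventional weight for annual panels.
    """
    y = np.asarray(series, dtype=float)
    if lam <= 0:
        raise ValueError("lam must be > 0")
    T = y.shape[-1]
    if T < 4:
        raise InsufficientSampleError(f"series length {T} < 4: cannot smooth")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(T - 2, T), format="csc")
    A = (sparse.eye(T, format="csc") + lam * (D.T @ D)).tocsc()
    lu = splu(A)
    if y.ndim == 1:
        return lu.solve(y)
    flat = y.reshape(-1, T)
    return lu.solve(flat.T).T.reshape(y.shape)


def transform_values(values: np.ndarray, transform: str = "levels", smooth=None) -> np.ndarray:
    """Apply the (log, HP-smoothing) preprocessing to a panel value matrix.

    The log is taken element-wise first; smoothing (if any) is applied per
    unit to the transformed series, never to the transition variance.
    """
    if transform == "log":
        x = np.log(values)
    elif transform == "levels":
        x = np.asarray(values, float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if smooth is not None:
        x = hp_smooth(x, smooth)
    return x


def transition_from_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """h and H from an already-transformed unit x time matrix."""
    mean_t = x.mean(axis=0)
    bad = np.nonzero(mean_t <= 0)[0]
    if bad.size:
        raise DegenerateCrossSectionError(int(bad[0]), float(mean_t[bad[0]]))
    h = x / mean_t
    H = np.mean((h - 1.0) ** 2, axis=0)
    return h, H


def relative_transition(panel: Panel, transform: str = "levels", smooth=None) -> TransitionPaths:
    """Relative transition paths of a panel.

    Computes h_it = x_it / mean_i(x_it) and H_t = mean_i (h_it - 1)^2, where
    x is the panel after the optional log transform and per-unit HP smoothing.
    The cross-sectional mean of h is identically 1 at every t.
    """
    x = transform_values(panel.values, transform, smooth)
    h, H = transition_from_matrix(x)
    return TransitionPaths(h=h, H=H, source_transform=transform)


def panel_from_values(values, unit_ids=None, years=None, start_year: int = 1990) -> Panel:
    """Build a Panel from a raw (n_units, n_years) array, generating ids/years."""
    values = np.asarray(values, float)
    n, t = values.shape
    if unit_ids is None:
        unit_ids = tuple(f"unit_{i:04d}" for i in range(n))
    if years is None:
        years = start_year + np.arange(t)
    return Panel(tuple(unit_ids), np.asarray(years, int), values)
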