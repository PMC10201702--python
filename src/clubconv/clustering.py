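"""Endogenous convergence-club identification.

The clustering procedure turns a rejected full-sample convergence test into a
partition of units into convergence clubs plus a divergent remainder:

1. *Order* units by the mean of the final half of their (log) series,
   decreasing.
2. *Core group*: scan prefixes of the ordering; the core is the prefix
   maximizing the log-t t-statistic among prefixes that pass the test
   (t > -1.65).  If no prefix starting at the top passes, the top unit is set
   aside and the scan restarts.
3. *Sieve*: every remaining unit is added, one at a time, to the core; it
   joins the provisional club when the one-unit-augmented t-statistic exceeds
   the sieve criterion c* (0 by default).  If the assembled club then fails
   its own log-t test, c* is raised in 0.05 steps and the sieve repeats.
4. *Recurse* on the units left over; leftovers that form no club (and
   singletons) are classified divergent.
5. *Merge*: adjacent clubs (by rank) whose union passes the log-t test are
   merged, so every reported club is "strong".

Clubs are numbered 1, 2, ... in decreasing final-window mean density, the
conventional high-density-first labelling.

The number of clubs is not fixed a priori: a fully convergent panel yields a
single all-units club, and a panel of mutually divergent paths yields none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import PanelError
from .logt import CRIT_5PCT, LogTResult, convergence_decision, logt_regression
from .panel import Panel, transform_values, transition_from_matrix

__all__ = [
    "ClubConfig",
    "ClubPartition",
    "order_units",
    "find_core_group",
    "sieve_members",
    "form_clubs",
    "merge_clubs",
    "ClubConvergence",
]


@dataclass(frozen=True)
class ClubConfig:
    """Every knob of the clustering procedure, with the annual-data defaults."""

    transform: str = "log"
    hp_lambda: Optional[float] = 400.0
    trim_fraction: float = 0.3
    crit: float = CRIT_5PCT
    hac_bandwidth: Optional[int] = None
    ordering_fraction: float = 0.5  # final-window share used to order units
    c_star: float = 0.0  # initial sieve criterion
    c_star_step: float = 0.05  # increment when a club fails its own test
    merge: bool = True

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "hp_lambda": self.hp_lambda,
            "trim_fraction": self.trim_fraction,
            "crit": self.crit,
            "hac_bandwidth": self.hac_bandwidth,
            "ordering_fraction": self.ordering_fraction,
            "c_star": self.c_star,
            "c_star_step": self.c_star_step,
            "merge": self.merge,
        }


@dataclass
class ClubPartition:
    """Clubs plus divergent units; together they partition the unit set.

    ``clubs`` are ordered high-density first; each club carries the
    :class:`LogTResult` of its own log-t test, and ``merge_log`` records every
    attempted club merge with its outcome.
    """

    clubs: list  # list[list[str]], members sorted lexicographically
    divergent: list  # list[str]
    club_results: list  # list[LogTResult]
    merge_log: list = field(default_factory=list)  # list[dict]

    @property
    def n_clubs(self) -> int:
        return len(self.clubs)

    def validate(self, unit_ids: Sequence[str]) -> None:
        """Check the disjoint/exhaustive partition property against a unit set."""
        seen: list = []
        for club in self.clubs:
            if len(club) < 2:
                raise PanelError("every club needs at least 2 members")
            seen.extend(club)
        seen.extend(self.divergent)
        if sorted(seen) != sorted(unit_ids) or len(seen) != len(set(seen)):
            raise PanelError("clubs + divergent do not partition the unit set")

    def labels(self, unit_ids: Sequence[str]) -> np.ndarray:
        """0-based club index per unit, -1 for divergent units."""
        lab = {u: -1 for u in self.divergent}
        for k, club in enumerate(self.clubs):
            lab.update({u: k for u in club})
        return np.asarray([lab[u] for u in unit_ids], dtype=int)

    def to_dict(self) -> dict:
        return {
            "clubs": [list(c) for c in self.clubs],
            "divergent": list(self.divergent),
            "club_results": [r.to_dict() for r in self.club_results],
            "merge_log": list(self.merge_log),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ClubPartition":
        return cls(
            clubs=[list(c) for c in d["clubs"]],
            divergent=list(d["divergent"]),
            club_results=[LogTResult.from_dict(r) for r in d["club_results"]],
            merge_log=list(d["merge_log"]),
        )

    def membership_frame(self, location_col="location_name") -> pd.DataFrame:
        """Two-column (location, club) table; divergent units get 'divergent'."""
        rows = [(u, f"Club {k + 1}") for k, club in enumerate(self.clubs) for u in club]
        rows += [(u, "divergent") for u in self.divergent]
        rows.sort()
        return pd.DataFrame(rows, columns=[location_col, "club"])


# ---------------------------------------------------------------------------
# internal engine operating on a pre-transformed unit x time matrix


class _Engine:
    """Caches the transformed matrix and runs subset log-t regressions."""

    def __init__(self, panel: Panel, config: ClubConfig):
        self.panel = panel
        self.cfg = config
        self.ids = list(panel.unit_ids)
        self.index = {u: i for i, u in enumerate(self.ids)}
        self.xt = transform_values(panel.values, config.transform, config.hp_lambda)
        # raw final-window mean density, used only for club numbering
        w = max(1, int(config.ordering_fraction * panel.n_years))
        self.final_density = panel.values[:, -w:].mean(axis=1)
        self.order_metric = self.xt[:, -w:].mean(axis=1)

    def logt(self, units: Sequence[str]) -> LogTResult:
        rows = [self.index[u] for u in units]
        _, H = transition_from_matrix(self.xt[rows])
        return logt_regression(
            H,
            self.cfg.trim_fraction,
            crit=self.cfg.crit,
            hac_bandwidth=self.cfg.hac_bandwidth,
            n_units=len(rows),
        )

    def order(self, units: Sequence[str]) -> list:
        """Decreasing final-window mean of the transformed series, ties by id."""
        return sorted(units, key=lambda u: (-self.order_metric[self.index[u]], u))

    def core(self, ordered: Sequence[str]) -> list:
        cfg = self.cfg
        ordered = list(ordered)
        while len(ordered) >= 2:
            best_k, best_t = None, None
            for k in range(2, len(ordered) + 1):
                t = self.logt(ordered[:k]).t_stat
                if t > cfg.crit and (best_t is None or t > best_t):
                    best_k, best_t = k, t
            if best_k is not None:
                return ordered[:best_k]
            ordered = ordered[1:]  # top unit joins no prefix; set it aside
        return []

    def sieve(self, core: Sequence[str], candidates: Sequence[str]):
        cfg = self.cfg
        core = list(core)
        # augmented t-statistics do not depend on c*, compute them once
        t_aug = {c: self.logt(core + [c]).t_stat for c in candidates}
        c_star = cfg.c_star
        while True:
            admitted = [c for c in candidates if t_aug[c] > c_star]
            club = core + admitted
            result = self.logt(club)
            if convergence_decision(result.t_stat, cfg.crit) or not admitted:
                return club, result, c_star
            c_star += cfg.c_star_step


# ---------------------------------------------------------------------------
# public operations


def order_units(panel: Panel, config: ClubConfig = ClubConfig()) -> list:
    """Units sorted by decreasing mean of the final window of the (log) series.

    Ties are broken lexicographically by unit id so the ordering is
    deterministic.
    """
    return _Engine(panel, config).order(panel.unit_ids)


def find_core_group(
    panel: Panel, ordered_units: Sequence[str], config: ClubConfig = ClubConfig()
) -> list:
    """The prefix of the ordering that seeds a club (possibly empty).

    Scans prefixes of length k = 2, 3, ... and returns the one maximizing the
    log-t t-statistic among prefixes with t > crit; drops the top unit and
    rescans when none qualifies.  An empty list signals that no two units
    converge.
    """
    return _Engine(panel, config).core(ordered_units)


def sieve_members(
    panel: Panel,
    core: Sequence[str],
    candidates: Sequence[str],
    config: ClubConfig = ClubConfig(),
) -> list:
    """Admit candidates whose one-unit-augmented t-statistic exceeds c*.

    When the assembled club fails its own log-t test the criterion is raised
    by ``c_star_step`` and the sieve repeats, so the returned club always
    passes (in the worst case it shrinks back to the core).
    """
    if not core:
        raise PanelError("sieve needs a non-empty core group")
    club, _, _ = _Engine(panel, config).sieve(core, candidates)
    return club


def _assemble(engine: _Engine, clubs: list, leftovers: list) -> ClubPartition:
    """Rank clubs high-density-first, attach results, fold in leftovers."""
    clubs = sorted(
        clubs,
        key=lambda c: (
            -float(np.mean([engine.final_density[engine.index[u]] for u in c])),
            sorted(c)[0],
        ),
    )
    return ClubPartition(
        clubs=[sorted(c) for c in clubs],
        divergent=sorted(leftovers),
        club_results=[engine.logt(c) for c in clubs],
    )


def form_clubs(panel: Panel, config: ClubConfig = ClubConfig()) -> ClubPartition:
    """Run the full clustering procedure on a panel.

    If the full sample already passes the log-t test a single all-units club
    is returned.  Otherwise order/core/sieve are applied repeatedly to the
    units not yet assigned, leftovers are classified divergent, and adjacent
    clubs are merged when their union converges.
    """
    engine = _Engine(panel, config)
    full = engine.logt(engine.ids)
    if full.converged:
        return ClubPartition(
            clubs=[sorted(engine.ids)], divergent=[], club_results=[full]
        )

    clubs: list = []
    remaining = list(engine.ids)
    while len(remaining) >= 2:
        ordered = engine.order(remaining)
        core = engine.core(ordered)
        if not core:
            break
        candidates = [u for u in ordered if u not in set(core)]
        club, _, _ = engine.sieve(core, candidates)
        clubs.append(club)
        in_club = set(club)
        remaining = [u for u in remaining if u not in in_club]

    partition = _assemble(engine, clubs, remaining)
    if config.merge and partition.n_clubs > 1:
        partition = merge_clubs(partition, panel, config)
    return partition


def merge_clubs(
    partition: ClubPartition, panel: Panel, config: ClubConfig = ClubConfig()
) -> ClubPartition:
    """Merge adjacent clubs whose union passes the log-t test.

    Clubs are scanned in rank order; when a union converges the pair is
    merged and the scan restarts, until no adjacent pair merges.  Every
    attempt is recorded in ``merge_log``.
    """
    engine = _Engine(panel, config)
    clubs = [list(c) for c in partition.clubs]
    log = list(partition.merge_log)
    i = 0
    while i < len(clubs) - 1:
        union = clubs[i] + clubs[i + 1]
        result = engine.logt(union)
        merged = convergence_decision(result.t_stat, config.crit)
        log.append(
            {
                "pair": [i + 1, i + 2],
                "sizes": [len(clubs[i]), len(clubs[i + 1])],
                "t_stat": result.t_stat,
                "merged": merged,
            }
        )
        if merged:
            clubs[i : i + 2] = [union]
            i = 0
        else:
            i += 1
    out = _assemble(engine, clubs, partition.divergent)
    out.merge_log = log
    return out


class ClubConvergence(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer assigning panel units to convergence clubs.

    ``fit(X)`` accepts a :class:`~clubconv.panel.Panel` or a raw
    (n_units, n_years) array of positive densities.  After fitting,
    ``labels_`` holds the 0-based club index of every unit (club 0 = highest
    final density) with -1 marking divergent units, mirroring the noise label
    convention of density-based clusterers.

    Parameters mirror :class:`ClubConfig`; see the module docstring for the
    algorithm.

    Attributes
    ----------
    labels_ : ndarray of shape (n_units,)
    partition_ : ClubPartition
    full_sample_ : LogTResult
        Log-t test on all units together.
    n_clusters_ : int
    """

    def __init__(
        self,
        transform: str = "log",
        hp_lambda: Optional[float] = 400.0,
        trim_fraction: float = 0.3,
        crit: float = CRIT_5PCT,
        hac_bandwidth: Optional[int] = None,
        ordering_fraction: float = 0.5,
        c_star: float = 0.0,
        c_star_step: float = 0.05,
        merge: bool = True,
    ):
        self.transform = transform
        self.hp_lambda = hp_lambda
        self.trim_fraction = trim_fraction
        self.crit = crit
        self.hac_bandwidth = hac_bandwidth
        self.ordering_fraction = ordering_fraction
        self.c_star = c_star
        self.c_star_step = c_star_step
        self.merge = merge

    def _config(self) -> ClubConfig:
        return ClubConfig(
            transform=self.transform,
            hp_lambda=self.hp_lambda,
            trim_fraction=self.trim_fraction,
            crit=self.crit,
            hac_bandwidth=self.hac_bandwidth,
            ordering_fraction=self.ordering_fraction,
            c_star=self.c_star,
            c_star_step=self.c_star_step,
            merge=self.merge,
        )

    def fit(self, X, y=None):
        if isinstance(X, Panel):
            panel = X
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be a Panel or a 2-D (n_units, n_years) array")
            from .panel import panel_from_values

            panel = panel_from_values(values)
        cfg = self._config()
        engine = _Engine(panel, cfg)
        self.full_sample_ = engine.logt(engine.ids)
        self.partition_ = form_clubs(panel, cfg)
        self.labels_ = self.partition_.labels(panel.unit_ids)
        self.n_clusters_ = self.partition_.n_clubs
        self.unit_ids_ = list(panel.unit_ids)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
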