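"""Synthetic density panels from the time-varying factor model.

Panels are generated as X_it = delta_it * mu_t with a common exponential
trend mu_t = mu_0 (1 + g)^t and unit-specific transition coefficients

    delta_it = delta_c + sigma_i * xi_it / (log(t + 1) * (t + 1)^alpha),

xi_it iid standard normal, so every unit in club c converges to the club
limit delta_c at rate governed by alpha (the log-t slope then satisfies
beta = 2 alpha in the large-N limit).  Divergent "fan" units instead follow
deterministic log-linear trends with distinct slopes, so they converge to no
club and to none of each other.

Defaults emulate a worldwide physician-density panel: 204 units in three
clubs of 110/66/28 converging to 21, 7 and 2 physicians per 10,000
population, 30 annual periods starting 1990, 3% yearly common growth, and
10% relative initial noise that decays at alpha = 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .panel import Panel

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_panel"]

#: divergent-unit label in SimulationTruth and cluster outputs
DIVERGENT = -1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the club-structured data-generating process.

    Attributes
    ----------
    n_units_per_club : sequence of int
        Club sizes; defaults to the 110/66/28 split of a 204-country panel.
    club_deltas : sequence of float
        Strictly positive club limits of the transition coefficient, in the
        units of the panel (here: density per 10,000 population at t = 0).
    n_divergent : int
        Number of deterministic fan units converging to no club.
    decay_alpha : float >= 0
        Decay rate of the idiosyncratic noise; the log-t slope under
        convergence is 2 * decay_alpha in levels mode.
    noise_sigma : float
        Relative scale of the initial idiosyncratic noise; each unit's
        absolute scale is sigma_i = noise_sigma * delta_c of its club.
    trend_growth : float
        Yearly growth rate g of the common trend mu_t = mu_0 (1 + g)^t.
    mu_0 : float
        Common-trend level in the first year.
    T : int
        Number of annual periods (>= 10).
    start_year : int
        Calendar year of the first period.
    seed : int
        Seed of the generator; identical configs yield identical panels.
    """

    n_units_per_club: Sequence[int] = (110, 66, 28)
    club_deltas: Sequence[float] = (21.0, 7.0, 2.0)
    n_divergent: int = 0
    decay_alpha: float = 0.5
    noise_sigma: float = 0.1
    trend_growth: float = 0.03
    mu_0: float = 1.0
    T: int = 30
    start_year: int = 1990
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "n_units_per_club", tuple(int(n) for n in self.n_units_per_club))
        object.__setattr__(self, "club_deltas", tuple(float(d) for d in self.club_deltas))
        if len(self.n_units_per_club) != len(self.club_deltas):
            raise ValueError("n_units_per_club and club_deltas must have equal length")
        if any(d <= 0 for d in self.club_deltas):
            raise ValueError("club_deltas must be strictly positive")
        if any(n < 0 for n in self.n_units_per_club):
            raise ValueError("club sizes must be non-negative")
        if sum(self.n_units_per_club) + self.n_divergent < 4:
            raise ValueError("need at least 4 units in total")
        if self.T < 10:
            raise ValueError("need T >= 10 periods")
        if self.decay_alpha < 0 or self.noise_sigma < 0:
            raise ValueError("decay_alpha and noise_sigma must be non-negative")
        if self.mu_0 <= 0:
            raise ValueError("mu_0 must be positive")

    def to_dict(self) -> dict:
        return {
            "n_units_per_club": list(self.n_units_per_club),
            "club_deltas": list(self.club_deltas),
            "n_divergent": self.n_divergent,
            "decay_alpha": self.decay_alpha,
            "noise_sigma": self.noise_sigma,
            "trend_growth": self.trend_growth,
            "mu_0": self.mu_0,
            "T": self.T,
            "start_year": self.start_year,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SimulationTruth:
    """Generating club labels (0-based; -1 = divergent) and the config echo."""

    labels: dict  # unit id -> club index or DIVERGENT
    config: SimulationConfig
    n_resampled: int = 0

    def label_array(self, unit_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.labels[u] for u in unit_ids], dtype=int)


def _fan_deltas(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Deterministic log-linear trends fanning away from the club range.

    Even-indexed fans start above the highest club limit and drift further
    up; odd-indexed fans start below the lowest limit and drift further
    down.  Slopes and starting levels are staggered so no two fans (and no
    fan and club) share a long-run relative path.
    """
    k = config.n_divergent
    top = float(np.log(max(config.club_deltas)))
    bot = float(np.log(min(config.club_deltas)))
    deltas = np.empty((k, t.size))
    for j in range(k):
        pair = j // 2
        if j % 2 == 0:
            slope = 0.05 + 0.02 * pair
            start = top + 0.4 + 0.2 * pair
        else:
            slope = -(0.02 + 0.015 * pair)
            start = bot - 0.35 - 0.1 * pair
        deltas[j] = np.exp(start + slope * (t - 1))
    return deltas


def simulate_panel(config: SimulationConfig = SimulationConfig()):
    """Draw one panel from the club-structured DGP.

    Returns
    -------
    (Panel, SimulationTruth)
        The panel is balanced and strictly positive (offending noise draws
        are resampled, keeping the Gaussian shape); the truth records each
        unit's generating club.
    """
    rng = np.random.default_rng(config.seed)
    T = config.T
    t = np.arange(1, T + 1, dtype=float)
    mu = config.mu_0 * (1.0 + config.trend_growth) ** (t - 1)
    decay = 1.0 / (np.log(t + 1.0) * (t + 1.0) ** config.decay_alpha)

    blocks, ids, labels = [], [], {}
    n_resampled = 0
    for c, (n_c, delta_c) in enumerate(zip(config.n_units_per_club, config.club_deltas)):
        if n_c == 0:
            continue
        sigma_i = config.noise_sigma * delta_c
        xi = rng.standard_normal((n_c, T))
        delta = delta_c + sigma_i * xi * decay
        # resample any draw that would push delta (hence the density) <= 0
        for _ in range(1000):
            bad = delta <= 0
            if not bad.any():
                break
            n_resampled += int(bad.sum())
            xi[bad] = rng.standard_normal(int(bad.sum()))
            delta = delta_c + sigma_i * xi * decay
        else:  # pragma: no cover - only reachable with absurd noise scales
            raise RuntimeError("could not draw strictly positive transition paths")
        blocks.append(delta)
        club_ids = [f"C{c + 1}_{i:03d}" for i in range(n_c)]
        ids.extend(club_ids)
        labels.update({u: c for u in club_ids})

    if config.n_divergent:
        blocks.append(_fan_deltas(config, t))
        fan_ids = [f"DIV_{j:02d}" for j in range(config.n_divergent)]
        ids.extend(fan_ids)
        labels.update({u: DIVERGENT for u in fan_ids})

    values = np.vstack(blocks) * mu
    panel = Panel(tuple(ids), config.start_year + np.arange(T), values)
    return panel, SimulationTruth(labels=labels, config=config, n_resampled=n_resampled)
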