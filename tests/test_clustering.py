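"""Club identification: ordering, core search, sieving, recursion, merging."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clubconv import (
    ClubConfig,
    ClubConvergence,
    Panel,
    SimulationConfig,
    find_core_group,
    form_clubs,
    merge_clubs,
    order_units,
    sieve_members,
    simulate_panel,
)

LEVELS = ClubConfig(transform="levels", hp_lambda=None)


def fan_panel(n=5, T=20, spread=0.15):
    """Deterministic trends fanning out: every pair diverges."""
    t = np.arange(T, dtype=float)
    values = np.exp(
        np.array([2.0 + (i - n / 2) * spread * t for i in range(n)])
    )
    return Panel(tuple(f"f{i}" for i in range(n)), 2000 + np.arange(T), values)


class TestOrderUnits:
    def test_sorts_by_final_window_mean(self):
        values = np.vstack([np.full(12, 2.0), np.full(12, 30.0), np.full(12, 21.0)])
        panel = Panel(("low", "high", "mid"), 2000 + np.arange(12), values)
        assert order_units(panel, LEVELS) == ["high", "mid", "low"]

    def test_identical_units_tie_break_lexicographic(self):
        values = np.tile(np.linspace(3, 4, 12), (3, 1))
        panel = Panel(("c", "a", "b"), 2000 + np.arange(12), values)
        assert order_units(panel, LEVELS) == ["a", "b", "c"]

    def test_matches_brute_force_sort(self, random_panel):
        cfg = ClubConfig(transform="log", hp_lambda=None, ordering_fraction=0.5)
        w = max(1, int(0.5 * random_panel.n_years))
        metric = np.log(random_panel.values)[:, -w:].mean(axis=1)
        expected = [
            u for _, u in sorted(zip(-metric, random_panel.unit_ids))
        ]
        assert order_units(random_panel, cfg) == expected


class TestCoreGroup:
    def test_identical_pair_is_core_with_sentinel(self):
        values = np.vstack([np.tile(np.linspace(2, 3, 15), (2, 1)), fan_panel(2, 15).values])
        panel = Panel(("a", "b", "f0", "f1"), 2000 + np.arange(15), values)
        cfg = LEVELS
        ordered = order_units(panel, cfg)
        core = find_core_group(panel, ordered, cfg)
        assert set(core) == {"a", "b"}

    def test_all_divergent_yields_empty_core(self):
        panel = fan_panel()
        cfg = LEVELS
        core = find_core_group(panel, order_units(panel, cfg), cfg)
        assert core == []

    def test_single_club_core_found(self, two_club_config):
        panel, truth = simulate_panel(two_club_config)
        cfg = ClubConfig()
        ordered = order_units(panel, cfg)
        core = find_core_group(panel, ordered, cfg)
        labels = truth.labels
        assert len(core) >= 2
        assert {labels[u] for u in core} == {0}  # entirely inside the top club


class TestSieve:
    def test_identical_candidate_always_admitted(self):
        base = np.tile(np.linspace(2, 3, 15), (3, 1))
        panel = Panel(("a", "b", "c"), 2000 + np.arange(15), base)
        club = sieve_members(panel, ["a", "b"], ["c"], LEVELS)
        assert set(club) == {"a", "b", "c"}

    def test_diverging_candidate_excluded(self, two_club_config):
        panel, truth = simulate_panel(two_club_config)
        cfg = ClubConfig()
        club0 = sorted(u for u, l in truth.labels.items() if l == 0)
        club1 = sorted(u for u, l in truth.labels.items() if l == 1)
        club = sieve_members(panel, club0[:5], club1[:3], cfg)
        assert set(club) == set(club0[:5])

    def test_empty_core_is_an_error(self, two_club_panel):
        panel, _ = two_club_panel
        with pytest.raises(ValueError):
            sieve_members(panel, [], list(panel.unit_ids))


class TestFormClubs:
    def test_convergent_panel_is_one_club(self):
        panel, _ = simulate_panel(
            SimulationConfig(n_units_per_club=(20,), club_deltas=(2.0,), mu_0=10.0, seed=3)
        )
        part = form_clubs(panel)
        assert part.n_clubs == 1
        assert sorted(part.clubs[0]) == sorted(panel.unit_ids)
        assert part.divergent == []

    def test_partition_property_holds(self, two_club_panel):
        panel, _ = two_club_panel
        part = form_clubs(panel)
        part.validate(panel.unit_ids)  # disjoint + exhaustive or raises
        assert all(len(c) >= 2 for c in part.clubs)
        assert all(r.t_stat >= -1.65 for r in part.club_results)

    def test_two_clubs_plus_fans_recovered(self):
        recovered = flagged = 0
        seeds = range(10)
        for seed in seeds:
            panel, truth = simulate_panel(
                SimulationConfig(
                    n_units_per_club=(20, 20),
                    club_deltas=(21.0, 2.0),
                    n_divergent=3,
                    seed=seed,
                )
            )
            part = form_clubs(panel)
            true = truth.label_array(panel.unit_ids)
            pred = part.labels(panel.unit_ids)
            m = true >= 0
            recovered += adjusted_rand_score(true[m], pred[m]) >= 0.9
            flagged += bool(np.all(pred[~m] == -1))
        assert recovered >= 9 and flagged >= 9

    def test_clubs_ranked_by_final_density(self, two_club_panel):
        panel, truth = two_club_panel
        part = form_clubs(panel)
        means = [
            np.mean([panel.values[panel.unit_ids.index(u), -1] for u in club])
            for club in part.clubs
        ]
        assert means == sorted(means, reverse=True)

    def test_determinism(self, two_club_panel):
        panel, _ = two_club_panel
        a, b = form_clubs(panel), form_clubs(panel)
        assert a.to_json() == b.to_json()

    def test_idempotence_on_a_single_club(self, two_club_config):
        panel, truth = simulate_panel(two_club_config)
        members = sorted(u for u, l in truth.labels.items() if l == 0)
        part = form_clubs(panel.subset(members))
        assert part.n_clubs == 1 and sorted(part.clubs[0]) == members


class TestMergeClubs:
    def test_artificial_split_is_merged(self, two_club_config):
        panel, truth = simulate_panel(two_club_config)
        members = sorted(u for u, l in truth.labels.items() if l == 0)
        sub = panel.subset(members)
        part = form_clubs(sub, ClubConfig(merge=False))
        # artificially split the single true club in two
        from clubconv.clustering import ClubPartition, _Engine

        half = len(members) // 2
        engine = _Engine(sub, ClubConfig())
        split = ClubPartition(
            clubs=[members[:half], members[half:]],
            divergent=[],
            club_results=[engine.logt(members[:half]), engine.logt(members[half:])],
        )
        merged = merge_clubs(split, sub)
        assert merged.n_clubs == 1
        assert sorted(merged.clubs[0]) == members
        assert merged.merge_log[-1]["merged"]

    def test_separated_clubs_do_not_merge(self, two_club_panel):
        panel, _ = two_club_panel
        part = form_clubs(panel, ClubConfig(merge=False))
        assert part.n_clubs == 2
        merged = merge_clubs(part, panel)
        assert merged.n_clubs == 2
        attempt = merged.merge_log[0]
        assert not attempt["merged"] and attempt["t_stat"] < -1.65

    def test_single_club_partition_unchanged(self, two_club_config):
        panel, truth = simulate_panel(two_club_config)
        members = sorted(u for u, l in truth.labels.items() if l == 0)
        part = form_clubs(panel.subset(members))
        merged = merge_clubs(part, panel.subset(members))
        assert merged.to_dict()["clubs"] == part.to_dict()["clubs"]


class TestEstimator:
    def test_labels_align_with_partition(self, two_club_panel):
        panel, truth = two_club_panel
        est = ClubConvergence().fit(panel)
        assert est.n_clusters_ == 2
        assert set(est.labels_) == {0, 1}
        # club 0 is the high-density club
        true = truth.label_array(panel.unit_ids)
        assert adjusted_rand_score(true, est.labels_) == 1.0
        assert (est.labels_ == 0).sum() == len(est.partition_.clubs[0])

    def test_accepts_raw_matrix(self, two_club_panel):
        panel, _ = two_club_panel
        est = ClubConvergence().fit(panel.values)
        assert est.labels_.shape == (panel.n_units,)

    def test_sklearn_param_interface(self):
        est = ClubConvergence(trim_fraction=0.25, merge=False)
        params = est.get_params()
        assert params["trim_fraction"] == 0.25 and params["merge"] is False
        est.set_params(crit=-1.7)
        assert est.crit == -1.7

    def test_full_sample_result_exposed(self, two_club_panel):
        panel, _ = two_club_panel
        est = ClubConvergence().fit(panel)
        assert not est.full_sample_.converged
        assert est.full_sample_.n_units == panel.n_units
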