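import itertools

import numpy as np
import pandas as pd
import pytest

from microcq import (
    ENVIRONMENTS,
    SimulationConfig,
    aggregate_habitats,
    community_environment_fractions,
    mann_whitney_u,
    period_contrast,
    rarefy,
    simulate_campaign,
)


def _hits(records):
    return pd.DataFrame(records, columns=["asv_id", "habitat", "hits"])


MAPPING = pd.Series(
    {"lake": "freshwater", "river": "freshwater", "field soil": "soil"}
)


class TestAggregateHabitats:
    def test_single_category_collapse(self):
        hits = _hits([("a", "lake", 3), ("a", "river", 1)])
        prof = aggregate_habitats(hits, MAPPING)
        assert prof.loc["a", "freshwater"] == pytest.approx(1.0)

    def test_no_hits_assigned_to_other(self):
        hits = _hits([("a", "lake", 0)])
        prof = aggregate_habitats(hits, MAPPING)
        assert prof.loc["a", "other"] == pytest.approx(1.0)

    def test_normalisation_arithmetic(self):
        hits = _hits([("a", "field soil", 3), ("a", "lake", 1)])
        prof = aggregate_habitats(hits, MAPPING)
        assert prof.loc["a", "soil"] == pytest.approx(0.75)
        assert prof.loc["a", "freshwater"] == pytest.approx(0.25)

    def test_unmapped_habitat_falls_to_other(self):
        hits = _hits([("a", "hot spring", 2)])
        prof = aggregate_habitats(hits, MAPPING)
        assert prof.loc["a", "other"] == pytest.approx(1.0)

    def test_negative_hits_rejected(self):
        with pytest.raises(ValueError):
            aggregate_habitats(_hits([("a", "lake", -1)]), MAPPING)

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        records = [
            (f"asv{i}", h, int(rng.integers(0, 10)))
            for i in range(30)
            for h in ("lake", "river", "field soil", "unknown spot")
        ]
        prof = aggregate_habitats(_hits(records), MAPPING)
        assert np.allclose(prof.sum(axis=1), 1.0)


class TestCommunityEnvironmentFractions:
    def _profiles(self, spec):
        rows = []
        for asv, env in spec.items():
            row = dict.fromkeys(ENVIRONMENTS, 0.0)
            row[env] = 1.0
            rows.append(pd.Series(row, name=asv))
        return pd.DataFrame(rows)

    def _counts(self, data, ids):
        dates = pd.date_range("2020-10-06", periods=len(data[0]), freq="D")
        return pd.DataFrame(data, index=ids, columns=dates)

    def test_single_asv_community_equals_its_profile(self):
        profiles = self._profiles({"a": "soil"})
        counts = self._counts([[10, 20]], ["a"])
        comp = community_environment_fractions(counts, profiles)
        assert np.allclose(comp["soil"], 1.0)

    def test_weighted_mean_arithmetic(self):
        profiles = self._profiles({"a": "freshwater", "b": "soil"})
        counts = self._counts([[300], [100]], ["a", "b"])
        comp = community_environment_fractions(counts, profiles)
        assert comp["freshwater"].iloc[0] == pytest.approx(0.75)
        assert comp["soil"].iloc[0] == pytest.approx(0.25)

    def test_equal_abundance_is_arithmetic_mean(self):
        profiles = self._profiles({"a": "freshwater", "b": "soil"})
        counts = self._counts([[50], [50]], ["a", "b"])
        comp = community_environment_fractions(counts, profiles)
        assert comp["freshwater"].iloc[0] == pytest.approx(0.5)

    def test_missing_profile_becomes_other_and_rows_sum_to_one(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=0)
        profiles = small_sim["habitats"].drop(index=rarefied.index[:5])
        comp = community_environment_fractions(rarefied, profiles)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_invariant_to_asv_ordering(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=0)
        profiles = small_sim["habitats"]
        a = community_environment_fractions(rarefied, profiles)
        perm = rarefied.sample(frac=1.0, random_state=1)
        b = community_environment_fractions(perm, profiles)
        pd.testing.assert_frame_equal(a, b)


class TestMannWhitney:
    def test_full_tie_gives_half_pairs(self):
        u, _, _ = mann_whitney_u([3.0, 3.0], [3.0, 3.0])
        assert u == pytest.approx(2.0)  # n_x * n_y / 2

    def test_complete_separation_small_sample(self):
        u, p1, _ = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p1 == pytest.approx(1 / 6)

    def test_four_below_four_above(self):
        _, p1, _ = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert p1 == pytest.approx(1 / 70)

    def test_interleaved_symmetric_two_sided_p_is_one(self):
        _, _, p2 = mann_whitney_u([1.0, 4.0], [2.0, 3.0])
        assert p2 == pytest.approx(1.0)

    def test_exact_matches_brute_force_enumeration(self):
        """Exact one-sided p equals the fraction of label arrangements with
        a U statistic at least as extreme, enumerated exhaustively."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(nx + ny, dtype=float) + 1)
            x, y = pooled[:nx], pooled[nx:]
            u_obs, p1, p2 = mann_whitney_u(x, y)

            def u_stat(xs, ys):
                return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

            us = [
                u_stat(pooled[list(c)], pooled[[i for i in range(nx + ny) if i not in c]])
                for c in itertools.combinations(range(nx + ny), nx)
            ]
            us = np.array(us)
            p_ge = (us >= u_obs).mean()
            p_le = (us <= u_obs).mean()
            assert p1 == pytest.approx(min(p_ge, p_le), abs=1e-12)
            assert p2 == pytest.approx(min(1.0, 2 * min(p_ge, p_le)), abs=1e-12)

    def test_exact_and_asymptotic_agree_moderately(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, _, p_exact = mann_whitney_u(x, y)
            import scipy.stats

            _, p_asym = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPeriodContrast:
    def _env_fracs(self, n_days=12, seed=0):
        rng = np.random.default_rng(seed)
        dates = pd.date_range("2020-10-06", periods=n_days, freq="D")
        vals = rng.dirichlet(np.ones(len(ENVIRONMENTS)), size=n_days)
        return pd.DataFrame(vals, index=dates, columns=ENVIRONMENTS)

    def _periods(self, env):
        d = env.index
        return {"pre": list(d[:4]), "early_event": list(d[4:8]), "post_event": list(d[8:])}

    def test_preevent_differences_average_to_zero(self):
        env = self._env_fracs()
        periods = self._periods(env)
        pre = env.loc[periods["pre"]]
        assert np.allclose((pre - pre.mean()).mean(axis=0), 0.0, atol=1e-12)

    def test_contrast_rows_and_direction(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=0)
        comp = community_environment_fractions(rarefied, small_sim["habitats"])
        periods = self._periods(comp)
        out = period_contrast(comp, periods)
        assert set(out["period"]) == {"early_event", "post_event"}
        assert len(out) == 2 * len(ENVIRONMENTS)
        for row in out.itertuples():
            assert row.direction == ("increase" if row.mean_difference_pct > 0 else "decrease")

    def test_overlapping_periods_rejected(self):
        env = self._env_fracs()
        d = env.index
        with pytest.raises(ValueError, match="overlap"):
            period_contrast(env, {"pre": list(d[:4]), "early_event": list(d[3:6])})

    def test_short_period_skipped_with_warning(self, caplog):
        env = self._env_fracs()
        d = env.index
        with caplog.at_level("WARNING"):
            out = period_contrast(
                env, {"pre": list(d[:4]), "early_event": [d[5]], "post_event": list(d[6:])}
            )
        assert "skipped" in caplog.text
        assert set(out["period"]) == {"post_event"}

    def test_designed_biofilm_shift_detected_in_direction(self):
        """Mobilized taxa (soil/biofilm-leaning) surge during the event, so
        biofilm representation should increase early-event vs pre."""
        increases = 0
        for seed in range(5):
            sim = simulate_campaign(SimulationConfig(rng_seed=seed))
            rarefied = rarefy(sim["counts"], 4000, seed=seed)
            comp = community_environment_fractions(rarefied, sim["habitats"])
            periods = self._periods(comp)
            out = period_contrast(comp, periods)
            row = out[(out.environment == "soil") & (out.period == "early_event")].iloc[0]
            increases += row["direction"] == "increase"
        assert increases >= 4
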