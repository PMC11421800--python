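import numpy as np
import pandas as pd
import pytest
import scipy.stats

from microcq import (
    SimulationConfig,
    class_fraction_timeseries,
    classify_all,
    classify_taxon,
    group_class_fractions,
    rarefy,
    simulate_campaign,
    surrogate_null,
)
from microcq.cq import shuffle_day_values

from .conftest import make_hydro


def _counts(rows, dates=None, ids=None):
    n = len(rows[0])
    dates = dates if dates is not None else pd.date_range("2020-10-06", periods=n, freq="D")
    ids = ids or [f"ASV{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=dates)


class TestClassifyTaxon:
    def test_counts_proportional_to_discharge_is_mobilized(self):
        hydro = make_hydro([0.2, 0.4, 0.8, 1.2, 1.6])
        abundance = pd.Series([10, 20, 40, 60, 80], index=hydro.index)
        res = classify_taxon(abundance, hydro)
        assert res["label"] == "mobilized"
        assert res["slope"] > 0
        assert res["p_value"] < 1e-6

    def test_two_detections_is_uncharacterized(self):
        hydro = make_hydro([0.2, 0.4, 0.8, 1.2, 1.6])
        abundance = pd.Series([10, 0, 0, 0, 5], index=hydro.index)
        res = classify_taxon(abundance, hydro)
        assert res["label"] == "uncharacterized"
        assert res["n_detections"] == 2

    def test_exact_negative_slope_hand_case(self):
        # Q = 1..5, counts = 50,40,30,20,10: slope exactly -10, perfect fit
        hydro = make_hydro([1, 2, 3, 4, 5])
        abundance = pd.Series([50, 40, 30, 20, 10], index=hydro.index)
        res = classify_taxon(abundance, hydro)
        assert res["label"] == "diluted"
        assert res["slope"] == pytest.approx(-10.0)
        assert res["p_value"] < 0.1

    def test_constant_abundance_is_static(self):
        hydro = make_hydro([1, 2, 3, 4, 5])
        abundance = pd.Series([7, 7, 7, 7, 7], index=hydro.index)
        res = classify_taxon(abundance, hydro)
        assert res["label"] == "static"
        assert res["slope"] == 0.0

    def test_agrees_with_first_principles_oracle(self):
        """Slope, p-value and label match scipy.stats.linregress on 1,000
        random small abundance series."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(5, 18))
            q = rng.uniform(0.1, 2.0, size=n)
            y = rng.poisson(rng.uniform(0, 30), size=n).astype(float)
            if (y > 0).sum() < 3 or np.var(y) == 0 or np.var(q) == 0:
                continue
            hydro = make_hydro(q)
            res = classify_taxon(pd.Series(y, index=hydro.index), hydro)
            ref = scipy.stats.linregress(q, y)
            assert res["slope"] == pytest.approx(ref.slope, rel=1e-9)
            assert res["p_value"] == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)
            if ref.pvalue < 0.1 and ref.slope > 0:
                assert res["label"] == "mobilized"
            elif ref.pvalue < 0.1 and ref.slope < 0:
                assert res["label"] == "diluted"
            else:
                assert res["label"] == "static"


class TestClassifyAll:
    def test_empty_matrix_gives_empty_table(self):
        hydro = make_hydro([1, 2, 3])
        out = classify_all(pd.DataFrame(columns=hydro.index), hydro)
        assert out.empty

    def test_vectorised_matches_per_taxon(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=3)
        table = classify_all(rarefied, small_sim["hydro"])
        for asv in rarefied.index[::7]:
            single = classify_taxon(rarefied.loc[asv], small_sim["hydro"])
            assert table.loc[asv, "label"] == single["label"]
            if single["label"] != "uncharacterized":
                assert table.loc[asv, "slope"] == pytest.approx(single["slope"])

    def test_recovers_true_classes_under_default_conditions(self):
        """Mobilized and diluted taxa with mean relative abundance >= 0.5%
        are recovered at >= 90% across seeds."""
        recovered, total = 0, 0
        for seed in range(20):
            sim = simulate_campaign(SimulationConfig(rng_seed=seed))
            rarefied = rarefy(sim["counts"], 4000, seed=seed)
            table = classify_all(rarefied, sim["hydro"])
            truth = pd.Series(sim["truth"].taxon_class)
            mean_rel = rarefied.sum(axis=1) / rarefied.to_numpy().sum()
            for label in ("mobilized", "diluted"):
                idx = truth[truth == label].index.intersection(rarefied.index)
                idx = idx[mean_rel.loc[idx] >= 0.005]
                recovered += (table.loc[idx, "label"] == label).sum()
                total += len(idx)
        assert total > 100
        assert recovered / total >= 0.90

    def test_proportions_equivalent_on_rarefied_matrix(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=1)
        a = classify_all(rarefied, small_sim["hydro"], use_proportions=False)
        b = classify_all(rarefied, small_sim["hydro"], use_proportions=True)
        assert (a["label"].astype(str) == b["label"].astype(str)).all()


class TestClassFractionTimeseries:
    def test_all_mobilized_gives_fraction_one(self):
        counts = _counts([[5, 6], [7, 8]])
        cls = pd.DataFrame(
            {"label": ["mobilized", "mobilized"]}, index=counts.index
        )
        frac = class_fraction_timeseries(counts, cls)
        assert np.allclose(frac["mobilized"], 1.0)

    def test_fractions_partition_each_day(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=2)
        cls = classify_all(rarefied, small_sim["hydro"])
        frac = class_fraction_timeseries(rarefied, cls)
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_mobilized_fraction_peaks_with_discharge(self):
        hits = 0
        for seed in range(10):
            sim = simulate_campaign(SimulationConfig(rng_seed=seed))
            rarefied = rarefy(sim["counts"], 4000, seed=seed)
            truth = pd.Series(sim["truth"].taxon_class).loc[rarefied.index]
            cls = pd.DataFrame({"label": truth.replace("event-only", "uncharacterized")})
            frac = class_fraction_timeseries(rarefied, cls)
            peak_day = sim["hydro"]["discharge_cms"].idxmax()
            if frac["mobilized"].idxmax() == peak_day:
                hits += 1
        assert hits >= 9

    def test_zero_retained_day_reported_missing(self):
        counts = _counts([[5, 0], [7, 0]])
        cls = pd.DataFrame({"label": ["mobilized", "diluted"]}, index=counts.index)
        frac = class_fraction_timeseries(counts, cls)
        assert frac.iloc[1].isna().all()


class TestGroupClassFractions:
    def test_toy_sequence_fraction(self):
        counts = _counts([[40, 40], [10, 10]], ids=["a", "b"])
        cls = pd.DataFrame({"label": ["mobilized", "static"]}, index=counts.index)
        groups = pd.Series({"a": "G", "b": "G"})
        out = group_class_fractions(cls, groups, counts)
        mob = out[(out.group == "G") & (out.label == "mobilized")].iloc[0]
        assert mob["fraction_sequences"] == pytest.approx(0.80)
        assert mob["fraction_taxa"] == pytest.approx(0.5)

    def test_fractions_partition_within_group(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=2)
        cls = classify_all(rarefied, small_sim["hydro"])
        groups = pd.Series("G1", index=rarefied.index)
        out = group_class_fractions(cls, groups, rarefied)
        assert out["fraction_sequences"].sum() == pytest.approx(1.0)
        assert out["fraction_taxa"].sum() == pytest.approx(1.0)

    def test_pure_diluted_group(self):
        counts = _counts([[9, 1], [4, 2]], ids=["a", "b"])
        cls = pd.DataFrame({"label": ["diluted", "diluted"]}, index=counts.index)
        groups = pd.Series({"a": "G", "b": "G"})
        out = group_class_fractions(cls, groups, counts)
        dil = out[out.label == "diluted"].iloc[0]
        assert dil["fraction_sequences"] == 1.0
        assert dil["fraction_taxa"] == 1.0


class TestSurrogates:
    def test_shuffle_preserves_per_day_multisets(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5, size=(30, 10)).astype(float)
        for scope in ("all", "nonzero"):
            shuffled = shuffle_day_values(y, np.random.default_rng(1), scope)
            for t in range(10):
                assert sorted(shuffled[:, t]) == sorted(y[:, t])
        # nonzero scope keeps zeros in place
        y[::3, 4] = 0.0
        shuffled = shuffle_day_values(y, np.random.default_rng(2), "nonzero")
        assert ((y[:, 4] == 0) == (shuffled[:, 4] == 0)).all()

    def test_same_seed_is_bit_identical(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=0)
        groups = pd.Series(
            [f"G{i % 4}" for i in range(len(rarefied))], index=rarefied.index
        )
        a = surrogate_null(rarefied, small_sim["hydro"], groups, n_surrogates=120, seed=5)
        b = surrogate_null(rarefied, small_sim["hydro"], groups, n_surrogates=120, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_fraction_outside_band_is_flagged(self, default_sim):
        """Strong true coupling puts at least one group's mobilized or
        diluted fraction outside the surrogate band."""
        rarefied = rarefy(default_sim["counts"], 4000, seed=0)
        from microcq import assign_groups

        groups = assign_groups(default_sim["taxonomy"], rarefied)
        out = surrogate_null(
            rarefied, default_sim["hydro"], groups, n_surrogates=200, seed=1
        )
        sig = out[out.significant]
        assert len(sig) >= 1
        for row in sig.itertuples():
            assert (
                row.observed_fraction < row.surrogate_p5
                or row.observed_fraction > row.surrogate_p95
            )

    def test_too_few_surrogates_rejected(self, small_sim):
        rarefied = rarefy(small_sim["counts"], 4000, seed=0)
        groups = pd.Series("G", index=rarefied.index)
        with pytest.raises(ValueError, match="100"):
            surrogate_null(rarefied, small_sim["hydro"], groups, n_surrogates=50)
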