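import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swardlab.diversity_effects import (
    additive_partition,
    expected_biomass,
    group_deviation,
    partition_per_period,
    proportional_deviation,
)


class TestExpectedBiomass:
    @pytest.mark.parametrize("mono, prop, expected", [
        (100.0, 0.5, 50.0),
        (100.0, 0.0, 0.0),
        (134.8, 0.2, 26.96),
    ])
    def test_product(self, mono, prop, expected):
        assert expected_biomass(mono, prop) == pytest.approx(expected)

    def test_missing_mono_rejected(self):
        with pytest.raises(ValueError):
            expected_biomass(float("nan"), 0.5)

    def test_proportion_bounds(self):
        with pytest.raises(ValueError):
            expected_biomass(10.0, 1.5)


class TestAdditivePartition:
    def test_pure_complementarity_worked_example(self):
        """Equal relative-yield surplus: net 30, CE 30, SE 0."""
        res = additive_partition([60.0, 120.0], [100.0, 200.0], [0.5, 0.5])
        assert res.net_effect == pytest.approx(30.0)
        assert res.complementarity == pytest.approx(30.0)
        assert res.selection == pytest.approx(0.0, abs=1e-12)

    def test_mixed_effects_worked_example(self):
        """Low-yielder over-performs: net 10, CE 30, SE -20."""
        res = additive_partition([80.0, 80.0], [100.0, 200.0], [0.5, 0.5])
        assert res.net_effect == pytest.approx(10.0)
        assert res.complementarity == pytest.approx(30.0)
        assert res.selection == pytest.approx(-20.0)

    def test_observed_equal_expected_gives_zeros(self):
        res = additive_partition([50.0, 100.0], [100.0, 200.0], [0.5, 0.5])
        assert res.net_effect == res.complementarity == res.selection == 0.0

    def test_zero_observed_is_valid(self):
        res = additive_partition([0.0, 100.0], [100.0, 200.0], [0.5, 0.5])
        assert res.delta_ry[0] == pytest.approx(-0.5)

    def test_zero_monoculture_rejected(self):
        with pytest.raises(ValueError, match="monoculture"):
            additive_partition([10.0, 10.0], [0.0, 100.0], [0.5, 0.5])

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="two species"):
            additive_partition([10.0], [100.0], [1.0])

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            additive_partition([10.0, 10.0], [100.0, 100.0], [0.3, 0.3])

    @given(
        n=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_net_equals_ce_plus_se(self, n, seed):
        rng = np.random.default_rng(seed)
        mono = rng.uniform(1.0, 500.0, n)
        obs = rng.uniform(0.0, 500.0, n)
        prop = rng.dirichlet(np.ones(n))
        res = additive_partition(obs, mono, prop)
        assert res.net_effect == pytest.approx(
            res.complementarity + res.selection, rel=1e-10, abs=1e-10
        )

    def test_selection_zero_when_all_mono_equal(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(10, 100, 5)
        res = additive_partition(obs, [120.0] * 5, [0.2] * 5)
        assert res.selection == pytest.approx(0.0, abs=1e-9)

    def test_selection_zero_when_all_delta_ry_equal(self):
        mono = np.array([80.0, 160.0, 240.0])
        prop = np.array([0.3, 0.3, 0.4])
        obs = mono * (prop + 0.07)  # dRY = 0.07 for every species
        res = additive_partition(obs, mono, prop)
        assert res.selection == pytest.approx(0.0, abs=1e-9)

    def test_species_order_invariance(self):
        obs, mono, prop = [60.0, 120.0, 30.0], [100.0, 200.0, 50.0], [0.4, 0.4, 0.2]
        a = additive_partition(obs, mono, prop)
        b = additive_partition(obs[::-1], mono[::-1], prop[::-1])
        assert a.net_effect == pytest.approx(b.net_effect)
        assert a.complementarity == pytest.approx(b.complementarity)
        assert a.selection == pytest.approx(b.selection)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_rescaling_biomass_scales_all_effects(self, c):
        obs, mono, prop = np.array([80.0, 80.0]), np.array([100.0, 200.0]), [0.5, 0.5]
        a = additive_partition(obs, mono, prop)
        b = additive_partition(c * obs, c * mono, prop)
        assert b.net_effect == pytest.approx(c * a.net_effect, rel=1e-9)
        assert b.complementarity == pytest.approx(c * a.complementarity, rel=1e-9)
        assert b.selection == pytest.approx(c * a.selection, rel=1e-9)


class TestDeviations:
    @pytest.mark.parametrize("obs, exp, d", [
        (100.0, 100.0, 0.0),
        (150.0, 100.0, 0.5),
        (50.0, 100.0, -0.5),
    ])
    def test_proportional_deviation(self, obs, exp, d):
        assert proportional_deviation(obs, exp) == pytest.approx(d)

    def test_nonpositive_expected_gives_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(proportional_deviation(10.0, 0.0))

    def test_singleton_group_equals_species_deviation(self):
        obs, exp = {"a": 150.0, "b": 10.0}, {"a": 100.0, "b": 40.0}
        assert group_deviation(obs, exp, ("a",)) == pytest.approx(
            proportional_deviation(150.0, 100.0)
        )

    def test_all_species_group_recovers_net_effect(self):
        obs = {"a": 60.0, "b": 120.0}
        exp = {"a": 50.0, "b": 100.0}
        d = group_deviation(obs, exp, ("a", "b"))
        net = sum(obs.values()) - sum(exp.values())
        assert d * sum(exp.values()) == pytest.approx(net)

    def test_matched_group_is_zero(self):
        obs = {"a": 50.0, "b": 999.0}
        exp = {"a": 50.0, "b": 1.0}
        assert group_deviation(obs, exp, ("a",)) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_deviation({}, {}, ())


class TestPartitionPerPeriod:
    def test_neutral_dataset_gives_all_zero_rows(self, neutral_dataset):
        ds = neutral_dataset
        effects, deviations = partition_per_period(ds.biomass, ds.design, ds.pool)
        comp = effects[effects["unit_type"] != "sward"]
        assert np.allclose(comp[["net_effect", "complementarity", "selection"]], 0.0,
                           atol=1e-9)
        assert np.allclose(deviations["D"], 0.0, atol=1e-12)

    def test_complementarity_only_matches_ground_truth(self, comp_only_dataset):
        ds = comp_only_dataset
        effects, _ = partition_per_period(ds.biomass, ds.design, ds.pool)
        comp = effects[effects["unit_type"] != "sward"]
        merged = comp.merge(ds.ground_truth, on=["composition", "period"],
                            suffixes=("", "_truth"))
        assert len(merged) == len(ds.ground_truth)
        np.testing.assert_allclose(merged["net_effect"], merged["net_effect_truth"],
                                   rtol=1e-9)
        np.testing.assert_allclose(merged["complementarity"],
                                   merged["complementarity_truth"], rtol=1e-9)
        assert np.allclose(merged["selection"], 0.0, atol=1e-9)
        assert (merged["complementarity"] > 0).all()

    def test_row_count_per_composition(self, neutral_dataset):
        ds = neutral_dataset
        effects, _ = partition_per_period(ds.biomass, ds.design, ds.pool)
        comp = effects[effects["unit_type"] != "sward"]
        n_mixtures = len(ds.design.compositions(min_richness=2))
        assert len(comp) == n_mixtures * len(ds.design.periods)

    def test_sward_aggregates_present(self, neutral_dataset):
        ds = neutral_dataset
        effects, _ = partition_per_period(ds.biomass, ds.design, ds.pool)
        sward = effects[effects["unit_type"] == "sward"]
        assert set(sward["sward_type"]) == {"2-", "2+", "5+"}

    def test_missing_monoculture_reference_raises(self, neutral_dataset):
        ds = neutral_dataset
        mono_pots = {p.pot_id for p in ds.design.pots
                     if p.richness == 1 and p.composition == ("tr",)}
        pruned = ds.biomass[~ds.biomass["pot_id"].isin(mono_pots)]
        with pytest.raises(ValueError, match="monoculture reference"):
            partition_per_period(pruned, ds.design, ds.pool)

    def test_observed_proportion_convention_labeled(self, neutral_dataset):
        ds = neutral_dataset
        effects, _ = partition_per_period(
            ds.biomass, ds.design, ds.pool, proportion_convention="observed"
        )
        assert (effects["proportion_convention"] == "observed").all()

    def test_pot_level_partition_has_one_row_per_pot(self, noisy_dataset):
        ds = noisy_dataset
        effects, _ = partition_per_period(ds.biomass, ds.design, ds.pool, level="pot")
        comp = effects[effects["unit_type"] != "sward"]
        n_mix_pots = sum(1 for p in ds.design.pots if p.richness >= 2)
        assert len(comp) == n_mix_pots * len(ds.design.periods)
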