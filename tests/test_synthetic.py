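"""Generator contracts: determinism, degenerate noise, unbiasedness,
multiplier semantics and ground-truth identities."""

import numpy as np
import pytest

from pbudget import (
    AMBIENT,
    ELEVATED,
    ConfigurationError,
    assemble_budgets,
    generate_measurements,
    sample_plot_budgets,
    truth,
)
from pbudget.budget import PRODUCTION_COMPONENTS
from pbudget.synthetic import TABLE_NAMES


class TestDeterminism:
    def test_identical_seed_gives_identical_tables(self, small_config):
        a = generate_measurements(small_config, seed=42)
        b = generate_measurements(small_config, seed=42)
        assert set(a) == set(TABLE_NAMES)
        for name in TABLE_NAMES:
            assert a[name].equals(b[name]), name

    def test_different_seeds_differ(self, small_config):
        a = generate_measurements(small_config, seed=1)
        b = generate_measurements(small_config, seed=2)
        assert not a["litterfall"]["value"].equals(b["litterfall"]["value"])


class TestNoiseModel:
    def test_cv_zero_reproduces_configured_means(self, cv0_config, cv0_tables):
        tissue = cv0_tables["tissue_concentration"]
        canopy = tissue[tissue["component"] == "canopy_green"]["value"]
        assert np.allclose(canopy, 0.5)
        soil = cv0_tables["soil_chemistry"]
        surface_total = soil[
            (soil["variable"] == "total_p") & (soil["depth_top_cm"] == 0)
        ]["value"]
        assert np.allclose(surface_total, 90.0)

    def test_no_negative_values_under_truncated_normal(self, site_config):
        tables = generate_measurements(site_config, seed=3)
        for name, frame in tables.items():
            assert (frame["value"] >= 0).all(), name

    def test_plot_effects_shared_across_tables(self, site_config):
        """The same plot-level factor drives a parameter wherever it appears:
        with sub-replicate noise off, unfumigated extracts equal the labile P
        concentrations in the soil-chemistry table."""
        config = site_config.model_copy(update={"subreplicate_cv_ratio": 0.0})
        tables = generate_measurements(config, seed=5)
        soil = tables["soil_chemistry"]
        fum = tables["fumigation_pairs"]
        for plot in ("A1", "E3"):
            lab = soil[
                (soil["plot_id"] == plot) & (soil["variable"] == "labile_p")
                & (soil["depth_top_cm"] == 0)
            ]["value"].iloc[0]
            unfum = fum[
                (fum["plot_id"] == plot) & (fum["variable"] == "unfumigated_p")
                & (fum["depth_top_cm"] == 0)
            ]["value"].iloc[0]
            assert unfum == pytest.approx(lab, rel=1e-12)

    def test_unbiased_at_many_plots(self, site_config):
        """Monte-Carlo check against closed-form truth: with 200 plots at
        CV = 0.1 every budget variable's sample mean falls within 3 standard
        errors of the generator truth."""
        data = site_config.model_dump()
        def set_cv(node):
            if isinstance(node, dict):
                if set(node) >= {"mean", "cv"}:
                    node["cv"] = 0.1
                else:
                    for v in node.values():
                        set_cv(v)
        set_cv(data)
        from pbudget.config import SiteConfig

        config = SiteConfig.model_validate(data)
        rng = np.random.default_rng(7)
        budgets = sample_plot_budgets(config, AMBIENT, 200, rng)
        expected = truth(config, AMBIENT)
        values = {k: np.array([b[k] for b in budgets]) for k in expected}
        failures = []
        for key, sample in values.items():
            se = sample.std(ddof=1) / np.sqrt(sample.size)
            if se == 0:
                assert sample.mean() == pytest.approx(expected[key])
                continue
            z = abs(sample.mean() - expected[key]) / se
            if z > 3.0:
                failures.append((key, z))
        # a few >3 SE excursions among ~90 correlated variables are chance;
        # systematic bias would fail many at once
        assert len(failures) <= 4, failures


class TestMultipliers:
    def test_identity_multipliers_leave_elevated_equal_ambient(self, site_config):
        assert truth(site_config, ELEVATED) == pytest.approx(
            truth(site_config, AMBIENT)
        )

    def test_uptake_multiplier_scales_uptake_exactly(self, site_config):
        config = site_config.model_copy(update={"co2_multipliers": {"uptake": 1.08}})
        amb, ele = truth(config, AMBIENT), truth(config, ELEVATED)
        assert ele["flux:uptake"] == pytest.approx(1.08 * amb["flux:uptake"])
        assert ele["flux:resorption:total"] == pytest.approx(
            amb["flux:resorption:total"]
        )
        # identity preserved: demand absorbs the uptake increment
        assert ele["flux:demand"] == pytest.approx(
            ele["flux:resorption:total"] + ele["flux:uptake"]
        )

    def test_demand_multiplier_scales_all_recycling_fluxes(self, site_config):
        config = site_config.model_copy(update={"co2_multipliers": {"demand": 1.06}})
        amb, ele = truth(config, AMBIENT), truth(config, ELEVATED)
        for key in ("flux:demand", "flux:uptake", "flux:resorption:total"):
            assert ele[key] == pytest.approx(1.06 * amb[key])

    def test_pool_multiplier_realized_in_generated_tables(self, cv0_config):
        config = cv0_config.model_copy(
            update={"co2_multipliers": {"pool:soil_microbial": 1.5}}
        )
        budgets = assemble_budgets(generate_measurements(config, seed=9))
        by_treatment = {}
        for b in budgets:
            by_treatment.setdefault(b.treatment, []).append(b["pool:soil_microbial"])
        assert np.mean(by_treatment[ELEVATED]) == pytest.approx(
            1.5 * np.mean(by_treatment[AMBIENT])
        )

    def test_unknown_multiplier_rejected(self, site_config):
        config = site_config.model_copy(
            update={"co2_multipliers": {"derived:mrt": 0.9}}
        )
        with pytest.raises(ConfigurationError):
            truth(config, ELEVATED)


class TestGeneratorTruth:
    def test_budget_identities(self, ambient_truth):
        t = ambient_truth
        assert t["flux:demand"] - t["flux:resorption:total"] - t["flux:uptake"] == (
            pytest.approx(0.0, abs=1e-12)
        )
        production_sum = sum(
            t[f"flux:production:{c}"] for c in PRODUCTION_COMPONENTS
        )
        assert t["flux:demand"] == pytest.approx(production_sum)
        assert t["pool:soil_total"] == pytest.approx(
            t["pool:soil_organic"] + t["pool:soil_inorganic"]
        )

    def test_microbial_share_of_organic_soil_p(self, ambient_truth):
        ratio = ambient_truth["pool:soil_microbial"] / ambient_truth["pool:soil_organic"]
        assert ratio == pytest.approx(0.238, abs=0.001)
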