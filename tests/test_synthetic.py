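"""Generators: design fidelity, determinism, and planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drugscreen as ds
from drugscreen.synthetic import (
    PLATE_DRUG_CAPACITY,
    VEHICLE_WELLS,
    default_drug_panel,
)


class TestDilutionSeries:
    @pytest.mark.parametrize(
        "max_dose, n, ratio, expected_min, decimals",
        [
            (10, 6, 3, 0.04, 2),     # six-point screening series
            (10, 9, 3, 0.0015, 4),   # nine-point grid series
        ],
    )
    def test_screening_series_minima(self, max_dose, n, ratio, expected_min, decimals):
        series = ds.generate_dilution_series(max_dose, n, ratio)
        assert series[0] == max_dose
        assert round(float(series.min()), decimals) == expected_min

    def test_two_point_halving(self):
        assert ds.generate_dilution_series(1, 2, 2).tolist() == [1.0, 0.5]

    @pytest.mark.parametrize(
        "max_dose, n, ratio",
        [(-1, 6, 3), (0, 6, 3), (10, 1, 3), (10, 6, 1.0), (10, 6, 0.5)],
    )
    def test_invalid_designs_rejected(self, max_dose, n, ratio):
        with pytest.raises(ds.DesignError):
            ds.generate_dilution_series(max_dose, n, ratio)

    @given(
        max_dose=st.floats(1e-3, 1e3),
        n=st.integers(2, 12),
        ratio=st.floats(1.1, 10),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_descending_geometric(self, max_dose, n, ratio):
        series = ds.generate_dilution_series(max_dose, n, ratio)
        assert len(series) == n
        assert np.all(np.diff(series) < 0)
        ratios = series[:-1] / series[1:]
        assert np.allclose(ratios, ratio, rtol=1e-9)


class TestSimulateScreen:
    def test_deterministic_for_fixed_seed(self, default_config):
        t1, g1 = ds.simulate_screen(default_config)
        t2, g2 = ds.simulate_screen(default_config)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1 == g2

    def test_different_seeds_differ(self, default_config):
        t1, _ = ds.simulate_screen(default_config)
        t2, _ = ds.simulate_screen(ds.SimulationConfig(seed=1))
        assert not t1["raw_intensity"].equals(t2["raw_intensity"])

    def test_plate_design(self, default_config):
        table, _ = ds.simulate_screen(default_config)
        for _, plate in table.groupby("plate_id"):
            assert (plate["role"] == "vehicle").sum() == 18
            ring = plate["row"].isin(list("ABOP")) | plate["col"].isin([1, 2, 23, 24])
            assert (plate.loc[ring, "role"] == "buffer").all()
            assert len(plate) == 384

    def test_triplicate_six_point_per_arm(self, default_config):
        table, _ = ds.simulate_screen(default_config)
        treated = table[table["role"] == "treated"]
        counts = treated.groupby(["cell_line", "arm", "compound", "dose_uM"]).size()
        assert (counts == 3).all()
        doses = treated.groupby(["cell_line", "arm", "compound"])["dose_uM"].nunique()
        assert (doses == 6).all()

    def test_oversized_panel_splits_plates(self):
        drugs = tuple(
            ds.DrugSpec(name=f"x{i:02d}", ec50_uM=1.0)
            for i in range(PLATE_DRUG_CAPACITY + 3)
        )
        cfg = ds.SimulationConfig(
            seed=0, cell_lines=("L1",), drugs=drugs, sensitizer_effect={}
        )
        table, _ = ds.simulate_screen(cfg)
        single = table[table["arm"] == "single"]
        assert single["plate_id"].nunique() == 2
        assert set(single.loc[single["role"] == "treated", "compound"]) == {
            d.name for d in drugs
        }

    def test_noiseless_wells_equal_planted_curve(self, noiseless_config):
        table, truth = ds.simulate_screen(noiseless_config)
        normalized = ds.normalize_plate(table)
        treated = normalized[normalized["role"] == "treated"]
        for (compound, arm), grp in treated.groupby(["compound", "arm"]):
            p = truth["drugs"][compound][arm]
            expected = p["c"] + (p["d"] - p["c"]) / (
                1 + (grp["dose_uM"] / p["e"]) ** p["b"]
            )
            assert np.allclose(grp["relative_ctg"], expected, atol=1e-12)

    def test_sensitizer_shifts_planted_ec50_and_delta(self, default_config):
        _, truth = ds.simulate_screen(default_config)
        shifted = truth["drugs"]["cmpd04"]
        assert shifted["sensitized"]["e"] == pytest.approx(shifted["single"]["e"] / 3)
        # the planted AUC drop for the shifted drug exceeds every unshifted drug's
        def planted_auc(p):
            curve = ds.DoseResponseCurve(
                b=p["b"], c=p["c"], d=p["d"], e=p["e"], rss=0, n_obs=0, converged=True
            )
            return ds.compute_auc(curve, (0.0412, 10.0))

        deltas = {
            name: planted_auc(entry["single"]) - planted_auc(entry["sensitized"])
            for name, entry in truth["drugs"].items()
        }
        assert deltas["cmpd04"] > max(v for k, v in deltas.items() if k != "cmpd04")

    def test_vehicle_wells_are_fixed_interior_positions(self):
        rows = {r for r, _ in VEHICLE_WELLS}
        cols = {c for _, c in VEHICLE_WELLS}
        assert len(VEHICLE_WELLS) == 18
        assert len(set(VEHICLE_WELLS)) == 18
        assert rows.isdisjoint(set("ABOP")) and cols.isdisjoint({1, 2, 23, 24})


class TestSimulateGrid:
    def test_additive_identical_agents_closed_form(self, unit_agent_grid_config):
        table, truth = ds.simulate_grid(unit_agent_grid_config, "agentA", "agentB")
        surface = ds.average_grid(table)
        i = int(np.argmin(np.abs(surface.doses_a - 1.1111111)))
        j = int(np.argmin(np.abs(surface.doses_b - 1.1111111)))
        a, b = surface.doses_a[i], surface.doses_b[j]
        assert surface.viability[i, j] == pytest.approx(1 / (1 + a + b), abs=1e-12)

    def test_zero_dose_margin_is_single_agent_curve(self, unit_agent_grid_config):
        table, _ = ds.simulate_grid(unit_agent_grid_config, "agentA", "agentB")
        surface = ds.average_grid(table)
        j0 = int(np.flatnonzero(surface.doses_b == 0)[0])
        margin = surface.viability[:, j0]
        expected = np.where(
            surface.doses_a == 0, 1.0, 1 / (1 + surface.doses_a)
        )
        assert np.allclose(margin, expected, atol=1e-12)

    def test_supra_lowers_interior_viability(self, unit_agent_grid_config):
        cfg_supra = ds.SimulationConfig(
            seed=0, noise_cv=0.0, drugs=unit_agent_grid_config.drugs,
            sensitizer_effect={}, grid_interaction="supra", grid_strength=2.0,
        )
        add, _ = ds.simulate_grid(unit_agent_grid_config, "agentA", "agentB")
        sup, _ = ds.simulate_grid(cfg_supra, "agentA", "agentB")
        va = ds.average_grid(add).viability
        vs = ds.average_grid(sup).viability
        interior = np.ix_(
            ds.average_grid(add).doses_a > 0, ds.average_grid(add).doses_b > 0
        )
        assert np.all(vs[interior] <= va[interior] + 1e-12)
        assert np.any(vs[interior] < va[interior])

    def test_grid_deterministic(self, default_config):
        t1, _ = ds.simulate_grid(default_config, "cmpd01", "cmpd02")
        t2, _ = ds.simulate_grid(default_config, "cmpd01", "cmpd02")
        pd.testing.assert_frame_equal(t1, t2)

    def test_mixed_agent_additive_surface_satisfies_loewe_identity(self):
        # non-identical curves: the planted surface must still solve
        # a/A(E) + b/B(E) = 1 with A, B the exact single-agent inversions
        ca = ds.DrugSpec(name="a", ec50_uM=0.5, slope=1.5, floor=0.1).curve()
        cb = ds.DrugSpec(name="b", ec50_uM=2.0, slope=0.8, floor=0.0).curve()
        from drugscreen.synthetic import loewe_additive_effect

        for a, b in [(0.3, 0.3), (1.0, 5.0), (0.01, 0.2)]:
            E = loewe_additive_effect(ca, cb, a, b)
            A = ds.dose_for_effect(ca, E)
            B = ds.dose_for_effect(cb, E)
            assert a / A + b / B == pytest.approx(1.0, abs=1e-9)


class TestSimulateOmics:
    def test_deterministic(self, default_config):
        r1 = ds.simulate_omics(default_config)
        r2 = ds.simulate_omics(default_config)
        pd.testing.assert_frame_equal(r1["proteins"], r2["proteins"])
        pd.testing.assert_frame_equal(r1["genes"], r2["genes"])
        assert r1["pathways"] == r2["pathways"]

    def test_planted_set_recovered_exactly(self, default_config):
        res = ds.simulate_omics(default_config)
        stage1 = ds.filter_stabilized_proteins(res["proteins"])
        stage2 = ds.filter_nonupregulated_genes(res["genes"])
        mapping = dict(zip(res["proteins"]["protein_id"], res["proteins"]["gene_id"]))
        nom = ds.nominate(stage1, stage2, ds.PathwayCollection(res["pathways"]), mapping)
        assert sorted(nom.stage4_proteins) == sorted(res["truth"]["stabilized_in_pathway"])

    def test_no_planted_effects_yields_empty_nomination(self):
        cfg = ds.SimulationConfig(
            seed=0, omics=ds.OmicsSpec(n_stabilized=0, n_in_pathway=0)
        )
        res = ds.simulate_omics(cfg)
        assert ds.filter_stabilized_proteins(res["proteins"]) == []
        assert (res["proteins"][["q_A1336", "q_A2780"]].min() >= 0.05).any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_stabilized": 600, "n_proteins": 500},
            {"n_in_pathway": 20, "n_stabilized": 10},
            {"n_proteins": 500, "n_genes": 100},
        ],
    )
    def test_inconsistent_spec_rejected(self, kwargs):
        with pytest.raises(ds.ConfigError):
            ds.OmicsSpec(**kwargs)


class TestSimulateTumours:
    def test_noiseless_slope_recovered_exactly(self):
        cfg = ds.SimulationConfig(
            seed=0, noise_cv=0.0,
            tumour=ds.TumourSpec(arms={"arm": 0.3}, animals_per_arm=3),
        )
        table, _ = ds.simulate_tumours(cfg)
        fits = ds.fit_growth_rates(table)
        assert np.allclose(fits["beta1"], 0.3, atol=1e-12)

    def test_zero_rate_means_constant_volume(self):
        cfg = ds.SimulationConfig(
            seed=0, noise_cv=0.0,
            tumour=ds.TumourSpec(arms={"flat": 0.0}, animals_per_arm=2),
        )
        table, _ = ds.simulate_tumours(cfg)
        vols = ds.tumour_volume(table["L_cm"], table["W_cm"])
        for _, grp in table.assign(v=vols).groupby("animal"):
            assert np.ptp(grp["v"]) == pytest.approx(0, abs=1e-9)

    def test_negative_days_rejected(self):
        with pytest.raises(ds.ConfigError):
            ds.TumourSpec(days=(-1, 0, 3))

    def test_mean_slope_unbiased_under_noise(self):
        # Monte-Carlo oracle: mean fitted slope within 5% of planted at CV 10%
        slopes = []
        for seed in range(200):
            cfg = ds.SimulationConfig(
                seed=seed, noise_cv=0.1,
                tumour=ds.TumourSpec(arms={"arm": 0.3}, animals_per_arm=1),
            )
            table, _ = ds.simulate_tumours(cfg)
            slopes.append(ds.fit_growth_rates(table)["beta1"].iloc[0])
        assert abs(np.mean(slopes) - 0.3) / 0.3 < 0.05


def test_config_validation_errors():
    with pytest.raises(ds.ConfigError):
        ds.SimulationConfig(noise_cv=-0.1)
    with pytest.raises(ds.ConfigError):
        ds.SimulationConfig(sensitizer_effect={"cmpd04": 0.0})
    with pytest.raises(ds.ConfigError):
        ds.SimulationConfig(sensitizer_effect={"nope": 2.0})
    with pytest.raises(ds.ConfigError):
        ds.SimulationConfig(grid_interaction="supra", grid_strength=0.5)
    with pytest.raises(ds.ConfigError):
        ds.DrugSpec(name="bad", ec50_uM=-1.0)
    assert len(default_drug_panel()) == 12
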