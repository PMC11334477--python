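import numpy as np
import pandas as pd
import pytest

from eutflux import isotopic_mfa as im
from eutflux import synthetic_data as sd
from eutflux.pso import minimize_pso


class TestNetwork:
    def test_three_compartments(self, eut_network):
        audit = eut_network.audit()
        assert audit["n_compartments"] == 3
        assert set(audit["compartments"]) == {"environment", "cytoplasm", "bmc"}

    def test_audit_reports_twin_counts(self, eut_network):
        audit = eut_network.audit()
        assert audit["n_species_with_twins"] > audit["n_species"]
        assert audit["n_reactions"] >= 12

    def test_cyt_etoh_disabled_means_ethanol_only_from_eutg(self, eut_network):
        sources = [r.id for r in eut_network.reactions if "ethanol" in r.products]
        assert sources == ["eutg"]

    def test_cyt_etoh_optional_route(self):
        net = im.build_eut_network(cyt_etoh=True)
        sources = {r.id for r in net.reactions if "ethanol" in r.products}
        assert sources == {"eutg", "cyt_etoh"}

    def test_bmc_reactions_consume_bmc_pools(self, eut_network):
        bmc_species = {s.id for s in eut_network.species if s.compartment == "bmc"}
        for rid in ("eute", "eutd", "eutg", "aal_release"):
            rxn = next(r for r in eut_network.reactions if r.id == rid)
            assert set(rxn.substrates) <= bmc_species

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            im.build_eut_network(tracer_purity=0.0)


class TestSteadyStateRelations:
    def test_reported_flux_values_balance(self):
        """EA branch closes at the reported fluxes: 2*2.7 + 1.7 = 7.1."""
        p = im.tracer_reference_parameters()
        res = im.steady_state_flux_relations(p)
        assert res["bmc_acetaldehyde"] == pytest.approx(0.0, abs=1e-12)
        assert res["cytosolic_acetyl_p"] == pytest.approx(0.0, abs=1e-12)
        assert res["ammonium"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_fluxes_balance(self):
        p = im.FluxParameterSet(
            x0=0.02, mu=0.0, glycerol0=1.0, ea0=1.0,
            v_glyc_uptake=0, v_glycolysis=0, v_ea=0, v_eutg=0, v_aal=0,
            v_acex=0, v_pta=0, v_nh4x=0,
        )
        assert all(abs(v) < 1e-12 for v in im.steady_state_flux_relations(p).values())

    def test_printed_rounded_values_leave_small_acp_residual(self):
        """At v_glycolysis 2.5, v_EutD 2.7, v_AceX 1.6, v_Pta 3.5 the acetyl-P
        balance misses by 0.1 — above numerical tolerance though within the
        reported flux uncertainty."""
        p = im.FluxParameterSet(
            x0=0.026, mu=0.45, glycerol0=30, ea0=20,
            v_glyc_uptake=14.7, v_glycolysis=2.5, v_ea=7.1, v_eutg=2.7,
            v_aal=1.7, v_acex=1.6, v_pta=3.5, v_nh4x=0.9,
        )
        res = im.steady_state_flux_relations(p)
        assert res["cytosolic_acetyl_p"] == pytest.approx(0.1, abs=1e-12)
        with pytest.raises(ValueError, match="cytosolic_acetyl_p"):
            im.validate_flux_set(p)


class TestSimulate:
    def test_null_dynamics_constant(self, eut_network):
        p = im.FluxParameterSet(
            x0=0.02, mu=0.0, glycerol0=30.0, ea0=20.0,
            v_glyc_uptake=0, v_glycolysis=0, v_ea=0, v_eutg=0, v_aal=0,
            v_acex=0, v_pta=0, v_nh4x=0, etoh0_unlabeled=0.5,
        )
        sim = im.simulate(eut_network, p, np.linspace(0, 5, 6))
        for col in ("biomass", "glycerol", "ethanolamine", "ammonium"):
            assert np.allclose(sim[col], sim[col].iloc[0])

    def test_ethanol_evaporation_closed_form(self, eut_network):
        """With production off, extracellular ethanol decays as e^{-0.0379 t}."""
        p = im.FluxParameterSet(
            x0=0.02, mu=0.0, glycerol0=30.0, ea0=20.0,
            v_glyc_uptake=0, v_glycolysis=0, v_ea=0, v_eutg=0, v_aal=0,
            v_acex=0, v_pta=0, v_nh4x=0, etoh0_unlabeled=1.0,
        )
        t = np.linspace(0, 10, 11)
        sim = im.simulate(eut_network, p, t)
        np.testing.assert_allclose(
            sim["ethanol_unlabeled"], np.exp(-0.0379 * t), rtol=1e-6
        )

    def test_carbon_and_nitrogen_conservation(self, eut_network, reference_fluxes):
        """Pools plus cumulative sinks conserve C and N to < 1e-6 relative."""
        t = np.linspace(0, 7, 15)
        sim = im.simulate(eut_network, reference_fluxes, t, full_state=True)
        s = lambda name: sim[f"state:{name}"]
        carbon = (
            3 * (s("glycerol") + s("cum_growth_glyc")) + s("cum_co2")
            + 2 * (s("ea_u") + s("ea_l")
                   + s("aal_bmc_u") + s("aal_bmc_l")
                   + s("accoa_bmc_u") + s("accoa_bmc_l")
                   + s("acp_u") + s("acp_l")
                   + s("etoh_u") + s("etoh_l")
                   + s("ace_u") + s("ace_l")
                   + s("aal_env_u") + s("aal_env_l")
                   + s("cum_accoa_u") + s("cum_accoa_l")
                   + s("cum_evap_u") + s("cum_evap_l"))
        )
        nitrogen = s("ea_u") + s("ea_l") + s("nh4") + s("cum_nh4_assim")
        assert (carbon.max() - carbon.min()) / carbon.iloc[0] < 1e-6
        assert (nitrogen.max() - nitrogen.min()) / nitrogen.iloc[0] < 1e-6

    def test_label_closure_against_label_blind_totals(self, eut_network, reference_fluxes):
        """Labeled + unlabeled twins reproduce the closed-form total pools."""
        from eutflux.physiology import PhysioParams, predict_concentrations

        p = reference_fluxes
        t = np.linspace(0, 7, 8)
        sim = im.simulate(eut_network, p, t, rtol=1e-10, atol=1e-12)
        blind = predict_concentrations(
            PhysioParams(
                x0=p.x0, mu=p.mu,
                substrates={"glycerol": (p.glycerol0, p.v_glyc_uptake),
                            "ethanolamine": (p.ea0, p.v_ea)},
                products={"acetate": (0.0, p.v_acex, 0.0),
                          "ethanol": (0.0, p.v_eutg, eut_network.k_evap)},
            ),
            t,
        )
        pairs = [
            ("glycerol", sim["glycerol"]),
            ("ethanolamine", sim["ethanolamine"]),
            ("acetate", sim["acetate_unlabeled"] + sim["acetate_labeled"]),
            ("ethanol", sim["ethanol_unlabeled"] + sim["ethanol_labeled"]),
        ]
        for q, total in pairs:
            expected = blind[blind["quantity"] == q]["value"].to_numpy()
            np.testing.assert_allclose(total, expected, atol=1e-7)

    def test_fast_route_matches_ode_route(self, eut_network, reference_fluxes):
        t = np.linspace(0.5, 7, 9)
        ode = im.simulate(eut_network, reference_fluxes, t, rtol=1e-10, atol=1e-12)
        fast = im.simulate_fast(eut_network, reference_fluxes, t)
        for col in im.OBSERVABLE_COLUMNS:
            np.testing.assert_allclose(fast[col], ode[col], atol=5e-7, rtol=1e-6)

    def test_tracer_dominates_ethanol_labeling(self, eut_network, reference_fluxes):
        """Without a cytosolic route, ethanol is virtually fully labeled."""
        sim = im.simulate(eut_network, reference_fluxes, np.linspace(0, 7, 8))
        final_l = sim["ethanol_labeled"].iloc[-1]
        final_u = sim["ethanol_unlabeled"].iloc[-1]
        assert final_l > 50 * final_u

    def test_substrate_exhaustion_raises(self, eut_network, reference_fluxes):
        with pytest.raises(RuntimeError, match="exhaust|negative"):
            im.simulate_fast(eut_network, reference_fluxes, np.linspace(0, 11, 12))

    def test_inconsistent_params_rejected(self, eut_network):
        p = im.FluxParameterSet(
            x0=0.02, mu=0.3, glycerol0=30, ea0=20,
            v_glyc_uptake=10, v_glycolysis=2, v_ea=7.1, v_eutg=2.7,
            v_aal=0.0, v_acex=1.6, v_pta=3.1, v_nh4x=0.9,
        )
        with pytest.raises(ValueError, match="bmc_acetaldehyde"):
            im.simulate(eut_network, p, [0.0, 1.0])


class TestObjective:
    def test_zero_on_generating_parameters(self, eut_network, reference_fluxes):
        design = sd.SamplingDesign(0, 7, 10, 1, 0.0, 0.0, rng_seed=0)
        data = sd.generate_labeling_timeseries(reference_fluxes, design, network=eut_network)
        data["sd"] = 0.02
        f = im.objective(reference_fluxes, data, eut_network, fast=False)
        assert f < 1e-6

    def test_single_point_arithmetic(self, eut_network):
        """x = 2, y = 1, sigma = 0.5 -> ((2-1)/0.5)^2 = 4."""
        p = im.FluxParameterSet(
            x0=1.0, mu=0.0, glycerol0=5.0, ea0=5.0,
            v_glyc_uptake=0, v_glycolysis=0, v_ea=0, v_eutg=0, v_aal=0,
            v_acex=0, v_pta=0, v_nh4x=0,
        )  # simulated ammonium stays 0 -> y = 0; use x = 2, sigma = 1 -> 4
        data = pd.DataFrame(
            [(1, 1.0, "ammonium", "total", 2.0, 1.0)],
            columns=["replicate", "time_h", "quantity", "label_state", "value", "sd"],
        )
        assert im.objective(p, data, im.build_eut_network()) == pytest.approx(4.0)

    def test_matches_naive_residual_loop(self, eut_network, reference_fluxes):
        design = sd.SamplingDesign(0, 7, 8, 2, 0.02, 0.02, rng_seed=9)
        data = sd.generate_labeling_timeseries(reference_fluxes, design, network=eut_network)
        f = im.objective(reference_fluxes, data, eut_network, fast=True)
        sim = im.simulate_fast(eut_network, reference_fluxes, np.unique(data["time_h"]))
        sim = sim.set_index("time_h")
        colmap = dict(im._QUANTITY_TO_COLUMN)
        total = 0.0
        for _, row in data.iterrows():
            y = sim.loc[row["time_h"], colmap[(row["quantity"], row["label_state"])]]
            total += ((row["value"] - y) / row["sd"]) ** 2
        assert f == pytest.approx(total, rel=1e-12)

    def test_missing_sd_rejected(self, eut_network, reference_fluxes):
        data = pd.DataFrame(
            [(1, 1.0, "ammonium", "total", 2.0, np.nan)],
            columns=["replicate", "time_h", "quantity", "label_state", "value", "sd"],
        )
        with pytest.raises(Exception):
            im.objective(reference_fluxes, data, eut_network)


class TestPso:
    def test_sphere_self_test(self):
        """The optimizer localizes the sphere minimum to < 1e-3."""
        res = minimize_pso(
            lambda x: float(np.dot(x, x)), [(-5.0, 5.0)] * 5,
            iterations=400, swarm_size=30, seed=2,
        )
        assert np.all(np.abs(res.x) < 1e-3)
        assert res.fun < 1e-6

    def test_trace_non_increasing(self):
        res = minimize_pso(
            lambda x: float(np.dot(x, x)), [(-5.0, 5.0)] * 3,
            iterations=100, swarm_size=10, seed=0,
        )
        assert np.all(np.diff(res.trace) <= 0)

    def test_seeded_determinism(self, eut_network, reference_fluxes):
        design = sd.SamplingDesign(0, 7, 8, 1, 0.02, 0.02, rng_seed=0)
        data = sd.generate_labeling_timeseries(reference_fluxes, design, network=eut_network)
        fit1 = im.pso_fit(data, eut_network, iterations=30, swarm_size=10, seed=5)
        fit2 = im.pso_fit(data, eut_network, iterations=30, swarm_size=10, seed=5)
        np.testing.assert_array_equal(fit1.free_values, fit2.free_values)
        assert fit1.objective == fit2.objective

    def test_result_within_bounds(self, eut_network, reference_fluxes):
        design = sd.SamplingDesign(0, 7, 8, 1, 0.02, 0.02, rng_seed=1)
        data = sd.generate_labeling_timeseries(reference_fluxes, design, network=eut_network)
        fit = im.pso_fit(data, eut_network, iterations=30, swarm_size=10, seed=3)
        for name, value in zip(fit.free_names, fit.free_values):
            lo, hi = fit.bounds[name]
            assert lo - 1e-12 <= value <= hi + 1e-12

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            minimize_pso(lambda x: 0.0, [(0.0, np.inf)], iterations=1, swarm_size=2)

    def test_noisy_recovery_median_under_10pct(self, eut_network, reference_fluxes):
        """Across seeded 2%-CV tracer datasets, the fitted fluxes land within
        10% of the generator (median), using desk-scale swarm settings plus
        the local polish."""
        names = ("v_eutg", "v_nh4x", "v_ea", "v_glycolysis", "v_acex")
        errs = {k: [] for k in names}
        for s in range(8):
            design = sd.SamplingDesign(0, 7, 12, 3, 0.02, 0.02, rng_seed=500 + s)
            data = sd.generate_labeling_timeseries(reference_fluxes, design, network=eut_network)
            fit = im.pso_fit(data, eut_network, iterations=250, swarm_size=40,
                             seed=s, polish=True)
            for k in names:
                true = getattr(reference_fluxes, k)
                errs[k].append(abs(getattr(fit.params, k) - true) / true)
        for k, v in errs.items():
            assert np.median(v) < 0.10, (k, v)


class TestLabeledFraction:
    def test_measured_ethanol_pools(self):
        """4.66 mM 13C2- vs 0.47 mM 12C2-ethanol -> ~91% labeled."""
        f = im.labeled_fraction(4.66, 0.47)
        assert f == pytest.approx(4.66 / 5.13, rel=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            im.labeled_fraction(0.0, 0.0)
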