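"""The four derived analyses: minimal glucose, relative error, carbon
recovery, and the counterfactual maximum ionone yield."""

import numpy as np
import pytest

from vertex_oracle import brute_force_optimum

from ionoflux.contextualization import StrainMeasurement, constrain_strain
from ionoflux.fba_core import optimize
from ionoflux.interrogation import (
    InterrogationError,
    biomass_carbon_content,
    carbon_recovery,
    counterfactual_max_ionone,
    interrogate_strain,
    predict_min_glucose,
    relative_error,
    reports_to_frame,
)
from ionoflux.model_io import MetabolicModel, Metabolite, Reaction
from ionoflux.pathway_extension import (
    RXN_CCD1_DOUBLE,
    RXN_CCD1_SINGLE,
    SINK_APO27,
    SINK_C14DIAL,
    EX_BIONONE,
)
from ionoflux.synthetic_data import make_true_state, simulate_measurements


def _noiseless_measurement(extended_model, pathway_spec, mu=0.3,
                           accum=0.005, cleave=0.001):
    state = make_true_state(extended_model, mu, {"beta_carotene": accum},
                            cleavage_double=cleave)
    (meas,) = simulate_measurements(extended_model, state, pathway_spec,
                                    noise_cv=0.0, seed=0)
    return state, meas


class TestPredictMinGlucose:
    def test_exact_recovery_at_zero_tolerance(self, extended_model, pathway_spec):
        state, meas = _noiseless_measurement(extended_model, pathway_spec)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec,
                                          tol_frac=0.0)
        q, sol = predict_min_glucose(constrained)
        assert sol.parsimonious
        assert q == pytest.approx(state.q_glc, rel=1e-5)

    def test_closed_form_yield(self, extended_model, pathway_spec, toy_config):
        """Without products the minimum uptake is mu/Y with the designed yield."""
        meas = StrainMeasurement("plain", mu=0.3, q_co2=50.0)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec,
                                          tol_frac=0.0)
        # relax CO2 (free) so only growth binds; ngam = 0.7 from the fixture
        constrained.set_bounds("EX_co2_e", 0, 1000)
        q, _ = predict_min_glucose(constrained)
        assert q == pytest.approx(toy_config.min_glucose(0.3, ngam=0.7), rel=1e-6)

    def test_forced_product_drain_increases_uptake(self, extended_model,
                                                   pathway_spec):
        lo = StrainMeasurement("lo", mu=0.3, q_co2=50.0, total_carotenoids=1.0)
        hi = StrainMeasurement("hi", mu=0.3, q_co2=50.0, total_carotenoids=5.0)
        uptakes = []
        for m in (lo, hi):
            constrained, _ = constrain_strain(extended_model, m, pathway_spec,
                                              tol_frac=0.0)
            constrained.set_bounds("EX_co2_e", 0, 1000)
            uptakes.append(predict_min_glucose(constrained)[0])
        assert uptakes[1] > uptakes[0]

    def test_infeasible_constraints_reported_distinctly(self, extended_model,
                                                        pathway_spec):
        bad = StrainMeasurement("bad", mu=5.0, q_co2=0.001)  # impossible combo
        constrained, _ = constrain_strain(extended_model, bad, pathway_spec)
        with pytest.raises(InterrogationError, match="infeasible"):
            predict_min_glucose(constrained)


class TestRelativeError:
    def test_basics(self):
        assert relative_error(10, 10) == 0.0
        assert relative_error(11, 10) == pytest.approx(10.0)
        assert relative_error(9, 10) == pytest.approx(10.0)

    def test_mean_of_errors_is_unweighted(self):
        errs = [relative_error(p, e) for p, e in [(11, 10), (9, 10), (10, 10)]]
        assert np.mean(errs) == pytest.approx((10 + 10 + 0) / 3)

    def test_requires_positive_reference(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestCarbonRecovery:
    def test_fully_measured_state_closes_to_100(self, extended_model, pathway_spec):
        state, meas = _noiseless_measurement(extended_model, pathway_spec,
                                             cleave=0.0)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec,
                                          tol_frac=0.0)
        _, sol = predict_min_glucose(constrained)
        rec = carbon_recovery(sol, meas, extended_model)
        assert rec == pytest.approx(100.0, abs=0.01)

    def test_half_unmeasured_secretion_gives_50(self, toy_model, toy_config):
        """Mixed respiro-fermentative state built so the (unmeasured) ethanol
        secretion carries exactly half the substrate carbon."""
        a = toy_config.atp_per_glucose
        m = toy_model.copy()
        # respiration x=1, fermentation y=3: measured C = 6x+2y = unmeasured 4y
        m.set_bounds("EX_glc__D_e", -4.0, -4.0)
        m.set_bounds("BIOMASS_toy", 0.0, 0.0)
        m.set_bounds("ATPM", a + 6.0, a + 6.0)
        sol = optimize(m, "EX_co2_e", "max")
        assert sol.optimal
        assert sol.fluxes["EX_etoh_e"] == pytest.approx(6.0, rel=1e-6)
        meas = StrainMeasurement("half", mu=0.0, q_co2=sol.fluxes["EX_co2_e"],
                                 glucose_uptake_exp=4.0)
        rec = carbon_recovery(sol, meas, toy_model, measured_reactions=[])
        assert rec == pytest.approx(50.0, abs=1e-6)

    def test_pure_co2_state_closes(self, toy_model, toy_config):
        """mu = 0, all uptake respired: CO2 alone accounts for all carbon."""
        m = toy_model.copy()
        m.set_bounds("EX_glc__D_e", -1.0, -1.0)
        m.set_bounds("BIOMASS_toy", 0.0, 0.0)
        m.set_bounds("ATPM", toy_config.atp_per_glucose,
                     toy_config.atp_per_glucose)
        sol = optimize(m, "EX_co2_e", "max")
        meas = StrainMeasurement("resp", mu=0.0, q_co2=sol.fluxes["EX_co2_e"],
                                 glucose_uptake_exp=1.0)
        assert carbon_recovery(sol, meas, toy_model,
                               measured_reactions=[]) == pytest.approx(100.0)

    def test_missing_experimental_uptake_is_directed(self, extended_model,
                                                     pathway_spec):
        state, meas = _noiseless_measurement(extended_model, pathway_spec)
        object.__setattr__(meas, "glucose_uptake_exp", None)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec)
        _, sol = predict_min_glucose(constrained)
        with pytest.raises(Exception, match="glucose_uptake_exp"):
            carbon_recovery(sol, meas, extended_model)

    def test_biomass_carbon_from_composition(self, toy_model, toy_config):
        assert biomass_carbon_content(toy_model) == pytest.approx(
            toy_config.carbon_per_biomass
        )


class TestCounterfactual:
    def test_double_only_ratio_is_half(self, extended_model, pathway_spec):
        _, meas = _noiseless_measurement(extended_model, pathway_spec,
                                         accum=0.005, cleave=0.001)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec,
                                          tol_frac=0.0)
        cf = counterfactual_max_ionone(constrained, meas, pathway_spec)
        assert cf.q_ionone_max == pytest.approx(2 * cf.divertible_carbon / 40,
                                                rel=1e-6)
        assert cf.c14_ionone_ratio == pytest.approx(0.5, abs=1e-4)
        lo, hi = cf.c14_ionone_ratio_range
        assert lo == pytest.approx(hi, abs=1e-4)  # no degeneracy without CCD1-single

    def test_departure_zero_when_observed_equals_max(self, extended_model,
                                                     pathway_spec):
        _, meas = _noiseless_measurement(extended_model, pathway_spec)
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec,
                                          tol_frac=0.0)
        cf = counterfactual_max_ionone(constrained, meas, pathway_spec)
        # rebuild the measurement with a titer that exactly attains the ceiling
        titer = cf.q_ionone_max * meas.biomass_conc * meas.culture_time * \
            pathway_spec.molar_masses["beta_ionone"]
        meas2 = StrainMeasurement(
            "attains-max", mu=meas.mu, q_co2=meas.q_co2,
            biomass_conc=meas.biomass_conc,
            total_carotenoids=meas.total_carotenoids,
            ionone_titer=titer, culture_time=meas.culture_time,
        )
        cf2 = counterfactual_max_ionone(constrained, meas2, pathway_spec)
        assert cf2.departure_pct == pytest.approx(0.0, abs=1e-4)

    def test_departure_monotone_in_titer(self, extended_model, pathway_spec):
        _, base = _noiseless_measurement(extended_model, pathway_spec)
        constrained, _ = constrain_strain(extended_model, base, pathway_spec,
                                          tol_frac=0.0)
        departures = []
        for titer in (5.0, 50.0, 150.0):
            m = StrainMeasurement(
                "t", mu=base.mu, q_co2=base.q_co2, biomass_conc=base.biomass_conc,
                total_carotenoids=base.total_carotenoids, ionone_titer=titer,
                culture_time=base.culture_time,
            )
            departures.append(
                counterfactual_max_ionone(constrained, m, pathway_spec).departure_pct
            )
        assert departures == sorted(departures, reverse=True)

    def test_cleavage_carbon_conservation(self, extended_model_single, full_spec):
        """In the step-3 optimum, carbon into CCD1 equals carbon out via
        ionone + C14 (+ C27) exactly."""
        state = make_true_state(extended_model_single, 0.3,
                                {"beta_carotene": 0.004}, cleavage_double=0.001)
        (meas,) = simulate_measurements(extended_model_single, state, full_spec,
                                        noise_cv=0.0, seed=0)
        constrained, _ = constrain_strain(extended_model_single, meas, full_spec,
                                          tol_frac=0.0)
        cf = counterfactual_max_ionone(constrained, meas, full_spec)
        v = cf.solution.fluxes
        carbon_in = 40 * (v[RXN_CCD1_DOUBLE] + v.get(RXN_CCD1_SINGLE, 0.0))
        carbon_out = 13 * v[EX_BIONONE] + 14 * v[SINK_C14DIAL] \
            + 27 * v.get(SINK_APO27, 0.0)
        assert carbon_in == pytest.approx(carbon_out, abs=1e-9)

    def test_single_cleavage_ceiling_cross_checked_by_enumeration(self):
        """On a minimal cleavage network with both routes, the LP ceiling
        matches brute-force vertex enumeration (double cleavage dominates:
        2 ionones per carotene)."""
        D = 0.2  # divertible carbon
        m = MetabolicModel()
        for mid, f in [("car", "C40H56"), ("ion", "C13H20O"),
                       ("c14", "C14H16O2"), ("c27", "C27H36O")]:
            m.add_metabolite(Metabolite(mid, formula=f))
        m.add_reaction(Reaction("SUPPLY", {"car": 1}, 0, D / 40))
        m.add_reaction(Reaction("DOUBLE", {"car": -1, "ion": 2, "c14": 1}, 0, 10))
        m.add_reaction(Reaction("SINGLE", {"car": -1, "ion": 1, "c27": 1}, 0, 10))
        m.add_reaction(Reaction("SK_ion", {"ion": -1}, 0, 10, "sink"))
        m.add_reaction(Reaction("SK_c14", {"c14": -1}, 0, 10, "sink"))
        m.add_reaction(Reaction("SK_c27", {"c27": -1}, 0, 10, "sink"))
        sol = optimize(m, "SK_ion", "max")

        rxns = list(m.reactions)
        S = np.zeros((len(m.metabolites), len(rxns)))
        met_idx = {mid: i for i, mid in enumerate(m.metabolites)}
        for j, rid in enumerate(rxns):
            for met, coef in m.reactions[rid].stoichiometry.items():
                S[met_idx[met], j] = coef
        lb = np.array([m.reactions[r].lower_bound for r in rxns])
        ub = np.array([m.reactions[r].upper_bound for r in rxns])
        c = np.zeros(len(rxns))
        c[rxns.index("SK_ion")] = 1
        expected = brute_force_optimum(S, lb, ub, c, "max")
        assert sol.objective_value == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2 * D / 40)

    def test_excess_measurement_flagged(self, extended_model, pathway_spec):
        meas = StrainMeasurement("greedy", mu=0.3, q_co2=8.0,
                                 total_carotenoids=500.0)  # beyond FPP capacity
        constrained, _ = constrain_strain(extended_model, meas, pathway_spec)
        with pytest.raises(InterrogationError, match="exceeds"):
            counterfactual_max_ionone(constrained, meas, pathway_spec)


class TestFullReport:
    def test_report_fields_populated(self, extended_model, pathway_spec):
        state, meas = _noiseless_measurement(extended_model, pathway_spec)
        rep = interrogate_strain(extended_model, meas, pathway_spec, tol_frac=0.0)
        assert rep.q_glc_pred == pytest.approx(state.q_glc, rel=1e-5)
        assert rep.rel_error_pct == pytest.approx(0.0, abs=1e-3)
        assert rep.carbon_recovery_pct == pytest.approx(100.0, abs=0.1)
        assert rep.departure_pct is not None
        assert rep.c14_ionone_ratio == pytest.approx(0.5, abs=1e-4)
        assert rep.parsimonious

    def test_missing_uptake_noted_not_fatal(self, extended_model, pathway_spec):
        _, meas = _noiseless_measurement(extended_model, pathway_spec)
        object.__setattr__(meas, "glucose_uptake_exp", None)
        rep = interrogate_strain(extended_model, meas, pathway_spec)
        assert rep.carbon_recovery_pct is None
        assert "glucose" in rep.notes

    def test_frame_round_trip(self, extended_model, pathway_spec):
        _, meas = _noiseless_measurement(extended_model, pathway_spec)
        rep = interrogate_strain(extended_model, meas, pathway_spec)
        frame = reports_to_frame([rep])
        assert frame.shape[0] == 1
        assert frame.loc[0, "strain_id"] == meas.strain_id
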