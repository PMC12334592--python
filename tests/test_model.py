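"""ODE model: rate laws, network structure, steady state, simulation
invariants, model reduction, and the chromatin-opening sub-model."""

import numpy as np
import pytest

from nfkbdyn.features import fit_gaussian_sum
from nfkbdyn.model import (N_SPECIES, S_INDEX, SPECIES, build_model,
                           dna_binding_rate, dna_unbinding_rates,
                           free_nfkb_fraction, ikbe_transcription_rate,
                           ikk_activation_rate, npio_value, nuclear_nfkb,
                           reaction_fluxes, run_to_steady_state,
                           simulate_response, submodel_dynamic_free_fraction,
                           total_nfkb)
from nfkbdyn.params import default_parameters
from nfkbdyn.synthetic import make_triangular_ci


class TestRateLaws:
    def test_ikk_activation_is_bilinear_product(self):
        assert ikk_activation_rate(1.0, 100.0, 0.001) == pytest.approx(0.1)
        assert ikk_activation_rate(1.0, 0.0, 0.001) == 0.0
        assert (ikk_activation_rate(0.5, 200.0, 0.001)
                == pytest.approx(2 * ikk_activation_rate(0.5, 100.0, 0.001)))

    def test_dcoop_half_saturation(self, truth):
        for h2 in (1.0, 2.0, 4.0):
            p = truth.with_updates(h2=h2)
            r = dna_binding_rate(p["kdNFKB"], 0.0, p)
            assert r == pytest.approx(p["ka1d"] * 0.5 * p["Ps0"])

    def test_npio_basal_is_one(self, truth):
        assert npio_value(0.0, truth) == pytest.approx(1.0)

    def test_binding_saturates_at_ka1d_times_one_plus_ps(self, truth):
        r = dna_binding_rate(1e9, 1e9, truth)
        assert r == pytest.approx(truth["ka1d"] * (1.0 + truth["Ps"]), rel=1e-6)

    def test_unbinding_rates_are_mass_action(self, truth):
        p = truth.with_updates(ka2a=0.1, kd1d=0.01)
        strip, basal = dna_unbinding_rates(3.0, 2.0, p)
        assert strip == pytest.approx(0.6)
        assert basal == pytest.approx(0.03)
        strip2, basal2 = dna_unbinding_rates(6.0, 2.0, p)
        assert strip2 == pytest.approx(2 * strip)
        assert basal2 == pytest.approx(2 * basal)
        assert dna_unbinding_rates(3.0, 0.0, p)[0] == 0.0

    def test_delayed_transcription_hill_midpoint(self):
        p = default_parameters("d2fc_ikbe").with_updates(K_tr=0.01)
        vmax = ikbe_transcription_rate(1e12, 1.0, p)       # t >> K_delay, NFkB >> K_tr
        half = ikbe_transcription_rate(p["K_delay"], 1.0, p)
        assert half == pytest.approx(0.5 * vmax, rel=1e-6)
        assert ikbe_transcription_rate(0.0, 1.0, p) == 0.0
        sharp = p.with_updates(n_delay=200.0)
        before = ikbe_transcription_rate(0.9 * p["K_delay"], 1.0, sharp)
        after = ikbe_transcription_rate(1.1 * p["K_delay"], 1.0, sharp)
        assert before < 1e-6 * vmax and after > 0.99 * vmax


class TestNetwork:
    def test_chromatin_variant_adds_exactly_the_dna_species(self):
        base = set(build_model("d2fc").species)
        chrom = set(build_model("d2fc2").species)
        assert chrom - base == {"N.NFkBDNA"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("d3fc")

    @pytest.mark.parametrize("variant", ["d2fc", "d2fc2", "d2fc_ikbe", "d2fc_ikbb"])
    def test_all_zero_state_fluxes_vanish_except_constitutive(self, variant):
        p = default_parameters(variant)
        m = build_model(variant, p)
        fluxes = reaction_fluxes(np.zeros(N_SPECIES), 5000.0, p, spots=10.0)
        constitutive = {r.name for r in m.reactions if r.constitutive}
        for r in m.reactions:
            if r.name in constitutive:
                assert fluxes[r.name] > 0.0
            else:
                assert fluxes[r.name] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("variant", ["d2fc", "d2fc2", "d2fc_ikbe", "d2fc_ikbb"])
    def test_declarative_network_matches_compiled_rhs(self, variant, rng):
        """The introspectable reaction list and the compiled RHS are the same
        vector field (stoichiometry x flux assembly at random states)."""
        from nfkbdyn.model import _pvec, _rhs
        p = default_parameters(variant)
        m = build_model(variant, p)
        for _ in range(5):
            y = rng.uniform(0.0, 0.5, N_SPECIES)
            for s in SPECIES:
                if s not in m.species:
                    y[S_INDEX[s]] = 0.0
            t, spots = float(rng.uniform(0, 9000)), float(rng.uniform(0, 80))
            fl = reaction_fluxes(y, t, p, spots=spots, stim_phase=True)
            dy = np.zeros(N_SPECIES)
            for r in m.reactions:
                for s, coef in r.stoichiometry.items():
                    dy[S_INDEX[s]] += coef * fl[r.name]
            ga = np.array([spots, 0, 0, 0.0])
            gb = np.array([t / 60.0, 0, 0, 0.0])
            gc = np.array([1e8, 1, 1, 1.0])
            np.testing.assert_allclose(dy, _rhs(y, t, _pvec(p, 1.0), ga, gb, gc),
                                       atol=1e-12)


class TestSteadyState:
    def test_default_parameters_sit_in_the_heuristic_band(self, steady_truth):
        assert 0.01 < steady_truth.R < 0.3
        assert steady_truth.stationary

    def test_invariant_to_doubling_the_equilibration(self, truth, steady_truth):
        ss2 = run_to_steady_state("d2fc2", truth, duration_s=2 * 10 * 24 * 3600.0)
        rel = np.abs(ss2.state - steady_truth.state) / (np.abs(steady_truth.state) + 1e-12)
        assert rel.max() < 1e-6

    def test_pure_shuttling_ratio_matches_closed_form(self):
        """With binding, feedback and DNA terms silenced and only free NF-kB
        shuttling active, the nuclear/cytoplasmic concentration ratio is
        cv * kin_N / kout_N."""
        p = default_parameters("d2fc").with_updates(
            kb=0.0, ktr=0.0, ktr0=0.0, kc=0.0, kc2=0.0, ktr_a20=0.0,
            kdeg_b=1e-3, kin_N=1e-3, kout_N=2e-3)
        ss = run_to_steady_state("d2fc", p)
        expected = p["cv"] * p["kin_N"] / p["kout_N"]
        assert ss.R == pytest.approx(expected, rel=1e-4)

    def test_variant_mismatch_rejected(self, truth):
        with pytest.raises(ValueError):
            run_to_steady_state("d2fc", truth)


class TestSimulation:
    def test_zero_input_keeps_fold_change_at_one(self, truth, steady_truth,
                                                 gaussian_fits):
        sim = simulate_response("d2fc2", truth, gaussian_fits["control"],
                                steady_state=steady_truth)
        np.testing.assert_allclose(sim.fold_change, 1.0, atol=1e-6)
        rel = np.abs(sim.states - steady_truth.state) / (np.abs(steady_truth.state) + 1e-12)
        assert rel.max() < 1e-6

    def test_pulse_rises_then_returns_toward_baseline(self, truth_sims):
        fc = truth_sims["1x6-like"].fold_change
        assert fc.max() > 1.5
        assert fc[-1] < 0.25 * (fc.max() - 1.0) + 1.0

    def test_total_nfkb_is_conserved(self, truth, truth_sims):
        tot = total_nfkb(truth_sims["4x1.5-like"].states, truth)
        assert (tot.max() - tot.min()) / tot.mean() < 1e-6

    def test_all_species_stay_nonnegative(self, truth_sims):
        for sim in truth_sims.values():
            assert sim.states.min() > -1e-8

    def test_npio_and_fold_change_channels(self, truth, truth_sims):
        sim = truth_sims["4x1.5-like"]
        assert sim.fold_change[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(sim.npio >= truth["Ps0"] - 1e-12)
        assert np.all(sim.npio <= truth["Ps0"] + truth["Ps"] + 1e-12)
        assert np.all(np.diff(sim.nfkb_dna_cum_auc) >= 0.0)

    def test_reduction_to_base_model_when_dna_binding_off(self, gaussian_fits):
        """The chromatin model with ka1d = 0 reproduces the base model's
        nuclear fold change on any pulse input."""
        p2 = default_parameters("d2fc2").with_updates(ka1d=0.0)
        p1 = default_parameters("d2fc")
        for cond in ("1x6-like", "4x1.5-like"):
            s2 = simulate_response("d2fc2", p2, gaussian_fits[cond])
            s1 = simulate_response("d2fc", p1, gaussian_fits[cond])
            np.testing.assert_allclose(s2.fold_change, s1.fold_change, rtol=1e-6)

    def test_raw_ci_trajectory_accepted_as_input(self, truth, steady_truth):
        ci = make_triangular_ci(40.0, 80.0)
        sim = simulate_response("d2fc2", truth, ci, steady_state=steady_truth)
        assert sim.fold_change.max() > 1.1


class TestSubModel:
    def test_zero_permissiveness_leaves_all_free(self, truth):
        assert free_nfkb_fraction(0.5, 0.0, truth, ikba_ss=0.1) == 1.0

    def test_fraction_decreases_with_permissiveness(self, truth, steady_truth):
        ikba = float(steady_truth.state[S_INDEX["N.IkBa"]])
        grid = np.linspace(0.0, 3.5, 30)
        fr = [free_nfkb_fraction(0.3, x, truth, ikba) for x in grid]
        assert all(a > b for a, b in zip(fr, fr[1:]) if a < 1.0 or b < 1.0)

    def test_equilibrium_agrees_with_dynamic_integration(self, truth, steady_truth):
        ikba = float(steady_truth.state[S_INDEX["N.IkBa"]])
        for tot, npio in [(0.1, 0.8), (0.5, 2.0), (1.0, 3.0)]:
            eq = free_nfkb_fraction(tot, npio, truth, ikba)
            dyn = submodel_dynamic_free_fraction(tot, npio, truth, ikba)
            assert abs(eq - dyn) / dyn < 1e-4

    def test_zero_total_is_trivially_free(self, truth):
        assert free_nfkb_fraction(0.0, 2.0, truth, 0.1) == 1.0
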