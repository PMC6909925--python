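import numpy as np
import pytest

from fcmsim import (
    SimulationConfig,
    TreatmentSpec,
    apply_fractional_inhibition,
    apply_knockout,
    compare_genotypes,
    dose_response_sweep,
    make_recipe,
    run_simulation,
    run_two_phase_treatment,
)
from fcmsim.network import NetworkError
from fcmsim.protocols import RecipeError


class TestRecipeGrammar:
    def test_aipsc_iopd_declaration(self, iopd_net):
        r = make_recipe("Fibroblast + OKSM + Dox + MYOD1 - GAA", iopd_net)
        pulses = [c for c in r.factors if c.mode == "initial_only"]
        holds = [c for c in r.factors if c.mode == "hold"]
        assert len(pulses) == 4 and all(c.value == 1.0 for c in pulses)
        assert {c.concept for c in holds} == {"Doxycycline", "MYOD1_exo"}
        assert r.deletions == ("GAA",)
        assert r.label == "disease"

    def test_aiskmc_wt_has_no_reprogramming_pulses(self, recipes):
        assert all(c.mode == "hold" for c in recipes["aiSkMC_WT"].factors)

    def test_unknown_concept_rejected(self, iopd_net):
        with pytest.raises(NetworkError, match="NOSUCH"):
            make_recipe("Fibroblast + NOSUCH", iopd_net)


class TestKnockout:
    def test_wt_plus_gaa_knockout_equals_disease_recipe(self, recipes):
        ko = apply_knockout(recipes["aiSkMC_WT"], "GAA")
        assert ko.intervention_signature() == recipes["aiSkMC_IOPD"].intervention_signature()
        assert ko.label == "disease"

    def test_idempotent(self, recipes):
        once = apply_knockout(recipes["aiSkMC_WT"], "GAA")
        assert apply_knockout(once, "GAA") == once

    def test_contradictory_clamp_rejected(self, recipes):
        with pytest.raises(RecipeError, match="held on"):
            apply_knockout(recipes["aiSkMC_WT"], "Doxycycline")


class TestFractionalInhibition:
    def test_full_inhibition_equals_knockout_trajectories(self, iopd_net, recipes):
        cfg = SimulationConfig()
        inhibited = apply_fractional_inhibition(
            recipes["aiSkMC_IOPD"], TreatmentSpec("VDCC", 1.0)
        )
        knocked = apply_knockout(recipes["aiSkMC_IOPD"], "VDCC")
        a = run_simulation(iopd_net, inhibited.clamps(), cfg)
        b = run_simulation(iopd_net, knocked.clamps(), cfg)
        assert np.array_equal(a.states, b.states)

    def test_quarter_dose_clamp_value(self, recipes):
        r = apply_fractional_inhibition(recipes["aiSkMC_IOPD"], TreatmentSpec("VDCC", 0.25))
        assert r.treatments[-1].value == -0.25

    def test_fraction_out_of_range(self):
        with pytest.raises(RecipeError):
            TreatmentSpec("VDCC", 1.5)

    def test_composition_order_independent(self, recipes):
        base = recipes["aiSkMC_WT"]
        t = TreatmentSpec("calpain", 0.5)
        a = apply_fractional_inhibition(apply_knockout(base, "GAA"), t)
        b = apply_knockout(apply_fractional_inhibition(base, t), "GAA")
        assert a.intervention_signature() == b.intervention_signature()


class TestTwoPhaseTreatment:
    def test_treatment_reduces_cell_death(self, iopd_net, recipes, sim_config):
        phase1, phase2 = run_two_phase_treatment(
            iopd_net, recipes["aiSkMC_IOPD"], TreatmentSpec("calpain", 0.25),
            sim_config, n_replicates=2,
        )
        assert phase2.value("cell_death") < phase1.value("cell_death")

    def test_zero_dose_clamp_silences_target(self, iopd_net, recipes, sim_config):
        # a clamp AT zero is silencing, which differs from no treatment
        phase1, phase2 = run_two_phase_treatment(
            iopd_net, recipes["aiSkMC_IOPD"], TreatmentSpec("calpain", 0.0),
            sim_config, n_replicates=1,
        )
        assert phase2.value("calpain") == 0.0
        assert not np.allclose(phase1.mean, phase2.mean)

    def test_from_start_schedule_rejected(self, iopd_net, recipes, sim_config):
        with pytest.raises(RecipeError, match="after_disease_steady_state"):
            run_two_phase_treatment(
                iopd_net, recipes["aiSkMC_IOPD"],
                TreatmentSpec("calpain", 0.25, "from_start"), sim_config,
            )


@pytest.fixture(scope="module")
def quiet_config():
    return SimulationConfig(noise_sigma=0.0, seed=5)


@pytest.fixture(scope="module")
def vdcc_sweep(iopd_net, recipes, quiet_config):
    return dose_response_sweep(
        iopd_net, recipes["aiSkMC_IOPD"], "VDCC", [0, 0.25, 0.5, 0.75, 1.0],
        config=quiet_config, n_replicates=1,
    )


class TestDoseResponse:
    def test_monotone_non_increasing_readouts(self, vdcc_sweep):
        m = vdcc_sweep.readout_means.to_numpy()
        assert np.all(np.diff(m, axis=0) <= 1e-9)

    def test_improvement_at_quarter_dose(self, vdcc_sweep, model_profiles):
        wt = model_profiles["aiSkMC_WT"]
        base = vdcc_sweep.readout_means.iloc[0]
        treated = vdcc_sweep.readout_means.loc[0.25]
        for c in vdcc_sweep.readout_means.columns:
            assert abs(treated[c] - wt.value(c)) < abs(base[c] - wt.value(c))

    def test_untreated_baseline_is_no_clamp(self, vdcc_sweep, iopd_net, recipes, quiet_config):
        from fcmsim import run_replicates

        untreated = run_replicates(iopd_net, recipes["aiSkMC_IOPD"].clamps(),
                                   quiet_config, 1)
        for c in vdcc_sweep.readout_means.columns:
            assert vdcc_sweep.readout_means.loc[0.0, c] == pytest.approx(
                untreated.value(c), abs=1e-12
            )

    def test_phenotype_establishes_under_low_from_start_inhibition(
        self, iopd_net, recipes, quiet_config
    ):
        res = dose_response_sweep(
            iopd_net, recipes["aiSkMC_IOPD"], "calpain", [0.10, 1.0],
            config=quiet_config, schedule="from_start", n_replicates=1,
        )
        assert res.phenotype_established[0.10]       # low dose cannot prevent disease
        assert not res.phenotype_established[1.0]    # full knockout does

    def test_empty_grid_rejected(self, iopd_net, recipes):
        with pytest.raises(RecipeError, match="non-empty"):
            dose_response_sweep(iopd_net, recipes["aiSkMC_IOPD"], "VDCC", [])


@pytest.fixture(scope="module")
def comparison(model_profiles):
    return compare_genotypes(
        model_profiles["aiSkMC_WT"], model_profiles["aiSkMC_IOPD"]
    ).set_index("concept")


class TestGenotypeComparison:
    def test_glycogen_up_in_disease(self, comparison):
        assert comparison.loc["lysosomal_glycogen", "direction"] == "up"

    def test_lysosomal_calcium_unchanged(self, comparison):
        assert comparison.loc["lysosomal_calcium", "direction"] == "unchanged"

    def test_identical_profiles_all_unchanged(self, model_profiles):
        p = model_profiles["aiSkMC_WT"]
        cmp = compare_genotypes(p, p)
        assert (cmp["direction"] == "unchanged").all()
        assert (cmp["delta"] == 0).all()

    def test_concept_mismatch_rejected(self, model_profiles, iopd_net):
        from fcmsim.dynamics import SteadyStateProfile

        other = SteadyStateProfile(concept_ids=["A"], terminal_values=[[0.0]],
                                   n_replicates=1)
        with pytest.raises(ValueError):
            compare_genotypes(model_profiles["aiSkMC_WT"], other)
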