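import numpy as np
import pytest

from pbpkddi import synthetic_data as sd
from pbpkddi.compounds import DoseRegimen
from pbpkddi.scenarios import ScenarioConfig, TrialDesign
from pbpkddi.synthetic_data import StudyDesign, generate_ddi_anchor, generate_profiles


def single_dose_design(cv=None):
    return StudyDesign(
        regimens=(DoseRegimen(compound="ipatasertib", dose=100.0),), cv=cv
    )


class TestGenerateProfiles:
    def test_noise_free_equals_engine_output(self, ipa_record, phys):
        study = generate_profiles(
            ipa_record, single_dose_design(cv={}), residual_cv=0.0, n=2, seed=4, phys=phys
        )
        obs = study.observations
        p0 = obs[obs.subject == 0].set_index("time_h")["conc_ng_per_ml"]
        p1 = obs[obs.subject == 1].set_index("time_h")["conc_ng_per_ml"]
        # variability off → identical subjects, deterministic engine output
        assert np.allclose(p0.to_numpy(), p1.to_numpy())
        assert (obs["conc_ng_per_ml"] > 0).all()

    def test_same_seed_same_dataset(self, ipa_record):
        s1 = generate_profiles(ipa_record, single_dose_design(), n=3, seed=8)
        s2 = generate_profiles(ipa_record, single_dose_design(), n=3, seed=8)
        assert s1.observations.equals(s2.observations)

    def test_residual_cv_recovered(self, ipa_record, phys):
        # with subject variability off, the only dispersion is residual error
        study = generate_profiles(
            ipa_record, single_dose_design(cv={}), residual_cv=0.2, n=500, seed=5,
            phys=phys,
        )
        ref = generate_profiles(
            ipa_record, single_dose_design(cv={}), residual_cv=0.0, n=1, seed=5,
            phys=phys,
        )
        merged = study.observations.merge(
            ref.observations[["time_h", "conc_ng_per_ml"]], on="time_h",
            suffixes=("", "_true"),
        )
        resid = np.log(merged["conc_ng_per_ml"] / merged["conc_ng_per_ml_true"])
        cv = np.sqrt(np.expm1(resid.var()))
        assert 0.18 < cv < 0.22


class TestDoseEscalation:
    @pytest.fixture(scope="class")
    def escalation(self, final_record):
        return sd.generate_dose_escalation(
            final_record, doses=(25.0, 100.0, 400.0, 800.0), n_per_dose=4,
            residual_cv=0.1, seed=6, cv={},
        )

    def test_saturable_pattern_in_cl_over_f(self, escalation):
        # apparent oral clearance falls with dose (saturable first pass and
        # systemic CYP3A4) and never rises again
        clf = sd.observed_cl_over_f(escalation)["single"]
        assert clf[25.0] > clf[100.0] > clf[400.0]
        assert clf[800.0] < 1.05 * clf[400.0]

    def test_linear_truth_gives_flat_cl_over_f(self, ipa_record):
        pw = ipa_record.cyp3a4
        linear = ipa_record.with_updates(
            enzyme_kinetics=[dict(enzyme="CYP3A4", vmax=pw.vmax * 1e6,
                                  km=pw.km * 1e6, fu_mic=1.0)],
            interaction=None,
        )
        study = sd.generate_dose_escalation(
            linear, doses=(25.0, 400.0), n_per_dose=4, residual_cv=0.05, seed=2,
            cv={},
        )
        clf = sd.observed_cl_over_f(study)["single"]
        assert clf[25.0] == pytest.approx(clf[400.0], rel=0.1)

    def test_nonlinearity_persists_without_tdi(self, ipa_record):
        """The low-dose clearance drop is saturation-driven: removing TDI
        barely changes the CL/F(25)/CL/F(400) contrast."""
        no_tdi = ipa_record.without_tdi()
        with_tdi = sd.generate_dose_escalation(
            ipa_record, doses=(25.0, 400.0), n_per_dose=3, residual_cv=0.0, seed=9,
            cv={},
        )
        without = sd.generate_dose_escalation(
            no_tdi, doses=(25.0, 400.0), n_per_dose=3, residual_cv=0.0, seed=9,
            cv={},
        )
        c1 = sd.observed_cl_over_f(with_tdi)["single"]
        c2 = sd.observed_cl_over_f(without)["single"]
        assert c1[25.0] / c1[400.0] > 1.3
        assert c2[25.0] / c2[400.0] > 1.3

    def test_unsorted_doses_rejected(self, ipa_record):
        with pytest.raises(ValueError, match="sorted"):
            sd.generate_dose_escalation(ipa_record, doses=(100.0, 25.0))


class TestDdiAnchor:
    def _scenario(self):
        return ScenarioConfig(
            name="anchor",
            victim="ipatasertib",
            victim_regimen=DoseRegimen(compound="ipatasertib", dose=100.0, start_time=96.0),
            perpetrator="itraconazole",
            perpetrator_regimen=DoseRegimen(compound="itraconazole", dose=200.0, n_doses=9),
            trial=TrialDesign(n_trials=1, n_subjects=1, seed=0, cv={}),
            metric="auc_inf_post_dose",
            follow_up_h=192.0,
        )

    def test_zero_perpetrator_dose_gives_unit_anchor(self, ipa_record):
        cfg = self._scenario().model_copy(update={
            "victim": ipa_record,
            "perpetrator_regimen": DoseRegimen(compound="itraconazole", dose=0.0, n_doses=9),
        })
        assert generate_ddi_anchor(ipa_record, cfg) == pytest.approx(1.0, rel=1e-6)

    def test_repeatable_without_jitter(self, ipa_record):
        cfg = self._scenario()
        a1 = generate_ddi_anchor(ipa_record, cfg)
        a2 = generate_ddi_anchor(ipa_record, cfg)
        assert a1 == a2
        assert a1 > 2.0  # strong-inhibitor scenario on the shipped record

    def test_jitter_is_seeded(self, ipa_record):
        cfg = self._scenario()
        j1 = generate_ddi_anchor(ipa_record, cfg, jitter_cv=0.1, seed=3)
        j2 = generate_ddi_anchor(ipa_record, cfg, jitter_cv=0.1, seed=3)
        j3 = generate_ddi_anchor(ipa_record, cfg, jitter_cv=0.1, seed=4)
        assert j1 == j2 != j3
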