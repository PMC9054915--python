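"""Shared fixtures.

Heavy artifacts (the calibrated model, virtual-trial reports) are
session-scoped and lazily built, so fast unit tests stay fast while the
trial-level tests share one calibration and one population run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pbpkddi import calibration, compounds, physiology, scenarios

#: one seed for every virtual-trial fixture in the suite
TRIAL_SEED = 20260929 % (2**31)


@pytest.fixture(scope="session")
def phys():
    return physiology.default_healthy_volunteer()


@pytest.fixture(scope="session")
def ipa_record():
    return compounds.ipatasertib_final()


@pytest.fixture(scope="session")
def targets():
    return calibration.CalibrationTargets()


@pytest.fixture(scope="session")
def final_model(targets):
    """Engine-calibrated final candidate (Km 0.195): steps 1–2 against the
    clinical anchors."""
    return calibration.calibrated_final_model(targets)


@pytest.fixture(scope="session")
def final_record(final_model):
    return final_model.apply()


@pytest.fixture(scope="session")
def table3_reports(final_record):
    """All application-scenario trial reports (10 trials × 10 subjects,
    21 days), sharing one population draw so baselines are reused."""
    reports = {}
    for name in scenarios.TABLE3_SCENARIOS:
        cfg = scenarios.load_scenario(name, seed=TRIAL_SEED)
        if name == "table3_midazolam_400":
            cfg = cfg.model_copy(update={"perpetrator": final_record})
        else:
            cfg = cfg.model_copy(update={"victim": final_record})
        reports[name] = scenarios.run_scenario(cfg)
    return reports


@pytest.fixture(scope="session")
def calibration_trial_reports(final_model, final_record):
    """Virtual-trial reruns of the two calibration anchor studies."""
    step1_record = final_model.model_copy(update={"kinact": 0.0}).apply()
    cfg_itz = scenarios.load_scenario(
        "calibration_itraconazole_100mg", seed=TRIAL_SEED
    ).model_copy(update={"victim": step1_record})
    cfg_mdz = scenarios.load_scenario(
        "calibration_midazolam_600mg", seed=TRIAL_SEED
    ).model_copy(update={"perpetrator": final_record})
    return {
        "itraconazole": scenarios.run_scenario(cfg_itz),
        "midazolam": scenarios.run_scenario(cfg_mdz),
    }


@pytest.fixture(scope="session")
def self_consistent_candidates(phys, ipa_record):
    """Three Km candidates fitted (steps 1–2) against anchors generated by
    the engine itself from the shipped record — the parameter-recovery
    setting where the printed values are the ground truth."""
    anchor_alone, anchor_combo = calibration.simulate_itz_anchor(
        ipa_record, phys, tdi_enabled=False
    )
    anchor_mdz = calibration.simulate_mdz_anchor(ipa_record, phys)
    t = calibration.CalibrationTargets(
        itz_auc_ratio=anchor_combo / anchor_alone,
        mdz_auc_ratio=anchor_mdz,
        ipa_100mg_auc_inf=anchor_alone,
    )
    out = []
    for km in calibration.KM_CANDIDATES:
        m1 = calibration.fit_step1_itraconazole(km, t, phys=phys)
        out.append(calibration.fit_step2_kinact(m1, t, phys=phys))
    return {"targets": t, "candidates": out}


@pytest.fixture(scope="session")
def km_selection_winner(self_consistent_candidates, ipa_record, phys):
    """Step-3 selection run against the self-consistent dose-escalation
    pattern of the shipped record."""
    table = calibration.simulate_cl_over_f(ipa_record, phys)
    observed = {
        phase: dict(zip(grp["dose"], grp["cl_over_f"]))
        for phase, grp in table.groupby("phase")
    }
    return calibration.select_final_model(
        self_consistent_candidates["candidates"], observed, phys=phys
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(TRIAL_SEED)
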