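"""Virtual "observed" datasets with the statistical structure the analysis
assumes.

The clinical concentration data behind the model (dose escalation, DDI
studies) are not public, so calibration and NCA are exercised against
synthetic studies: the engine simulates each virtual subject, observations
are thinned to a clinical sampling grid and perturbed with multiplicative
lognormal residual error, and the generating record ("truth") is retained so
parameter-recovery tests can score themselves.

What this emulates: between-subject variability in CYP3A4 abundance,
absorption and non-CYP3A4 clearance; proportional assay/model error; rich
early sampling (absorption is fast, Tmax 0.5–3 h) with follow-up to 72 h
(half-life tens of hours).  What it does not: dropout, values below the
quantitation limit, covariate structure, or model misspecification —
passing recovery tests therefore shows the pipeline is self-consistent, not
that the model is structurally correct for real patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import engine, nca
from .compounds import CompoundRecord, DoseRegimen, resolve_distribution
from .physiology import SystemPhysiology, default_healthy_volunteer
from .scenarios import ScenarioConfig, run_scenario

#: default sampling grid (h post dose): dense over absorption, out to 72 h
DEFAULT_SAMPLING_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)
DEFAULT_RESIDUAL_CV = 0.20


@dataclass
class StudyDesign:
    """Regimens plus the post-dose sampling grid for one synthetic study."""

    regimens: Tuple[DoseRegimen, ...]
    sampling_times: Tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    #: dose whose profile is sampled (times are relative to its last dose)
    observed_compound: Optional[str] = None
    cv: Optional[Dict[str, float]] = None  # None → engine defaults; {} → none


@dataclass
class SyntheticStudy:
    design: StudyDesign
    truth: CompoundRecord
    residual_cv: float
    n_subjects: int
    seed: int
    observations: pd.DataFrame  # subject, dose, phase, time_h, conc_ng_per_ml
    cl_over_f: Optional[pd.DataFrame] = None
    manifest: Dict[str, object] = field(default_factory=dict)


def _apply_noise(conc: np.ndarray, residual_cv: float, rng: np.random.Generator) -> np.ndarray:
    if residual_cv <= 0:
        return conc
    sigma = np.sqrt(np.log1p(residual_cv**2))
    return conc * np.exp(rng.normal(0.0, sigma, size=conc.shape))


def generate_profiles(
    truth: CompoundRecord,
    design: StudyDesign,
    residual_cv: float = DEFAULT_RESIDUAL_CV,
    n: int = 10,
    seed: int = 0,
    phys: Optional[SystemPhysiology] = None,
) -> SyntheticStudy:
    """Simulate ``n`` subjects under the design and emit noisy observations."""
    if residual_cv < 0:
        raise ValueError("residual_cv must be non-negative")
    phys = phys or default_healthy_volunteer()
    observed = design.observed_compound or truth.name
    reg_obs = [r for r in design.regimens if r.compound == observed][-1]
    t_ref = reg_obs.dose_times[-1]
    t_samples = t_ref + np.asarray(design.sampling_times)
    t_end = float(t_samples[-1])
    rng = np.random.default_rng(seed)
    subj_seed = int(rng.integers(0, 2**31 - 1))
    subjects = engine.sample_trial_subjects(phys, [truth], n, subj_seed, design.cv)
    t_eval = np.unique(np.concatenate([np.arange(0.0, t_end + 1e-9, 0.5), t_samples]))
    rows = []
    for i, (subj_phys, subj_records) in enumerate(subjects):
        res = engine.simulate_subject(
            subj_records, design.regimens, subj_phys, t_end,
            t_eval=t_eval, solver_opts={"rtol": 1e-6, "atol": 1e-9},
        )
        conc = np.interp(t_samples, res.time, res.conc_ng_ml[observed])
        noisy = _apply_noise(conc, residual_cv, rng)
        for t, c in zip(design.sampling_times, noisy):
            rows.append(dict(subject=i, time_h=t, conc_ng_per_ml=c))
    return SyntheticStudy(
        design=design, truth=truth, residual_cv=residual_cv, n_subjects=n,
        seed=seed, observations=pd.DataFrame(rows),
        manifest=dict(truth=truth.model_dump(mode="json"), seed=seed,
                      residual_cv=residual_cv, n=n),
    )


def generate_dose_escalation(
    truth: CompoundRecord,
    doses: Sequence[float] = (25.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0),
    days: int = 8,
    n_per_dose: int = 6,
    residual_cv: float = DEFAULT_RESIDUAL_CV,
    seed: int = 0,
    phys: Optional[SystemPhysiology] = None,
    cv: Optional[Dict[str, float]] = None,
) -> SyntheticStudy:
    """Emulated first-in-human escalation: single-dose and day-``days``
    profiles per cohort, with a per-subject CL/F table (dose/AUC0–∞ after a
    single dose; dose/AUC0–τ at steady state)."""
    if list(doses) != sorted(doses):
        raise ValueError("doses must be sorted ascending")
    phys = phys or default_healthy_volunteer()
    rng = np.random.default_rng(seed)
    sampling = np.asarray(DEFAULT_SAMPLING_TIMES)
    rows = []
    clf_rows = []
    for dose in doses:
        subj_seed = int(rng.integers(0, 2**31 - 1))
        subjects = engine.sample_trial_subjects(phys, [truth], n_per_dose, subj_seed, cv)
        for i, (subj_phys, subj_records) in enumerate(subjects):
            rec = subj_records[0]
            # single dose, 72 h follow-up
            reg = DoseRegimen(compound=rec.name, dose=dose)
            t_eval = np.unique(np.concatenate([np.arange(0.0, 72.0 + 1e-9, 0.5), sampling]))
            res = engine.simulate_subject(
                [rec], [reg], subj_phys, 72.0, t_eval=t_eval,
                solver_opts={"rtol": 1e-6, "atol": 1e-9},
            )
            conc = _apply_noise(
                np.interp(sampling, res.time, res.conc_ng_ml[rec.name]), residual_cv, rng
            )
            s = nca.nca_single(sampling, conc, dose=dose)
            clf = s.cl_over_f if s.cl_over_f is not None else dose * 1000.0 / s.auc_0_t
            clf_rows.append(dict(dose=dose, subject=i, phase="single", cl_over_f=clf))
            for t, c in zip(sampling, conc):
                rows.append(dict(subject=i, dose=dose, phase="single",
                                 time_h=t, conc_ng_per_ml=c))
            # day-`days` steady state, AUC over the final interval
            reg_md = DoseRegimen(compound=rec.name, dose=dose, n_doses=days)
            t_last = (days - 1) * 24.0
            grid = t_last + sampling[sampling <= 24.0]
            t_eval8 = np.unique(np.concatenate([
                np.arange(0.0, t_last + 24.0 + 1e-9, 2.0), grid, [t_last + 24.0]]))
            res8 = engine.simulate_subject(
                [rec], [reg_md], subj_phys, t_last + 24.0, t_eval=t_eval8,
                solver_opts={"rtol": 1e-6, "atol": 1e-9},
            )
            grid_full = np.concatenate([grid, [t_last + 24.0]])
            conc8 = _apply_noise(
                np.interp(grid_full, res8.time, res8.conc_ng_ml[rec.name]),
                residual_cv, rng,
            )
            auc_tau = nca._linuplogdown_auc(grid_full - t_last, conc8)
            clf_rows.append(dict(dose=dose, subject=i, phase=f"day{days}",
                                 cl_over_f=dose * 1000.0 / auc_tau))
            for t, c in zip(grid_full - t_last, conc8):
                rows.append(dict(subject=i, dose=dose, phase=f"day{days}",
                                 time_h=t, conc_ng_per_ml=c))
    design = StudyDesign(regimens=(DoseRegimen(compound=truth.name, dose=0.0),),
                         cv=cv)
    return SyntheticStudy(
        design=design, truth=truth, residual_cv=residual_cv,
        n_subjects=n_per_dose * len(doses), seed=seed,
        observations=pd.DataFrame(rows), cl_over_f=pd.DataFrame(clf_rows),
        manifest=dict(truth=truth.model_dump(mode="json"), seed=seed,
                      residual_cv=residual_cv, doses=list(doses), days=days),
    )


def observed_cl_over_f(study: SyntheticStudy) -> Dict[str, Dict[float, float]]:
    """Geometric-mean CL/F per phase and dose, in the shape the model-selection
    step consumes."""
    if study.cl_over_f is None:
        raise ValueError("study carries no CL/F table")
    out: Dict[str, Dict[float, float]] = {}
    for (phase, dose), grp in study.cl_over_f.groupby(["phase", "dose"]):
        out.setdefault(phase, {})[float(dose)] = nca.geometric_mean(grp["cl_over_f"])
    return out


def generate_ddi_anchor(
    truth: CompoundRecord,
    scenario: ScenarioConfig,
    jitter_cv: float = 0.0,
    seed: int = 0,
) -> float:
    """Run the scenario with the victim replaced by ``truth`` and return the
    AUC geometric-mean ratio as a pseudo-observation (optionally jittered)."""
    cfg = scenario.model_copy(update={"victim": truth})
    gmr = run_scenario(cfg).gmr_auc.geo_mean_ratio
    if jitter_cv > 0:
        rng = np.random.default_rng(seed)
        gmr *= float(np.exp(rng.normal(0.0, np.sqrt(np.log1p(jitter_cv**2)))))
    return gmr
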