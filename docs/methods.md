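# Methods

## The model

`pbpkddi` implements a fit-for-purpose whole-body physiologically based
pharmacokinetic (PBPK) model for the AKT inhibitor ipatasertib and its
CYP3A4-mediated drug–drug interactions (DDIs), together with the stepwise
calibration workflow that produced the original model and the virtual-trial
machinery used to predict untested interactions at the 400-mg therapeutic
dose.

### Circulation and distribution

The virtual subject is a perfusion-limited mammillary circulation: eleven
tissues (lung in series with the heart; gut and spleen draining through the
liver via the portal vein) plus arterial and venous blood pools.  For each
tissue,

    dC_t/dt = (Q_t / V_t) · (C_in − C_t · B:P / (s·Kp_t)),

with `C_in` the arterial blood concentration (venous for lung), `Kp_t` the
tissue:plasma partition coefficient predicted mechanistically from tissue
composition (water, neutral lipid, neutral phospholipid, acidic-phospholipid
binding of the ionized base — the standard composition-based equations for a
diprotic base, with the acidic-phospholipid association constant derived
from the blood-cell partition implied by the measured B:P ratio), and `s` a
single Kp scalar solved so that the model Vss matches the observed
39.13 L/kg.  The scalar that achieves this in this implementation is ≈6.9;
its literal value depends on the composition table used, which is why only
the Vss round trip is enforced, not the scalar itself.

### Absorption and gut wall

Oral drug enters a first-order depot (`fa` applied at depot filling,
dA/dt = −ka·A).  The absorbed stream passes the gut wall, where the nominal
flow `Qgut` competes with enterocyte CYP3A4:

    C_ent = ka·A / Qgut          (flow-normalized driving concentration)
    Fg(t) = Qgut / (Qgut + fu_gut · CLu_int,gut(t)),
    CLu_int,gut(t) = Vmax_gut · E_gut(t) / (Km,app + C_ent,u)

Survivors enter the portal vein directly.  Because `C_ent` at clinical doses
(≥25 mg) is far above Km, gut extraction of ipatasertib is nearly saturated
at all study doses; the gut matters mostly for midazolam (Fg ≈ 0.6), which
is what makes midazolam a sensitive DDI probe.

### Hepatic elimination and the unbound convention

Liver elimination combines saturable CYP3A4 metabolism with a linear
additional intrinsic clearance and renal clearance on venous plasma:

    v_CYP3A4 = Vmax_tot · E_liver(t) · Cu / (Km,app + Cu),
    Vmax_tot = vmax · abundance · MPPGL · liver weight,
    v_add    = CL_additional · Cu,       CL_R · C_venous,plasma

with the unbound liver-water concentration fixed as

    Cu = fu_plasma · B:P · C_liver / (s·Kp_liver),

i.e. unbound tissue water equilibrates with the unbound emergent blood
stream.  This convention is stated explicitly because it decides where Km
bites; the calibration absorbs it into the fitted Vmax.  In the linear
limit the engine's oral bioavailability reduces exactly to
fa·Fg·Qh/(Qh + fu·CLint) and IV AUC to Dose/CL, which the tests verify to
0.5–1%.

### Shared CYP3A4 pools

Liver and gut CYP3A4 are first-order-turnover pools shared by co-dosed
compounds:

    dE/dt = kdeg·(1 + ind(t)) − kdeg·E − E·Σ_c kinact_c·Iu_c/(Kapp_c + Iu_c)

with induction `ind = Ind_max·Iu/(IndC50 + Iu)` and the liver pool driven by
each compound's Cu and the gut pool by its C_ent,u.  Competitive interaction
raises every other substrate's apparent Km by (1 + Σ Iu/Ki).  Baseline
turnover: kdeg 0.0193 h⁻¹ (liver), 0.03 h⁻¹ (gut) — the published
population-simulator values, like all physiology defaults
(`data/physiology_healthy_volunteer.yaml`).

## Calibration workflow

The clinical concentration data behind the original model are not public;
what is public are the anchors.  The stepwise fit mirrors the original
workflow:

1. **Itraconazole anchor (step 1).**  With Km fixed (0.195/1.95/19.47 µM)
   and TDI off, Vmax and CL_additional are fitted (Nelder–Mead on the log
   scale, three multistarts, converged when the summed squared log-deviation
   < 1e-6) so the simulated 100-mg ipatasertib AUC0–∞ ratio with
   itraconazole equals 5.45 and the ipatasertib-alone AUC0–∞ equals the
   observed 327 ng·h/mL.
2. **Midazolam anchor (step 2).**  With Ki/Kapp at in vitro values (4.4 and
   9.66 µM), kinact is fitted by monotone bracketing + Brent so the
   midazolam AUC ratio under 600 mg QD ipatasertib equals 2.22.
3. **Nonlinearity selection (step 3).**  Each candidate's CL/F–dose profile
   (25–800 mg, single dose and day 8) is scored by squared log-deviation
   against the observed escalation pattern; ties go to the lowest Km.

Objective evaluations use the single mean-physiology subject; population
variability enters only at the trial/reporting layer (fitting a stochastic
objective would be noisy, and the original anchors are geometric means).

In this engine the step-1/2 solution at Km 0.195 µM is Vmax ≈ 0.10
pmol/min/pmol, CL_additional ≈ 8.5 L/h, kinact ≈ 0.13 h⁻¹ — the same order
as the originally printed 0.135/2.7/0.17 but not identical, as expected for
a re-implementation with different Kp, gut and unbound conventions.  The
shipped `ipatasertib.yaml` record keeps the printed values (it is the
authoritative parameter table); predictions use the engine-calibrated
candidate, exactly as the original workflow used its own calibrated model.
In self-consistent mode (anchors generated by the engine from the shipped
record) the stepwise fit recovers the generating Vmax, CL_additional and
kinact to within a few percent and step 3 picks the generating Km, which is
what the recovery tests assert.

A retrograde utility converts an observed IV plasma clearance into CYP3A4
intrinsic clearance by inverting the textbook well-stirred liver
(fu_B = fu/B:P), with Vmax = CLint × Km.  Note the engine itself applies fu
to the emergent blood stream (the convention above); the two differ by a
factor B:P, which the calibration absorbs.  The retrograde operation is
checked by its own forward/inverse round trip.

## Perpetrator fixtures

The original study used the simulator's default compound files, which are
not printed.  The shipped fixtures are *effective* records assembled from
the compound-summary literature and then gated by qualification scenarios
(`analysis/00_qualify_fixtures.py`):

| fixture | key interaction parameters | qualification gate |
|---|---|---|
| itraconazole | effective unbound Ki 0.3 nM (parent + OH-metabolite), saturable self-elimination (Km 3.9 nM) giving strong accumulation | midazolam AUC ratio ≥ 5 |
| erythromycin | Kapp 10 µM, kinact 1.6 h⁻¹ | midazolam ratio in [2, 5) |
| diltiazem | Kapp 2.2 µM, kinact 0.7 h⁻¹ (metabolite folded in) | midazolam ratio in [2, 5) |
| fluvoxamine | Ki 10 µM (CYP3A4 component only) | ipatasertib ratio < 1.25 |
| rifampin | Ind_max 12, IndC50 0.32 µM, Ki 18.5 µM | midazolam ratio ≤ 0.2 |
| efavirenz | Ind_max 3.2, IndC50 0.012 µM (unbound) | midazolam ratio ≤ 0.5 |
| midazolam | CYP3A4 Vmax 5.23, Km 2.16 µM; fm ≈ 0.95, Fg ≈ 0.6 | fm,CYP3A4 > 0.9 |

Two qualification choices deserve note.  First, itraconazole is carried
without an explicit metabolite; sustaining trough inhibition therefore
requires both the nonlinear self-elimination and the low effective Ki.
Second, the midazolam probe compresses differences between inducers: once
induction multiplies hepatic intrinsic clearance several-fold, hepatic blood
clearance saturates at liver blood flow, so rifampin and efavirenz produce
similar midazolam ratios even though their effects on ipatasertib differ
strongly.  Inducer ranking is therefore checked on the victim (the class-
ordering property) and the efavirenz gate only requires material induction.
Efavirenz's Ind_max is half the commonly published value, consistent with
its moderate-inducer classification on this engine's induction response.

## Virtual trials and statistics

A scenario is victim + regimen, optional perpetrator + regimen, and a trial
design (default 10 trials × 10 subjects, matching the application
simulations; the calibration studies use their historical 10 × 15 and
10 × 13 designs).  Every subject is simulated twice on the identical
parameter draw (paired design).  Between-subject variability is lognormal
with the base value as median: CV 0.45 on hepatic and gut CYP3A4 amounts,
0.30 on CL_R, CL_additional, fa (capped at 1) and ka.  The original study
does not state which system parameters varied, so these CVs are
reporting-layer choices, not study facts; the paired design makes the
geometric-mean ratios insensitive to them.

Exposure metrics: steady-state scenarios use AUC0–24 h of the final (21st)
dosing day, computed exactly from an AUC state integrated by the solver;
single-dose scenarios use AUC0–∞ by linear-up/log-down trapezoid with λz
from the terminal ≥3-point run maximizing adjusted R² (ties → fewer
points).  DDI effects are paired geometric-mean ratios with 90% t-based CIs
on within-subject log differences; a Monte-Carlo test checks 90% ± 2%
coverage.

## Numerics

Stiff LSODA integration; engine defaults rtol 1e-8/atol 1e-10 mg, trial
layer 1e-6/1e-9 (population summaries are insensitive at this level and it
keeps a full acceptance run in minutes); doses are integration restarts, no
impulse smoothing.  The right-hand side is numba-compiled.  Mass balance
(fa-adjusted dose = body burden + metabolized + excreted) is ledgered at
every output time and holds to ~1e-14 relative.  Negative states beyond
100× atol abort the run rather than being clipped.  Problem sizes
throughout (trial counts, escalation cohorts of 4–6 subjects, 1000-replicate
coverage runs) are chosen so the full suite and the acceptance pipeline run
on a single CPU in minutes while keeping Monte-Carlo error well inside the
stated tolerances.

## Synthetic data

`synthetic_data` emulates the studies the analysis assumes: rich early
sampling (0.5–72 h; absorption is fast, half-life tens of hours),
multiplicative lognormal residual error (default CV 20%), escalation
cohorts across 25–800 mg with single-dose and day-8 phases.  It does not
model BLQ censoring, dropout, covariates, or structural misspecification —
recovery tests therefore demonstrate self-consistency of the pipeline, not
correctness of the model for real patients.

## Known limitations

* P-glycoprotein transport, ipatasertib's own (weak) CYP3A4 induction,
  metabolite kinetics, enterohepatic recirculation and multi-segment
  intestinal absorption are out of scope, as in the original model.
* The flow-normalized enterocyte concentration (`ka·A/Qgut`) saturates gut
  CYP3A4 at far lower doses than a dissolution-based absorption model
  would; gut contributions to ipatasertib DDIs are accordingly small here.
* Under the fixed unbound-liver convention, the printed Km of 0.195 µM
  leaves CYP3A4 only ~60% saturated at 400 mg, so apparent oral clearance
  keeps declining above 200 mg rather than plateauing; the monotone
  dose-dependence and the low-dose nonlinearity are reproduced, the strict
  plateau is not (see the acceptance notes in the repository).
* Physiology is a single adult reference subject with lognormal scatter;
  age/sex scaling is metadata only.
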