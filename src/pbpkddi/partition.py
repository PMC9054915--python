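"""Mechanistic tissue-to-plasma partition coefficients (Rodgers–Rowland).

Two tissue-composition mechanisms are used depending on ionization class:

* moderate-to-strong bases (at least one basic pKa ≥ 7): partitioning into
  tissue water, neutral lipid, neutral phospholipid, plus electrostatic
  binding of the ionized species to tissue acidic phospholipids, with the
  acidic-phospholipid association constant back-calculated from the
  blood-cell:plasma partition (via the measured blood:plasma ratio);
* acids, neutrals and weak bases: the same water/lipid terms plus binding to
  extracellular tissue proteins, scaled from plasma protein binding by
  tissue:plasma protein concentration ratios.

Neutral-lipid partitioning uses the vegetable-oil:water coefficient
(log Pvo:w = 1.115·logP − 1.35); for adipose the oil:water *distribution*
coefficient at plasma pH is used, which is what keeps lipophilic bases from
piling into fat when they are overwhelmingly ionized.

The predicted Kp set feeds the steady-state volume of distribution; a single
Kp scalar is then solved so that Vss matches the clinically observed value,
absorbing composition-table and method differences.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Dict

from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .compounds import CompoundRecord
    from .physiology import SystemPhysiology

PH_PLASMA = 7.4
PH_INTRACELL = 7.0
PH_BLOOD_CELL = 7.22

# fractional tissue composition (wet weight): extracellular water,
# intracellular water, neutral lipid, neutral phospholipid,
# acidic phospholipid (mg/g), albumin-type protein tissue:plasma ratio.
TISSUE_COMPOSITION: Dict[str, Dict[str, float]] = {
    "lung":    dict(f_ew=0.336, f_iw=0.446, f_nl=0.0219, f_np=0.0128, ap=3.91, pr=0.212),
    "adipose": dict(f_ew=0.135, f_iw=0.017, f_nl=0.8530, f_np=0.0016, ap=0.40, pr=0.049),
    "bone":    dict(f_ew=0.100, f_iw=0.346, f_nl=0.0174, f_np=0.0016, ap=0.67, pr=0.100),
    "brain":   dict(f_ew=0.162, f_iw=0.620, f_nl=0.0391, f_np=0.0015, ap=0.40, pr=0.048),
    "gut":     dict(f_ew=0.282, f_iw=0.475, f_nl=0.0375, f_np=0.0124, ap=2.41, pr=0.158),
    "heart":   dict(f_ew=0.320, f_iw=0.456, f_nl=0.0135, f_np=0.0106, ap=2.25, pr=0.157),
    "kidney":  dict(f_ew=0.273, f_iw=0.483, f_nl=0.0121, f_np=0.0240, ap=5.03, pr=0.130),
    "liver":   dict(f_ew=0.161, f_iw=0.573, f_nl=0.0135, f_np=0.0238, ap=4.56, pr=0.086),
    "muscle":  dict(f_ew=0.118, f_iw=0.630, f_nl=0.0100, f_np=0.0072, ap=1.53, pr=0.064),
    "skin":    dict(f_ew=0.382, f_iw=0.291, f_nl=0.0603, f_np=0.0044, ap=1.32, pr=0.277),
    "spleen":  dict(f_ew=0.207, f_iw=0.579, f_nl=0.0077, f_np=0.0113, ap=3.18, pr=0.097),
}

BLOOD_CELL = dict(f_iw=0.603, f_nl=0.0017, f_np=0.0029, ap=0.50)

# plasma lipid fractions, used when deriving protein binding from 1/fu
PLASMA = dict(f_nl=0.0023, f_np=0.0013)


def _ionization(compound_type: str, pka1: float | None, pka2: float | None, ph: float) -> float:
    """Ratio of ionized to un-ionized species (X in the partition equations)."""
    if compound_type == "neutral" or pka1 is None:
        return 0.0
    if compound_type == "monoprotic base":
        return 10.0 ** (pka1 - ph)
    if compound_type == "diprotic base":
        x = 10.0 ** (pka1 - ph)
        if pka2 is not None:
            x += 10.0 ** (pka1 + pka2 - 2.0 * ph)
        return x
    if compound_type == "acid":
        return 10.0 ** (ph - pka1)
    raise ValueError(f"unknown compound type: {compound_type}")


def _is_strong_base(c: "CompoundRecord") -> bool:
    return c.compound_type in ("monoprotic base", "diprotic base") and c.pka1 is not None and c.pka1 >= 7.0


def predict_kp_set(c: "CompoundRecord", phys: "SystemPhysiology") -> Dict[str, float]:
    """Predict unscaled plasma-referenced Kp for every perfused tissue."""
    for field in ("logp", "bp_ratio", "fu_plasma"):
        if getattr(c, field) is None:
            raise ValueError(f"cannot predict Kp: missing physicochemical field {field!r}")
    if c.compound_type != "neutral" and c.pka1 is None:
        raise ValueError("cannot predict Kp: missing physicochemical field 'pka1'")

    p_ow = 10.0 ** c.logp
    p_vow = 10.0 ** (1.115 * c.logp - 1.35)
    x_p = _ionization(c.compound_type, c.pka1, c.pka2, PH_PLASMA)
    x_iw = _ionization(c.compound_type, c.pka1, c.pka2, PH_INTRACELL)
    fu = c.fu_plasma
    hct = phys.hematocrit

    def lipid_term(f_nl: float, f_np: float, p_nl: float) -> float:
        return (p_nl * f_nl + (0.3 * p_ow + 0.7) * f_np) / (1.0 + x_p)

    kp = {}
    if _is_strong_base(c):
        x_bc = _ionization(c.compound_type, c.pka1, c.pka2, PH_BLOOD_CELL)
        kpu_bc = (c.bp_ratio - (1.0 - hct)) / (hct * fu)
        if kpu_bc <= 0:
            raise ValueError("blood:plasma ratio inconsistent with hematocrit")
        ka_ap = (
            kpu_bc
            - ((1.0 + x_bc) / (1.0 + x_p)) * BLOOD_CELL["f_iw"]
            - lipid_term(BLOOD_CELL["f_nl"], BLOOD_CELL["f_np"], p_vow)
        ) * (1.0 + x_p) / (BLOOD_CELL["ap"] * x_bc)
        ka_ap = max(ka_ap, 0.0)
        for tissue, comp in TISSUE_COMPOSITION.items():
            p_nl = p_vow / (1.0 + x_p) if tissue == "adipose" else p_vow
            kpu = (
                comp["f_ew"]
                + ((1.0 + x_iw) / (1.0 + x_p)) * comp["f_iw"]
                + ka_ap * comp["ap"] * x_iw / (1.0 + x_p)
                + lipid_term(comp["f_nl"], comp["f_np"], p_nl)
            )
            kp[tissue] = kpu * fu
    else:
        ka_pr = max(1.0 / fu - 1.0 - lipid_term(PLASMA["f_nl"], PLASMA["f_np"], p_vow), 0.0)
        for tissue, comp in TISSUE_COMPOSITION.items():
            p_nl = p_vow / (1.0 + x_p) if tissue == "adipose" else p_vow
            kpu = (
                comp["f_ew"]
                + ((1.0 + x_iw) / (1.0 + x_p)) * comp["f_iw"]
                + lipid_term(comp["f_nl"], comp["f_np"], p_nl)
                + ka_pr * comp["pr"]
            )
            kp[tissue] = kpu * fu
    return kp


def erythrocyte_partition(bp_ratio: float, hematocrit: float) -> float:
    """Blood-cell:plasma concentration ratio implied by B:P and hematocrit."""
    return (bp_ratio - (1.0 - hematocrit)) / hematocrit


def compute_vss(
    kps: Dict[str, float],
    phys: "SystemPhysiology",
    c: "CompoundRecord",
    scalar: float,
) -> float:
    """Steady-state volume of distribution (L/kg) for a given Kp scalar."""
    if scalar <= 0:
        raise ValueError("Kp scalar must be positive")
    v_tissue = sum(scalar * kps[t] * phys.tissue_volumes[t] for t in kps)
    v_bc = phys.blood_volume * phys.hematocrit
    v_ery = v_bc * erythrocyte_partition(c.bp_ratio, phys.hematocrit)
    return (phys.plasma_volume + v_tissue + v_ery) / phys.body_weight


def find_kp_scalar(
    c: "CompoundRecord",
    phys: "SystemPhysiology",
    target_vss: float,
    kps: Dict[str, float] | None = None,
) -> float:
    """Solve the Kp scalar so that the computed Vss matches ``target_vss``.

    Monotone 1-D root find; raises if the target sits below the plasma +
    erythrocyte floor (unreachable with any positive scalar).
    """
    if kps is None:
        kps = predict_kp_set(c, phys)
    floor = compute_vss(kps, phys, c, 1e-12)
    if target_vss <= floor:
        raise ValueError(
            f"target Vss {target_vss:.4g} L/kg is unreachable "
            f"(blood-only floor {floor:.4g} L/kg)"
        )
    lo, hi = 1e-9, 1.0
    while compute_vss(kps, phys, c, hi) < target_vss:
        hi *= 4.0
        if hi > 1e9:
            raise ValueError("target Vss unreachable: scalar exceeds 1e9")
    scalar = brentq(
        lambda s: compute_vss(kps, phys, c, s) - target_vss, lo, hi,
        xtol=1e-14, rtol=1e-12,
    )
    assert abs(compute_vss(kps, phys, c, scalar) - target_vss) <= 1e-6 * target_vss
    return scalar
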