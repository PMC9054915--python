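"""Concentration unit conversions.

Internally the engine works in mg/L (equal to µg/mL); enzyme interfaces use
µM; reported plasma concentrations use ng/mL.  All conversions are exact
arithmetic on the molecular weight, so round trips are lossless to machine
precision.
"""

from __future__ import annotations


def um_to_ng_per_ml(conc_um: float, mw: float) -> float:
    """µM → ng/mL (µmol/L × g/mol = µg/L = ng/mL)."""
    return conc_um * mw


def ng_per_ml_to_um(conc_ng_ml: float, mw: float) -> float:
    return conc_ng_ml / mw


def mg_per_l_to_um(conc_mg_l: float, mw: float) -> float:
    """mg/L → µM (mg/L = 1000 µg/L; ÷ MW g/mol)."""
    return conc_mg_l * 1000.0 / mw


def um_to_mg_per_l(conc_um: float, mw: float) -> float:
    return conc_um * mw / 1000.0


def mg_per_l_to_ng_per_ml(conc_mg_l: float) -> float:
    """mg/L = µg/mL = 1000 ng/mL."""
    return conc_mg_l * 1000.0
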