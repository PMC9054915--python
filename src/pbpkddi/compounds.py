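"""Compound parameter records, fixtures and distribution utilities.

A :class:`CompoundRecord` holds everything the engine needs about one drug:
physicochemistry (for tissue partitioning), first-order absorption with the
Qgut gut-wall model, saturable CYP3A4 kinetics plus additional hepatic and
renal clearance, and — for perpetrators — competitive inhibition,
time-dependent inactivation and induction parameters acting on the shared
CYP3A4 pools.

The victim record ``ipatasertib_final`` carries the final optimized model
parameters.  Perpetrator and midazolam records are versioned fixtures
assembled from the published compound-summary literature (citations inside
each YAML file) and gated by the qualification scenarios in
:mod:`pbpkddi.scenarios`; they are deliberately *effective* models (e.g.
itraconazole's inhibition constant folds in its active hydroxy-metabolite).
"""

from __future__ import annotations

import enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import partition
from .physiology import SystemPhysiology

FIXTURE_NAMES = (
    "itraconazole", "erythromycin", "diltiazem", "fluvoxamine",
    "rifampin", "efavirenz", "midazolam",
)


class Route(str, enum.Enum):
    ORAL = "oral"
    IV_BOLUS = "iv-bolus"
    IV_INFUSION = "iv-infusion"


class EnzymePathway(BaseModel):
    model_config = ConfigDict(frozen=True)

    enzyme: str = "CYP3A4"
    vmax: float = Field(ge=0, description="pmol/min/pmol enzyme")
    km: float = Field(gt=0, description="µM, unbound")
    fu_mic: float = Field(default=1.0, gt=0, le=1)


class InteractionParams(BaseModel):
    """Perpetrator parameters acting on CYP3A4 (all concentrations unbound µM)."""

    model_config = ConfigDict(frozen=True)

    ki: Optional[float] = Field(default=None, gt=0)        # competitive
    kapp: Optional[float] = Field(default=None, gt=0)      # TDI half-max conc
    kinact: float = Field(default=0.0, ge=0)               # 1/h
    ind_max: Optional[float] = Field(default=None, ge=0)   # fold increase in synthesis
    ind_c50: Optional[float] = Field(default=None, gt=0)   # µM
    fu_mic: float = Field(default=1.0, gt=0, le=1)

    @model_validator(mode="after")
    def _paired(self) -> "InteractionParams":
        if self.kinact > 0 and self.kapp is None:
            raise ValueError("kinact requires kapp")
        if self.ind_max and self.ind_c50 is None:
            raise ValueError("ind_max requires ind_c50")
        return self


class CompoundRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    mw: float = Field(gt=0, description="g/mol")
    logp: float
    compound_type: str
    pka1: Optional[float] = None
    pka2: Optional[float] = None
    bp_ratio: float = Field(gt=0)
    fu_plasma: float = Field(gt=0, le=1)
    fa: float = Field(ge=0, le=1)
    ka: float = Field(gt=0, description="1/h")
    fu_gut: float = Field(gt=0, le=1)
    q_gut: float = Field(gt=0, description="L/h")
    peff: Optional[float] = Field(default=None, description="1e-4 cm/s")
    papp_mdck: Optional[float] = Field(default=None, description="1e-6 cm/s")
    perm_scalar: Optional[float] = None
    vss_target: Optional[float] = Field(default=None, gt=0, description="L/kg")
    kp_scalar: float = Field(default=1.0, gt=0)
    enzyme_kinetics: List[EnzymePathway] = Field(default_factory=list)
    cl_additional: float = Field(default=0.0, ge=0, description="L/h, intrinsic on unbound liver water")
    cl_renal: float = Field(default=0.0, ge=0, description="L/h, plasma")
    interaction: Optional[InteractionParams] = None

    @field_validator("compound_type")
    @classmethod
    def _type(cls, v: str) -> str:
        allowed = ("monoprotic base", "diprotic base", "acid", "neutral")
        if v not in allowed:
            raise ValueError(f"compound_type must be one of {allowed}")
        return v

    @property
    def cyp3a4(self) -> Optional[EnzymePathway]:
        for p in self.enzyme_kinetics:
            if p.enzyme == "CYP3A4":
                return p
        return None

    def with_updates(self, **kwargs) -> "CompoundRecord":
        """Functional update preserving immutability."""
        data = self.model_dump()
        data.update(kwargs)
        return CompoundRecord(**data)

    def without_tdi(self) -> "CompoundRecord":
        if self.interaction is None or self.interaction.kinact == 0:
            return self
        inter = self.interaction.model_dump()
        inter["kinact"] = 0.0
        return self.with_updates(interaction=inter)


class DoseRegimen(BaseModel):
    model_config = ConfigDict(frozen=True)

    compound: str
    dose: float = Field(ge=0, description="mg")
    route: Route = Route.ORAL
    interval: float = Field(default=24.0, description="h")
    n_doses: int = Field(default=1, ge=1)
    start_time: float = Field(default=0.0, ge=0, description="h")
    infusion_duration: float = Field(default=1.0, gt=0, description="h (iv-infusion only)")

    @model_validator(mode="after")
    def _interval(self) -> "DoseRegimen":
        if self.n_doses > 1 and self.interval <= 0:
            raise ValueError("interval must be positive for repeated dosing")
        return self

    @property
    def dose_times(self) -> List[float]:
        return [self.start_time + i * self.interval for i in range(self.n_doses)]

    @property
    def end_of_last_interval(self) -> float:
        return self.start_time + self.n_doses * self.interval


# -- fixtures ---------------------------------------------------------------

def _record_from_dict(raw: dict) -> CompoundRecord:
    raw = dict(raw)
    raw.pop("provenance", None)
    raw.pop("version", None)
    return CompoundRecord(**raw)


def load_compound(path: Path | str) -> CompoundRecord:
    with open(path) as fh:
        return _record_from_dict(yaml.safe_load(fh))


def save_compound(record: CompoundRecord, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(record.model_dump(mode="json"), fh, sort_keys=False)


@lru_cache(maxsize=None)
def _load_fixture(name: str) -> CompoundRecord:
    path = resources.files("pbpkddi.data.compounds") / f"{name}.yaml"
    with path.open("r") as fh:
        return _record_from_dict(yaml.safe_load(fh))


def ipatasertib_final() -> CompoundRecord:
    """Final optimized victim model (saturable CYP3A4, TDI carried)."""
    return _load_fixture("ipatasertib")


def perpetrator_fixture(name: str) -> CompoundRecord:
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown compound fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        )
    return _load_fixture(name)


# -- distribution helpers ---------------------------------------------------

_DIST_CACHE: Dict[tuple, Tuple[Dict[str, float], float]] = {}


def resolve_distribution(
    c: CompoundRecord, phys: SystemPhysiology
) -> Tuple[Dict[str, float], float]:
    """Predicted Kp set and the scalar matching the record's Vss target.

    If the record carries no ``vss_target`` the stored ``kp_scalar`` is used
    as-is.  Results are cached per (compound name + parameters, physiology).
    """
    key = (c.model_dump_json(), phys.model_dump_json())
    hit = _DIST_CACHE.get(key)
    if hit is not None:
        return hit
    kps = partition.predict_kp_set(c, phys)
    if c.vss_target is not None:
        scalar = partition.find_kp_scalar(c, phys, c.vss_target, kps=kps)
    else:
        scalar = c.kp_scalar
    _DIST_CACHE[key] = (kps, scalar)
    return kps, scalar


def qgut_from_clperm(q_villi: float, cl_perm: float) -> float:
    """Hybrid Qgut: Qgut = Qvilli·CLperm / (Qvilli + CLperm).

    Utility mirroring how the nominal gut flow is formed from villous blood
    flow and a permeability clearance; the shipped records use their printed
    Qgut values directly.
    """
    if q_villi <= 0 or cl_perm <= 0:
        raise ValueError("flows must be positive")
    return q_villi * cl_perm / (q_villi + cl_perm)
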