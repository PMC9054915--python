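"""Virtual healthy-volunteer physiology.

The system model is a perfusion-limited whole-body circulation: eleven
perfused tissues (lung in series with the heart; gut and spleen draining
through the liver via the portal vein) plus arterial and venous blood pools.
CYP3A4 is carried as two first-order-turnover enzyme pools, one hepatic and
one enterocytic, whose baseline amounts and degradation rates are part of the
system rather than of any compound.

Numeric defaults live in ``data/physiology_healthy_volunteer.yaml`` and are
the published population-simulator healthy-volunteer values for a 70-kg
adult.  Between-subject variability is sampled lognormally with the base
value as the median, which keeps population medians anchored to the default
subject.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources
from typing import Dict, List

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: tissues perfused in the systemic circulation (lung handled in series).
PERFUSED_TISSUES = (
    "lung", "adipose", "bone", "brain", "gut", "heart",
    "kidney", "liver", "muscle", "skin", "spleen",
)
#: tissues whose venous outflow drains into the portal vein / liver.
SPLANCHNIC_TISSUES = ("gut", "spleen")

#: physiology fields eligible for between-subject variability.
SAMPLABLE_FIELDS = (
    "cyp3a4_hepatic_abundance",
    "cyp3a4_gut_total",
    "body_weight",
    "cardiac_output",
    "liver_weight",
)


class SystemPhysiology(BaseModel):
    """One virtual subject: organ volumes, blood flows, CYP3A4 system data.

    Flows are arterial-side blood flows in L/h; the liver entry is the
    hepatic-artery flow only, so the sum of all entries equals venous return
    (= cardiac output) because gut and spleen reach the vena cava only through
    the liver.
    """

    model_config = ConfigDict(frozen=True)

    body_weight: float = Field(gt=0, description="kg")
    hematocrit: float = Field(gt=0, lt=1)
    tissue_volumes: Dict[str, float]          # L, keys: PERFUSED_TISSUES + blood pools
    tissue_blood_flows: Dict[str, float]      # L/h, systemic tissues (no lung)
    cardiac_output: float = Field(gt=0)       # L/h
    liver_weight: float = Field(gt=0)         # g
    mppgl: float = Field(gt=0)                # mg microsomal protein / g liver
    cyp3a4_hepatic_abundance: float = Field(gt=0)  # pmol / mg microsomal protein
    cyp3a4_gut_total: float = Field(gt=0)     # nmol
    kdeg_hepatic: float = Field(gt=0)         # 1/h
    kdeg_gut: float = Field(gt=0)             # 1/h
    q_villi: float = Field(gt=0)              # L/h

    @field_validator("tissue_volumes")
    @classmethod
    def _volumes_positive_and_complete(cls, v: Dict[str, float]) -> Dict[str, float]:
        required = set(PERFUSED_TISSUES) | {"arterial_blood", "venous_blood"}
        missing = required - set(v)
        if missing:
            raise ValueError(f"missing tissue volumes: {sorted(missing)}")
        for name, vol in v.items():
            if vol <= 0:
                raise ValueError(f"tissue volume must be positive: {name}={vol}")
        return v

    @field_validator("tissue_blood_flows")
    @classmethod
    def _flows_positive_and_complete(cls, v: Dict[str, float]) -> Dict[str, float]:
        required = set(PERFUSED_TISSUES) - {"lung"}
        missing = required - set(v)
        if missing:
            raise ValueError(f"missing tissue blood flows: {sorted(missing)}")
        for name, q in v.items():
            if q <= 0:
                raise ValueError(f"tissue blood flow must be positive: {name}={q}")
        return v

    @model_validator(mode="after")
    def _conservation(self) -> "SystemPhysiology":
        total = sum(self.tissue_blood_flows.values())
        if abs(total - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError(
                f"tissue outflows ({total:.6f} L/h) do not sum to cardiac "
                f"output ({self.cardiac_output:.6f} L/h)"
            )
        if self.cyp3a4_hepatic_total_pmol <= self.cyp3a4_gut_total_pmol:
            raise ValueError("hepatic CYP3A4 total must exceed gut CYP3A4 total")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def liver_total_flow(self) -> float:
        """Total hepatic blood flow (hepatic artery + portal vein), L/h."""
        return self.tissue_blood_flows["liver"] + sum(
            self.tissue_blood_flows[t] for t in SPLANCHNIC_TISSUES
        )

    @property
    def cyp3a4_hepatic_total_pmol(self) -> float:
        return self.cyp3a4_hepatic_abundance * self.mppgl * self.liver_weight

    @property
    def cyp3a4_gut_total_pmol(self) -> float:
        return self.cyp3a4_gut_total * 1e3

    @property
    def blood_volume(self) -> float:
        return self.tissue_volumes["arterial_blood"] + self.tissue_volumes["venous_blood"]

    @property
    def plasma_volume(self) -> float:
        return self.blood_volume * (1.0 - self.hematocrit)


class VariabilitySpec(BaseModel):
    """Lognormal between-subject variability, keyed by physiology field name."""

    cv_map: Dict[str, float]
    seed: int = 0

    @field_validator("cv_map")
    @classmethod
    def _cv_range(cls, v: Dict[str, float]) -> Dict[str, float]:
        for name, cv in v.items():
            if name not in SAMPLABLE_FIELDS:
                raise ValueError(
                    f"unknown or non-samplable parameter: {name!r} "
                    f"(samplable: {SAMPLABLE_FIELDS})"
                )
            if not 0.0 <= cv <= 2.0:
                raise ValueError(f"CV for {name!r} must be in [0, 2], got {cv}")
        return v


def _load_fixture() -> dict:
    path = resources.files("pbpkddi.data") / "physiology_healthy_volunteer.yaml"
    with path.open("r") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def default_healthy_volunteer() -> SystemPhysiology:
    """The fixture virtual subject used throughout model development."""
    raw = _load_fixture()
    return SystemPhysiology(
        body_weight=raw["body_weight_kg"],
        hematocrit=raw["hematocrit"],
        tissue_volumes=raw["tissue_volumes_L"],
        tissue_blood_flows=raw["tissue_blood_flows_L_per_h"],
        cardiac_output=raw["cardiac_output_L_per_h"],
        liver_weight=raw["liver_weight_g"],
        mppgl=raw["mppgl_mg_per_g"],
        cyp3a4_hepatic_abundance=raw["cyp3a4_hepatic_abundance_pmol_per_mg"],
        cyp3a4_gut_total=raw["cyp3a4_gut_total_nmol"],
        kdeg_hepatic=raw["kdeg_hepatic_per_h"],
        kdeg_gut=raw["kdeg_gut_per_h"],
        q_villi=raw["q_villi_L_per_h"],
    )


def lognormal_sigma(cv: float) -> float:
    """Shape parameter of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def sample_population(
    base: SystemPhysiology, n: int, spec: VariabilitySpec
) -> List[SystemPhysiology]:
    """Draw ``n`` virtual subjects around ``base``.

    Each parameter named in ``spec.cv_map`` is drawn lognormally with median
    equal to the base value; all other parameters are copied.  Tissue blood
    flows are renormalized so every subject's outflows sum to that subject's
    cardiac output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for _ in range(n):
        values = base.model_dump()
        for name, cv in spec.cv_map.items():
            if cv == 0.0:
                continue
            sigma = lognormal_sigma(cv)
            values[name] = values[name] * math.exp(rng.normal(0.0, sigma))
        total = sum(values["tissue_blood_flows"].values())
        scale = values["cardiac_output"] / total
        values["tissue_blood_flows"] = {
            k: q * scale for k, q in values["tissue_blood_flows"].items()
        }
        subjects.append(SystemPhysiology(**values))
    return subjects
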