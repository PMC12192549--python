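"""Anthropometric primitives: BSA, BMI, and the height-minus-BSA body-build index.

The central quantity here is the unitless difference ``d = h - BSA`` between
the numeric value of height (in meters) and the numeric value of the
Mosteller body surface area (in square meters).  A subject with ``d = 0`` is
the "standard human": their weight is exactly the weight attributable to
their height (``w = 36 h``), and height- and BSA-indexed cardiac volumes
coincide.  Positive ``d`` means lighter than the standard build, negative
``d`` heavier; at fixed height, ``d`` decreases strictly with weight and
hence with BMI.

All functions accept scalars or numpy arrays, compute at full float
precision, and leave rounding to the reporting layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "Sex",
    "BmiClass",
    "SubjectRecord",
    "Anthropometry",
    "mosteller_bsa",
    "bmi",
    "bmi_class",
    "h_minus_bsa",
    "standard_weight",
    "derive_anthropometry",
]

# BMI class bounds (kg/m^2): normal range starts at 17.8, overweight at 25,
# obesity at 30.  Below 17.8 is an explicit class, not an error, so that
# cohorts containing underweight subjects still process (they are simply
# never part of the reference group).
BMI_LOWER_NORMAL = 17.8
BMI_LOWER_OVERWEIGHT = 25.0
BMI_LOWER_OBESE = 30.0


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class BmiClass(str, enum.Enum):
    BELOW_RANGE = "below_range"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class SubjectRecord(BaseModel):
    """One subject: anthropometry, risk factors, and the measured THV.

    Heights are meters, weights kilograms, volumes milliliters, CACS in
    Agatston units.  ``lav``/``rav``/``biv`` (atrial and biventricular
    volumes) are carried through unchanged and never analyzed here.
    """

    id: str
    sex: Sex
    age: float = Field(gt=0, lt=130)
    height: float = Field(gt=0.5, lt=2.5)
    weight: float = Field(gt=20, lt=300)
    smoker: bool = False
    sah: bool = False  # systemic arterial hypertension
    hl: bool = False  # dyslipidemia
    t2dm: bool = False  # treated type 2 diabetes
    cacs: float = Field(default=0.0, ge=0)
    thv_measured: Optional[float] = None
    lav: Optional[float] = None
    rav: Optional[float] = None
    biv: Optional[float] = None

    @field_validator("thv_measured")
    @classmethod
    def _thv_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (v > 0):
            raise ValueError("thv_measured must be > 0 when present")
        return v


@dataclass(frozen=True)
class Anthropometry:
    """Derived body-size quantities for one subject."""

    bsa: float  # m^2, Mosteller
    bmi: float  # kg/m^2
    bmi_class: BmiClass
    d: float  # unitless h - BSA


def _check_positive_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if not np.all(arr > 0):
        raise ValueError(f"{name} must be positive")
    return arr


def mosteller_bsa(height, weight):
    """Mosteller body surface area, sqrt(height_cm * weight_kg / 3600) m^2.

    ``height`` is in meters and is converted to centimeters internally.
    """
    h = _check_positive_finite("height", height)
    w = _check_positive_finite("weight", weight)
    out = np.sqrt(h * 100.0 * w / 3600.0)
    return float(out) if out.ndim == 0 else out


def bmi(weight, height):
    """Body mass index, weight / height**2 (kg/m^2)."""
    w = _check_positive_finite("weight", weight)
    h = _check_positive_finite("height", height)
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def bmi_class(value: float) -> BmiClass:
    """Nutritional-status class for a BMI value.

    below_range < 17.8 <= normal < 25 <= overweight < 30 <= obese.
    """
    if not math.isfinite(value) or value <= 0:
        raise ValueError("bmi must be positive and finite")
    if value < BMI_LOWER_NORMAL:
        return BmiClass.BELOW_RANGE
    if value < BMI_LOWER_OVERWEIGHT:
        return BmiClass.NORMAL
    if value < BMI_LOWER_OBESE:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def h_minus_bsa(height, weight):
    """The unitless body-build index d = height(m) - Mosteller BSA(m^2).

    Zero identifies the standard human; strictly decreasing in weight at
    fixed height.
    """
    h = np.asarray(height, dtype=float)
    out = h - mosteller_bsa(height, weight)
    return float(out) if out.ndim == 0 else out


def standard_weight(height):
    """Weight (kg) at which h - BSA = 0 for the given height.

    Solving sqrt(100 h w / 3600) = h gives the closed form w = 36 h.
    """
    h = _check_positive_finite("height", height)
    out = 36.0 * h
    return float(out) if out.ndim == 0 else out


def derive_anthropometry(height: float, weight: float) -> Anthropometry:
    """Bundle BSA, BMI, BMI class and the h-BSA index for one subject."""
    b = mosteller_bsa(height, weight)
    m = bmi(weight, height)
    return Anthropometry(bsa=b, bmi=m, bmi_class=bmi_class(m), d=height - b)
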