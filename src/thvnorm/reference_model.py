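"""Reference regression for total heart volume and the standard-human limits.

The reference model is a pooled linear regression of mid-diastolic total
heart volume (THV, mL) on height ``h`` (m) and the unitless body-build index
``d = h - BSA``:

    THV_expected = coef_height * h + coef_d * d + intercept

with a fixed 95% prediction half-width around the expected value.  The
published model, pinned by :func:`paper_model`, is

    THV = 456 h - 221 (h - BSA) - 335   (+/- 142 mL)

so the individual upper normal limit is 456 h - 221 d - 193.  A measured THV
above that limit is flagged as abnormal: heart size larger than height and
body-weight gain alone explain.

``fit_reference_model`` refits the same functional form on a reference
cohort by ordinary least squares; the half-width is then the normal-quantile
multiple of the residual SD (a single, non-leverage-adjusted band, matching
how the published limits are used).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ReferenceModel",
    "ThvAssessment",
    "FitError",
    "paper_model",
    "expected_thv",
    "standard_thv",
    "prediction_limits",
    "classify_thv",
    "fit_reference_model",
    "index_thv",
    "reindex_bsa_to_height",
    "save_model",
    "load_model",
]

# Published coefficients, pinned exactly.
PAPER_COEF_HEIGHT = 456.0
PAPER_COEF_D = -221.0
PAPER_INTERCEPT = -335.0
PAPER_HALF_WIDTH = 142.0
PAPER_N_FIT = 353
PAPER_R_MULTIPLE = 0.56
PAPER_F_STAT = 80.2


class FitError(ValueError):
    """Raised when the reference regression cannot be fit."""


@dataclass
class ReferenceModel:
    """Coefficients and prediction band of the reference THV regression."""

    coef_height: float  # mL per m of height
    coef_d: float  # mL per unit of h - BSA (stored signed)
    intercept: float  # mL
    half_width: float  # mL, 95% prediction half-width
    n_fit: Optional[int] = None
    r_multiple: Optional[float] = None
    f_stat: Optional[float] = None
    residual_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")


@dataclass(frozen=True)
class ThvAssessment:
    """Per-subject THV assessment against the reference model."""

    id: str
    thv_expected: float  # mL
    thv_standard: float  # mL, expected at d = 0
    thv_lower: float  # mL
    thv_upper: float  # mL, individual upper normal limit
    delta: Optional[float]  # mL, measured - upper limit (None if unmeasured)
    abnormal: Optional[bool]  # None = undetermined (no measured THV)
    thv_per_h: Optional[float]  # mL/m, measured / height
    thv_per_bsa: Optional[float]  # mL/m^2, measured / BSA
    index_correction: Optional[float]  # mL/m, thv_per_h - thv_per_bsa


def paper_model() -> ReferenceModel:
    """The published reference model with its exact printed coefficients."""
    return ReferenceModel(
        coef_height=PAPER_COEF_HEIGHT,
        coef_d=PAPER_COEF_D,
        intercept=PAPER_INTERCEPT,
        half_width=PAPER_HALF_WIDTH,
        n_fit=PAPER_N_FIT,
        r_multiple=PAPER_R_MULTIPLE,
        f_stat=PAPER_F_STAT,
        residual_sd=PAPER_HALF_WIDTH / stats.norm.ppf(0.975),
    )


def expected_thv(model: ReferenceModel, height, d):
    """Expected THV (mL) at the given height (m) and h-BSA index."""
    h = np.asarray(height, dtype=float)
    if not np.all(np.isfinite(h)) or not np.all(h > 0):
        raise ValueError("height must be positive and finite")
    dd = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(dd)):
        raise ValueError("d must be finite")
    out = model.coef_height * h + model.coef_d * dd + model.intercept
    return float(out) if out.ndim == 0 else out


def standard_thv(model: ReferenceModel, height):
    """Standard-human THV: the expected THV at d = 0."""
    return expected_thv(model, height, 0.0)


def prediction_limits(model: ReferenceModel, thv_expected) -> Tuple:
    """Symmetric prediction limits (lower, upper) around an expected THV."""
    e = np.asarray(thv_expected, dtype=float)
    lower = e - model.half_width
    upper = e + model.half_width
    if e.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def classify_thv(thv_measured: float, thv_upper: float) -> str:
    """Classify a measured THV against the individual upper normal limit.

    Returns ``"abnormal"`` iff measured - upper > 0; a difference of exactly
    zero is still within the expected range.
    """
    for name, v in (("thv_measured", thv_measured), ("thv_upper", thv_upper)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite")
    return "abnormal" if thv_measured - thv_upper > 0 else "within_expected"


def _as_design(records) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise FitError("records must be (height, d, thv) triples")
    return arr[:, 0], arr[:, 1], arr[:, 2]


def fit_reference_model(records, coverage: float = 0.95) -> ReferenceModel:
    """Fit the reference regression THV ~ height + d by ordinary least squares.

    Parameters
    ----------
    records
        Sequence (or (n, 3) array) of ``(height_m, d, thv_ml)`` triples.
    coverage
        Prediction-band coverage; the half-width is
        ``z_{(1+coverage)/2} * residual_sd`` with
        ``residual_sd = sqrt(RSS / (n - 3))``.
    """
    height, d, thv = _as_design(records)
    n = len(thv)
    if n < 10:
        raise FitError(f"need at least 10 records to fit, got {n}")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    if np.ptp(height) == 0:
        raise FitError("degenerate design: height is constant")
    if np.ptp(d) == 0:
        raise FitError("degenerate design: d (h - BSA) is constant")
    X = sm.add_constant(np.column_stack([height, d]))
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("degenerate design: height and d are collinear")
    res = sm.OLS(thv, X).fit()
    residual_sd = float(np.sqrt(res.ssr / (n - 3)))
    z = float(stats.norm.ppf((1 + coverage) / 2))
    return ReferenceModel(
        coef_height=float(res.params[1]),
        coef_d=float(res.params[2]),
        intercept=float(res.params[0]),
        half_width=z * residual_sd,
        n_fit=n,
        r_multiple=float(np.sqrt(res.rsquared)),
        f_stat=float(res.fvalue),
        residual_sd=residual_sd,
    )


def index_thv(thv: float, height: float, bsa: float) -> Tuple[float, float, float]:
    """Height- and BSA-indexed THV and the correction between them.

    Returns ``(thv/height, thv/bsa, thv/height - thv/bsa)``.  The correction
    is the amount by which a BSA-indexed volume must be adjusted to match
    height indexing; it is zero exactly for the standard human (h = BSA) and
    its sign equals the sign of ``bsa - height``.
    """
    for name, v in (("thv", thv), ("height", height), ("bsa", bsa)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite")
    per_h = thv / height
    per_bsa = thv / bsa
    return per_h, per_bsa, per_h - per_bsa


def reindex_bsa_to_height(
    value_per_bsa: float, mean_height: float, mean_bsa: float
) -> float:
    """Convert a published BSA-indexed mean onto the height scale.

    Multiplies by the cohort's mean BSA and divides by its mean height,
    i.e. evaluates the re-indexation at the cohort's mean body build.
    """
    for name, v in (
        ("value_per_bsa", value_per_bsa),
        ("mean_height", mean_height),
        ("mean_bsa", mean_bsa),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite")
    return value_per_bsa * mean_bsa / mean_height


def save_model(model: ReferenceModel, path) -> None:
    """Serialize a model to flat JSON; floats round-trip bit-exactly."""
    Path(path).write_text(json.dumps(asdict(model), indent=2))


def load_model(path) -> ReferenceModel:
    data = json.loads(Path(path).read_text())
    return ReferenceModel(**data)
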