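"""Colour-to-thickness calibration and no-shell inference.

Directly measured shell thicknesses are regressed (ordinary least squares,
with intercept) on the measured R-B colour intensity:

    h = slope * (R - B) + intercept

The fitted line is then used to predict the thickness of capsules whose
shell is too thin to measure.  A negative predicted thickness is physically
impossible and is read as evidence that no continuous shell formed, so each
prediction carries a status: ``continuous`` (h_pred above the tolerance) or
``absent``.  The formation threshold is the largest tested concentration at
which every replicate is classified absent.

The intercept is essential: a through-origin line could never predict a
negative thickness at a non-negative colour intensity, and the negative
extrapolations are precisely the no-shell signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, DomainError

__all__ = [
    "ColourCalibration",
    "ThicknessEstimate",
    "STATUS_CONTINUOUS",
    "STATUS_ABSENT",
    "fit_colour_calibration",
    "predict_thickness_from_colour",
    "aggregate_by_concentration",
    "detect_formation_threshold",
]

logger = logging.getLogger(__name__)

STATUS_CONTINUOUS = "continuous"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class ColourCalibration:
    """Affine map from R-B colour intensity to shell thickness.

    slope is in micrometres per intensity unit and must be positive for a
    physically meaningful calibration (thicker shells are redder).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError(f"calibration needs n >= 2 points, got {self.n}")
        if not self.slope > 0:
            raise DomainError(
                f"calibration slope must be positive, got {self.slope:.4g}; "
                "the colour metric does not increase with thickness in these data"
            )
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise DomainError(f"r_squared={self.r_squared} outside [0, 1]")

    def predict(self, R_minus_B) -> np.ndarray | float:
        x = np.asarray(R_minus_B, dtype=float)
        out = self.slope * x + self.intercept
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThicknessEstimate:
    """A colour-predicted thickness (may be negative) and its classification."""

    h_pred: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in (STATUS_CONTINUOUS, STATUS_ABSENT):
            raise DomainError(f"unknown status {self.status!r}")


def fit_colour_calibration(
    pairs: Iterable[Sequence[float]] | pd.DataFrame,
) -> ColourCalibration:
    """OLS fit (with intercept) of measured thickness on R-B intensity.

    ``pairs`` is an iterable of ``(R_minus_B, h_um)`` or a DataFrame with
    columns ``R_minus_B`` and ``h_um``.  The closed-form normal-equations
    solution is used; r_squared is 1 - RSS/TSS (taken as 1 for a perfect
    fit to constant-thickness data).
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["R_minus_B", "h_um"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be (R_minus_B, h) couples")
    if len(arr) < 2:
        raise DegenerateDesignError("calibration needs at least two pairs")
    x, y = arr.T
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all R-B values identical; slope is unidentifiable")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if tss == 0.0 else 1.0 - float(np.sum(resid**2)) / tss
    return ColourCalibration(
        slope=slope, intercept=intercept, r_squared=min(max(r2, 0.0), 1.0), n=len(x)
    )


def predict_thickness_from_colour(
    cal: ColourCalibration, R_minus_B: float, tolerance: float = 0.0
) -> ThicknessEstimate:
    """Predict thickness from colour and classify shell presence.

    Predictions at or below ``tolerance`` (default 0 um) are classified
    ``absent``: the affine extrapolation produced a thickness that is not
    physically realisable, which is the no-shell signature.  Negative
    predictions are valid outputs, never errors.
    """
    h_pred = float(cal.predict(R_minus_B))
    status = STATUS_ABSENT if h_pred <= tolerance else STATUS_CONTINUOUS
    return ThicknessEstimate(h_pred=h_pred, status=status)


def aggregate_by_concentration(
    values: Iterable[Sequence[float]] | pd.DataFrame,
    value_name: str = "value",
) -> pd.DataFrame:
    """Per-concentration sample mean and standard deviation, sorted ascending.

    ``values`` is an iterable of ``(conc_mM, value)`` or a DataFrame with a
    ``conc_mM`` column and a ``value_name`` column.  The standard deviation
    uses the n-1 denominator and is 0 for singleton groups.
    """
    if isinstance(values, pd.DataFrame):
        df = values[["conc_mM", value_name]].rename(columns={value_name: "value"})
    else:
        rows = list(values)
        if not rows:
            raise DomainError("no values to aggregate")
        df = pd.DataFrame(rows, columns=["conc_mM", "value"])
    if df.empty:
        raise DomainError("no values to aggregate")
    g = df.groupby("conc_mM")["value"]
    out = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()}
    ).reset_index()
    out = out.sort_values("conc_mM", ignore_index=True)
    out = out.rename(columns={"mean": f"{value_name}_mean", "sd": f"{value_name}_sd"})
    return out


def detect_formation_threshold(
    per_sample: Iterable[tuple[float, ThicknessEstimate]] | pd.DataFrame,
) -> Optional[float]:
    """Largest tested concentration at which ALL replicates are shell-absent.

    Returns ``None`` when no concentration has all replicates absent.  A
    warning is logged when the absent/continuous pattern is non-monotone in
    concentration (an all-absent concentration above one with a continuous
    shell), since the growth model predicts monotone shell formation.
    """
    if isinstance(per_sample, pd.DataFrame):
        rows = [
            (float(c), str(s)) for c, s in zip(per_sample["conc_mM"], per_sample["status"])
        ]
    else:
        rows = [(float(c), est.status) for c, est in per_sample]
    if not rows:
        raise DomainError("no samples supplied")
    concs = sorted({c for c, _ in rows})
    if len(concs) < 2:
        raise DomainError("need samples at >= 2 distinct concentrations")
    all_absent = {
        c: all(s == STATUS_ABSENT for cc, s in rows if cc == c) for c in concs
    }
    qualifying = [c for c in concs if all_absent[c]]
    if not qualifying:
        return None
    threshold = max(qualifying)
    lowest_continuous = min(
        (c for c in concs if not all_absent[c]), default=None
    )
    if lowest_continuous is not None and lowest_continuous < threshold:
        logger.warning(
            "non-monotone formation pattern: all replicates absent at %g mM but a "
            "continuous shell was seen at %g mM",
            threshold,
            lowest_continuous,
        )
    return threshold
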