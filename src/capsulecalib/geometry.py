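"""Volumetric shell-growth model for ionotropically gelled core-shell capsules.

A spherical hydrogel core of radius ``R_c`` is soaked in CaCl2 at
concentration ``c`` (mM) and then immersed in alginate solution.  The
Ca2+ ions released from the core crosslink an alginate shell whose volume
is assumed proportional to the number of moles of Ca2+ the core absorbed:

    V_s = alpha' * n_Ca

With n_Ca proportional to V_c * c and both volumes expressed through the
radii, the shell thickness follows

    h = R_c * ((alpha * c + 1)^(1/3) - 1)

where ``alpha`` (mM^-1) absorbs all proportionality and unit factors.
The model linearises exactly,

    y = (h / R_c + 1)^3 - 1 = alpha * c,

so ``alpha`` is estimated by through-origin least squares of the
linearised response ``y`` on concentration ``x = c``.

Units are micrometres and millimolar throughout; ``alpha`` is reported in
mM^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, DomainError

__all__ = [
    "CapsuleGeometry",
    "CalciumLoad",
    "ShellModel",
    "AlphaFit",
    "predict_thickness",
    "linearized_response",
    "fit_alpha",
    "invert_concentration",
    "read_observations",
    "write_observations",
    "OBSERVATION_COLUMNS",
]

#: Litres per cubic micrometre (1 um^3 = 1e-15 L); converts mM * um^3 to moles.
_LITRES_PER_UM3 = 1e-15
_MOL_PER_MMOL = 1e-3

#: Canonical observation-table schema (CSV header order).
OBSERVATION_COLUMNS = ("sample_id", "conc_mM", "R_c_um", "h_um")


@dataclass(frozen=True)
class CapsuleGeometry:
    """Core radius and shell thickness of one capsule, micrometres.

    Derived volumes are exact sphere / spherical-shell volumes in um^3.
    """

    R_c: float
    h: float

    def __post_init__(self) -> None:
        if not self.R_c > 0:
            raise DomainError(f"core radius must be positive, got {self.R_c}")
        if self.h < 0:
            raise DomainError(f"shell thickness must be non-negative, got {self.h}")

    @property
    def V_c(self) -> float:
        """Core volume, cubic micrometres."""
        return (4.0 / 3.0) * math.pi * self.R_c**3

    @property
    def V_s(self) -> float:
        """Shell volume, cubic micrometres (0 iff h == 0)."""
        return (4.0 / 3.0) * math.pi * ((self.R_c + self.h) ** 3 - self.R_c**3)


@dataclass(frozen=True)
class CalciumLoad:
    """Ca2+ soaked into a core: concentration (mM) and derived moles."""

    conc: float
    V_c: float

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise DomainError(f"concentration must be non-negative, got {self.conc}")
        if not self.V_c > 0:
            raise DomainError(f"core volume must be positive, got {self.V_c}")

    @property
    def n_moles(self) -> float:
        """Moles of Ca2+ in the core: V_c [um^3] * conc [mM], unit-converted."""
        return self.V_c * _LITRES_PER_UM3 * self.conc * _MOL_PER_MMOL


@dataclass(frozen=True)
class ShellModel:
    """Proportionality constant of the volumetric growth law, mM^-1."""

    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise DomainError(f"alpha must be positive, got {self.alpha}")


class AlphaFit(NamedTuple):
    """Result of :func:`fit_alpha`: the model plus fit diagnostics."""

    model: ShellModel
    rss: float
    n: int


def _as_alpha(model: ShellModel | float):
    alpha = model.alpha if isinstance(model, ShellModel) else np.asarray(model, dtype=float)
    if np.any(np.asarray(alpha) <= 0):
        raise DomainError(f"alpha must be positive, got {alpha}")
    return alpha


def predict_thickness(model: ShellModel | float, conc, R_c):
    """Expected shell thickness (um) at soaking concentration ``conc`` (mM).

    Implements h = R_c * ((alpha*conc + 1)^(1/3) - 1): zero at zero
    concentration and strictly increasing in ``conc``, ``alpha`` and ``R_c``.
    Accepts scalars or arrays (broadcast).
    """
    alpha = _as_alpha(model)
    conc = np.asarray(conc, dtype=float)
    R_c = np.asarray(R_c, dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentration must be non-negative")
    if np.any(R_c <= 0):
        raise DomainError("core radius must be positive")
    h = R_c * (np.cbrt(alpha * conc + 1.0) - 1.0)
    return float(h) if h.ndim == 0 else h


def linearized_response(h, R_c):
    """Dimensionless linearised response y = (h/R_c + 1)^3 - 1.

    For data generated by the thickness law, y = alpha * conc exactly, which
    is what makes the through-origin fit of :func:`fit_alpha` valid.
    """
    h = np.asarray(h, dtype=float)
    R_c = np.asarray(R_c, dtype=float)
    if np.any(h < 0):
        raise DomainError("shell thickness must be non-negative")
    if np.any(R_c <= 0):
        raise DomainError("core radius must be positive")
    y = (h / R_c + 1.0) ** 3 - 1.0
    return float(y) if y.ndim == 0 else y


def fit_alpha(observations: Iterable[Sequence[float]] | pd.DataFrame) -> AlphaFit:
    """Estimate alpha by through-origin least squares on linearised data.

    ``observations`` is an iterable of ``(conc_mM, R_c_um, h_um)`` triples
    (or a DataFrame with columns ``conc_mM``, ``R_c_um``, ``h_um``).  With
    x_i = conc_i and y_i = (h_i/R_c_i + 1)^3 - 1 the estimate is the exact
    global minimiser of sum (y_i - alpha x_i)^2 over alpha:

        alpha_hat = sum(x_i y_i) / sum(x_i^2)

    Zero-concentration observations are accepted; they carry x = 0 and hence
    no leverage.  At least two observations with conc > 0 are required.
    """
    if isinstance(observations, pd.DataFrame):
        arr = observations[["conc_mM", "R_c_um", "h_um"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(observations), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DomainError("observations must be (conc, R_c, h) triples")
    conc, R_c, h = arr.T
    if np.count_nonzero(conc > 0) < 2:
        raise DegenerateDesignError(
            "need at least two observations with conc > 0 to estimate alpha"
        )
    y = linearized_response(h, R_c)
    sxx = float(np.sum(conc * conc))
    alpha_hat = float(np.sum(conc * y)) / sxx
    if not alpha_hat > 0:
        raise DegenerateDesignError(
            f"through-origin fit gave non-positive alpha ({alpha_hat:.3g}); "
            "data are inconsistent with shell growth"
        )
    rss = float(np.sum((y - alpha_hat * conc) ** 2))
    return AlphaFit(model=ShellModel(alpha=alpha_hat), rss=rss, n=len(conc))


def invert_concentration(model: ShellModel | float, h, R_c):
    """Concentration (mM) that would produce thickness ``h`` on core ``R_c``.

    Exact inverse of :func:`predict_thickness`: c = ((h/R_c + 1)^3 - 1)/alpha.
    """
    alpha = _as_alpha(model)
    y = linearized_response(h, R_c)
    out = np.asarray(y) / alpha
    return float(out) if out.ndim == 0 else out


def read_observations(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an observation table (CSV) into the canonical schema.

    ``column_map`` maps canonical names (``sample_id``, ``conc_mM``,
    ``R_c_um``, ``h_um``) to the headers actually present in the file.
    """
    from .pipeline import load_external_measurements  # local import: avoids cycle

    return load_external_measurements(path, column_map=column_map)


def write_observations(df: pd.DataFrame, path) -> None:
    """Write observations in the canonical CSV schema."""
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)
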