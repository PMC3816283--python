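"""Fluorescence-to-concentration calibration via brain-homogenate standards.

A dye standard curve relates sum fluorescence intensity per gram of brain
homogenate to the known dye concentration (ug dye / g tissue). Imaged tissue
regions are converted to an analyzed mass through
``area (um^2) x section thickness (um) x tissue density (g/cm^3)``, and the
fitted line is inverted to express a region's signal as ug dye per gram.

The intercept is retained by default: homogenate autofluorescence and any
non-dark-subtracted camera offset are absorbed there. A through-origin fit
is available as an option.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BRAIN_DENSITY_G_PER_CM3",
    "CalibrationCurve",
    "TissueRegionMeasurement",
    "fit_standard_curve",
    "region_mass",
    "intensity_to_concentration",
]

logger = logging.getLogger(__name__)

#: Density of brain tissue used for the area -> mass conversion, g/cm^3.
BRAIN_DENSITY_G_PER_CM3 = 1.04


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line: intensity per gram = slope * concentration + intercept.

    Attributes
    ----------
    slope : float
        Intensity units per (ug dye / g tissue). Must be > 0 for a usable
        curve (a non-positive slope cannot be inverted).
    intercept : float
        Intensity-per-gram background (autofluorescence + camera offset).
    r_squared : float
        Coefficient of determination of the fit, in [0, 1].
    n_points : int
        Number of standard measurements used.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d[k] for k in ("slope", "intercept", "r_squared", "n_points")})


@dataclass
class TissueRegionMeasurement:
    """One imaged tissue region and its derived mass / dye concentration.

    ``mass`` and ``concentration`` are filled in by :func:`measure_region`;
    ``density`` defaults to brain tissue (1.04 g/cm^3).
    """

    sum_intensity: float
    area_um2: float
    thickness_um: float = 20.0
    density_g_cm3: float = BRAIN_DENSITY_G_PER_CM3
    mass_g: float | None = None
    concentration_ug_per_g: float | None = None
    negative_flagged: bool = False


def fit_standard_curve(
    standards: pd.DataFrame, *, through_origin: bool = False
) -> CalibrationCurve:
    """OLS fit of intensity-per-gram on concentration for dye standards.

    Parameters
    ----------
    standards : DataFrame
        Columns ``conc_ug_per_g``, ``sum_intensity``, ``mass_g``; each row is
        one imaged homogenate section.
    through_origin : bool
        Force the line through zero (no background term).

    Raises
    ------
    ValueError
        Fewer than three distinct concentrations, or zero concentration
        variance.
    """
    required = {"conc_ug_per_g", "sum_intensity", "mass_g"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns: {sorted(missing)}")
    conc = standards["conc_ug_per_g"].to_numpy(float)
    ipg = standards["sum_intensity"].to_numpy(float) / standards["mass_g"].to_numpy(float)
    if np.unique(conc).size < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    if np.var(conc) == 0:
        raise ValueError("standard concentrations have zero variance")

    if through_origin:
        slope = float(conc @ ipg / (conc @ conc))
        resid = ipg - slope * conc
        ss_tot = float(np.sum((ipg - ipg.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(resid @ resid) / ss_tot)
        return CalibrationCurve(slope, 0.0, min(r2, 1.0), conc.size)

    fit = sps.linregress(conc, ipg)
    return CalibrationCurve(
        float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2, conc.size
    )


def region_mass(
    area_um2: float,
    thickness_um: float = 20.0,
    density_g_cm3: float = BRAIN_DENSITY_G_PER_CM3,
) -> float:
    """Analyzed tissue mass in grams from region area and section thickness.

    mass = area (um^2) * thickness (um) -> volume (um^3), * 1e-12 -> cm^3,
    * density -> g.
    """
    if area_um2 < 0:
        raise ValueError(f"area must be >= 0, got {area_um2}")
    if thickness_um <= 0 or density_g_cm3 <= 0:
        raise ValueError("thickness and density must be > 0")
    return area_um2 * thickness_um * 1e-12 * density_g_cm3


def intensity_to_concentration(
    sum_intensity: float, mass_g: float, curve: CalibrationCurve
) -> float:
    """Invert the standard curve: sum intensity + mass -> ug dye / g tissue.

    concentration = ((sum_intensity / mass) - intercept) / slope.
    Values below zero (regions dimmer than the fitted background) are
    returned as-is and logged, not clamped, so population means stay
    unbiased.
    """
    if mass_g <= 0:
        raise ValueError(f"mass must be > 0, got {mass_g}")
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert")
    conc = ((sum_intensity / mass_g) - curve.intercept) / curve.slope
    if conc < 0:
        logger.warning(
            "back-calculated concentration is negative (%.4g ug/g); "
            "region dimmer than fitted background",
            conc,
        )
    return float(conc)


def measure_region(
    sum_intensity: float,
    area_um2: float,
    curve: CalibrationCurve,
    thickness_um: float = 20.0,
    density_g_cm3: float = BRAIN_DENSITY_G_PER_CM3,
) -> TissueRegionMeasurement:
    """Full region workflow: area -> mass -> concentration, with flagging."""
    m = region_mass(area_um2, thickness_um, density_g_cm3)
    meas = TissueRegionMeasurement(
        sum_intensity=sum_intensity,
        area_um2=area_um2,
        thickness_um=thickness_um,
        density_g_cm3=density_g_cm3,
        mass_g=m,
    )
    if m > 0:
        c = intensity_to_concentration(sum_intensity, m, curve)
        meas.concentration_ug_per_g = c
        meas.negative_flagged = bool(c < 0 or not math.isfinite(c))
    return meas
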