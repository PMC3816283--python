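"""Efflux-substrate profiling from the LogD vs Log K_in relationship.

Compounds that enter brain by passive transcellular diffusion show a linear
relationship between lipophilicity (LogD, octanol/water distribution
coefficient at pH 7.4) and the log of their observed transfer constant
Log10 K_in (K_in in mL/s/g). A compound whose observed Log K_in falls well
below the line fitted to known passive permeants is a suspected substrate
of active efflux (P-gp and related transporters): the barrier extrudes it
faster than lipophilicity alone predicts.

The deviation is measured in log10 units below the fitted passive line;
compounds at or above the line are not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CompoundRecord",
    "PassiveLine",
    "EffluxCall",
    "log_kin",
    "fit_passive_line",
    "efflux_deviation",
    "screen",
    "load_reference_compounds",
]

#: Default deviation (log10 units below the passive line) at which a
#: compound is flagged as an efflux suspect. Passive-line scatter is
#: typically well under 0.5 log units, while strong efflux substrates sit
#: several units below, so 1.0 separates the two regimes robustly.
DEFAULT_THRESHOLD_LOG10 = 1.0


def log_kin(kin_ul_s_g: float) -> float:
    """Log10 of K_in expressed in mL/s/g, from K_in given in uL/s/g."""
    if kin_ul_s_g <= 0:
        raise ValueError(f"K_in must be > 0 to take a log, got {kin_ul_s_g}")
    return float(np.log10(kin_ul_s_g / 1000.0))


@dataclass(frozen=True)
class CompoundRecord:
    """A compound's lipophilicity and observed brain-uptake constant."""

    name: str
    logd: float
    kin_ul_s_g: float
    known_class: str = "unknown"  # passive | efflux | unknown

    @property
    def log_kin(self) -> float:
        return log_kin(self.kin_ul_s_g)


@dataclass(frozen=True)
class PassiveLine:
    """OLS line log10 K_in = slope * LogD + intercept over passive permeants."""

    slope: float
    intercept: float
    residual_sd: float
    n: int

    def predict(self, logd: float) -> float:
        return self.slope * logd + self.intercept


@dataclass(frozen=True)
class EffluxCall:
    """Deviation of one compound from the passive line and the resulting flag."""

    name: str
    deviation_log10: float  # positive = below the line
    flagged: bool
    threshold_log10: float


def fit_passive_line(compounds: Sequence[CompoundRecord]) -> PassiveLine:
    """Fit the passive-diffusion reference line over known passive permeants.

    Raises ``ValueError`` with fewer than two passive compounds of distinct
    LogD.
    """
    passive = [c for c in compounds if c.known_class == "passive"]
    if len(passive) < 2 or len({c.logd for c in passive}) < 2:
        raise ValueError("need >= 2 passive compounds with distinct LogD")
    x = np.array([c.logd for c in passive])
    y = np.array([c.log_kin for c in passive])
    fit = sps.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sd = float(np.sqrt(resid @ resid / (x.size - 2))) if x.size > 2 else 0.0
    return PassiveLine(float(fit.slope), float(fit.intercept), sd, int(x.size))


def efflux_deviation(
    compound: CompoundRecord,
    line: PassiveLine,
    threshold_log10: float = DEFAULT_THRESHOLD_LOG10,
) -> EffluxCall:
    """Log-units a compound falls below the passive line, with classification.

    deviation = predicted Log K_in - observed Log K_in; positive means the
    compound sits below the line (less brain uptake than lipophilicity
    predicts). Flagged when deviation >= threshold.
    """
    dev = line.predict(compound.logd) - compound.log_kin
    return EffluxCall(
        name=compound.name,
        deviation_log10=float(dev),
        flagged=bool(dev >= threshold_log10),
        threshold_log10=threshold_log10,
    )


def screen(
    compounds: pd.DataFrame | Sequence[CompoundRecord],
    threshold_log10: float = DEFAULT_THRESHOLD_LOG10,
) -> tuple[PassiveLine, pd.DataFrame]:
    """Screen every compound of a table against the passive line.

    Accepts a DataFrame (columns ``name, logd, kin_ul_s_g, known_class``)
    or a sequence of :class:`CompoundRecord`. The line is fitted on rows
    with ``known_class == 'passive'``; deviations and flags are reported
    for all rows.
    """
    if isinstance(compounds, pd.DataFrame):
        recs = [
            CompoundRecord(str(r.name_), float(r.logd), float(r.kin_ul_s_g), str(r.known_class))
            for r in compounds.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
    else:
        recs = list(compounds)
    line = fit_passive_line(recs)
    rows = []
    for c in recs:
        call = efflux_deviation(c, line, threshold_log10)
        rows.append(
            dict(name=c.name, logd=c.logd, kin_ul_s_g=c.kin_ul_s_g,
                 log_kin=c.log_kin, known_class=c.known_class,
                 deviation_log10=call.deviation_log10, flagged=call.flagged)
        )
    return line, pd.DataFrame(rows)


def load_reference_compounds() -> pd.DataFrame:
    """Load the packaged synthetic reference compound set.

    The compound names and LogD values are literature-plausible, but the
    K_in values are synthetic: constructed on a reference passive line so
    that the set is internally consistent. Treat the file as editable
    configuration, not measured ground truth; replace it with your own
    laboratory's reference panel for real analyses.
    """
    with resources.files("btbkin.data").joinpath("reference_compounds_synthetic.csv").open() as f:
        return pd.read_csv(f, comment="#")
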