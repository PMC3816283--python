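"""Unidirectional blood-to-brain transfer-constant (K_in) estimation.

During an in situ perfusion at constant perfusate tracer concentration C*
(ug/mL), tracer accumulates in tissue within the linear uptake window as

    Q*/C* = K_in * T + V0

where Q* is the tissue tracer quantity (ug/g) at the end of a perfusion of
duration T (s), K_in is the unidirectional transfer constant (mL/s/g) and
V0 is the intercept at T = 0, the tracer-accessible vascular volume (mL/g).

Two estimators are provided:

* multi-timepoint: OLS of Q*/C* on T across perfusions of different
  durations; the slope is K_in and the intercept V0;
* single-timepoint: with V0 known (e.g. from an impermeant sucrose
  perfusion), K_in = (Q* - V0 * C*) / (C* * T) per animal.

K_in is reported in uL/s/g (x1000 from the mL/s/g of the fit) to match the
scale on which brain-perfusion results are conventionally quoted; V0 stays
in mL/g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PerfusionRecord",
    "KineticsResult",
    "fit_kin_multipoint",
    "kin_single_timepoint",
    "vascular_volume",
    "inhibitor_fold",
    "records_to_frame",
    "frame_to_records",
]

logger = logging.getLogger(__name__)

ML_TO_UL = 1000.0


@dataclass(frozen=True)
class PerfusionRecord:
    """One timed-perfusion tissue measurement.

    qstar: tissue tracer quantity Q* (ug/g); cstar: perfusate concentration
    C* (ug/mL); time_s: perfusion duration T (s); region e.g. ``normal``,
    ``BDT`` or ``lesion``; inhibitor is ``None`` for baseline perfusions.
    """

    tracer: str
    qstar_ug_per_g: float
    cstar_ug_per_ml: float
    time_s: float
    region: str = "normal"
    inhibitor: str | None = None

    def __post_init__(self) -> None:
        if self.qstar_ug_per_g < 0:
            raise ValueError(f"Q* must be >= 0, got {self.qstar_ug_per_g}")
        if self.cstar_ug_per_ml <= 0:
            raise ValueError(f"C* must be > 0, got {self.cstar_ug_per_ml}")
        if self.time_s <= 0:
            raise ValueError(f"perfusion time must be > 0, got {self.time_s}")

    @property
    def uptake_ml_per_g(self) -> float:
        """Volume of distribution Q*/C* in mL/g."""
        return self.qstar_ug_per_g / self.cstar_ug_per_ml


@dataclass
class KineticsResult:
    """Estimated K_in (uL/s/g) and V0 (mL/g) with standard errors."""

    kin_ul_s_g: float
    kin_se_ul_s_g: float
    v0_ml_g: float
    v0_se_ml_g: float
    n: int
    method: str  # "multipoint" | "single_timepoint"
    r_squared: float | None = None
    v0_source: str = "fit"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kin_se_ul_s_g < 0 or self.v0_se_ml_g < 0:
            raise ValueError("standard errors must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _check_single_group(records: Sequence[PerfusionRecord]) -> None:
    keys = {(r.tracer, r.region, r.inhibitor) for r in records}
    if len(keys) > 1:
        raise ValueError(
            f"records span multiple (tracer, region, inhibitor) groups: {sorted(map(str, keys))}"
        )


def fit_kin_multipoint(records: Sequence[PerfusionRecord]) -> KineticsResult:
    """OLS fit of Q*/C* (mL/g) on perfusion time T (s) for one tracer group.

    The slope is K_in (converted to uL/s/g); the intercept is the vascular
    volume V0 (mL/g). Standard errors come from the OLS fit. Linearity over
    the time window is assumed, not detected; check ``r_squared``.

    Raises
    ------
    ValueError
        Mixed groups, or only one distinct time (use
        :func:`kin_single_timepoint` with a known V0 instead).
    """
    records = list(records)
    if not records:
        raise ValueError("no perfusion records given")
    _check_single_group(records)
    t = np.array([r.time_s for r in records], float)
    y = np.array([r.uptake_ml_per_g for r in records], float)
    if np.unique(t).size < 2:
        raise ValueError(
            "only one distinct perfusion time; use kin_single_timepoint with a known V0"
        )
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    intercept, slope = fit.params
    se_i, se_s = fit.bse if len(records) > 2 else (0.0, 0.0)
    # 2 points determine the line exactly; statsmodels returns NaN SEs there
    if not np.isfinite(se_s):
        se_s, se_i = 0.0, 0.0
    # r^2 is undefined when y has no variance (impermeant tracer)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(fit.ssr) / ss_tot if ss_tot > 0 else None
    res = KineticsResult(
        kin_ul_s_g=float(slope) * ML_TO_UL,
        kin_se_ul_s_g=float(se_s) * ML_TO_UL,
        v0_ml_g=float(intercept),
        v0_se_ml_g=float(se_i),
        n=len(records),
        method="multipoint",
        r_squared=r2,
        v0_source="intercept",
    )
    if res.kin_ul_s_g < 0:
        res.flags.append("negative_kin")
    return res


def kin_single_timepoint(
    qstar_ug_per_g: float | Sequence[float],
    cstar_ug_per_ml: float | Sequence[float],
    time_s: float | Sequence[float],
    v0_ml_g: float,
    v0_source: str = "argument",
) -> KineticsResult:
    """Single-timepoint K_in with vascular-volume correction.

    K_in = (Q* - V0 * C*) / (C* * T), evaluated per replicate record and
    then averaged (mean +/- SEM across animals), reported in uL/s/g.
    Negative values (tissue signal below the vascular contribution) are
    kept and flagged, not truncated.
    """
    q = np.atleast_1d(np.asarray(qstar_ug_per_g, float))
    c = np.atleast_1d(np.asarray(cstar_ug_per_ml, float))
    t = np.atleast_1d(np.asarray(time_s, float))
    q, c, t = np.broadcast_arrays(q, c, t)
    if np.any(t <= 0):
        raise ValueError("perfusion time must be > 0")
    if np.any(c <= 0):
        raise ValueError("C* must be > 0")
    if v0_ml_g < 0:
        raise ValueError("V0 must be >= 0")
    kin = (q - v0_ml_g * c) / (c * t) * ML_TO_UL  # uL/s/g
    n = kin.size
    sem = float(np.std(kin, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    res = KineticsResult(
        kin_ul_s_g=float(kin.mean()),
        kin_se_ul_s_g=sem,
        v0_ml_g=float(v0_ml_g),
        v0_se_ml_g=0.0,
        n=int(n),
        method="single_timepoint",
        v0_source=v0_source,
    )
    if np.any(kin < 0):
        res.flags.append("negative_kin")
        logger.warning("single-timepoint K_in negative for %d/%d records", int((kin < 0).sum()), n)
    return res


def vascular_volume(records: Sequence[PerfusionRecord]) -> tuple[float, float]:
    """Vascular volume from an impermeant-tracer perfusion.

    For a tracer that does not cross the barrier (e.g. sucrose), Q*/C* has
    no time dependence and estimates V0 directly. Returns (mean, SEM) of
    Q*/C* in mL/g; SEM is 0 for a single record.
    """
    records = list(records)
    if not records:
        raise ValueError("no records given for vascular volume")
    v = np.array([r.uptake_ml_per_g for r in records], float)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem


def inhibitor_fold(kin_with_ul_s_g: float, kin_baseline_ul_s_g: float) -> float:
    """Fold increase in K_in under transporter inhibition (ratio of K_in)."""
    if kin_baseline_ul_s_g <= 0:
        raise ValueError(f"baseline K_in must be > 0, got {kin_baseline_ul_s_g}")
    return kin_with_ul_s_g / kin_baseline_ul_s_g


# ---------------------------------------------------------------------------
# table <-> record conversion (perfusion CSV surface)

_COLUMNS = ["tracer", "region", "inhibitor", "qstar_ug_per_g", "cstar_ug_per_ml", "time_s"]


def records_to_frame(records: Iterable[PerfusionRecord]) -> pd.DataFrame:
    rows = [
        (r.tracer, r.region, r.inhibitor or "", r.qstar_ug_per_g, r.cstar_ug_per_ml, r.time_s)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PerfusionRecord]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"perfusion table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        inhib = getattr(row, "inhibitor")
        inhib = None if (inhib is None or (isinstance(inhib, float) and np.isnan(inhib)) or inhib == "") else str(inhib)
        out.append(
            PerfusionRecord(
                tracer=str(row.tracer),
                qstar_ug_per_g=float(row.qstar_ug_per_g),
                cstar_ug_per_ml=float(row.cstar_ug_per_ml),
                time_s=float(row.time_s),
                region=str(row.region),
                inhibitor=inhib,
            )
        )
    return out


def fit_groups(
    df: pd.DataFrame,
    v0_ml_g: float | None = None,
    impermeant_tracer: str = "sucrose",
) -> pd.DataFrame:
    """Fit K_in for every (tracer, region, inhibitor) group of a perfusion table.

    V0 precedence when a group has a single distinct time: explicit
    ``v0_ml_g`` argument, else a sucrose estimate from the same table, else
    error. Multi-time groups use the fitted intercept. The impermeant
    tracer's own rows are summarized as a vascular-volume estimate.
    """
    records = frame_to_records(df)
    sucrose = [r for r in records if r.tracer == impermeant_tracer]
    v0_est = vascular_volume(sucrose)[0] if sucrose else None

    rows = []
    groups: dict[tuple, list[PerfusionRecord]] = {}
    for r in records:
        groups.setdefault((r.tracer, r.region, r.inhibitor), []).append(r)
    for (tracer, region, inhib), grp in groups.items():
        if tracer == impermeant_tracer:
            v0, v0_sem = vascular_volume(grp)
            rows.append(
                dict(tracer=tracer, region=region, inhibitor=inhib or "",
                     kin_ul_s_g=np.nan, kin_se_ul_s_g=np.nan, v0_ml_g=v0,
                     v0_se_ml_g=v0_sem, n=len(grp), method="vascular_volume",
                     v0_source="impermeant")
            )
            continue
        times = {r.time_s for r in grp}
        if len(times) >= 2:
            res = fit_kin_multipoint(grp)
        else:
            if v0_ml_g is not None:
                v0_use, src = v0_ml_g, "argument"
            elif v0_est is not None:
                v0_use, src = v0_est, impermeant_tracer
            else:
                raise ValueError(
                    f"group {(tracer, region, inhib)} has one timepoint and no V0 source"
                )
            res = kin_single_timepoint(
                [r.qstar_ug_per_g for r in grp],
                [r.cstar_ug_per_ml for r in grp],
                [r.time_s for r in grp],
                v0_use,
                v0_source=src,
            )
        rows.append(
            dict(tracer=tracer, region=region, inhibitor=inhib or "",
                 kin_ul_s_g=res.kin_ul_s_g, kin_se_ul_s_g=res.kin_se_ul_s_g,
                 v0_ml_g=res.v0_ml_g, v0_se_ml_g=res.v0_se_ml_g, n=res.n,
                 method=res.method, v0_source=res.v0_source)
        )
    return pd.DataFrame(rows)
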