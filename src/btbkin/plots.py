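"""Diagnostic figures for the pipeline stages (Agg backend, file output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .efflux import PassiveLine

__all__ = ["plot_standard_curve", "plot_uptake", "plot_logd_profile"]


def plot_standard_curve(standards: pd.DataFrame, curve: CalibrationCurve, path: str | Path) -> None:
    """Intensity-per-gram vs concentration with the fitted line."""
    conc = standards["conc_ug_per_g"]
    ipg = standards["sum_intensity"] / standards["mass_g"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(conc, ipg, "o", ms=4, alpha=0.7)
    xs = np.linspace(0, conc.max(), 50)
    ax.plot(xs, curve.slope * xs + curve.intercept, "-", lw=1)
    ax.set_xlabel("dye concentration (ug/g)")
    ax.set_ylabel("sum intensity per gram (A.U./g)")
    ax.set_title(f"standard curve, r$^2$={curve.r_squared:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_uptake(perf: pd.DataFrame, kin_ul_s_g: float, v0_ml_g: float, path: str | Path) -> None:
    """Q*/C* vs perfusion time with the fitted uptake line."""
    y = perf["qstar_ug_per_g"] / perf["cstar_ug_per_ml"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(perf["time_s"], y, "o", ms=4, alpha=0.7)
    xs = np.linspace(0, perf["time_s"].max() * 1.05, 50)
    ax.plot(xs, kin_ul_s_g / 1000.0 * xs + v0_ml_g, "-", lw=1)
    ax.set_xlabel("perfusion time (s)")
    ax.set_ylabel("Q*/C* (mL/g)")
    ax.set_title(f"K$_{{in}}$ = {kin_ul_s_g:.3g} uL/s/g, V$_0$ = {v0_ml_g:.3g} mL/g")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_logd_profile(screen_df: pd.DataFrame, line: PassiveLine, path: str | Path) -> None:
    """LogD vs Log K_in scatter with the fitted passive-diffusion line."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for cls, marker in (("passive", "s"), ("efflux", "^"), ("unknown", "o")):
        sub = screen_df[screen_df.known_class == cls]
        if len(sub):
            ax.plot(sub.logd, sub.log_kin, marker, ms=5, label=cls, alpha=0.8)
    xs = np.linspace(screen_df.logd.min() - 0.2, screen_df.logd.max() + 0.2, 20)
    ax.plot(xs, line.slope * xs + line.intercept, "k-", lw=1, label="passive line")
    ax.set_xlabel("LogD (pH 7.4)")
    ax.set_ylabel("log$_{10}$ K$_{in}$ (mL/s/g)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
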