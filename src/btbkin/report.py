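"""End-to-end report assembly and validation.

The report is a single provenance-stamped JSON document collecting every
stage's outputs: calibration curve, K_in table with inhibitor folds,
efflux deviations, vessel-expression summary with its group test, lesion
table with correlations, and the seeds/configuration that produced them.
Stages that were not run are listed under ``missing`` rather than raising,
so a partial run still yields a well-formed document. Reports contain no
wall-clock timestamps: two runs with the same seed and configuration are
byte-identical.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

from . import __version__

__all__ = ["build_report", "validate_report", "write_report", "load_schema"]

_SECTIONS = ("calibration", "kinetics", "efflux", "vessels", "lesions", "stats")


def load_schema() -> dict:
    with resources.files("btbkin.data").joinpath("report_schema_v1.json").open() as f:
        return json.load(f)


def build_report(
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
    calibration: Mapping[str, Any] | None = None,
    kinetics: Mapping[str, Any] | None = None,
    efflux: Mapping[str, Any] | None = None,
    vessels: Mapping[str, Any] | None = None,
    lesions: Mapping[str, Any] | None = None,
    stats: Mapping[str, Any] | None = None,
) -> dict:
    """Assemble the pipeline report; absent stages become explicit gaps."""
    stages = {
        "calibration": calibration,
        "kinetics": kinetics,
        "efflux": efflux,
        "vessels": vessels,
        "lesions": lesions,
        "stats": stats,
    }
    report = {
        "schema_version": 1,
        "package": f"btbkin {__version__}",
        "seed": seed,
        "config": dict(config) if config else {},
        "sections": {k: dict(v) for k, v in stages.items() if v is not None},
        "missing": sorted(k for k, v in stages.items() if v is None),
    }
    validate_report(report)
    return report


def validate_report(report: Mapping[str, Any]) -> None:
    """Check a report against the packaged schema; raises ``ValueError``."""
    schema = load_schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["schema_version"] != schema["version"]:
        raise ValueError(
            f"schema version mismatch: report {report['schema_version']} vs {schema['version']}"
        )
    for name, section in report["sections"].items():
        if name not in schema["section_names"]:
            raise ValueError(f"unknown report section {name!r}")
        for key in schema["section_required"].get(name, []):
            if key not in section:
                raise ValueError(f"section {name!r} missing key {key!r}")
    declared = set(report["sections"]) | set(report["missing"])
    if declared != set(_SECTIONS):
        raise ValueError(f"sections + missing must cover exactly {_SECTIONS}")


def _summary_lines(report: Mapping[str, Any]) -> list[str]:
    lines = [f"{report['package']} run report (seed={report['seed']})", ""]
    s = report["sections"]
    if "calibration" in s:
        c = s["calibration"]
        lines.append(
            f"Calibration: slope {c['slope']:.4g} AU/(ug/g), intercept {c['intercept']:.4g}, "
            f"r^2 {c['r_squared']:.4f} (n={c['n_points']})"
        )
    if "kinetics" in s:
        k = s["kinetics"]
        lines.append(f"Vascular volume V0: {k['v0_ml_g']:.4g} mL/g")
        for g in k["groups"]:
            if g.get("kin_ul_s_g") is None:
                continue
            lines.append(
                f"  K_in[{g['tracer']}|{g['region']}|{g.get('inhibitor') or '-'}] = "
                f"{g['kin_ul_s_g']:.3g} +/- {g.get('kin_se_ul_s_g', 0):.2g} uL/s/g (n={g['n']})"
            )
        for name, fold in k.get("inhibitor_folds", {}).items():
            lines.append(f"  {name}: {fold:.3g}-fold increase in K_in")
    if "efflux" in s:
        flagged = [c["name"] for c in s["efflux"]["compounds"] if c["flagged"]]
        lines.append(f"Efflux suspects (>= threshold below passive line): {', '.join(flagged) or 'none'}")
    if "vessels" in s:
        for row in s["vessels"]["summary"]:
            lines.append(
                f"P-gp per vessel [{row['vessel_class']}]: {row['mean_au']:.3g} +/- "
                f"{row['sem_au']:.2g} A.U. (n={row['n_vessels']})"
            )
        cmp_ = s["vessels"]["comparison"]
        lines.append(f"  BBB vs BTB t-test: p = {cmp_['p_value']:.3g}")
    if "lesions" in s:
        for row in s["lesions"]["per_lesion"]:
            lines.append(
                f"Lesion {row['lesion_id']}: area {row['area_mm2']:.4g} mm^2, "
                f"AIB fold {row.get('fold_aib', float('nan')):.3g}, "
                f"R123 fold {row.get('fold_r123', float('nan')):.3g}"
            )
        for name, corr in s["lesions"]["correlations"].items():
            lines.append(f"  r^2[{name}] = {corr['r_squared']:.3g}")
    if report["missing"]:
        lines.append("Missing stages: " + ", ".join(report["missing"]))
    return lines


def write_report(report: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write ``report.json`` and a human-readable ``summary.txt``; returns JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "summary.txt").write_text("\n".join(_summary_lines(report)) + "\n")
    return path
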