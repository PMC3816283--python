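"""End-to-end orchestration: simulate -> calibrate -> kinetics -> efflux ->
image quantification -> statistics -> report.

`SimConfig` holds the study conditions the simulation emulates: a baseline
transfer constant of 0.12 uL/s/g with a 0.015 mL/g vascular volume and a
50 ug/mL perfusate over 30-120 s; transporter inhibition raising K_in to
2.4 (cyclosporin A) and 2.2 (verapamil) uL/s/g; per-vessel transporter
staining near 22.6 A.U. (normal brain) and 22.9 A.U. (lesion vasculature);
and lesions whose passive-tracer signal is amplified ~4.9-fold while the
efflux substrate stays near 1.0-fold. YAML keys with the same names
override any field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, efflux, image_quant, kinetics, report, stats, synthetic
from . import io as bio
from ._rng import substream

__all__ = ["SimConfig", "simulate_run", "analyze_run", "run_pipeline"]


@dataclass
class SimConfig:
    # calibration standards
    standard_concs: list[float] = field(default_factory=lambda: [0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
    calib_slope: float = 1000.0  # AU per (ug/g) per g analyzed
    calib_intercept: float = 50.0  # AU/g background
    calib_noise_sd: float = 20.0
    calib_replicates: int = 3
    # perfusion kinetics
    true_kin_ul_s_g: float = 0.12
    true_v0_ml_g: float = 0.015
    cstar_ug_per_ml: float = 50.0
    times_s: list[float] = field(default_factory=lambda: [30.0, 60.0, 90.0, 120.0])
    noise_cv: float = 0.1
    n_per_time: int = 5
    inhibitor_kin_ul_s_g: dict = field(
        default_factory=lambda: {"cyclosporinA": 2.4, "verapamil": 2.2}
    )
    inhibitor_time_s: float = 120.0
    n_per_inhibitor: int = 4
    n_sucrose: int = 4
    # section imagery
    shape: tuple = (384, 384)
    pixel_size_um: float = 2.0
    n_lesions: int = 3
    n_vessels_bbb: int = 25
    n_vessels_btb: int = 12
    pgp_mean_bbb: float = 22.6
    pgp_mean_btb: float = 22.9
    pgp_sd: float = 10.5
    blur_sigma: float = 1.0
    background: float = 10.0
    image_noise_sd: float = 1.0
    # autoradiograph
    downsample_factor: int = 4
    autorad_background: float = 50.0
    autorad_noise_sd: float = 1.0
    autorad_shift_px: tuple = (0, 0)
    # efflux screen
    efflux_threshold_log10: float = efflux.DEFAULT_THRESHOLD_LOG10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        d["autorad_shift_px"] = list(d["autorad_shift_px"])
        return d


def _btb_vessel_specs(cfg: SimConfig, lesions, occupied, seed):
    """Short vessel tubes placed inside lesion disks (tumor vasculature)."""
    rng = substream(seed, "vessels_btb")
    specs = []
    tries = 0
    next_id = cfg.n_vessels_bbb + 1
    while len(specs) < cfg.n_vessels_btb and tries < 4000:
        tries += 1
        les = lesions[rng.integers(len(lesions))]
        r = rng.uniform(1.5, 3.0)
        length = rng.uniform(8.0, min(20.0, les.radius_px))
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(0, les.radius_px * 0.5, size=2) * rng.choice([-1, 1], 2)
        c0 = np.asarray(les.center) + offset
        d = np.array([np.sin(theta), np.cos(theta)]) * length / 2
        start, end = c0 - d, c0 + d
        for p in (start, end):
            if np.hypot(p[0] - les.center[0], p[1] - les.center[1]) > les.radius_px - r - 1:
                break
        else:
            padded = synthetic._paint_tube(cfg.shape, start, end, r + 2.0)
            if np.any(occupied & padded):
                continue
            occupied |= padded
            intensity = float(max(rng.normal(cfg.pgp_mean_btb, cfg.pgp_sd), 0.5))
            specs.append(
                synthetic.VesselSpec(
                    vessel_id=next_id, start=tuple(start), end=tuple(end),
                    radius_px=float(r), pgp_intensity=intensity,
                )
            )
            next_id += 1
    if len(specs) < cfg.n_vessels_btb:
        raise RuntimeError("could not place all tumor vessels; enlarge lesions or image")
    return specs


def simulate_run(cfg: SimConfig, out_dir: str | Path, seed: int) -> dict:
    """Generate every pipeline input into ``out_dir``; returns ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    standards = synthetic.generate_standards(
        cfg.standard_concs, cfg.calib_slope, cfg.calib_intercept,
        cfg.calib_noise_sd, cfg.calib_replicates, seed=seed,
    )
    standards.to_csv(out / "standards.csv", index=False)

    records = synthetic.generate_perfusion_series(
        cfg.true_kin_ul_s_g, cfg.true_v0_ml_g, cfg.cstar_ug_per_ml, cfg.times_s,
        cfg.noise_cv, cfg.n_per_time, seed=seed,
    )
    records += synthetic.generate_perfusion_series(
        0.0, cfg.true_v0_ml_g, cfg.cstar_ug_per_ml,
        [cfg.inhibitor_time_s] * cfg.n_sucrose, cfg.noise_cv, 1,
        seed=seed, tracer="sucrose",
    )
    for name, kin in cfg.inhibitor_kin_ul_s_g.items():
        records += synthetic.generate_perfusion_series(
            kin, cfg.true_v0_ml_g, cfg.cstar_ug_per_ml,
            [cfg.inhibitor_time_s] * cfg.n_per_inhibitor, cfg.noise_cv, 1,
            seed=seed, inhibitor=name,
        )
    kinetics.records_to_frame(records).to_csv(out / "perfusion.csv", index=False)

    lesions = synthetic.random_lesion_specs(cfg.shape, cfg.n_lesions, seed=seed)
    lesion_area = np.zeros(cfg.shape, bool)
    for les in lesions:
        lesion_area |= synthetic._disk(cfg.shape, les.center, les.radius_px + 4)
    bbb_vessels = synthetic.random_vessel_specs(
        cfg.shape, cfg.n_vessels_bbb, seed=seed,
        intensity_mean=cfg.pgp_mean_bbb, intensity_sd=cfg.pgp_sd, exclude=lesion_area,
    )
    occupied = lesion_area.copy()
    for v in bbb_vessels:
        occupied |= synthetic._paint_tube(cfg.shape, v.start, v.end, v.radius_px + 2)
    occupied &= ~lesion_area  # tumor vessels may sit inside lesions
    btb_vessels = _btb_vessel_specs(cfg, lesions, occupied, seed)

    section, masks = synthetic.generate_section(
        cfg.shape, cfg.pixel_size_um, bbb_vessels + btb_vessels, lesions,
        blur_sigma=cfg.blur_sigma, background=cfg.background,
        noise_sd=cfg.image_noise_sd, seed=seed,
    )
    bio.write_section(section, out / "section.tif")
    bio.write_mask(masks["vessels"], out / "vessel_mask.tif")
    bio.write_mask(masks["lesions"], out / "lesion_mask.tif")

    fold_map = {les.lesion_id: les.folds["aib"] for les in lesions}
    autorad = synthetic.generate_autoradiograph(
        masks["lesions"], fold_map, cfg.downsample_factor, cfg.autorad_background,
        tuple(cfg.autorad_shift_px), cfg.autorad_noise_sd, seed=seed,
    )
    bio.write_autoradiograph(autorad, out / "autorad.tif")

    gt = synthetic.GroundTruth(
        true_kin_ul_s_g=cfg.true_kin_ul_s_g,
        true_v0_ml_g=cfg.true_v0_ml_g,
        calib_slope=cfg.calib_slope,
        calib_intercept=cfg.calib_intercept,
        lesion_folds={les.lesion_id: dict(les.folds) for les in lesions},
        vessel_intensities={v.vessel_id: v.pgp_intensity for v in bbb_vessels + btb_vessels},
        seed=seed,
    )
    gt.to_json(out / "ground_truth.json")
    n_bbb = len(bbb_vessels)
    (out / "vessel_classes.json").write_text(json.dumps({
        "bbb_ids": [v.vessel_id for v in bbb_vessels],
        "btb_ids": [v.vessel_id for v in btb_vessels],
    }, indent=2) + "\n")
    return {"ground_truth": gt, "n_bbb_vessels": n_bbb, "out_dir": str(out)}


def analyze_run(run_dir: str | Path, seed: int = 0, cfg: SimConfig | None = None) -> dict:
    """Run every analysis stage on a simulated (or equivalently laid-out) run.

    Returns the validated report dict; also writes ``report.json`` and
    ``summary.txt`` into ``run_dir``.
    """
    cfg = cfg or SimConfig()
    run = Path(run_dir)

    # calibration
    standards = bio.read_standards(run / "standards.csv")
    curve = calibration.fit_standard_curve(standards)
    calib_section = dict(slope=curve.slope, intercept=curve.intercept,
                         r_squared=curve.r_squared, n_points=curve.n_points)

    # kinetics
    perf = bio.read_perfusion(run / "perfusion.csv")
    groups = kinetics.fit_groups(perf)
    v0_row = groups[groups.method == "vascular_volume"]
    v0 = float(v0_row.v0_ml_g.iloc[0]) if len(v0_row) else float(
        groups.v0_ml_g.dropna().iloc[0]
    )
    base = groups[(groups.inhibitor == "") & groups.kin_ul_s_g.notna()]
    baseline_kin = float(base.kin_ul_s_g.iloc[0])
    folds = {
        str(r.inhibitor): kinetics.inhibitor_fold(float(r.kin_ul_s_g), baseline_kin)
        for r in groups.itertuples() if r.inhibitor and np.isfinite(r.kin_ul_s_g)
    }
    kin_section = dict(
        groups=groups.replace({np.nan: None}).to_dict("records"),
        v0_ml_g=v0, inhibitor_folds=folds,
    )

    # ANOVA + Dunnett on per-animal single-timepoint K_in: control vs inhibitors
    def _per_animal_kin(sub):
        return ((sub.qstar_ug_per_g - v0 * sub.cstar_ug_per_ml)
                / (sub.cstar_ug_per_ml * sub.time_s) * 1000.0).to_numpy()

    r123 = perf[(perf.tracer == "R123")]
    ctrl = _per_animal_kin(r123[r123.inhibitor.isna() | (r123.inhibitor == "")])
    treat_labels = sorted(set(r123.inhibitor.dropna()) - {""})
    dunnett = None
    if treat_labels:
        treats = [_per_animal_kin(r123[r123.inhibitor == lab]) for lab in treat_labels]
        d = stats.anova_dunnett(ctrl, treats, labels=treat_labels, seed=seed + 1)
        dunnett = dict(
            f_statistic=d.statistic, p_value=d.p_value, critical_value=d.critical_value,
            decisions={c.label: c.significant for c in d.comparisons},
        )

    # efflux screen: reference panel with R123's kin replaced by our estimate
    compounds = efflux.load_reference_compounds()
    compounds.loc[compounds.name == "R123", "kin_ul_s_g"] = baseline_kin
    line, screen_df = efflux.screen(compounds, cfg.efflux_threshold_log10)
    efflux_section = dict(
        line=dict(slope=line.slope, intercept=line.intercept,
                  residual_sd=line.residual_sd, n=line.n),
        compounds=screen_df.to_dict("records"),
    )

    # vessel expression (ground-truth masks; auto-segmentation is a separate QC path)
    section = bio.read_section(run / "section.tif")
    vmask = bio.read_mask(run / "vessel_mask.tif")
    per_vessel = image_quant.vessel_expression(section.channels["pgp"], vmask)
    classes = json.loads((run / "vessel_classes.json").read_text())
    id_to_class = {i: "BBB" for i in classes["bbb_ids"]}
    id_to_class.update({i: "BTB" for i in classes["btb_ids"]})
    per_vessel["vessel_class"] = per_vessel.vessel_id.map(id_to_class)
    per_vessel.to_csv(run / "per_vessel.csv", index=False)
    vsummary = image_quant.summarize_vessel_classes(per_vessel)
    a = per_vessel[per_vessel.vessel_class == "BBB"].mean_intensity
    b = per_vessel[per_vessel.vessel_class == "BTB"].mean_intensity
    vtest = stats.two_sample_t(a, b)
    vessels_section = dict(
        summary=vsummary.to_dict("records"),
        comparison=dict(statistic=vtest.statistic, p_value=vtest.p_value),
    )

    # lesions: same-slice dual modality
    lmask = bio.read_mask(run / "lesion_mask.tif")
    bdt = image_quant.bdt_mask(lmask, margin_px=50)
    r123_folds = image_quant.lesion_fold_change(
        section.channels["r123"], lmask, bdt, section.pixel_size_um
    )
    autorad = bio.read_autoradiograph(run / "autorad.tif")
    shift, peak = image_quant.register_modalities(
        np.where(autorad.lesion_labels > 0,
                 autorad.background_level * 2, autorad.background_level),
        autorad.image,
        max_shift_px=10,
    )
    aligned = np.full_like(autorad.image, autorad.background_level)
    H, W = autorad.image.shape
    dy, dx = shift
    aligned[max(0, -dy):H - max(0, dy), max(0, -dx):W - max(0, dx)] = autorad.image[
        max(0, dy):H - max(0, -dy), max(0, dx):W - max(0, -dx)]
    coarse_bdt = image_quant.bdt_mask(
        autorad.lesion_labels, margin_px=max(1, 50 // autorad.downsample_factor)
    ) & autorad.background_mask
    aib_folds = image_quant.lesion_fold_change(
        aligned, autorad.lesion_labels, coarse_bdt, section.pixel_size_um * autorad.downsample_factor
    )
    aib_by_id = {m.lesion_id: m for m in aib_folds}
    per_lesion = []
    for m in r123_folds:
        row = dict(lesion_id=m.lesion_id, area_mm2=m.area_mm2, fold_r123=m.fold,
                   n_pixels=m.n_pixels)
        if m.lesion_id in aib_by_id:
            row["fold_aib"] = aib_by_id[m.lesion_id].fold
        per_lesion.append(row)
    corrs = {}
    if len(per_lesion) >= 3 and all("fold_aib" in r for r in per_lesion):
        areas = [r["area_mm2"] for r in per_lesion]
        fa = [r["fold_aib"] for r in per_lesion]
        fr = [r["fold_r123"] for r in per_lesion]
        for name, (x, y) in {
            "aib_vs_size": (areas, fa),
            "r123_vs_size": (areas, fr),
            "aib_vs_r123": (fa, fr),
        }.items():
            try:
                r2, slope = image_quant.correlate(x, y)
                corrs[name] = dict(r_squared=r2, slope=slope)
            except ValueError:
                pass
    lesions_section = dict(per_lesion=per_lesion,
                           correlations=corrs,
                           registration=dict(shift_px=list(shift), peak_correlation=peak))

    rep = report.build_report(
        seed=seed,
        config=cfg.to_dict(),
        calibration=calib_section,
        kinetics=kin_section,
        efflux=efflux_section,
        vessels=vessels_section,
        lesions=lesions_section,
        stats=dict(dunnett=dunnett) if dunnett else dict(dunnett=None),
    )
    report.write_report(rep, run)
    return rep


def run_pipeline(cfg: SimConfig, out_dir: str | Path, seed: int) -> dict:
    """simulate + analyze in one call; returns the report dict."""
    simulate_run(cfg, out_dir, seed)
    return analyze_run(out_dir, seed=seed, cfg=cfg)
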