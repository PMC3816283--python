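"""Synthetic-data generator for the whole barrier-permeability pipeline.

Every input the analysis consumes can be generated here with its ground
truth recorded, so all downstream stages are testable without measured
data:

* dye **standards** tables — intensity-per-gram linear in concentration,
  additive Gaussian noise (camera read noise);
* **perfusion series** — tissue uptake obeying Q*/C* = K_in*T + V0 with
  multiplicative (CV-parameterized) Gaussian noise on Q* (inter-animal
  variability);
* multi-channel **section images** (nuclei / endothelial / P-gp / R123) —
  vessels drawn as constant-intensity tubes, lesions as disks whose tracer
  signal is the surrounding tissue level times a per-lesion amplification;
  optical blur and additive noise applied last; true label masks emitted
  alongside;
* a coarse **autoradiograph** of the same slice for a passive tracer, with
  a configurable lesion fold change and an optional known integer shift
  for registration tests.

With zero blur and zero noise every generated image's region statistics
equal the configured ground truth exactly, and the perfusion model is
exactly the model the kinetics module fits. All randomness flows from one
top-level seed through named substreams (see :mod:`btbkin._rng`), so adding
an artifact to a run never perturbs existing ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._rng import substream
from .kinetics import PerfusionRecord

__all__ = [
    "GroundTruth",
    "SectionImage",
    "VesselSpec",
    "LesionSpec",
    "Autoradiograph",
    "generate_standards",
    "generate_perfusion_series",
    "generate_section",
    "generate_autoradiograph",
    "random_vessel_specs",
    "random_lesion_specs",
]

CHANNEL_ORDER = ("nuclei", "endothelial", "pgp", "r123")


@dataclass
class GroundTruth:
    """Generative parameters of one simulated animal / run.

    Units: ``true_kin_ul_s_g`` uL/s/g; ``true_v0_ml_g`` mL/g;
    ``calib_slope`` intensity per (ug/g); ``lesion_folds`` maps lesion id to
    the per-tracer amplification over surrounding tissue;
    ``vessel_intensities`` maps vessel id to mean transporter-channel
    intensity (A.U.).
    """

    true_kin_ul_s_g: float
    true_v0_ml_g: float
    calib_slope: float
    calib_intercept: float
    lesion_folds: dict[int, dict[str, float]] = field(default_factory=dict)
    vessel_intensities: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kin_ul_s_g < 0:
            raise ValueError("true K_in must be >= 0")
        if self.true_v0_ml_g <= 0:
            raise ValueError("true V0 must be > 0")
        for lid, folds in self.lesion_folds.items():
            if any(f <= 0 for f in folds.values()):
                raise ValueError(f"lesion {lid} has a non-positive fold")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        # JSON keys are strings; keep ids recoverable
        d["lesion_folds"] = {str(k): v for k, v in self.lesion_folds.items()}
        d["vessel_intensities"] = {str(k): v for k, v in self.vessel_intensities.items()}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["lesion_folds"] = {int(k): v for k, v in d["lesion_folds"].items()}
        d["vessel_intensities"] = {int(k): float(v) for k, v in d["vessel_intensities"].items()}
        return cls(**d)


@dataclass
class SectionImage:
    """Multi-channel section with physical pixel size and slice thickness."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    thickness_um: float = 20.0
    exposure_tag: str = "exp15ms_gain615"

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        if self.pixel_size_um <= 0 or self.thickness_um <= 0:
            raise ValueError("pixel size and thickness must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class VesselSpec:
    """A vessel drawn as a constant-intensity tube around a line segment."""

    vessel_id: int
    start: tuple[float, float]  # (row, col), pixels
    end: tuple[float, float]
    radius_px: float
    pgp_intensity: float
    endothelial_intensity: float = 100.0


@dataclass(frozen=True)
class LesionSpec:
    """A disk-shaped metastatic lesion with per-tracer signal amplification."""

    lesion_id: int
    center: tuple[float, float]  # (row, col), pixels
    radius_px: float
    folds: Mapping[str, float]  # tracer name -> amplification over background


@dataclass
class Autoradiograph:
    """Coarse activity image of a passive tracer, registered to the section.

    ``lesion_labels`` / ``background_mask`` live on the coarse grid and keep
    only blocks lying entirely inside one lesion / entirely in background,
    so region means are exact at any downsample factor. ``shift_px`` is the
    known integer offset (coarse pixels) applied to the image relative to
    the section geometry.
    """

    image: np.ndarray
    downsample_factor: int
    shift_px: tuple[int, int]
    lesion_labels: np.ndarray
    background_mask: np.ndarray
    background_level: float
    fold_map: dict[int, float]


# ---------------------------------------------------------------------------
# tabular generators

def generate_standards(
    concentrations_ug_per_g: Sequence[float],
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    mass_g: float = 2.08e-3,
) -> pd.DataFrame:
    """Simulate a dye standard table for the calibration module.

    Each row is one imaged homogenate section: intensity per gram is
    ``slope * conc + intercept`` plus additive N(0, noise_sd); the stored
    ``sum_intensity`` is that per-gram value times the analyzed mass.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conc = np.asarray(concentrations_ug_per_g, float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = substream(seed, "standards")
    conc_rep = np.repeat(conc, n_replicates)
    ipg = slope * conc_rep + intercept
    if noise_sd > 0:
        ipg = ipg + rng.normal(0.0, noise_sd, size=ipg.size)
    return pd.DataFrame(
        {
            "conc_ug_per_g": conc_rep,
            "sum_intensity": ipg * mass_g,
            "mass_g": np.full(conc_rep.size, mass_g),
        }
    )


def generate_perfusion_series(
    true_kin_ul_s_g: float,
    v0_ml_g: float,
    cstar_ug_per_ml: float,
    times_s: Sequence[float],
    noise_cv: float = 0.0,
    n_per_time: int = 1,
    seed: int = 0,
    tracer: str = "R123",
    region: str = "normal",
    inhibitor: str | None = None,
    linear_window_s: tuple[float, float] = (30.0, 120.0),
) -> list[PerfusionRecord]:
    """Simulate timed-perfusion records obeying Q*/C* = K_in*T + V0.

    Q* is drawn around C* * (K_in*T + V0) with multiplicative Gaussian
    noise of coefficient of variation ``noise_cv`` (inter-animal
    variability). Times must lie in the linear-uptake window (default
    30-120 s) within which the single-compartment line is valid; pass
    ``linear_window_s=None`` to disable the check.
    """
    if cstar_ug_per_ml <= 0:
        raise ValueError("C* must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    times = np.asarray(times_s, float)
    if linear_window_s is not None:
        lo, hi = linear_window_s
        if np.any((times < lo) | (times > hi)):
            raise ValueError(f"times outside the linear-uptake window {linear_window_s}")
    rng = substream(seed, f"perfusion/{tracer}/{region}/{inhibitor or ''}")
    kin_ml = true_kin_ul_s_g / 1000.0
    records = []
    for t in times:
        mean_q = cstar_ug_per_ml * (kin_ml * t + v0_ml_g)
        for _ in range(n_per_time):
            q = mean_q
            if noise_cv > 0:
                q = mean_q * (1.0 + rng.normal(0.0, noise_cv))
            records.append(
                PerfusionRecord(
                    tracer=tracer,
                    qstar_ug_per_g=float(max(q, 0.0)),
                    cstar_ug_per_ml=float(cstar_ug_per_ml),
                    time_s=float(t),
                    region=region,
                    inhibitor=inhibitor,
                )
            )
    return records


# ---------------------------------------------------------------------------
# image generators

def _paint_tube(mask_shape, start, end, radius):
    """Boolean mask of pixels whose center lies within `radius` of a segment."""
    rr, cc = np.meshgrid(
        np.arange(mask_shape[0], dtype=float),
        np.arange(mask_shape[1], dtype=float),
        indexing="ij",
    )
    p0 = np.asarray(start, float)
    d = np.asarray(end, float) - p0
    len2 = float(d @ d)
    if len2 == 0:
        dist = np.hypot(rr - p0[0], cc - p0[1])
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    return dist <= radius


def _disk(mask_shape, center, radius):
    rr, cc = np.ogrid[: mask_shape[0], : mask_shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_section(
    shape: tuple[int, int],
    pixel_size_um: float,
    vessels: Sequence[VesselSpec] = (),
    lesions: Sequence[LesionSpec] = (),
    blur_sigma: float = 0.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    thickness_um: float = 20.0,
    nuclei_density_per_mm2: float = 800.0,
    pgp_rim_intensity: float | None = None,
    pgp_rim_width_px: float = 3.0,
) -> tuple[SectionImage, dict[str, np.ndarray]]:
    """Render a synthetic multi-channel section plus ground-truth masks.

    Channels: ``nuclei`` (scattered dots), ``endothelial`` (nonzero only on
    vessel tubes), ``pgp`` (each vessel's configured intensity on its tube,
    plus an optional pericellular rim just inside lesion borders), ``r123``
    (``background`` outside lesions, ``background * fold`` inside). Gaussian
    blur then additive noise are applied last, to all channels.

    Returns the image and masks ``{"vessels": label image, "lesions":
    label image}``. Overlapping lesions raise; vessels with radius < 1 px
    are skipped with a warning.
    """
    rng = substream(seed, "section")
    vessel_labels = np.zeros(shape, np.int32)
    lesion_labels = np.zeros(shape, np.int32)

    for les in lesions:
        m = _disk(shape, les.center, les.radius_px)
        if np.any(lesion_labels[m] != 0):
            raise ValueError(f"lesion {les.lesion_id} overlaps an earlier lesion")
        if les.lesion_id <= 0:
            raise ValueError("lesion ids must be positive integers")
        lesion_labels[m] = les.lesion_id

    endothelial = np.zeros(shape, float)
    pgp = np.zeros(shape, float)
    for v in vessels:
        if v.radius_px < 1.0:
            warnings.warn(
                f"vessel {v.vessel_id} radius {v.radius_px} px < 1 px; skipped",
                stacklevel=2,
            )
            continue
        m = _paint_tube(shape, v.start, v.end, v.radius_px)
        vessel_labels[m] = v.vessel_id
        endothelial[m] = v.endothelial_intensity
        pgp[m] = v.pgp_intensity

    # R123: tissue background, amplified inside each lesion by its fold
    r123 = np.full(shape, background, float)
    for les in lesions:
        r123[lesion_labels == les.lesion_id] = background * float(les.folds.get("r123", 1.0))

    # optional pericellular transporter rim just inside the lesion boundary
    if pgp_rim_intensity is not None and len(lesions) > 0:
        inside = lesion_labels > 0
        eroded = ndi.binary_erosion(inside, iterations=max(1, int(round(pgp_rim_width_px))))
        pgp[inside & ~eroded] = np.maximum(pgp[inside & ~eroded], pgp_rim_intensity)

    # nuclei: scattered dots on a dim background (appearance only; no
    # downstream quantity is measured on this channel)
    area_mm2 = shape[0] * shape[1] * (pixel_size_um * 1e-3) ** 2
    n_nuclei = rng.poisson(nuclei_density_per_mm2 * area_mm2)
    nuclei = np.full(shape, 2.0)
    if n_nuclei > 0:
        pos = np.column_stack(
            [rng.uniform(0, shape[0], n_nuclei), rng.uniform(0, shape[1], n_nuclei)]
        )
        for r, c in pos:
            nuclei[_disk(shape, (r, c), 2.0)] = 60.0

    channels = {"nuclei": nuclei, "endothelial": endothelial, "pgp": pgp, "r123": r123}
    if blur_sigma > 0:
        channels = {k: ndi.gaussian_filter(v, blur_sigma) for k, v in channels.items()}
    if noise_sd > 0:
        noise_rng = substream(seed, "section/noise")
        channels = {
            k: v + noise_rng.normal(0.0, noise_sd, size=shape) for k, v in channels.items()
        }

    img = SectionImage(channels=channels, pixel_size_um=pixel_size_um, thickness_um=thickness_um)
    return img, {"vessels": vessel_labels, "lesions": lesion_labels}


def generate_autoradiograph(
    lesion_labels: np.ndarray,
    fold_map: Mapping[int, float],
    downsample_factor: int = 4,
    background: float = 50.0,
    shift_px: tuple[int, int] = (0, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Autoradiograph:
    """Render a coarse passive-tracer activity image of the same slice.

    A full-resolution activity map (``background`` outside lesions,
    ``background * fold`` inside lesion k) is block-averaged by the integer
    ``downsample_factor``. Coarse ground-truth masks keep only blocks that
    lie entirely inside one lesion or entirely in background, so the
    lesion-mean / background-mean ratio equals the configured fold exactly
    before noise. The image (not the masks) is then offset by ``shift_px``
    coarse pixels, background-filled, for registration exercises; noise is
    added last.
    """
    f = int(downsample_factor)
    if f < 1:
        raise ValueError("downsample_factor must be an integer >= 1")
    for k, fold in fold_map.items():
        if fold <= 0:
            raise ValueError(f"fold for lesion {k} must be > 0")
    labels = np.asarray(lesion_labels)
    activity = np.full(labels.shape, background, float)
    for k, fold in fold_map.items():
        activity[labels == k] = background * float(fold)

    H = labels.shape[0] - labels.shape[0] % f
    W = labels.shape[1] - labels.shape[1] % f
    if H == 0 or W == 0:
        raise ValueError("image smaller than one coarse block")
    blocks = activity[:H, :W].reshape(H // f, f, W // f, f)
    coarse = blocks.mean(axis=(1, 3))

    lab_blocks = labels[:H, :W].reshape(H // f, f, W // f, f)
    bmin = lab_blocks.min(axis=(1, 3))
    bmax = lab_blocks.max(axis=(1, 3))
    coarse_labels = np.where(bmin == bmax, bmax, 0).astype(np.int32)
    background_mask = bmax == 0  # blocks entirely outside every lesion

    dy, dx = (int(shift_px[0]), int(shift_px[1]))
    shifted = np.full_like(coarse, background)
    src = coarse[
        max(0, -dy) : coarse.shape[0] - max(0, dy),
        max(0, -dx) : coarse.shape[1] - max(0, dx),
    ]
    shifted[
        max(0, dy) : max(0, dy) + src.shape[0],
        max(0, dx) : max(0, dx) + src.shape[1],
    ] = src

    if noise_sd > 0:
        rng = substream(seed, "autoradiograph")
        shifted = shifted + rng.normal(0.0, noise_sd, size=shifted.shape)

    return Autoradiograph(
        image=shifted,
        downsample_factor=f,
        shift_px=(dy, dx),
        lesion_labels=coarse_labels,
        background_mask=background_mask,
        background_level=float(background),
        fold_map={int(k): float(v) for k, v in fold_map.items()},
    )


# ---------------------------------------------------------------------------
# randomized geometry helpers

def random_vessel_specs(
    shape: tuple[int, int],
    n_vessels: int,
    seed: int = 0,
    radius_px: tuple[float, float] = (2.0, 4.0),
    length_px: tuple[float, float] = (20.0, 60.0),
    intensity_mean: float = 22.6,
    intensity_sd: float = 10.5,
    endothelial_intensity: float = 100.0,
    exclude: np.ndarray | None = None,
    min_gap_px: float = 3.0,
    start_id: int = 1,
    max_tries: int = 2000,
    stream: str = "vessels",
) -> list[VesselSpec]:
    """Place straight, mutually disjoint vessel tubes at random.

    Per-vessel transporter intensity is N(intensity_mean, intensity_sd)
    clipped below at 0.5 A.U. (an intensity cannot be negative). Candidate
    tubes are rejection-sampled so that, dilated by ``min_gap_px``, they
    touch neither an earlier vessel nor the ``exclude`` mask. Raises if
    placement fails after ``max_tries`` attempts.
    """
    rng = substream(seed, stream)
    occupied = np.zeros(shape, bool) if exclude is None else exclude.astype(bool).copy()
    specs: list[VesselSpec] = []
    tries = 0
    while len(specs) < n_vessels:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {len(specs)}/{n_vessels} vessels after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*radius_px)
        length = rng.uniform(*length_px)
        theta = rng.uniform(0, np.pi)
        margin = r + min_gap_px + 1
        c0 = np.array(
            [rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin)]
        )
        d = np.array([np.sin(theta), np.cos(theta)]) * length / 2
        start, end = c0 - d, c0 + d
        if np.any(np.minimum(start, end) < margin) or np.any(
            np.maximum(start, end) > np.array(shape) - margin
        ):
            continue
        padded = _paint_tube(shape, start, end, r + min_gap_px)
        if np.any(occupied & padded):
            continue
        occupied |= padded
        intensity = float(max(rng.normal(intensity_mean, intensity_sd), 0.5))
        specs.append(
            VesselSpec(
                vessel_id=start_id + len(specs),
                start=tuple(start),
                end=tuple(end),
                radius_px=float(r),
                pgp_intensity=intensity,
                endothelial_intensity=endothelial_intensity,
            )
        )
    return specs


def random_lesion_specs(
    shape: tuple[int, int],
    n_lesions: int,
    seed: int = 0,
    radius_px: tuple[float, float] = (15.0, 35.0),
    fold_aib: float = 4.9,
    fold_aib_sigma_log: float = 0.35,
    fold_r123: float = 0.98,
    fold_r123_sigma_log: float = 0.08,
    min_gap_px: float = 12.0,
    max_tries: int = 2000,
    stream: str = "lesions",
) -> list[LesionSpec]:
    """Place disjoint disk lesions with per-lesion, per-tracer fold changes.

    Per-lesion folds are lognormal around the configured medians: the
    passive tracer's amplification varies widely between metastases while
    the efflux substrate stays near unity.
    """
    rng = substream(seed, stream)
    specs: list[LesionSpec] = []
    tries = 0
    while len(specs) < n_lesions:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {len(specs)}/{n_lesions} lesions after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*radius_px)
        margin = r + min_gap_px
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        ok = all(
            np.hypot(center[0] - s.center[0], center[1] - s.center[1])
            > r + s.radius_px + min_gap_px
            for s in specs
        )
        if not ok:
            continue
        folds = {
            "aib": float(fold_aib * np.exp(rng.normal(0.0, fold_aib_sigma_log))),
            "r123": float(fold_r123 * np.exp(rng.normal(0.0, fold_r123_sigma_log))),
        }
        specs.append(
            LesionSpec(
                lesion_id=len(specs) + 1,
                center=center,
                radius_px=float(r),
                folds=folds,
            )
        )
    return specs
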