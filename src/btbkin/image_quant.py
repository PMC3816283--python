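"""Per-vessel and per-lesion image quantification.

Operations for co-registered same-slice imagery:

* segment endothelial-marker channels into labeled vessel regions and
  measure a target channel (e.g. transporter staining) per vessel;
* register a coarse second modality (autoradiograph) to the fluorescence
  grid by exhaustive integer-shift normalized cross-correlation;
* measure per-lesion area (mm^2) and per-tracer fold change relative to
  "brain distant to tumor" (BDT) background tissue;
* correlate fold changes with lesion size or with each other (r^2, slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "VesselMask",
    "LesionMeasurement",
    "segment_vessels",
    "vessel_expression",
    "summarize_vessel_classes",
    "register_modalities",
    "bdt_mask",
    "lesion_fold_change",
    "correlate",
    "upsample_to_section",
]

logger = logging.getLogger(__name__)


@dataclass
class VesselMask:
    """Labeled vessel regions (0 = background, k = vessel k)."""

    labels: np.ndarray
    pixel_counts: dict[int, int]
    source_channel: str
    threshold: float
    n_rejected_small: int = 0

    @property
    def n_vessels(self) -> int:
        return len(self.pixel_counts)


@dataclass(frozen=True)
class LesionMeasurement:
    """Area and tracer fold change (lesion mean / BDT mean) of one lesion."""

    lesion_id: int
    area_mm2: float
    fold: float
    n_pixels: int


def segment_vessels(
    channel: np.ndarray,
    min_size_px: int = 10,
    threshold: float | str = "otsu",
    source_channel: str = "endothelial",
) -> VesselMask:
    """Threshold + 8-connected component labeling of an endothelial channel.

    ``threshold='otsu'`` (default) picks the threshold automatically; pass a
    float for a manual override. Components smaller than ``min_size_px`` are
    dropped and counted. An all-zero channel yields an empty mask, not an
    error.
    """
    chan = np.asarray(channel, float)
    if chan.ndim != 2:
        raise ValueError("endothelial channel must be 2-D")
    if not np.any(chan > 0):
        return VesselMask(np.zeros(chan.shape, np.int32), {}, source_channel, 0.0)
    thr = float(threshold_otsu(chan)) if threshold == "otsu" else float(threshold)
    binary = chan > thr
    labels = cc_label(binary, connectivity=2)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    small = ids[counts < min_size_px]
    if small.size:
        logger.info("segment_vessels: dropped %d components < %d px", small.size, min_size_px)
        labels[np.isin(labels, small)] = 0
    # relabel to a dense 1..n range
    labels = cc_label(labels > 0, connectivity=2).astype(np.int32)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return VesselMask(
        labels=labels,
        pixel_counts={int(i): int(c) for i, c in zip(ids, counts)},
        source_channel=source_channel,
        threshold=thr,
        n_rejected_small=int(small.size),
    )


def vessel_expression(channel: np.ndarray, mask: VesselMask | np.ndarray) -> pd.DataFrame:
    """Mean target-channel intensity over each labeled vessel region.

    Returns a table (vessel_id, mean_intensity, n_pixels); relabeling the
    mask permutes rows but not values.
    """
    labels = mask.labels if isinstance(mask, VesselMask) else np.asarray(mask)
    chan = np.asarray(channel, float)
    if chan.shape != labels.shape:
        raise ValueError(f"channel shape {chan.shape} != mask shape {labels.shape}")
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return pd.DataFrame(columns=["vessel_id", "mean_intensity", "n_pixels"])
    means = ndi.mean(chan, labels=labels, index=ids)
    counts = ndi.sum_labels(np.ones_like(chan), labels=labels, index=ids)
    return pd.DataFrame(
        {
            "vessel_id": ids.astype(int),
            "mean_intensity": np.asarray(means, float),
            "n_pixels": np.asarray(counts, int),
        }
    )


def summarize_vessel_classes(per_vessel: pd.DataFrame, class_col: str = "vessel_class") -> pd.DataFrame:
    """Mean +/- SEM of per-vessel intensity by vessel class (e.g. BBB vs BTB)."""
    if class_col not in per_vessel.columns:
        raise ValueError(f"missing class column {class_col!r}")
    g = per_vessel.groupby(class_col)["mean_intensity"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out.columns = [class_col, "mean_au", "sem_au", "n_vessels"]
    out["sem_au"] = out["sem_au"].fillna(0.0)
    return out


def register_modalities(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift_px: int = 10,
    min_overlap_frac: float = 0.5,
    low_corr_warn: float = 0.2,
) -> tuple[tuple[int, int], float]:
    """Integer-shift registration by exhaustive normalized cross-correlation.

    Finds the (dy, dx) within +/- ``max_shift_px`` maximizing the Pearson
    correlation between the overlapping parts of ``reference`` and
    ``moving``, under the convention ``moving[i, j] ~ reference[i-dy, j-dx]``
    (i.e. the moving image content sits (dy, dx) further down/right).
    Returns the shift and the peak correlation. Same-slice modalities share
    orientation, so only translation is searched. Raises on zero-variance
    images; warns via the log when the peak correlation is below
    ``low_corr_warn`` (likely meaningless alignment).
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ValueError(f"shapes differ: {ref.shape} vs {mov.shape}")
    if np.var(ref) == 0 or np.var(mov) == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    H, W = ref.shape
    best = (-2.0, (0, 0))
    for dy in range(-max_shift_px, max_shift_px + 1):
        for dx in range(-max_shift_px, max_shift_px + 1):
            r0, r1 = max(0, -dy), min(H, H - dy)
            c0, c1 = max(0, -dx), min(W, W - dx)
            if (r1 - r0) * (c1 - c0) < min_overlap_frac * H * W:
                continue
            a = ref[r0:r1, c0:c1].ravel()
            b = mov[r0 + dy : r1 + dy, c0 + dx : c1 + dx].ravel()
            if np.var(a) == 0 or np.var(b) == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r > best[0]:
                best = (r, (dy, dx))
    peak, shift = best
    if peak < low_corr_warn:
        logger.warning(
            "registration peak correlation %.3f < %.2f; alignment unreliable", peak, low_corr_warn
        )
    return shift, peak


def bdt_mask(
    lesion_labels: np.ndarray,
    margin_px: int = 50,
    tissue_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Brain-distant-to-tumor mask: tissue >= ``margin_px`` from any lesion.

    The fold-change denominator region. ``tissue_mask`` restricts to tissue
    (default: the whole frame).
    """
    lesions = np.asarray(lesion_labels) > 0
    if margin_px < 0:
        raise ValueError("margin must be >= 0")
    if not np.any(lesions):
        far = np.ones(lesions.shape, bool)
    else:
        dist = ndi.distance_transform_edt(~lesions)
        far = dist >= margin_px
    if tissue_mask is not None:
        far &= np.asarray(tissue_mask, bool)
    return far


def lesion_fold_change(
    signal: np.ndarray,
    lesion_labels: np.ndarray,
    bdt: np.ndarray,
    pixel_size_um: float,
) -> list[LesionMeasurement]:
    """Per-lesion area (mm^2) and fold change vs BDT background.

    fold = mean(signal inside lesion) / mean(signal over the BDT region);
    area = pixel count x pixel_size^2 (um^2 -> mm^2). Lesion and BDT masks
    must be disjoint and the BDT mean positive.
    """
    sig = np.asarray(signal, float)
    labels = np.asarray(lesion_labels)
    bdt = np.asarray(bdt, bool)
    if sig.shape != labels.shape or sig.shape != bdt.shape:
        raise ValueError("signal, lesion labels and BDT mask must share one shape")
    if np.any(bdt & (labels > 0)):
        raise ValueError("BDT mask overlaps lesion mask")
    if not np.any(bdt):
        raise ValueError("BDT mask is empty")
    denom = float(sig[bdt].mean())
    if denom <= 0:
        raise ValueError(f"BDT mean must be > 0, got {denom}")
    px_area_mm2 = (pixel_size_um * 1e-3) ** 2
    out = []
    for lid in np.unique(labels[labels > 0]):
        m = labels == lid
        n = int(m.sum())
        out.append(
            LesionMeasurement(
                lesion_id=int(lid),
                area_mm2=float(n * px_area_mm2),
                fold=float(sig[m].mean() / denom),
                n_pixels=n,
            )
        )
    return out


def correlate(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and OLS slope of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = sps.linregress(x, y)
    return float(fit.rvalue) ** 2, float(fit.slope)


def upsample_to_section(coarse: np.ndarray, factor: int) -> np.ndarray:
    """Nearest (block-replicate) upsampling of a coarse image to the section grid."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.repeat(np.asarray(coarse), factor, axis=0), factor, axis=1)
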