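"""File formats: multi-channel TIFF + JSON sidecars, CSV tables.

Images travel as single-file multi-channel TIFF (channel axis first) with a
JSON sidecar holding physical metadata (pixel size, slice thickness,
channel order, known shift). Label masks are 16-bit TIFF. Tables are CSV
with units encoded in the column names (e.g. ``qstar_ug_per_g``).
Writers avoid embedding timestamps so identical runs produce identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CHANNEL_ORDER, Autoradiograph, SectionImage

__all__ = [
    "write_section",
    "read_section",
    "write_mask",
    "read_mask",
    "write_autoradiograph",
    "read_autoradiograph",
    "read_standards",
    "read_perfusion",
    "read_compounds",
]


def write_section(section: SectionImage, tif_path: str | Path, shift_px=(0, 0)) -> None:
    """Write channels as one float32 TIFF stack plus a ``.json`` sidecar."""
    tif_path = Path(tif_path)
    order = [c for c in CHANNEL_ORDER if c in section.channels] + [
        c for c in section.channels if c not in CHANNEL_ORDER
    ]
    stack = np.stack([section.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": section.pixel_size_um,
        "thickness_um": section.thickness_um,
        "channel_order": order,
        "shift_px": list(shift_px),
        "exposure_tag": section.exposure_tag,
    }
    tif_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_section(tif_path: str | Path) -> SectionImage:
    tif_path = Path(tif_path)
    stack = tifffile.imread(tif_path)
    meta = json.loads(tif_path.with_suffix(".json").read_text())
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channel_order"])}
    return SectionImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        thickness_um=float(meta.get("thickness_um", 20.0)),
        exposure_tag=str(meta.get("exposure_tag", "")),
    )


def write_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as 16-bit TIFF (raises if > 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more labels than a 16-bit mask can hold")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_autoradiograph(autorad: Autoradiograph, tif_path: str | Path) -> None:
    """Activity image as float32 TIFF; sidecar carries the section-grid mapping."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, autorad.image.astype(np.float32))
    write_mask(autorad.lesion_labels, tif_path.with_name(tif_path.stem + "_labels.tif"))
    write_mask(autorad.background_mask.astype(np.uint16),
               tif_path.with_name(tif_path.stem + "_bg.tif"))
    sidecar = {
        "downsample_factor": autorad.downsample_factor,
        "shift_px": list(autorad.shift_px),
        "background_level": autorad.background_level,
        "fold_map": {str(k): v for k, v in autorad.fold_map.items()},
    }
    tif_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_autoradiograph(tif_path: str | Path) -> Autoradiograph:
    tif_path = Path(tif_path)
    img = tifffile.imread(tif_path).astype(float)
    meta = json.loads(tif_path.with_suffix(".json").read_text())
    labels = read_mask(tif_path.with_name(tif_path.stem + "_labels.tif"))
    bg = read_mask(tif_path.with_name(tif_path.stem + "_bg.tif")).astype(bool)
    return Autoradiograph(
        image=img,
        downsample_factor=int(meta["downsample_factor"]),
        shift_px=tuple(meta["shift_px"]),
        lesion_labels=labels,
        background_mask=bg,
        background_level=float(meta["background_level"]),
        fold_map={int(k): float(v) for k, v in meta["fold_map"].items()},
    )


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_standards(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"conc_ug_per_g", "sum_intensity", "mass_g"})


def read_perfusion(path: str | Path) -> pd.DataFrame:
    return _read_csv(
        path, {"tracer", "region", "inhibitor", "qstar_ug_per_g", "cstar_ug_per_ml", "time_s"}
    )


def read_compounds(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"name", "logd", "kin_ul_s_g", "known_class"})
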