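"""Readers/writers and image QC for multi-channel 16-bit site TIFFs.

Site identity and channel roles travel in the TIFF image-description tag as
plain ``key=value`` lines, so a plate directory is self-describing.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import (
    MAX_GREY,
    BitDepthError,
    ChannelMap,
    ChannelMismatchError,
    SiteIds,
    SiteImage,
)
from .segmentation import otsu_threshold

__all__ = [
    "read_site_image",
    "write_site_image",
    "qc_flag_image",
    "write_site_index",
]


def _metadata_text(image: SiteImage) -> str:
    pairs = {
        "culture": image.ids.culture,
        "group": image.ids.group,
        "well": image.ids.well,
        "site": image.ids.site,
        "qc_flags": ",".join(sorted(image.qc_flags)),
    }
    pairs.update({f"channel_{k}": v for k, v in image.channel_map.to_dict().items()})
    return "\n".join(f"{k}={v}" for k, v in pairs.items())


def _parse_metadata(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in (text or "").splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out


def write_site_image(image: SiteImage, path: str | Path) -> Path:
    """Lossless 16-bit multi-page TIFF; ids and channel roles in the
    description tag."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.pixels,
        photometric="minisblack",
        description=_metadata_text(image),
        metadata=None,
    )
    return path


def read_site_image(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    ids: SiteIds | None = None,
    allow_other_dtypes: bool = False,
) -> SiteImage:
    """Read a site TIFF without rescaling pixel values.

    ``channel_map``/``ids`` override anything stored in the file; when left
    ``None`` they are recovered from the description tag.  Raises
    ``BitDepthError`` for non-16-bit data unless ``allow_other_dtypes`` is
    set (in which case values are clipped into the 16-bit range).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = _parse_metadata(tf.pages[0].description)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret TIFF of shape {arr.shape} as (C, H, W)")
    if arr.dtype != np.uint16:
        if not allow_other_dtypes:
            raise BitDepthError(
                f"{path.name}: dtype {arr.dtype}, expected 16-bit unsigned"
            )
        arr = np.clip(np.rint(np.asarray(arr, dtype=np.float64)), 0, MAX_GREY)
        arr = arr.astype(np.uint16)

    if channel_map is None:
        keys = {k.removeprefix("channel_"): v or None
                for k, v in meta.items() if k.startswith("channel_")}
        if "nuclei" not in keys:
            raise ValueError(f"{path.name}: no channel map stored and none given")
        channel_map = ChannelMap.from_dict(keys)
    if arr.shape[0] < channel_map.n_channels:
        raise ChannelMismatchError(
            f"{path.name}: {arr.shape[0]} channels, map needs "
            f"{channel_map.n_channels}"
        )
    if ids is None:
        ids = SiteIds(
            culture=meta.get("culture", ""),
            group=meta.get("group", ""),
            well=int(meta.get("well", 0) or 0),
            site=int(meta.get("site", 0) or 0),
        )
    flags = frozenset(f for f in meta.get("qc_flags", "").split(",") if f)
    return SiteImage(arr, channel_map, ids, flags)


def qc_flag_image(
    image: SiteImage,
    saturation_fraction_max: float = 0.01,
    foreground_fraction_max: float = 0.8,
) -> SiteImage:
    """Automated surrogate for manual removal of anomalous sites.

    Flags "saturated" when the fraction of pixels at the 16-bit ceiling in
    any channel exceeds ``saturation_fraction_max``, and "debris" when the
    Otsu-foreground fraction of any channel exceeds
    ``foreground_fraction_max`` (large bright blobs dominate the field).
    Pixel data are never modified; re-flagging is idempotent.
    """
    for name, v in (("saturation_fraction_max", saturation_fraction_max),
                    ("foreground_fraction_max", foreground_fraction_max)):
        if not (0 < v <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    flags: set[str] = set()
    n_mapped = image.channel_map.n_channels
    for ch in image.pixels[:n_mapped]:
        if (ch == MAX_GREY).mean() > saturation_fraction_max:
            flags.add("saturated")
        lo, hi = int(ch.min()), int(ch.max())
        if lo == hi:
            continue  # constant channel: no foreground
        hist = np.bincount(ch.ravel(), minlength=MAX_GREY + 1)
        thr = otsu_threshold(hist)
        if (ch >= thr).mean() > foreground_fraction_max:
            flags.add("debris")
    return image.with_flags(flags)


def write_site_index(images: list[SiteImage], paths: list[Path],
                     out_path: str | Path) -> Path:
    """CSV index of a plate directory (one row per site file)."""
    rows = [
        {
            "path": str(p),
            "culture": im.ids.culture,
            "group": im.ids.group,
            "well": im.ids.well,
            "site": im.ids.site,
            "qc_flags": ";".join(sorted(im.qc_flags)),
        }
        for im, p in zip(images, paths)
    ]
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path
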