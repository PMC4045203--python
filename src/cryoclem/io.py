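"""Image and point-table I/O with a fixed coordinate convention.

All positions are continuous ``(x, y)`` coordinates in pixel units with the
centre of the pixel at row ``r``, column ``c`` located at ``(x=c, y=r)``
(0-based).  Conversion to physical units is a multiplication by the pixel
size in nanometres; every inter-module interface carries nanometres so that
fluorescence (≈100 nm/px) and electron-microscope (≈2–4 nm/px) frames
compose without implicit unit errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

CHANNEL_LABELS = ("red", "green", "blue", "em")
FRAME_LABELS = ("fm", "em")

#: minimum image side length: anything smaller cannot host a fit window
MIN_IMAGE_SIDE = 16

POINT_COLUMNS = ["id", "frame", "channel", "x_nm", "y_nm"]


@dataclass
class ChannelImage:
    """A single 2D intensity frame of one acquisition channel.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative intensity grid (row = y, column = x).
    channel_label : str
        One of ``red``, ``green``, ``blue``, ``em``.
    pixel_size_nm : float
        Physical length of one pixel in nanometres.
    """

    pixels: np.ndarray
    channel_label: str
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, "
                f"got {self.pixels.shape}"
            )
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(f"channel_label must be one of {CHANNEL_LABELS}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def px_to_nm(self, xy_px) -> np.ndarray:
        """Convert continuous pixel coordinates to nanometres."""
        return np.asarray(xy_px, dtype=float) * self.pixel_size_nm

    def nm_to_px(self, xy_nm) -> np.ndarray:
        """Convert nanometre coordinates to continuous pixel coordinates."""
        return np.asarray(xy_nm, dtype=float) / self.pixel_size_nm


@dataclass
class PointRecord:
    """A position in nanometres in a named coordinate frame (``fm`` or ``em``)."""

    id: str
    frame: str
    channel: str
    x_nm: float
    y_nm: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame not in FRAME_LABELS:
            raise ValueError(f"frame must be one of {FRAME_LABELS}, got {self.frame!r}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm], dtype=float)


def read_channel_image(path, channel_label: str, pixel_size_nm: float | None = None) -> ChannelImage:
    """Read a single-frame grayscale TIFF or a 2D MRC map.

    ``pixel_size_nm`` given by the caller overrides pixel-size metadata found
    in the file (a warning is logged on conflict); if the caller gives none,
    the file metadata is used; if neither exists, an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".ccp4"):
        data, meta_nm = _read_mrc(path)
    else:
        data, meta_nm = _read_tiff(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single 2D frame, got shape {data.shape}; "
            "extract one frame before loading"
        )
    if pixel_size_nm is None:
        if meta_nm is None:
            raise ValueError(f"{path.name}: no pixel-size metadata; pass pixel_size_nm")
        pixel_size_nm = meta_nm
    elif meta_nm is not None and not np.isclose(meta_nm, pixel_size_nm, rtol=1e-3):
        logger.warning(
            "%s: pixel size %.4g nm overrides file metadata %.4g nm",
            path.name, pixel_size_nm, meta_nm,
        )
    return ChannelImage(pixels=data, channel_label=channel_label, pixel_size_nm=pixel_size_nm)


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) > 1:
            raise ValueError(f"{path.name}: multi-frame stack without a frame selector")
        page = tif.pages[0]
        data = page.asarray()
        meta_nm = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0:
                # pixels per unit -> nm per pixel
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit.value))
                if unit_nm is not None:
                    meta_nm = unit_nm * den / num
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise ValueError(f"{path.name}: RGB TIFF; supply one grayscale frame per channel")
    return np.asarray(data, dtype=float), meta_nm


def _read_mrc(path: Path):
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid, copy=True)
    # gemmi grids are (nx, ny, nz); a 2D projection has nz == 1
    if arr.ndim == 3:
        if arr.shape[2] != 1:
            raise ValueError(f"{path.name}: MRC volume with nz={arr.shape[2]}; only 2D supported")
        arr = arr[:, :, 0]
    data = arr.T  # (row=y, col=x)
    spacing = ccp4.grid.spacing  # Angstrom
    meta_nm = None
    if spacing[0] > 0:
        meta_nm = spacing[0] * 0.1
    return np.asarray(data, dtype=float), meta_nm


def write_image(path, image: ChannelImage) -> None:
    """Write a ChannelImage to TIFF with resolution metadata (nm per pixel)."""
    px_per_cm = 1e7 / image.pixel_size_nm
    tifffile.imwrite(
        Path(path),
        image.pixels.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_points(path, points: list[PointRecord]) -> None:
    """Write point records to CSV (columns id, frame, channel, x_nm, y_nm + extras)."""
    rows = []
    for p in points:
        row = {"id": p.id, "frame": p.frame, "channel": p.channel,
               "x_nm": p.x_nm, "y_nm": p.y_nm}
        row.update(p.extra)
        rows.append(row)
    df = pd.DataFrame(rows, columns=POINT_COLUMNS if not rows else None)
    if rows:
        ordered = POINT_COLUMNS + [c for c in df.columns if c not in POINT_COLUMNS]
        df = df[ordered]
    df.to_csv(Path(path), index=False, float_format="%.9f")


def read_points(path) -> list[PointRecord]:
    """Read point records from CSV; extra columns are preserved verbatim."""
    df = pd.read_csv(Path(path))
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    points = []
    extras = [c for c in df.columns if c not in POINT_COLUMNS]
    for _, row in df.iterrows():
        frame = str(row["frame"])
        if frame not in FRAME_LABELS:
            raise ValueError(f"{path}: frame label {frame!r} not in {FRAME_LABELS}")
        points.append(PointRecord(
            id=str(row["id"]), frame=frame, channel=str(row["channel"]),
            x_nm=float(row["x_nm"]), y_nm=float(row["y_nm"]),
            extra={c: row[c] for c in extras},
        ))
    return points
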