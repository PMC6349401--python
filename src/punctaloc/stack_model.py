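"""Core data types and image/trace I/O.

Conventions used throughout the package:

* all pixel coordinates are 0-based and ordered ``(z, y, x)``;
* physical calibration (µm/pixel, µm/layer) is carried as metadata, but the
  algorithm itself operates in pixel units;
* the "green" channel is the segmentation channel by default (the cell mask is
  computed from it), the "red" channel is the second fluorophore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

COORD_HEADER = "# coordinates are 0-based (z, y, x)"

MIN_YX = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TwoChannelStack:
    """A two-channel 3D fluorescence z-stack with calibration metadata.

    Parameters
    ----------
    green, red
        Intensity arrays of identical shape ``(z, y, x)`` with nonnegative
        values.  ``green`` is the segmentation channel by default.
    pixel_size_xy
        Lateral pixel size in µm/pixel (> 0).
    z_step
        Axial layer spacing in µm (> 0).
    source_id
        Free-text provenance label.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size_xy: float
    z_step: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise ValueError("channels must be 3D (z, y, x) arrays")
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shape mismatch: green {self.green.shape} "
                f"vs red {self.red.shape}"
            )
        nz, ny, nx = self.green.shape
        if nz < 1 or ny < MIN_YX or nx < MIN_YX:
            raise ValueError(
                f"stack shape {self.green.shape} too small; need z >= 1 and "
                f"y, x >= {MIN_YX}"
            )
        if self.green.min() < 0 or self.red.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be > 0")
        if not self.z_step > 0:
            raise ValueError("z_step must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape

    def channel(self, name: str) -> np.ndarray:
        if name == "green":
            return self.green
        if name == "red":
            return self.red
        raise KeyError(f"unknown channel {name!r}; expected 'green' or 'red'")


@dataclass
class CellMask:
    """Per-layer boolean footprint of the single selected cell."""

    layers: np.ndarray  # (z, y, x) bool

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=bool)
        if self.layers.ndim != 3:
            raise ValueError("CellMask layers must be a 3D (z, y, x) array")

    @property
    def projected(self) -> np.ndarray:
        """Union over z of the per-layer masks (2D bool)."""
        return self.layers.any(axis=0)

    @property
    def projected_area(self) -> int:
        return int(self.projected.sum())

    @property
    def n_voxels(self) -> int:
        return int(self.layers.sum())


@dataclass
class ForegroundImage:
    """Background-subtracted, edge-attenuated intensity ("fluorescent foreground").

    Values are >= 0 everywhere and exactly 0 outside the cell mask.
    """

    values: np.ndarray  # (z, y, x) float
    mask: CellMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.layers.shape:
            raise ValueError("foreground shape must match its mask")
        if self.values.min() < -1e-12:
            raise ValueError("foreground values must be nonnegative")
        if np.any(self.values[~self.mask.layers] != 0):
            raise ValueError("foreground must be exactly 0 outside the mask")


@dataclass
class Punctum2D:
    """One punctum's body in a single z-layer: a watershed basin.

    ``pixels`` is an ``(n, 2)`` integer array of (y, x) coordinates, sorted
    lexicographically so that equality and export order are deterministic.
    """

    layer: int
    pixels: np.ndarray  # (n, 2) int, (y, x)
    intensity: float
    seed: tuple[float, float, float]  # (y, x, scale) of the LoG detection

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if pix.shape[0] == 0:
            raise ValueError("Punctum2D must contain at least one pixel")
        order = np.lexsort((pix[:, 1], pix[:, 0]))
        self.pixels = pix[order]
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class Punctum3D:
    """A 3D punctum: 2D basins chained through adjacent-layer overlap."""

    id: int
    channel: str
    slices: list[Punctum2D]

    @property
    def volume(self) -> int:
        return sum(s.area for s in self.slices)

    @property
    def intensity(self) -> float:
        return float(sum(s.intensity for s in self.slices))

    @property
    def layer_range(self) -> tuple[int, int]:
        zs = [s.layer for s in self.slices]
        return min(zs), max(zs)

    def voxels(self) -> np.ndarray:
        """All (z, y, x) voxel coordinates as an (n, 3) int array."""
        parts = [
            np.column_stack(
                [np.full(s.area, s.layer, dtype=int), s.pixels]
            )
            for s in self.slices
        ]
        return np.concatenate(parts, axis=0)

    def centroid(self) -> tuple[float, float, float]:
        vox = self.voxels()
        return tuple(vox.mean(axis=0))  # type: ignore[return-value]


@dataclass
class FrapTrace:
    """Raw FRAP ROI time series (bleach, reference, background means)."""

    times: np.ndarray
    bleach_roi: np.ndarray
    reference_roi: np.ndarray
    background_roi: np.ndarray
    n_prebleach: int
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        self.background_roi = np.asarray(self.background_roi, dtype=float)
        n = len(self.times)
        for name in ("bleach_roi", "reference_roi", "background_roi"):
            if len(getattr(self, name)) != n:
                raise ValueError("all FRAP series must have equal length")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if n < self.n_prebleach + 2:
            raise ValueError("trace too short: need n_prebleach + 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
) -> TwoChannelStack:
    """Read a two-channel z-stack from a multi-page (OME-)TIFF.

    The series axes are taken from the TIFF metadata; any combination of
    ``Z``, ``C``, ``Y``, ``X`` is accepted and reordered to (c, z, y, x).
    Pixel sizes are taken from metadata when present; the ``pixel_size_xy``
    and ``z_step`` arguments are fallbacks and it is an error if neither
    source provides them.

    Parameters
    ----------
    channel_map
        Maps ``"green"`` and ``"red"`` to distinct channel indices.
        Defaults to ``{"green": 0, "red": 1}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel_map is None:
        channel_map = {"green": 0, "red": 1}
    gi, ri = int(channel_map["green"]), int(channel_map["red"])
    if gi == ri:
        raise ValueError("green and red must map to distinct channel indices")

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZCYX"
        meta_px, meta_dz = _calibration_from_tiff(tif)

    data, n_channels = _to_czyx(data, axes)
    if max(gi, ri) >= n_channels:
        raise ValueError(
            f"channel_map requires channel index {max(gi, ri)} but the file "
            f"has only {n_channels} channel(s)"
        )

    px = meta_px if meta_px is not None else pixel_size_xy
    dz = meta_dz if meta_dz is not None else z_step
    if px is None or dz is None:
        raise ValueError(
            "missing calibration: the file carries no pixel-size metadata and "
            "no fallback pixel_size_xy / z_step was supplied"
        )
    return TwoChannelStack(
        green=data[gi], red=data[ri], pixel_size_xy=float(px),
        z_step=float(dz), source_id=str(path),
    )


def _to_czyx(data: np.ndarray, axes: str) -> tuple[np.ndarray, int]:
    """Reorder a TIFF series array to (c, z, y, x), inserting missing axes."""
    axes = axes.upper()
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"unsupported TIFF axes {axes!r}")
    for ax in list(axes):
        if ax not in "CZYXQ":
            if data.shape[axes.index(ax)] == 1:
                data = np.squeeze(data, axis=axes.index(ax))
                axes = axes.replace(ax, "", 1)
            else:
                raise ValueError(f"unsupported TIFF axis {ax!r} in {axes!r}")
    # files without axis metadata come back with unknown ('Q') axes; read
    # them under this package's own ZCYX writing convention
    if "Q" in axes:
        n_q = axes.count("Q")
        if n_q == 1 and "Z" not in axes:
            axes = axes.replace("Q", "Z")
        elif n_q == 1 and "C" not in axes:
            axes = axes.replace("Q", "C")
        elif n_q == 2 and "Z" not in axes and "C" not in axes:
            axes = axes.replace("Q", "Z", 1).replace("Q", "C", 1)
        else:
            raise ValueError(f"cannot interpret TIFF axes {axes!r}")
    for missing in ("C", "Z"):
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(ax) for ax in "CZYX"]
    data = np.transpose(data, order)
    return data, data.shape[0]


def _calibration_from_tiff(tif: tifffile.TiffFile):
    """Extract (pixel_size_xy_um, z_step_um) from ImageJ/OME metadata."""
    px = dz = None
    ij = tif.imagej_metadata
    if ij is not None and "spacing" in ij:
        dz = float(ij["spacing"])
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        # a 1:1 resolution is the writer default for uncalibrated files
        if num and num != den:
            px = den / num  # resolution is pixels per unit
    if tif.ome_metadata:
        try:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    if "PhysicalSizeX" in el.attrib:
                        px = float(el.attrib["PhysicalSizeX"])
                    if "PhysicalSizeZ" in el.attrib:
                        dz = float(el.attrib["PhysicalSizeZ"])
        except ET.ParseError:
            pass
    return px, dz


def write_stack(stack: TwoChannelStack, path: str | Path) -> None:
    """Write a TwoChannelStack as an ImageJ-style ZCYX TIFF with calibration."""
    data = np.stack([stack.green, stack.red], axis=1)  # (z, c, y, x)
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)  # ImageJ TIFF supports u1/u2/f4
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_xy, 1.0 / stack.pixel_size_xy),
        metadata={"spacing": stack.z_step, "unit": "um", "axes": "ZCYX"},
    )


def read_frap_trace(path: str | Path, n_prebleach: int | None = None) -> FrapTrace:
    """Read a FRAP trace CSV with columns time_s, bleach, reference, background.

    The pre-bleach frame count may be given in a ``# n_prebleach = N`` header
    comment or via the argument (the argument wins if both are present).
    """
    path = Path(path)
    header_n = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "n_prebleach" in line:
                header_n = int(line.split("=")[1])
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "bleach", "reference", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV {path} missing columns: {sorted(missing)}")
    n_pre = n_prebleach if n_prebleach is not None else header_n
    if n_pre is None:
        raise ValueError(
            f"FRAP CSV {path}: n_prebleach not in header and not supplied"
        )
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        bleach_roi=df["bleach"].to_numpy(),
        reference_roi=df["reference"].to_numpy(),
        background_roi=df["background"].to_numpy(),
        n_prebleach=int(n_pre),
        label=path.stem,
    )


def write_frap_trace(trace: FrapTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_prebleach = {trace.n_prebleach}\n")
        pd.DataFrame(
            {
                "time_s": trace.times,
                "bleach": trace.bleach_roi,
                "reference": trace.reference_roi,
                "background": trace.background_roi,
            }
        ).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def puncta_table(puncta: Sequence[Punctum3D]) -> pd.DataFrame:
    """Deterministic per-punctum table (sorted by channel then id)."""
    rows = []
    for p in sorted(puncta, key=lambda p: (p.channel, p.id)):
        vox = p.voxels()
        cz, cy, cx = vox.mean(axis=0)
        z0, z1 = p.layer_range
        rows.append(
            {
                "punctum_id": p.id,
                "channel": p.channel,
                "n_layers": len({s.layer for s in p.slices}),
                "volume_px": p.volume,
                "intensity": p.intensity,
                "centroid_z": cz,
                "centroid_y": cy,
                "centroid_x": cx,
                "z_min": z0,
                "z_max": z1,
                "y_min": int(vox[:, 1].min()),
                "y_max": int(vox[:, 1].max()),
                "x_min": int(vox[:, 2].min()),
                "x_max": int(vox[:, 2].max()),
            }
        )
    columns = [
        "punctum_id", "channel", "n_layers", "volume_px", "intensity",
        "centroid_z", "centroid_y", "centroid_x",
        "z_min", "z_max", "y_min", "y_max", "x_min", "x_max",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_results(records, path: str | Path, format: str = "csv") -> None:
    """Write result records deterministically as CSV or JSON.

    ``records`` may be a DataFrame, a sequence of dataclass-like mappings, or
    a sequence of Punctum3D (converted via :func:`puncta_table`).  CSV files
    carry the coordinate-convention header comment.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    elif len(records) > 0 and isinstance(records[0], Punctum3D):
        df = puncta_table(records)
    else:
        df = pd.DataFrame(list(records))
    fmt = format.lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(COORD_HEADER + "\n")
            df.to_csv(fh, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {"coordinates": "0-based (z, y, x)",
                 "records": df.to_dict(orient="records")},
                fh, indent=2, sort_keys=True, default=float,
            )
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def label_volume(puncta: Sequence[Punctum3D], shape: tuple[int, int, int]) -> np.ndarray:
    """Render puncta as an integer label volume (0 = background)."""
    labels = np.zeros(shape, dtype=np.int32)
    for p in sorted(puncta, key=lambda p: p.id):
        vox = p.voxels()
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = p.id
    return labels


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32),
                     photometric="minisblack")


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
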