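"""Readers/writers for polar OCT rasters, label maps and metadata.

Conventions used throughout the package:

* A polar B-scan is stored with rows = A-lines (angle) and columns = depth
  samples.  Row 0 corresponds to angle 0 deg and angles increase
  counter-clockwise; column 0 is the catheter surface and the physical depth
  of column ``c`` is ``c * axial_spacing`` millimetres.
* On disk a dataset is a directory holding ``image.tiff`` (single-frame
  16-bit grayscale, linear intensity), ``meta.json`` (acquisition metadata),
  and optionally ``labels.png`` (8-bit indexed tissue annotation) and
  ``boundary.csv`` (per-A-line lumen boundary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "BACKGROUND",
    "FIBROUS",
    "CALCIFIED",
    "LIPID",
    "LABEL_NAMES",
    "LABEL_COLORS",
    "PolarImage",
    "TissueLabelMap",
    "read_dataset",
    "write_dataset",
    "scan_convert",
]

BACKGROUND, FIBROUS, CALCIFIED, LIPID = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", FIBROUS: "fibrous",
               CALCIFIED: "calcified", LIPID: "lipid"}
# Fixed display palette: green fibrous, white calcified, pink lipid,
# black background.
LABEL_COLORS = {
    BACKGROUND: (0, 0, 0),
    FIBROUS: (0, 200, 0),
    CALCIFIED: (255, 255, 255),
    LIPID: (255, 105, 180),
}

_MAX_UINT16 = 65535


@dataclass
class PolarImage:
    """A polar-coordinate OCT B-scan on a linear intensity scale.

    Parameters
    ----------
    pixels
        2-D non-negative float array, shape ``(n_alines, n_depth)``.
    axial_spacing
        Millimetres per depth pixel (> 0).
    """

    pixels: np.ndarray
    axial_spacing: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not self.axial_spacing > 0:
            raise ValueError("axial_spacing must be positive")

    @property
    def n_alines(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[1]

    @property
    def angular_step(self) -> float:
        """Degrees per A-line; the rows always span a full revolution."""
        return 360.0 / self.n_alines

    def depth_mm(self) -> np.ndarray:
        """Physical depth of each column in millimetres."""
        return np.arange(self.n_depth) * self.axial_spacing


@dataclass
class TissueLabelMap:
    """Integer tissue annotation raster sharing a PolarImage's geometry."""

    labels: np.ndarray
    color_table: dict = field(default_factory=lambda: dict(LABEL_COLORS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        bad = np.setdiff1d(np.unique(self.labels), list(LABEL_NAMES))
        if bad.size:
            raise ValueError(f"illegal label value(s) {bad.tolist()}; "
                             f"legal labels are {sorted(LABEL_NAMES)}")
        self.labels = self.labels.astype(np.uint8)


def _palette() -> list[int]:
    pal = [0] * (256 * 3)
    for lab, (r, g, b) in LABEL_COLORS.items():
        pal[3 * lab: 3 * lab + 3] = [r, g, b]
    return pal


def write_dataset(path, img: PolarImage, labels: TissueLabelMap | None = None,
                  meta: dict | None = None,
                  boundary: np.ndarray | None = None,
                  shadow_mask: np.ndarray | None = None) -> Path:
    """Write a dataset directory (image.tiff + meta.json [+ labels.png,
    boundary.csv]).

    Intensities are rounded to the nearest integer and stored as 16-bit
    grayscale; values must fit in [0, 65535].
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    px = np.rint(img.pixels)
    if px.max(initial=0) > _MAX_UINT16:
        raise ValueError("intensities exceed the 16-bit output range")
    tifffile.imwrite(path / "image.tiff", px.astype(np.uint16),
                     photometric="minisblack")
    full_meta = {"axial_spacing_mm": img.axial_spacing,
                 "n_alines": img.n_alines}
    if meta:
        full_meta.update(meta)
    (path / "meta.json").write_text(json.dumps(full_meta, indent=1,
                                               sort_keys=True))
    if labels is not None:
        if labels.labels.shape != img.pixels.shape:
            raise ValueError("label map shape does not match image shape")
        pim = Image.fromarray(labels.labels, mode="P")
        pim.putpalette(_palette())
        pim.save(path / "labels.png")
    if boundary is not None:
        boundary = np.asarray(boundary, dtype=int)
        if shadow_mask is None:
            shadow_mask = np.zeros(boundary.shape, dtype=bool)
        rows = ["aline_index,radius_px,shadowed_flag"]
        rows += [f"{i},{r},{int(s)}" for i, (r, s)
                 in enumerate(zip(boundary, shadow_mask))]
        (path / "boundary.csv").write_text("\n".join(rows) + "\n")
    return path


def read_dataset(path):
    """Read a dataset directory written by :func:`write_dataset`.

    Returns ``(PolarImage, TissueLabelMap | None, metadata dict)``.  A
    missing ``labels.png`` is not an error; a missing ``meta.json`` or a
    geometry mismatch between TIFF and PNG is.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    px = tifffile.imread(path / "image.tiff").astype(np.float64)
    if px.ndim != 2:
        raise ValueError("image.tiff must hold a single 2-D frame")
    if "n_alines" in meta and px.shape[0] != meta["n_alines"]:
        raise ValueError(
            f"TIFF has {px.shape[0]} A-lines but metadata says "
            f"{meta['n_alines']}")
    img = PolarImage(px, axial_spacing=float(meta["axial_spacing_mm"]))
    labels = None
    png = path / "labels.png"
    if png.exists():
        arr = np.asarray(Image.open(png))
        if arr.shape != px.shape:
            raise ValueError(
                f"labels.png shape {arr.shape} does not match image shape "
                f"{px.shape}")
        labels = TissueLabelMap(arr)
    return img, labels, meta


def read_boundary(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a boundary.csv file; returns (radius_px, shadowed_flag)."""
    lines = Path(path).read_text().strip().splitlines()[1:]
    rad, shad = [], []
    for ln in lines:
        _, r, s = ln.split(",")
        rad.append(int(r))
        shad.append(bool(int(s)))
    return np.asarray(rad), np.asarray(shad)


def scan_convert(img: PolarImage, out_size: int) -> np.ndarray:
    """Nearest-neighbour polar-to-Cartesian conversion for visualization.

    The catheter axis sits at the centre of the ``out_size`` x ``out_size``
    output raster; pixels beyond the maximum imaged depth are zero.
    """
    if out_size < 16:
        raise ValueError("out_size must be at least 16")
    n_rows, n_cols = img.pixels.shape
    c = (out_size - 1) / 2.0
    yy, xx = np.mgrid[0:out_size, 0:out_size]
    dx = xx - c
    dy = c - yy          # +y up so angles run counter-clockwise on screen
    angle = np.degrees(np.arctan2(dy, dx)) % 360.0
    row = np.rint(angle / img.angular_step).astype(int) % n_rows
    # the full depth range maps onto the inscribed disk radius
    radius_px = np.hypot(dx, dy)
    col = np.rint(radius_px * (n_cols / (out_size / 2.0))).astype(int)
    inside = col < n_cols
    out = np.zeros((out_size, out_size), dtype=np.float64)
    out[inside] = img.pixels[row[inside], col[inside]]
    return out
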