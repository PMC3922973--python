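"""Dual-resolution multiband scene model and file I/O.

A WorldView2-style acquisition delivers eight multispectral (MS) bands at
~2 m ground sample distance (GSD) and one panchromatic band at 4x finer
linear resolution (0.5 m), quantized as 11-bit digital numbers (DN).
Band 5 is the "coastal" band (400-450 nm), far-blue light that penetrates
the water column much deeper than the other bands and is the only band
that registers submerged objects.

Raster conventions used throughout the package:

* 0-based (row, col), origin at the upper-left corner of the scene;
* row increases southward (world y decreases with row);
* pixel-centre convention: pixel (r, c) sits at world
  ``(origin_x + (c + 0.5) * gsd, origin_y - (r + 0.5) * gsd)``;
* MS and pan grids cover the identical world extent;
* annotations travel in world metres so one file serves both grids.

Scenes are stored as a GeoTIFF pair: the MS stack (8 pages) at ``path``
and the pan band in a ``*.pan.tif`` sidecar, both carrying the GeoTIFF
ModelPixelScale / ModelTiepoint tags and a JSON ImageDescription with the
band table. Annotations are GeoJSON FeatureCollections (Point geometry)
or flat CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "BandSpec",
    "MultibandScene",
    "ReferenceAnnotation",
    "SceneError",
    "AnnotationError",
    "CLASS_LABELS",
    "CATEGORIES",
    "COASTAL_BAND_INDEX",
    "default_band_specs",
    "read_scene",
    "write_scene",
    "read_annotations",
    "write_annotations",
    "world_to_pixel",
    "pixel_to_world",
]

MODEL_PIXEL_SCALE_TAG = 33550
MODEL_TIEPOINT_TAG = 33922

#: The three manual detection classes.
CLASS_LABELS = ("probable", "possible", "band5_only")

#: Simulator truth categories: real whales plus the confounder taxonomy
#: (seabird aggregations, bubble slicks from subsurface whales, boats,
#: subsurface rocks).
CATEGORIES = ("whale", "seabird_cluster", "bubble_slick", "boat", "rock")

#: 1-based index of the water-penetrating coastal band.
COASTAL_BAND_INDEX = 5


class SceneError(ValueError):
    """Invalid scene structure (shape/DN/band-metadata violations)."""


class AnnotationError(ValueError):
    """Invalid annotation record or file."""


@dataclass(frozen=True)
class BandSpec:
    """One sensor band: index (1-8 or "pan"), name, passband and GSD."""

    band_index: int | str
    name: str
    wavelength_lo_nm: float
    wavelength_hi_nm: float
    gsd_m: float

    def __post_init__(self) -> None:
        if self.band_index == COASTAL_BAND_INDEX:
            if (self.wavelength_lo_nm, self.wavelength_hi_nm) != (400.0, 450.0):
                raise SceneError(
                    "coastal band (band 5) must span [400, 450] nm, got "
                    f"[{self.wavelength_lo_nm}, {self.wavelength_hi_nm}]"
                )
        if self.wavelength_hi_nm <= self.wavelength_lo_nm:
            raise SceneError("band spec incomplete: empty wavelength range")
        if self.gsd_m <= 0:
            raise SceneError("band spec incomplete: non-positive gsd")


def default_band_specs(ms_gsd_m: float = 2.0, pan_gsd_m: float = 0.5) -> list[BandSpec]:
    """The nine-band WorldView2-like band table.

    Band 5 is the coastal band; the MS GSD must be 4x the pan GSD.
    """
    if abs(ms_gsd_m - 4.0 * pan_gsd_m) > 1e-9:
        raise SceneError("resolution mismatch: MS gsd must be 4x pan gsd")
    table = [
        (1, "red", 630.0, 690.0),
        (2, "blue", 450.0, 510.0),
        (3, "green", 510.0, 580.0),
        (4, "yellow", 585.0, 625.0),
        (5, "coastal", 400.0, 450.0),
        (6, "red_edge", 705.0, 745.0),
        (7, "nir1", 770.0, 895.0),
        (8, "nir2", 860.0, 1040.0),
    ]
    specs = [BandSpec(i, n, lo, hi, ms_gsd_m) for i, n, lo, hi in table]
    specs.append(BandSpec("pan", "pan", 450.0, 800.0, pan_gsd_m))
    return specs


@dataclass
class MultibandScene:
    """Dual-resolution raster stack: 8 MS bands + 1 pan band.

    ``ms_stack`` has shape (8, H, W); ``pan`` has shape (4H, 4W). DN values
    are unsigned integers in [0, dn_max] (default 2047 = 11-bit).
    """

    ms_stack: np.ndarray
    pan: np.ndarray
    origin_xy_m: tuple[float, float] = (0.0, 0.0)
    band_specs: list[BandSpec] = field(default_factory=default_band_specs)
    dn_max: int = 2047

    def __post_init__(self) -> None:
        self.ms_stack = np.asarray(self.ms_stack)
        self.pan = np.asarray(self.pan)
        if self.ms_stack.ndim != 3 or self.ms_stack.shape[0] != 8:
            raise SceneError("resolution mismatch: MS stack must be (8, H, W)")
        if self.pan.ndim != 2:
            raise SceneError("resolution mismatch: pan must be 2-D")
        h, w = self.ms_stack.shape[1:]
        if self.pan.shape != (4 * h, 4 * w):
            raise SceneError(
                f"resolution mismatch: pan shape {self.pan.shape} is not 4x MS {(h, w)}"
            )
        if len(self.band_specs) != 9:
            raise SceneError("band spec incomplete: expected 9 band specs")
        for arr, label in ((self.ms_stack, "MS"), (self.pan, "pan")):
            if arr.min() < 0 or arr.max() > self.dn_max:
                raise SceneError(f"{label} DN values outside [0, {self.dn_max}]")

    # -- geometry -----------------------------------------------------------

    @property
    def ms_shape(self) -> tuple[int, int]:
        return self.ms_stack.shape[1:]

    @property
    def pan_shape(self) -> tuple[int, int]:
        return self.pan.shape

    @property
    def ms_gsd_m(self) -> float:
        return self.band_specs[0].gsd_m

    @property
    def pan_gsd_m(self) -> float:
        return self.band_specs[8].gsd_m

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the scene footprint in metres."""
        h, w = self.ms_shape
        return w * self.ms_gsd_m, h * self.ms_gsd_m

    def band(self, index: int | str) -> np.ndarray:
        """Grid for 1-based MS band index or ``"pan"``."""
        if index == "pan":
            return self.pan
        return self.ms_stack[int(index) - 1]

    @property
    def coastal(self) -> np.ndarray:
        return self.band(COASTAL_BAND_INDEX)

    def grid_gsd(self, grid: Literal["ms", "pan"]) -> float:
        return self.ms_gsd_m if grid == "ms" else self.pan_gsd_m


def _grid_shape(scene: MultibandScene, grid: str) -> tuple[int, int]:
    return scene.ms_shape if grid == "ms" else scene.pan_shape


def world_to_pixel(
    scene: MultibandScene, xy_m: tuple[float, float], grid: Literal["ms", "pan"] = "ms"
) -> tuple[int, int]:
    """Map world metres to 0-based (row, col) on the requested grid.

    Raises :class:`SceneError` ("outside scene") for out-of-extent points.
    """
    ox, oy = scene.origin_xy_m
    gsd = scene.grid_gsd(grid)
    x, y = xy_m
    col = int(np.floor((x - ox) / gsd))
    row = int(np.floor((oy - y) / gsd))
    h, w = _grid_shape(scene, grid)
    if not (0 <= row < h and 0 <= col < w):
        raise SceneError(f"outside scene: point {xy_m} not in extent")
    return row, col


def pixel_to_world(
    scene: MultibandScene, rowcol: tuple[int, int], grid: Literal["ms", "pan"] = "ms"
) -> tuple[float, float]:
    """Pixel-centre world coordinates of (row, col) on the requested grid."""
    ox, oy = scene.origin_xy_m
    gsd = scene.grid_gsd(grid)
    row, col = rowcol
    return ox + (col + 0.5) * gsd, oy - (row + 0.5) * gsd


# -- annotations -----------------------------------------------------------


@dataclass
class ReferenceAnnotation:
    """One reference object: manual digitization or simulator truth.

    ``class_label`` uses the three manual classes: ``probable`` (whale-shaped
    and whale-sized), ``possible`` (weaker signals, bubble slicks, some
    seabird groups), ``band5_only`` (visible only in the water-penetrating
    coastal band). ``depth_m`` and ``category`` are filled only by the
    simulator (truth not available for real imagery).
    """

    object_id: str
    centroid_xy_m: tuple[float, float]
    length_m: float
    class_label: str
    depth_m: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise AnnotationError(f"unknown class: {self.class_label!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise AnnotationError(f"unknown category: {self.category!r}")
        self.centroid_xy_m = (float(self.centroid_xy_m[0]), float(self.centroid_xy_m[1]))


_CSV_COLUMNS = ["object_id", "x_m", "y_m", "length_m", "class_label", "depth_m", "category"]


def write_annotations(annotations: Sequence[ReferenceAnnotation], path: str | Path) -> None:
    """Write annotations as GeoJSON (``.geojson``/``.json``) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "object_id": a.object_id,
                "x_m": a.centroid_xy_m[0],
                "y_m": a.centroid_xy_m[1],
                "length_m": a.length_m,
                "class_label": a.class_label,
                "depth_m": a.depth_m,
                "category": a.category,
            }
            for a in annotations
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
        return
    features = []
    for a in annotations:
        props = {
            "object_id": a.object_id,
            "length_m": a.length_m,
            "class_label": a.class_label,
        }
        if a.depth_m is not None:
            props["depth_m"] = a.depth_m
        if a.category is not None:
            props["category"] = a.category
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(a.centroid_xy_m)},
                "properties": props,
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_annotations(path: str | Path) -> list[ReferenceAnnotation]:
    """Read annotations from GeoJSON or CSV (inverse of write_annotations)."""
    path = Path(path)
    out: list[ReferenceAnnotation] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if df.empty:
            return []
        for _, r in df.iterrows():
            out.append(
                ReferenceAnnotation(
                    object_id=str(r["object_id"]),
                    centroid_xy_m=(float(r["x_m"]), float(r["y_m"])),
                    length_m=float(r["length_m"]),
                    class_label=str(r["class_label"]),
                    depth_m=None if pd.isna(r.get("depth_m")) else float(r["depth_m"]),
                    category=None if pd.isna(r.get("category")) else str(r["category"]),
                )
            )
        return out
    doc = json.loads(path.read_text())
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        x, y = feat["geometry"]["coordinates"]
        out.append(
            ReferenceAnnotation(
                object_id=str(props["object_id"]),
                centroid_xy_m=(float(x), float(y)),
                length_m=float(props["length_m"]),
                class_label=str(props["class_label"]),
                depth_m=props.get("depth_m"),
                category=props.get("category"),
            )
        )
    return out


# -- raster I/O ------------------------------------------------------------


def _pan_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".pan.tif")


def _geo_tags(gsd: float, origin: tuple[float, float]) -> list[tuple]:
    # GeoTIFF: pixel scale + tiepoint mapping raster (0,0) to the world
    # upper-left corner of the scene.
    return [
        (MODEL_PIXEL_SCALE_TAG, "d", 3, (gsd, gsd, 0.0)),
        (MODEL_TIEPOINT_TAG, "d", 6, (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)),
    ]


def write_scene(scene: MultibandScene, path: str | Path) -> None:
    """Write the scene as a GeoTIFF pair: MS stack at ``path``, pan sidecar."""
    path = Path(path)
    meta = {
        "dn_max": scene.dn_max,
        "band_specs": [asdict(b) for b in scene.band_specs],
    }
    desc = json.dumps(meta)
    tifffile.imwrite(
        path,
        scene.ms_stack.astype(np.uint16),
        photometric="minisblack",
        description=desc,
        extratags=_geo_tags(scene.ms_gsd_m, scene.origin_xy_m),
    )
    tifffile.imwrite(
        _pan_sidecar(path),
        scene.pan.astype(np.uint16),
        photometric="minisblack",
        description=desc,
        extratags=_geo_tags(scene.pan_gsd_m, scene.origin_xy_m),
    )


def _read_geo(page: tifffile.TiffPage) -> tuple[float, tuple[float, float]]:
    try:
        scale = page.tags[MODEL_PIXEL_SCALE_TAG].value
        tie = page.tags[MODEL_TIEPOINT_TAG].value
    except KeyError as exc:
        raise SceneError("band spec incomplete: missing georeferencing tags") from exc
    return float(scale[0]), (float(tie[3]), float(tie[4]))


def read_scene(path: str | Path, pan_path: str | Path | None = None) -> MultibandScene:
    """Read a scene written by :func:`write_scene`.

    Raises :class:`SceneError` for shape mismatches ("resolution mismatch")
    or missing band metadata ("band spec incomplete").
    """
    path = Path(path)
    pan_path = Path(pan_path) if pan_path is not None else _pan_sidecar(path)
    with tifffile.TiffFile(path) as tf:
        ms = tf.asarray()
        page = tf.pages[0]
        desc = page.description
        ms_gsd, origin = _read_geo(page)
    with tifffile.TiffFile(pan_path) as tf:
        pan = tf.asarray()
    if not desc:
        raise SceneError("band spec incomplete: no band metadata in file")
    try:
        meta = json.loads(desc)
        specs = [BandSpec(**b) for b in meta["band_specs"]]
        dn_max = int(meta["dn_max"])
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise SceneError("band spec incomplete: unreadable band metadata") from exc
    if abs(specs[0].gsd_m - ms_gsd) > 1e-9:
        raise SceneError("band spec incomplete: gsd tag disagrees with band table")
    return MultibandScene(
        ms_stack=ms, pan=pan, origin_xy_m=origin, band_specs=specs, dn_max=dn_max
    )
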