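"""Automatic whale detection in multiband scenes.

Four detection routines are provided, mirroring the comparison run on the
original Golfo Nuevo WorldView2 census image:

* single-band histogram thresholding of the panchromatic band or the
  water-penetrating coastal band (band 5), with the threshold chosen to
  maximize the ratio of multi-pixel to single-pixel connected components
  — whales are large and should produce multiple bright pixels, while
  noise produces isolated single pixels;
* unsupervised k-means and ISODATA pixel clustering of the MS stack;
* supervised maximum-likelihood (per-pixel multivariate Gaussian)
  classification from user-supplied class signatures.

Bright components are promoted to :class:`DetectionObject` candidates with
second-moment shape measures, passed through a whale size/shape filter
(roughly ellipsoidal, up to 16 m long), and labelled with the three-class
scheme used for manual digitization: ``probable`` (whale-shaped and
whale-sized, visible at the surface), ``possible`` (weaker, small or
ambiguous signals), ``band5_only`` (visible only in the coastal band,
i.e. submerged).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .scene import (
    COASTAL_BAND_INDEX,
    BandSpec,
    MultibandScene,
    SceneError,
    pixel_to_world,
    world_to_pixel,
)

__all__ = [
    "ThresholdResult",
    "DetectionObject",
    "ClassSignature",
    "DetectionConfig",
    "band_cross_section",
    "label_components",
    "optimize_threshold",
    "threshold_segment",
    "shape_filter",
    "kmeans_segment",
    "kmeans_fit",
    "isodata_segment",
    "maxlike_segment",
    "signature_from_pixels",
    "cluster_to_candidates",
    "classify_detections",
    "detect_whales",
    "write_detections",
    "read_detections",
    "DETECTION_METHODS",
]

DETECTION_METHODS = ("threshold_pan", "threshold_band5", "kmeans", "isodata", "maxlike")


@dataclass
class ThresholdResult:
    """A band threshold with its multi:single component-ratio statistic."""

    band: BandSpec | None
    threshold_dn: int
    n_multi_pixel_components: int
    n_single_pixel_components: int
    ratio: float


@dataclass(eq=False)
class DetectionObject:
    """A connected bright component promoted to a candidate whale.

    Pixels live on a named grid ("ms" or "pan"); world measures use that
    grid's GSD. Axis lengths and orientation come from second-order
    moments of the pixel set.
    """

    pixels: np.ndarray  # (N, 2) int array of (row, col)
    grid: Literal["ms", "pan"]
    centroid_xy_m: tuple[float, float]
    area_m2: float
    major_axis_m: float
    minor_axis_m: float
    orientation_rad: float
    mean_dn: float
    source: str
    mean_dn_per_band: dict[str, float] | None = None
    detection_class: str | None = None
    shape_pass: bool | None = None
    weak: bool = False
    ms_surface_support: bool = False  # strong contrast in a non-coastal MS band

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def single_pixel(self) -> bool:
        return self.n_pixels == 1

    @property
    def gsd_m(self) -> float:
        return math.sqrt(self.area_m2 / self.n_pixels) if self.n_pixels else 0.0

    @property
    def aspect(self) -> float:
        """Major/minor axis ratio with a one-pixel floor on the minor axis.

        Second-moment minor axes collapse to zero for collinear pixel
        sets, but a pixel line is physically one GSD wide; the floor keeps
        small genuine objects from looking infinitely elongated.
        """
        floor = max(self.minor_axis_m, self.gsd_m)
        if floor <= 0:
            return math.inf
        return self.major_axis_m / floor


@dataclass
class ClassSignature:
    """Mean/covariance DN signature of one class across the MS bands."""

    class_name: str
    mean_dn_per_band: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean_dn_per_band = np.asarray(self.mean_dn_per_band, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
            raise ValueError("covariance must be positive semi-definite")


def signature_from_pixels(class_name: str, pixels: np.ndarray) -> ClassSignature:
    """Build a signature from an (N, B) array of training pixel vectors."""
    x = np.asarray(pixels, dtype=float)
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False) if len(x) > 1 else np.eye(x.shape[1])
    cov = np.atleast_2d(cov)
    return ClassSignature(class_name, mean, 0.5 * (cov + cov.T))


# -- cross-sections ---------------------------------------------------------


def band_cross_section(
    scene: MultibandScene,
    start_xy_m: tuple[float, float],
    end_xy_m: tuple[float, float],
    n_samples: int = 100,
) -> dict[str, np.ndarray]:
    """DN profiles of all 9 bands along a world-coordinate segment.

    Each band is sampled at ``n_samples`` evenly spaced points using the
    nearest pixel on that band's own grid — the diagnostic used to show
    that all bands respond to surface features while only the coastal band
    responds to submerged ones.
    """
    xs = np.linspace(start_xy_m[0], end_xy_m[0], n_samples)
    ys = np.linspace(start_xy_m[1], end_xy_m[1], n_samples)
    profiles: dict[str, np.ndarray] = {}
    for spec in scene.band_specs:
        grid = "pan" if spec.band_index == "pan" else "ms"
        g = scene.band(spec.band_index)
        vals = np.empty(n_samples)
        for i, (x, y) in enumerate(zip(xs, ys)):
            r, c = world_to_pixel(scene, (x, y), grid)  # raises "outside scene"
            vals[i] = g[r, c]
        profiles[spec.name] = vals
    return profiles


# -- connected components and thresholding ---------------------------------


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(binary: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label connected regions of a binary grid; background stays 0."""
    labels, n = ndimage.label(np.asarray(binary, dtype=bool), structure=_structure(connectivity))
    return labels, n


def _component_counts(binary: np.ndarray, connectivity: int) -> tuple[int, int]:
    """(# components of >= 2 pixels, # single-pixel components)."""
    labels, n = label_components(binary, connectivity)
    if n == 0:
        return 0, 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= 2).sum()), int((sizes == 1).sum())


def optimize_threshold(
    grid: np.ndarray,
    candidate_thresholds: Sequence[int] | None = None,
    connectivity: int = 8,
    band: BandSpec | None = None,
    max_foreground_frac: float = 0.02,
) -> ThresholdResult:
    """Exhaustively choose the threshold maximizing the multi:single ratio.

    The ratio is ``(# components of >= 2 px) / max(# 1-px components, 1)``.
    Default candidates are every integer DN from the background median to
    the grid maximum, excluding thresholds that leave more than
    ``max_foreground_frac`` of the grid as foreground — whales are sparse,
    so a background-dominated binarization cannot be a whale threshold
    (and near the median the ratio statistic degenerates into counting
    noise-percolation blobs). Ties are broken toward the higher threshold
    (fewest residual noise pixels).

    Explicitly supplied candidates are used as-is.
    """
    grid = np.asarray(grid)
    if candidate_thresholds is None:
        lo = int(np.median(grid))
        hi = int(grid.max())
        candidate_thresholds = [
            t for t in range(lo, hi)
            if (grid > t).mean() <= max_foreground_frac
        ]
    candidates = sorted(int(t) for t in candidate_thresholds)
    if not candidates:
        raise ValueError("empty candidate set")
    if not (grid > candidates[0]).any():
        raise ValueError("no signal above threshold")
    best: tuple[float, int] | None = None
    best_counts = (0, 0)
    for t in candidates:
        multi, single = _component_counts(grid > t, connectivity)
        ratio = multi / max(single, 1)
        if best is None or ratio >= best[0]:
            best = (ratio, t)
            best_counts = (multi, single)
    ratio, t = best
    return ThresholdResult(
        band=band,
        threshold_dn=t,
        n_multi_pixel_components=best_counts[0],
        n_single_pixel_components=best_counts[1],
        ratio=ratio,
    )


def _components_to_objects(
    binary: np.ndarray,
    grid_values: np.ndarray,
    connectivity: int,
    gsd_m: float,
    origin_xy_m: tuple[float, float],
    grid_name: str,
    source: str,
) -> list[DetectionObject]:
    labels, n = label_components(binary, connectivity)
    objects: list[DetectionObject] = []
    if n == 0:
        return objects
    props = measure.regionprops(labels, intensity_image=np.asarray(grid_values, dtype=float))
    for p in props:
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        r_bar, c_bar = p.centroid
        cx = origin_xy_m[0] + (c_bar + 0.5) * gsd_m
        cy = origin_xy_m[1] - (r_bar + 0.5) * gsd_m
        objects.append(
            DetectionObject(
                pixels=p.coords.copy(),
                grid=grid_name,  # type: ignore[arg-type]
                centroid_xy_m=(cx, cy),
                area_m2=float(p.num_pixels) * gsd_m * gsd_m,
                major_axis_m=float(p.axis_major_length) * gsd_m,
                minor_axis_m=float(p.axis_minor_length) * gsd_m,
                orientation_rad=float(p.orientation),
                mean_dn=float(p.intensity_mean),
                source=source,
            )
        )
    return objects


def threshold_segment(
    grid: np.ndarray,
    threshold_dn: float,
    connectivity: int = 8,
    *,
    gsd_m: float = 1.0,
    origin_xy_m: tuple[float, float] = (0.0, 0.0),
    grid_name: str = "ms",
    source: str = "threshold",
) -> list[DetectionObject]:
    """Promote components of pixels with DN > threshold to detections."""
    grid = np.asarray(grid)
    return _components_to_objects(
        grid > threshold_dn, grid, connectivity, gsd_m, origin_xy_m, grid_name, source
    )


# -- size/shape filter ------------------------------------------------------


def shape_filter(
    objects: Iterable[DetectionObject],
    min_len_m: float = 5.0,
    max_len_m: float = 16.0,
    max_aspect: float = 7.0,
    min_pixels: int = 2,
) -> tuple[list[DetectionObject], list[DetectionObject]]:
    """Split candidates into (kept, rejected) by whale size/shape.

    Rejected: longer than ``max_len_m`` (boats, slicks, wakes) or
    whale-length but far too elongated. Objects smaller than the whale
    minimum — including valid single pixels from deep whales — are KEPT
    but fail ``shape_pass``, flagging them for the "possible" class.
    """
    kept: list[DetectionObject] = []
    rejected: list[DetectionObject] = []
    for obj in objects:
        # one-GSD tolerance: second-moment lengths of rasterized ellipses
        # read up to about one pixel long or short of the true axis
        too_long = obj.major_axis_m > max_len_m + obj.gsd_m
        # aspect is only a reliable discriminator with enough pixels; a
        # handful of eroded pixels from a genuine whale can read collinear
        too_thin = (
            obj.aspect > max_aspect
            and obj.major_axis_m >= min_len_m
            and obj.n_pixels >= 10
        )
        if too_long or too_thin:
            obj.shape_pass = False
            rejected.append(obj)
            continue
        obj.shape_pass = (
            obj.major_axis_m >= min_len_m - obj.gsd_m
            and obj.major_axis_m <= max_len_m
            and obj.aspect <= max_aspect
            and obj.n_pixels >= min_pixels
        )
        kept.append(obj)
    return kept, rejected


# -- unsupervised clustering -----------------------------------------------


def _as_feature_matrix(stack: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        shape = stack.shape
        return stack.reshape(-1, 1), shape
    shape = stack.shape[1:]
    return stack.reshape(stack.shape[0], -1).T, shape


def _even_init(x: np.ndarray, k: int) -> np.ndarray:
    """Initial class means evenly distributed between data min and max."""
    lo, hi = x.min(axis=0), x.max(axis=0)
    if k == 1:
        return ((lo + hi) / 2.0)[None, :]
    return np.linspace(lo, hi, k)


def _lloyd(
    x: np.ndarray,
    means: np.ndarray,
    max_iter: int,
    tol: float,
    post=None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Minimum-distance assignment / mean update, with an optional per-pass
    post-processing hook (ISODATA discard/split/merge). Returns final
    labels, means and the within-cluster sum-of-squares trajectory."""
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(len(x)), labels].sum()))
        occupied = [j for j in range(len(means)) if (labels == j).any()]
        if len(occupied) < len(means):
            # degenerate clusters dropped deterministically (by index order)
            warnings.warn("degenerate cluster dropped", stacklevel=2)
        new_means = np.array([x[labels == j].mean(axis=0) for j in occupied])
        moved = (
            np.inf
            if len(occupied) < len(means)
            else float(np.sqrt(((new_means - means[occupied]) ** 2).sum(axis=1)).max())
        )
        means = new_means
        changed = False
        if post is not None:
            means, changed = post(x, means)
        if moved < tol and not changed:
            break
    d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, means, history


def kmeans_fit(
    stack: np.ndarray, k: int, max_iter: int = 100, tol: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """k-means with deterministic evenly-spaced initial means.

    Initial class means are evenly distributed in the data space (between
    the per-feature min and max), then pixels are iteratively clustered to
    the nearest class by minimum distance — no randomness, so no seed.
    Returns (label grid, means, objective history).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, shape = _as_feature_matrix(stack)
    means = _even_init(x, k)
    labels, means, history = _lloyd(x, means, max_iter, tol)
    return labels.reshape(shape), means, history


def kmeans_segment(
    stack: np.ndarray, k: int, max_iter: int = 100, tol: float = 1e-3
) -> np.ndarray:
    """Per-pixel cluster labels from deterministic k-means."""
    labels, _, _ = kmeans_fit(stack, k, max_iter, tol)
    return labels


def _isodata_post(min_cluster_size: int, split_sd: float, merge_dist: float):
    def post(x: np.ndarray, means: np.ndarray) -> tuple[np.ndarray, bool]:
        changed = False
        d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        sizes = np.array([(labels == j).sum() for j in range(len(means))])
        # discard undersized clusters (keep at least one)
        if min_cluster_size > 1 and (sizes < min_cluster_size).any() and len(means) > 1:
            keep = [j for j in range(len(means)) if sizes[j] >= min_cluster_size]
            if not keep:
                keep = [int(sizes.argmax())]
            if len(keep) < len(means):
                means = means[keep]
                changed = True
                d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
                labels = d2.argmin(axis=1)
        # split clusters with excessive spread along their widest dimension
        if np.isfinite(split_sd):
            new_means = []
            for j in range(len(means)):
                members = x[labels == j]
                if len(members) > 1:
                    sd = members.std(axis=0)
                    dim = int(sd.argmax())
                    if sd[dim] > split_sd:
                        off = np.zeros(means.shape[1])
                        off[dim] = sd[dim]
                        new_means.extend([means[j] - off, means[j] + off])
                        changed = True
                        continue
                new_means.append(means[j])
            means = np.array(new_means)
        # merge cluster pairs closer than merge_dist (ascending distance)
        if merge_dist > 0 and len(means) > 1:
            merged = True
            while merged and len(means) > 1:
                merged = False
                dd = np.sqrt(((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=2))
                np.fill_diagonal(dd, np.inf)
                i, j = np.unravel_index(dd.argmin(), dd.shape)
                if dd[i, j] < merge_dist:
                    pair_mean = 0.5 * (means[i] + means[j])
                    means = np.vstack(
                        [means[t] for t in range(len(means)) if t not in (i, j)]
                        + [pair_mean]
                    )
                    changed = True
                    merged = True
        return means, changed

    return post


def isodata_segment(
    stack: np.ndarray,
    k_init: int,
    max_iter: int = 30,
    min_cluster_size: int = 1,
    split_sd: float = math.inf,
    merge_dist: float = 0.0,
    tol: float = 1e-3,
) -> np.ndarray:
    """ISODATA clustering: k-means core + discard/split/merge steps.

    Clusters smaller than ``min_cluster_size`` are discarded, clusters
    whose widest per-band SD exceeds ``split_sd`` are split in two, and
    cluster pairs closer than ``merge_dist`` are merged, between k-means
    passes. With ``min_cluster_size=1``, ``split_sd=inf`` and
    ``merge_dist=0`` the post-steps are no-ops and the result is
    pixel-identical to :func:`kmeans_segment`.
    """
    if k_init < 1:
        raise ValueError("k_init must be >= 1")
    x, shape = _as_feature_matrix(stack)
    means = _even_init(x, k_init)
    post = _isodata_post(min_cluster_size, split_sd, merge_dist)
    labels, means, _ = _lloyd(x, means, max_iter, tol, post=post)
    return labels.reshape(shape)


# -- supervised classification ---------------------------------------------


def maxlike_segment(
    stack: np.ndarray,
    signatures: Sequence[ClassSignature],
    ridge_eps: float = 1e-6,
) -> np.ndarray:
    """Per-pixel maximum-likelihood class under Gaussian signatures.

    Each pixel vector is assigned the class maximizing the multivariate
    normal log-likelihood. Singular covariances are ridge-regularized
    (``eps * mean diagonal`` added) with a warning.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 class signatures")
    x, shape = _as_feature_matrix(stack)
    n, b = x.shape
    loglik = np.empty((n, len(signatures)))
    for i, sig in enumerate(signatures):
        cov = sig.covariance.copy()
        if cov.shape != (b, b):
            raise ValueError(
                f"signature {sig.class_name!r} has covariance {cov.shape}, stack has {b} bands"
            )
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular covariance for class {sig.class_name!r}; ridge-regularized",
                stacklevel=2,
            )
            cov = cov + ridge_eps * max(np.trace(cov) / b, 1.0) * np.eye(b)
            chol = np.linalg.cholesky(cov)
        diff = x - sig.mean_dn_per_band
        z = np.linalg.solve(chol, diff.T)
        maha = (z ** 2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        loglik[:, i] = -0.5 * (b * math.log(2 * math.pi) + logdet + maha)
    return loglik.argmax(axis=1).reshape(shape)


# -- cluster post-processing -----------------------------------------------


def cluster_to_candidates(
    label_grid: np.ndarray,
    intensity: np.ndarray,
    sd_multiple: float = 2.0,
) -> np.ndarray:
    """Binary candidate mask from a cluster/class label grid.

    The modal (largest) cluster is taken as the water background; clusters
    whose mean intensity exceeds the water level by ``sd_multiple``
    background SDs are selected, restricted to pixels actually above the
    water level. The water level and SD are estimated robustly
    (median/MAD over the whole grid) so that a background accidentally
    split across two clusters does not shrink the SD and admit the second
    background cluster. An empty mask is a valid outcome.
    """
    labels = np.asarray(label_grid)
    intensity = np.asarray(intensity, dtype=float)
    ids, counts = np.unique(labels, return_counts=True)
    modal = ids[counts.argmax()]
    water_mean, water_sd = _robust_background(intensity)
    mask = np.zeros(labels.shape, dtype=bool)
    for j in ids:
        if j == modal:
            continue
        if float(intensity[labels == j].mean()) > water_mean + sd_multiple * max(water_sd, 1.0):
            mask |= labels == j
    return mask & (intensity > water_mean)


# -- three-class labelling --------------------------------------------------


def _has_counterpart(
    obj: DetectionObject, others: Sequence[DetectionObject], radius_m: float
) -> bool:
    ox, oy = obj.centroid_xy_m
    return any(
        math.hypot(ox - o.centroid_xy_m[0], oy - o.centroid_xy_m[1]) <= radius_m
        for o in others
    )


def classify_detections(
    pan_detections: Sequence[DetectionObject],
    band5_detections: Sequence[DetectionObject],
    match_radius_m: float = 10.0,
    primary: Sequence[DetectionObject] | None = None,
) -> list[DetectionObject]:
    """Assign the three-class labels to detections.

    Rules (formalizing the manual protocol): a detection with no surface
    evidence (no panchromatic counterpart and no strong contrast in any
    non-coastal MS band) but coastal-band support is ``band5_only``
    (submerged); a shape-passing detection with surface evidence is
    ``probable``; everything else — weak, single-pixel or oddly shaped —
    is ``possible``.

    By default the classified list is the union of the pan detections and
    the pan-unmatched band-5 detections; pass ``primary`` to classify
    another method's candidate list against the same support sets.
    """
    if primary is None:
        primary = list(pan_detections) + [
            b for b in band5_detections
            if not _has_counterpart(b, pan_detections, match_radius_m)
        ]
    out = []
    for obj in primary:
        pan_support = (
            obj.grid == "pan"
            or _has_counterpart(obj, pan_detections, match_radius_m)
            or getattr(obj, "ms_surface_support", False)
        )
        band5_support = obj.source == "threshold_band5" or _has_counterpart(
            obj, band5_detections, match_radius_m
        )
        shape_ok = obj.shape_pass
        if shape_ok is None:
            kept, _ = shape_filter([obj])
            shape_ok = bool(kept) and kept[0].shape_pass
        if not pan_support and band5_support:
            obj.detection_class = "band5_only"
        elif shape_ok and pan_support and not obj.weak:
            obj.detection_class = "probable"
        else:
            obj.detection_class = "possible"
        out.append(obj)
    return out


# -- end-to-end -------------------------------------------------------------


@dataclass
class DetectionConfig:
    """Parameters of the end-to-end detection pipeline."""

    connectivity: int = 8
    min_len_m: float = 5.0
    max_len_m: float = 16.0
    max_aspect: float = 7.0
    min_pixels: int = 2
    match_radius_m: float = 10.0
    threshold_pan: int | None = None  # None -> optimized
    threshold_band5: int | None = None
    k: int = 4
    isodata_min_cluster_size: int = 10
    isodata_split_sd: float = math.inf
    isodata_merge_dist: float = 0.0
    sd_multiple: float = 2.0
    weak_contrast_sigma: float = 2.0
    min_support_ratio: float = 1.0  # min multi:single ratio to trust a band as support
    signatures: list[ClassSignature] | None = None
    water_class: str = "water"


def _robust_background(grid: np.ndarray) -> tuple[float, float]:
    med = float(np.median(grid))
    mad = float(np.median(np.abs(grid - med)))
    return med, 1.4826 * mad


def _annotate_objects(
    scene: MultibandScene,
    objects: list[DetectionObject],
    surface_support_sigma: float = 2.0,
) -> None:
    """Fill per-band mean DN and cross-band support flags for each object.

    ``ms_surface_support`` marks objects whose footprint-mean contrast in
    any non-coastal MS band reaches ``surface_support_sigma`` robust
    background SDs — i.e. the object is visible outside the
    water-penetrating band and therefore at/near the surface.
    """
    bg: dict[str, tuple[float, float]] = {}
    for spec in scene.band_specs:
        if spec.band_index == "pan":
            continue
        bg[spec.name] = _robust_background(scene.band(spec.band_index))
    coastal_name = scene.band_specs[COASTAL_BAND_INDEX - 1].name
    for obj in objects:
        gsd = scene.grid_gsd(obj.grid)
        means: dict[str, float] = {}
        # map pixel centres to MS pixels to sample every band
        ms_rc = []
        for r, c in obj.pixels:
            x = scene.origin_xy_m[0] + (c + 0.5) * gsd
            y = scene.origin_xy_m[1] - (r + 0.5) * gsd
            ms_rc.append(world_to_pixel(scene, (x, y), "ms"))
        rr = np.array([p[0] for p in ms_rc])
        cc = np.array([p[1] for p in ms_rc])
        for spec in scene.band_specs:
            if spec.band_index == "pan":
                continue
            means[spec.name] = float(scene.band(spec.band_index)[rr, cc].mean())
        if obj.grid == "pan":
            means["pan"] = obj.mean_dn
        else:
            prr = np.clip(rr * 4 + 2, 0, scene.pan_shape[0] - 1)
            pcc = np.clip(cc * 4 + 2, 0, scene.pan_shape[1] - 1)
            means["pan"] = float(scene.pan[prr, pcc].mean())
        obj.mean_dn_per_band = means
        # 3-DN floor on the noise scale: below that, band-to-band contrast
        # is indistinguishable from 11-bit quantization residue
        obj.ms_surface_support = any(
            means[name] - med >= surface_support_sigma * max(sd, 3.0)
            for name, (med, sd) in bg.items()
            if name != coastal_name
        )


def detect_whales(
    scene: MultibandScene,
    method: str,
    config: DetectionConfig | None = None,
) -> list[DetectionObject]:
    """Run one detection method end to end and return classed detections.

    Pipeline: segment -> connected components -> size/shape filter ->
    three-class labelling. Panchromatic and coastal-band threshold
    detections are always computed as cross-band support evidence.
    Deterministic for a given scene and config.
    """
    if method not in DETECTION_METHODS:
        raise ValueError(f"unknown method: {method!r}")
    cfg = config or DetectionConfig()
    band5 = scene.coastal
    pan = scene.pan
    common5 = dict(
        connectivity=cfg.connectivity,
        gsd_m=scene.ms_gsd_m,
        origin_xy_m=scene.origin_xy_m,
        grid_name="ms",
    )
    commonp = dict(
        connectivity=cfg.connectivity,
        gsd_m=scene.pan_gsd_m,
        origin_xy_m=scene.origin_xy_m,
        grid_name="pan",
    )
    def _auto(grid, fixed, spec):
        """(threshold, trustworthy) for a band; None if nothing to segment.

        A band whose best multi:single ratio is below 1 is noise-dominated
        (isolated singles outnumber multi-pixel components); its
        detections are still usable as a primary candidate list but are
        not trusted as cross-band support evidence.
        """
        if fixed is not None:
            return fixed, True
        try:
            res = optimize_threshold(grid, connectivity=cfg.connectivity, band=spec)
        except ValueError:
            # constant / signal-free band: nothing to segment
            return None, False
        return res.threshold_dn, res.ratio >= cfg.min_support_ratio

    t5, trust5 = _auto(band5, cfg.threshold_band5, scene.band_specs[COASTAL_BAND_INDEX - 1])
    tp, trustp = _auto(pan, cfg.threshold_pan, scene.band_specs[8])
    band5_dets = (
        [] if t5 is None
        else threshold_segment(band5, t5, source="threshold_band5", **common5)
    )
    pan_dets = (
        [] if tp is None
        else threshold_segment(pan, tp, source="threshold_pan", **commonp)
    )
    band5_support = band5_dets if trust5 else []
    pan_support = pan_dets if trustp else []

    if method == "threshold_band5":
        primary = band5_dets
    elif method == "threshold_pan":
        primary = pan_dets
    else:
        stack = scene.ms_stack.astype(float)
        if method == "kmeans":
            labels = kmeans_segment(stack, cfg.k)
        elif method == "isodata":
            labels = isodata_segment(
                stack,
                cfg.k,
                min_cluster_size=cfg.isodata_min_cluster_size,
                split_sd=cfg.isodata_split_sd,
                merge_dist=cfg.isodata_merge_dist,
            )
        else:  # maxlike
            if not cfg.signatures:
                raise ValueError("maxlike requires class signatures in config")
            labels = maxlike_segment(stack, cfg.signatures)
            names = [s.class_name for s in cfg.signatures]
            if cfg.water_class in names:
                # water is background regardless of cluster sizes
                labels = np.where(labels == names.index(cfg.water_class), 0, labels + 1)
        mask = cluster_to_candidates(labels, stack.mean(axis=0), cfg.sd_multiple)
        primary = _components_to_objects(
            mask, stack.mean(axis=0), cfg.connectivity, scene.ms_gsd_m,
            scene.origin_xy_m, "ms", method,
        )

    # weak-contrast flag relative to the source grid's robust background
    for obj in primary:
        g = pan if obj.grid == "pan" else band5
        med, sd = _robust_background(g)
        obj.weak = (obj.mean_dn - med) < cfg.weak_contrast_sigma * max(sd, 1.0)

    kept, _rejected = shape_filter(
        primary, cfg.min_len_m, cfg.max_len_m, cfg.max_aspect, cfg.min_pixels
    )
    _annotate_objects(scene, kept)
    return classify_detections(pan_support, band5_support, cfg.match_radius_m, primary=kept)


# -- detection I/O ----------------------------------------------------------


def write_detections(
    detections: Sequence[DetectionObject],
    path: str | Path,
    gsd_by_grid: dict[str, float] | None = None,
    origin_xy_m: tuple[float, float] = (0.0, 0.0),
) -> None:
    """Write detections as GeoJSON (pixel-set polygons) or CSV summary."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for d in detections:
            rows.append(
                {
                    "source": d.source,
                    "detection_class": d.detection_class,
                    "x_m": d.centroid_xy_m[0],
                    "y_m": d.centroid_xy_m[1],
                    "area_m2": d.area_m2,
                    "major_axis_m": d.major_axis_m,
                    "minor_axis_m": d.minor_axis_m,
                    "n_pixels": d.n_pixels,
                    "mean_dn": d.mean_dn,
                    "grid": d.grid,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)
        return
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    gsd_by_grid = gsd_by_grid or {"ms": 2.0, "pan": 0.5}
    features = []
    for d in detections:
        gsd = gsd_by_grid[d.grid]
        squares = [
            box(
                origin_xy_m[0] + c * gsd,
                origin_xy_m[1] - (r + 1) * gsd,
                origin_xy_m[0] + (c + 1) * gsd,
                origin_xy_m[1] - r * gsd,
            )
            for r, c in d.pixels
        ]
        poly = unary_union(squares)
        props = {
            "source": d.source,
            "detection_class": d.detection_class,
            "centroid_x_m": d.centroid_xy_m[0],
            "centroid_y_m": d.centroid_xy_m[1],
            "area_m2": d.area_m2,
            "major_axis_m": d.major_axis_m,
            "minor_axis_m": d.minor_axis_m,
            "orientation_rad": d.orientation_rad,
            "n_pixels": d.n_pixels,
            "mean_dn": d.mean_dn,
            "mean_dn_per_band": d.mean_dn_per_band,
            "grid": d.grid,
        }
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_detections(path: str | Path) -> list[DetectionObject]:
    """Read detections written by :func:`write_detections` (GeoJSON/CSV).

    Pixel sets are not reconstructed; the returned objects carry the
    centroid, shape measures and class needed for evaluation.
    """
    path = Path(path)
    out: list[DetectionObject] = []

    def _mk(props: dict, x: float, y: float) -> DetectionObject:
        return DetectionObject(
            pixels=np.zeros((0, 2), dtype=int),
            grid=props.get("grid", "ms"),
            centroid_xy_m=(float(x), float(y)),
            area_m2=float(props.get("area_m2", 0.0)),
            major_axis_m=float(props.get("major_axis_m", 0.0)),
            minor_axis_m=float(props.get("minor_axis_m", 0.0)),
            orientation_rad=float(props.get("orientation_rad", 0.0)),
            mean_dn=float(props.get("mean_dn", 0.0)),
            source=props.get("source", "unknown"),
            detection_class=props.get("detection_class"),
        )

    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        for _, r in df.iterrows():
            out.append(_mk(r.to_dict(), r["x_m"], r["y_m"]))
        return out
    doc = json.loads(path.read_text())
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        out.append(_mk(props, props["centroid_x_m"], props["centroid_y_m"]))
    return out
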