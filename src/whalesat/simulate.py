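"""Synthetic WorldView2-like scene generator with known truth.

The generator emulates the imaging situation of a calm-sea whale census
scene: a near-uniform water background with per-band sensor noise (pan
noisier than the MS bands), a weak low-frequency surface-texture field,
whales rendered as ellipsoidal bright features with a brighter callus
spot at the head end, and the standard confounders — seabird clusters
(1-2 pan-pixel bright dots), diffuse bubble slicks, boats (uniform bright
rectangles with a linear wake, longer/brighter than any whale), and
subsurface rocks (bright in every band alike).

Submersion is modelled with a two-way Beer-Lambert attenuation: a whale at
depth d adds ``surface_contrast * exp(-K_d(band) * d)`` DN in each band,
where the diffuse attenuation coefficient K_d is strictly smallest for the
coastal band (band 5). That ordering is the mechanism behind the key
observed behaviour: all bands respond to surface features, but only the
coastal band responds to submerged ones. The coefficients are model
parameters, not physical claims; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .scene import (
    CATEGORIES,
    COASTAL_BAND_INDEX,
    BandSpec,
    MultibandScene,
    ReferenceAnnotation,
    SceneError,
    default_band_specs,
)

__all__ = [
    "SimulationConfig",
    "SceneTruth",
    "PlacementError",
    "simulate_scene",
    "whale_dn_contrast",
    "render_whale",
    "render_confounders",
    "band5_only_depth_window",
    "DEFAULT_ATTENUATION",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails after retries."""


#: Default two-way diffuse attenuation K_d per band, 1/m. The coastal band
#: (5) is strictly the minimum; red through NIR attenuate within metres.
DEFAULT_ATTENUATION: dict[int | str, float] = {
    1: 1.60,  # red
    2: 0.45,  # blue
    3: 0.55,  # green
    4: 0.80,  # yellow
    5: 0.20,  # coastal
    6: 3.00,  # red edge
    7: 5.00,  # nir1
    8: 6.00,  # nir2
    "pan": 1.30,
}


@dataclass
class SimulationConfig:
    """All knobs of the scene generator. Defaults are the study conditions.

    DN values are dimensionless digital numbers on an 11-bit scale;
    lengths/depths are metres. ``attenuation_coeff_per_band`` maps band
    index (1-8 or "pan") to the two-way K_d in 1/m.
    """

    ms_shape: tuple[int, int] = (128, 128)
    ms_gsd_m: float = 2.0
    origin_xy_m: tuple[float, float] = (0.0, 0.0)
    dn_max: int = 2047

    water_mean_dn: float = 300.0
    water_noise_sd: float = 8.0
    pan_noise_sd: float = 18.0
    surface_texture_amplitude_dn: float = 3.0
    texture_correlation_length_m: float = 40.0

    n_whales: int = 20
    whale_length_range_m: tuple[float, float] = (5.0, 15.0)
    whale_aspect_range: tuple[float, float] = (0.25, 0.45)
    depth_range_m: tuple[float, float] = (0.0, 2.0)
    whale_surface_contrast_dn: float = 150.0
    attenuation_coeff_per_band: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    callus_contrast_dn: float = 80.0
    callus_fraction: float = 0.15
    whale_pair_fraction: float = 0.0

    n_seabird_clusters: int = 0
    n_bubble_slicks: int = 0
    n_boats: int = 0
    n_rocks: int = 0
    pan_glint_density: float = 0.0

    min_separation_m: float = 20.0
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize band keys (JSON round-trips turn 1..8 into "1".."8")
        self.attenuation_coeff_per_band = {
            (int(k) if str(k).isdigit() else str(k)): float(v)
            for k, v in self.attenuation_coeff_per_band.items()
        }
        kd = self.attenuation_coeff_per_band
        k5 = kd[COASTAL_BAND_INDEX]
        for b, k in kd.items():
            if b != COASTAL_BAND_INDEX and k <= k5:
                raise ValueError(
                    "attenuation ordering violated: coastal K_d must be the "
                    f"strict minimum (band {b}: {k} <= {k5})"
                )
        lo, hi = self.whale_length_range_m
        if not (0 < lo <= hi):
            raise ValueError("invalid whale geometry: bad length range")
        if self.depth_range_m[0] < 0:
            raise ValueError("invalid depth: negative depth range")

    def band_specs(self) -> list[BandSpec]:
        return default_band_specs(self.ms_gsd_m, self.ms_gsd_m / 4.0)

    def noise_sd(self, band_index: int | str) -> float:
        return self.pan_noise_sd if band_index == "pan" else self.water_noise_sd


@dataclass
class SceneTruth:
    """Rendered-object truth: one annotation per object, plus the config."""

    annotations: list[ReferenceAnnotation]
    config: SimulationConfig


def whale_dn_contrast(
    surface_contrast_dn: float,
    depth_m: float,
    band: BandSpec | int | str,
    config: SimulationConfig,
) -> float:
    """DN contrast of a whale at depth in one band.

    ``surface_contrast * exp(-K_d(band) * depth)``: equals the surface
    contrast at depth 0 and decays monotonically, slowest in the coastal
    band.
    """
    if depth_m < 0:
        raise ValueError(f"invalid depth: {depth_m}")
    idx = band.band_index if isinstance(band, BandSpec) else band
    kd = config.attenuation_coeff_per_band[idx]
    return surface_contrast_dn * math.exp(-kd * depth_m)


def band5_only_depth_window(config: SimulationConfig) -> tuple[float, float]:
    """Depth interval where a whale is visible only in the coastal band.

    Solves the two exponential inequalities: coastal contrast >= 2x its
    noise SD (detectable) while every other band's contrast is < 1x its
    own noise SD (invisible). Lower bound is the max over the non-coastal
    bands; upper bound comes from the coastal band. Empty window (lo >= hi)
    is possible for pathological configs.
    """
    c0 = config.whale_surface_contrast_dn
    kd = config.attenuation_coeff_per_band
    lo = 0.0
    for b, k in kd.items():
        if b == COASTAL_BAND_INDEX:
            continue
        sd = config.noise_sd(b)
        if sd <= 0:
            # no noise floor: the band sees arbitrarily deep, no window
            return math.inf, math.inf
        if c0 > sd:
            lo = max(lo, math.log(c0 / sd) / k)
    sd5 = config.noise_sd(COASTAL_BAND_INDEX)
    if sd5 <= 0:
        return lo, math.inf
    hi = math.log(c0 / (2.0 * sd5)) / kd[COASTAL_BAND_INDEX] if c0 > 2 * sd5 else 0.0
    return lo, hi


# -- rendering helpers ------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    centre_rc: tuple[float, float],
    semi_major_px: float,
    semi_minor_px: float,
    orientation_rad: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean mask of a rotated ellipse, plus the bounding window used."""
    h, w = shape
    r0, c0 = centre_rc
    rad = max(semi_major_px, 1.0) + 1.5
    rlo, rhi = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
    clo, chi = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    # +0.5: pixel centres. Orientation: angle of the major axis from the
    # +col (east) direction, counterclockwise in world (northward-up) terms.
    dy = rr + 0.5 - r0
    dx = cc + 0.5 - c0
    ca, sa = math.cos(orientation_rad), math.sin(orientation_rad)
    u = dx * ca - dy * sa
    v = dx * sa + dy * ca
    mask = (u / max(semi_major_px, 1e-9)) ** 2 + (v / max(semi_minor_px, 1e-9)) ** 2 <= 1.0
    if not mask.any() and mask.size:
        # a thin ellipse can slip between pixel centres; the object still
        # covers its centre pixel, so light the nearest one
        rr0 = int(np.clip(round(r0 - 0.5), rlo, rhi - 1)) - rlo
        cc0 = int(np.clip(round(c0 - 0.5), clo, chi - 1)) - clo
        mask[rr0, cc0] = True
    return mask, (slice(rlo, rhi), slice(clo, chi))


def _add_ellipse(
    grid: np.ndarray,
    gsd: float,
    centre_rc: tuple[float, float],
    semi_major_m: float,
    semi_minor_m: float,
    orientation_rad: float,
    amplitude: float,
) -> np.ndarray:
    """Add a flat-top elliptical DN bump; returns the boolean footprint."""
    mask, win = _ellipse_mask(
        grid.shape, centre_rc, semi_major_m / gsd, semi_minor_m / gsd, orientation_rad
    )
    sub = grid[win]
    sub[mask] += amplitude
    foot = np.zeros(grid.shape, dtype=bool)
    foot[win][mask] = True
    return foot


def _world_to_rc(xy: tuple[float, float], origin: tuple[float, float], gsd: float):
    # continuous (row, col) of a world point; pixel centres at integer+0.5
    return (origin[1] - xy[1]) / gsd - 0.5, (xy[0] - origin[0]) / gsd - 0.5


class _Grids:
    """Float working copies of the MS stack + pan during rendering."""

    def __init__(self, config: SimulationConfig):
        h, w = config.ms_shape
        self.ms = np.zeros((8, h, w), dtype=np.float64)
        self.pan = np.zeros((4 * h, 4 * w), dtype=np.float64)
        self.config = config

    def band(self, index: int | str) -> np.ndarray:
        return self.pan if index == "pan" else self.ms[int(index) - 1]

    def gsd(self, index: int | str) -> float:
        return self.config.ms_gsd_m / 4.0 if index == "pan" else self.config.ms_gsd_m


def render_whale(
    grids: _Grids,
    centre_xy_m: tuple[float, float],
    length_m: float,
    aspect: float,
    orientation_rad: float,
    depth_m: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Render one whale into all bands; returns the pan-grid footprint mask.

    The body is a flat-top ellipse of per-band contrast given by
    :func:`whale_dn_contrast`; a circular callus spot of extra
    ``callus_contrast_dn`` (attenuated identically) sits at one semi-major
    end, making it the brightest part of the footprint.
    """
    lo, hi = config.whale_length_range_m
    if not (lo <= length_m <= hi):
        raise ValueError(f"invalid whale geometry: length {length_m} outside [{lo}, {hi}]")
    if depth_m < 0:
        raise ValueError(f"invalid depth: {depth_m}")
    a = length_m / 2.0
    b = a * aspect
    # callus at the head end, centred just inside the ellipse tip; the
    # callosity patch is well under a metre across, i.e. at most one pixel
    # even in pan, so it is deposited into the single containing pixel
    # (area-diluted in the coarser MS bands)
    head_xy = (
        centre_xy_m[0] + (a * (1 - config.callus_fraction)) * math.cos(orientation_rad),
        centre_xy_m[1] + (a * (1 - config.callus_fraction)) * math.sin(orientation_rad),
    )
    callus_area_m2 = 0.25
    pan_foot = None
    for band in ("pan", 1, 2, 3, 4, 5, 6, 7, 8):
        g = grids.band(band)
        gsd = grids.gsd(band)
        amp = whale_dn_contrast(config.whale_surface_contrast_dn, depth_m, band, config)
        camp = whale_dn_contrast(config.callus_contrast_dn, depth_m, band, config)
        rc = _world_to_rc(centre_xy_m, config.origin_xy_m, gsd)
        foot = _add_ellipse(g, gsd, rc, a, b, orientation_rad, amp)
        hr, hc = _world_to_rc(head_xy, config.origin_xy_m, gsd)
        hr, hc = int(round(hr)), int(round(hc))
        if 0 <= hr < g.shape[0] and 0 <= hc < g.shape[1]:
            g[hr, hc] += camp * min(1.0, callus_area_m2 / (gsd * gsd))
        if band == "pan":
            pan_foot = foot
    return pan_foot


def _place(
    rng: np.random.Generator,
    config: SimulationConfig,
    placed: list[tuple[float, float]],
    margin_m: float,
) -> tuple[float, float]:
    """Rejection-sample a centre keeping min_separation_m from others."""
    w_m = config.ms_shape[1] * config.ms_gsd_m
    h_m = config.ms_shape[0] * config.ms_gsd_m
    ox, oy = config.origin_xy_m
    if 2 * margin_m >= min(w_m, h_m):
        raise PlacementError("placement failure: object larger than scene")
    for _ in range(config.max_retries):
        x = ox + rng.uniform(margin_m, w_m - margin_m)
        y = oy - rng.uniform(margin_m, h_m - margin_m)
        if all(
            math.hypot(x - px, y - py) >= config.min_separation_m for px, py in placed
        ):
            placed.append((x, y))
            return x, y
    raise PlacementError("placement failure: could not place object without overlap")


def _render_whales(
    grids: _Grids, rng: np.random.Generator, config: SimulationConfig,
    placed: list[tuple[float, float]],
) -> list[ReferenceAnnotation]:
    anns = []
    for i in range(config.n_whales):
        length = rng.uniform(*config.whale_length_range_m)
        aspect = rng.uniform(*config.whale_aspect_range)
        orient = rng.uniform(0.0, 2 * math.pi)
        depth = rng.uniform(*config.depth_range_m)
        pair = rng.uniform() < config.whale_pair_fraction
        x, y = _place(rng, config, placed, margin_m=length)
        render_whale(grids, (x, y), length, aspect, orient, depth, config)
        if pair:
            # touching second ellipse (mother-and-calf style); truth keeps
            # one annotation, mirroring the manual digitizer's ambiguity
            calf_len = max(config.whale_length_range_m[0], 0.5 * length)
            off = (length / 2 + calf_len / 2)
            cx = x + off * math.cos(orient + math.pi / 2)
            cy = y + off * math.sin(orient + math.pi / 2)
            render_whale(grids, (cx, cy), calf_len, aspect, orient, depth, config)
        lo, hi = band5_only_depth_window(config)
        label = "band5_only" if depth > lo else "probable"
        anns.append(
            ReferenceAnnotation(
                object_id=f"whale_{i:03d}",
                centroid_xy_m=(x, y),
                length_m=length,
                class_label=label,
                depth_m=depth,
                category="whale",
            )
        )
    return anns


def render_confounders(
    grids: _Grids, rng: np.random.Generator, config: SimulationConfig,
    placed: list[tuple[float, float]],
) -> list[ReferenceAnnotation]:
    """Render the confounder taxonomy; returns their truth annotations.

    Seabird clusters: scattered 1-2 pan-pixel bright dots. Bubble slicks:
    diffuse low-contrast elongated patches. Boats: uniform bright
    rectangles (brighter than any whale) with a linear wake, > 16 m long.
    Rocks: bright patches rendered identically in every band (no depth
    attenuation — they are static surface-level reflectors).
    """
    anns: list[ReferenceAnnotation] = []
    pan_gsd = config.ms_gsd_m / 4.0

    for i in range(config.n_seabird_clusters):
        x, y = _place(rng, config, placed, margin_m=12.0)
        n_dots = int(rng.integers(8, 18))
        # jittered grid keeps dots >= ~2.5 m apart so pan components stay
        # 1-2 pixels and never merge into whale-sized blobs
        cells = [(gx, gy) for gx in range(-3, 4) for gy in range(-3, 4)]
        rng.shuffle(cells)
        for gx, gy in cells[:n_dots]:
            dx = gx * 3.0 + rng.uniform(-0.25, 0.25)
            dy = gy * 3.0 + rng.uniform(-0.25, 0.25)
            # a bird body is smaller than even a pan pixel, so its white is
            # area-diluted into the pixel and reads dimmer than a whale
            # back; a whale-level threshold suppresses dots as residuals
            amp = rng.uniform(0.25, 0.45) * config.whale_surface_contrast_dn
            # pan: a bright dot of 1-2 explicit pixels (a bird is sub-metre)
            pr = int(round((config.origin_xy_m[1] - (y + dy)) / pan_gsd - 0.5))
            pc = int(round(((x + dx) - config.origin_xy_m[0]) / pan_gsd - 0.5))
            px_list = [(pr, pc)]
            if rng.uniform() < 0.5:
                dr, dc = [(0, 1), (1, 0), (0, -1), (-1, 0)][int(rng.integers(4))]
                px_list.append((pr + dr, pc + dc))
            for r, c in px_list:
                if 0 <= r < grids.pan.shape[0] and 0 <= c < grids.pan.shape[1]:
                    grids.pan[r, c] += amp
            # MS: sub-pixel object -> dilute by covered-area fraction (1-2 of
            # the 16 pan pixels inside one MS pixel)
            mr = int(round((config.origin_xy_m[1] - (y + dy)) / config.ms_gsd_m - 0.5))
            mc = int(round(((x + dx) - config.origin_xy_m[0]) / config.ms_gsd_m - 0.5))
            if 0 <= mr < grids.ms.shape[1] and 0 <= mc < grids.ms.shape[2]:
                grids.ms[:, mr, mc] += amp * len(px_list) / 16.0
        anns.append(ReferenceAnnotation(f"seabirds_{i:03d}", (x, y), 10.0,
                                        "possible", None, "seabird_cluster"))

    for i in range(config.n_bubble_slicks):
        x, y = _place(rng, config, placed, margin_m=20.0)
        length = rng.uniform(15.0, 35.0)
        orient = rng.uniform(0.0, 2 * math.pi)
        amp = 1.5 * config.water_noise_sd
        for band in ("pan", 1, 2, 3, 4, 5, 6, 7, 8):
            g, gsd = grids.band(band), grids.gsd(band)
            rc = _world_to_rc((x, y), config.origin_xy_m, gsd)
            _add_ellipse(g, gsd, rc, length / 2, length / 6, orient, amp)
        anns.append(ReferenceAnnotation(f"bubbles_{i:03d}", (x, y), length,
                                        "possible", None, "bubble_slick"))

    for i in range(config.n_boats):
        length = rng.uniform(20.0, 30.0)
        x, y = _place(rng, config, placed, margin_m=length)
        orient = rng.uniform(0.0, 2 * math.pi)
        beam = rng.uniform(3.0, 5.0)
        amp = 1.5 * config.whale_surface_contrast_dn + 50.0  # brighter than any whale
        wake_len = rng.uniform(1.0, 1.6) * length
        wake_halfwidth_m = 0.5
        for band in ("pan", 1, 2, 3, 4, 5, 6, 7, 8):
            g, gsd = grids.band(band), grids.gsd(band)
            rc = _world_to_rc((x, y), config.origin_xy_m, gsd)
            # rectangle approximated by a high-aspect flat ellipse hull
            # with a stern-to-bow brightness ramp (superstructure towards
            # the bow), plus a linear wake trailing the stern; the ~1 m
            # foam line is sub-pixel in the MS bands, so area-diluted there
            mask, win = _ellipse_mask(g.shape, rc, (length / 2) / gsd,
                                      (beam / 2) / gsd, orient)
            rr, cc = np.mgrid[win[0], win[1]]
            ca, sa = math.cos(orient), math.sin(orient)
            u = ((cc + 0.5 - rc[1]) * ca - (rr + 0.5 - rc[0]) * sa) * gsd
            ramp = 1.0 + 0.3 * np.clip(u / (length / 2), -1.0, 1.0)
            sub = g[win]
            sub[mask] += amp * ramp[mask]
            wx = x - (length / 2 + wake_len / 2) * math.cos(orient)
            wy = y - (length / 2 + wake_len / 2) * math.sin(orient)
            wrc = _world_to_rc((wx, wy), config.origin_xy_m, gsd)
            dilution = min(1.0, 2 * wake_halfwidth_m / gsd)
            _add_ellipse(g, gsd, wrc, wake_len / 2, max(wake_halfwidth_m, gsd * 0.51),
                         orient, 0.2 * config.whale_surface_contrast_dn * dilution)
        anns.append(ReferenceAnnotation(f"boat_{i:03d}", (x, y), length,
                                        "possible", None, "boat"))

    for i in range(config.n_rocks):
        x, y = _place(rng, config, placed, margin_m=10.0)
        size = rng.uniform(4.0, 12.0)
        orient = rng.uniform(0.0, 2 * math.pi)
        amp = rng.uniform(0.8, 1.1) * config.whale_surface_contrast_dn
        for band in ("pan", 1, 2, 3, 4, 5, 6, 7, 8):
            g, gsd = grids.band(band), grids.gsd(band)
            rc = _world_to_rc((x, y), config.origin_xy_m, gsd)
            # identical amplitude in all bands: no water-column attenuation
            _add_ellipse(g, gsd, rc, size / 2, size / 3, orient, amp)
        anns.append(ReferenceAnnotation(f"rock_{i:03d}", (x, y), size,
                                        "possible", None, "rock"))
    return anns


def _texture_field(rng, shape, gsd, amplitude, corr_len_m):
    if amplitude <= 0:
        return np.zeros(shape)
    sigma_px = max(corr_len_m / gsd, 1.0)
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma_px, mode="reflect")
    sd = f.std()
    return f * (amplitude / sd) if sd > 0 else f


def simulate_scene(config: SimulationConfig) -> tuple[MultibandScene, SceneTruth]:
    """Generate one scene + truth, deterministic for a given config/seed.

    Draw order is fixed (background, whales, confounders) so partial
    configs stay reproducible. DN grids are clipped to [0, dn_max] and
    quantized to uint16 at the end.
    """
    rng = np.random.default_rng(config.seed)
    grids = _Grids(config)
    h, w = config.ms_shape

    # background: mean + shared low-frequency surface texture + per-band noise
    tex = _texture_field(rng, (h, w), config.ms_gsd_m,
                         config.surface_texture_amplitude_dn,
                         config.texture_correlation_length_m)
    tex_pan = np.kron(tex, np.ones((4, 4)))
    for b in range(8):
        grids.ms[b] += config.water_mean_dn + tex
        if config.water_noise_sd > 0:
            grids.ms[b] += rng.normal(0.0, config.water_noise_sd, size=(h, w))
    grids.pan += config.water_mean_dn + tex_pan
    if config.pan_noise_sd > 0:
        grids.pan += rng.normal(0.0, config.pan_noise_sd, size=grids.pan.shape)
    if config.pan_glint_density > 0:
        n = int(config.pan_glint_density * grids.pan.size)
        rr = rng.integers(0, grids.pan.shape[0], n)
        cc = rng.integers(0, grids.pan.shape[1], n)
        grids.pan[rr, cc] += rng.uniform(3, 8, n) * config.pan_noise_sd

    placed: list[tuple[float, float]] = []
    anns = _render_whales(grids, rng, config, placed)
    anns += render_confounders(grids, rng, config, placed)

    ms = np.clip(np.rint(grids.ms), 0, config.dn_max).astype(np.uint16)
    pan = np.clip(np.rint(grids.pan), 0, config.dn_max).astype(np.uint16)
    scene = MultibandScene(
        ms_stack=ms,
        pan=pan,
        origin_xy_m=config.origin_xy_m,
        band_specs=config.band_specs(),
        dn_max=config.dn_max,
    )
    return scene, SceneTruth(annotations=anns, config=config)
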