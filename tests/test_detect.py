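"""Detection: components, threshold optimization, clustering, classing."""

import math
import warnings
from collections import deque

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from skimage import measure

from whalesat import (
    ClassSignature,
    DetectionConfig,
    SimulationConfig,
    band_cross_section,
    band5_only_depth_window,
    classify_detections,
    detect_whales,
    isodata_segment,
    kmeans_segment,
    label_components,
    match_detections,
    maxlike_segment,
    optimize_threshold,
    shape_filter,
    simulate_scene,
    threshold_segment,
)
from whalesat.detect import DetectionObject, kmeans_fit, signature_from_pixels


# -- independent oracles -----------------------------------------------------


def flood_fill_components(binary, connectivity):
    """Brute-force BFS component count (independent of scipy/skimage)."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary)
    sizes = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                q = deque([(r, c)])
                seen[r, c] = True
                size = 0
                while q:
                    rr, cc = q.popleft()
                    size += 1
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
                sizes.append(size)
    return sizes


def exhaustive_best_threshold(grid, connectivity=8, max_frac=0.02):
    """Independent exhaustive threshold search (skimage labeller)."""
    grid = np.asarray(grid)
    lo, hi = int(np.median(grid)), int(grid.max())
    best = None
    for t in range(lo, hi):
        if (grid > t).mean() > max_frac:
            continue
        lab = measure.label(grid > t, connectivity=2 if connectivity == 8 else 1)
        sizes = np.bincount(lab.ravel())[1:]
        ratio = int((sizes >= 2).sum()) / max(int((sizes == 1).sum()), 1)
        if best is None or ratio >= best[0]:
            best = (ratio, t)
    return best


# -- connected components ----------------------------------------------------


@pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
def test_diagonal_pixels_connectivity(connectivity, expected):
    g = np.zeros((4, 4), dtype=bool)
    g[1, 1] = g[2, 2] = True
    _, n = label_components(g, connectivity)
    assert n == expected


def test_all_false_grid_has_no_components():
    _, n = label_components(np.zeros((5, 5), dtype=bool), 8)
    assert n == 0


@pytest.mark.parametrize("connectivity", [4, 8])
def test_label_components_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(123)
    for _ in range(100):
        g = rng.random((20, 20)) < 0.35
        labels, n = label_components(g, connectivity)
        oracle_sizes = sorted(flood_fill_components(g, connectivity))
        assert n == len(oracle_sizes)
        assert sorted(np.bincount(labels.ravel())[1:].tolist()) == oracle_sizes


# -- threshold optimization --------------------------------------------------


def test_single_blob_chooses_highest_plateau_threshold():
    g = np.full((50, 50), 100, dtype=np.uint16)
    g[10:12, 10:15] = 500  # one 10-px blob
    res = optimize_threshold(g)
    assert 100 < res.threshold_dn < 500
    assert res.threshold_dn == 499  # tie-break toward the higher threshold
    assert res.n_multi_pixel_components == 1
    assert res.n_single_pixel_components == 0
    assert res.ratio == 1.0


def test_isolated_singles_push_threshold_up():
    rng = np.random.default_rng(5)
    g = np.full((200, 200), 100, dtype=np.uint16)
    g[5:10, 5:11] = 500  # one 30-px blob
    # 200 isolated single bright pixels at DN 400, on a sparse lattice so
    # they never touch each other or the blob
    placed = 0
    for cell in rng.permutation(99 * 99):
        r, c = divmod(int(cell), 99)
        rr, cc = 2 * r, 2 * c
        if g[rr, cc] == 100 and not (g[max(rr - 1, 0):rr + 2, max(cc - 1, 0):cc + 2] > 100).any():
            g[rr, cc] = 400
            placed += 1
        if placed == 200:
            break
    assert placed == 200
    res = optimize_threshold(g)
    assert res.threshold_dn >= 400
    assert res.n_single_pixel_components == 0


def test_empty_candidate_set_rejected():
    with pytest.raises(ValueError, match="empty candidate set"):
        optimize_threshold(np.full((10, 10), 7, dtype=np.uint16), candidate_thresholds=[])


def test_no_signal_above_threshold():
    with pytest.raises(ValueError, match="no signal above threshold"):
        optimize_threshold(np.full((10, 10), 7, dtype=np.uint16), candidate_thresholds=[7, 8])


def test_optimizer_matches_exhaustive_oracle_on_simulated_bands():
    for seed in range(50):
        cfg = SimulationConfig(seed=seed, ms_shape=(40, 40), n_whales=3,
                               depth_range_m=(0.0, 0.0), min_separation_m=18.0)
        scene, _ = simulate_scene(cfg)
        g = scene.coastal
        res = optimize_threshold(g)
        ratio, t = exhaustive_best_threshold(g)
        assert res.threshold_dn == t
        assert res.ratio == pytest.approx(ratio)


def test_threshold_counts_verifiable_by_labeller(surface_scene):
    scene, _ = surface_scene
    res = optimize_threshold(scene.coastal)
    labels, _ = label_components(scene.coastal > res.threshold_dn, 8)
    sizes = np.bincount(labels.ravel())[1:]
    assert res.n_multi_pixel_components == int((sizes >= 2).sum())
    assert res.n_single_pixel_components == int((sizes == 1).sum())


# -- segmentation to objects -------------------------------------------------


def test_threshold_segment_single_blob():
    g = np.full((50, 50), 100, dtype=np.uint16)
    g[10:12, 10:15] = 500
    objs = threshold_segment(g, 300, gsd_m=2.0)
    assert len(objs) == 1
    assert objs[0].area_m2 == pytest.approx(10 * 4.0)
    assert threshold_segment(g, 2047, gsd_m=2.0) == []


def test_moments_recover_ellipse_axes():
    cfg = SimulationConfig(seed=1, n_whales=1, whale_length_range_m=(12.0, 12.0),
                           whale_aspect_range=(1 / 3, 1 / 3), depth_range_m=(0.0, 0.0),
                           water_noise_sd=0.0, pan_noise_sd=0.0,
                           surface_texture_amplitude_dn=0.0)
    scene, _ = simulate_scene(cfg)
    objs = threshold_segment(scene.pan, cfg.water_mean_dn + 5, gsd_m=0.5, grid_name="pan")
    assert len(objs) == 1
    assert objs[0].major_axis_m == pytest.approx(12.0, rel=0.2)
    assert objs[0].minor_axis_m == pytest.approx(4.0, rel=0.2)


# -- shape filter ------------------------------------------------------------


def _mk_obj(major, minor, n_pixels, grid="ms", centroid=(0.0, 0.0)):
    gsd = 2.0 if grid == "ms" else 0.5
    return DetectionObject(
        pixels=np.zeros((n_pixels, 2), dtype=int), grid=grid, centroid_xy_m=centroid,
        area_m2=n_pixels * gsd * gsd, major_axis_m=major, minor_axis_m=minor,
        orientation_rad=0.0, mean_dn=400.0, source="threshold_band5",
    )


def test_shape_filter_rules():
    boat = _mk_obj(30.0, 4.0, 60)
    whale = _mk_obj(10.0, 3.5, 9)
    single = _mk_obj(0.0, 0.0, 1)
    kept, rejected = shape_filter([boat, whale, single])
    assert rejected == [boat]
    assert any(o is whale for o in kept) and any(o is single for o in kept)
    assert whale.shape_pass is True
    assert single.shape_pass is False  # kept, but flagged for "possible"


def test_shape_filter_keeps_whales_rejects_boats_on_simulated_scene():
    # generous separation so a whale never fuses with an adjacent boat's
    # component (that case is a placement question, not a filter one)
    cfg = SimulationConfig(seed=101, depth_range_m=(0.0, 0.0), n_whales=10,
                           n_boats=5, n_seabird_clusters=8, ms_shape=(192, 192),
                           min_separation_m=45.0)
    scene, truth = simulate_scene(cfg)
    res = optimize_threshold(scene.coastal)
    objs = threshold_segment(scene.coastal, res.threshold_dn, gsd_m=2.0,
                             origin_xy_m=scene.origin_xy_m)
    kept, _ = shape_filter(objs)
    match = match_detections(kept, truth.annotations, 10.0)
    matched_cats = [truth.annotations[j].category for _, j, _ in match.pairs]
    assert matched_cats.count("whale") == 10
    assert matched_cats.count("boat") == 0


# -- k-means and ISODATA -----------------------------------------------------


def test_kmeans_recovers_two_separated_populations():
    rng = np.random.default_rng(8)
    g = rng.normal(300, 5, size=(60, 60))
    truth = rng.random((60, 60)) < 0.3
    g[truth] += 200
    labels = kmeans_segment(g, 2)
    hi = labels == labels[truth].flat[0]
    agreement = (hi == truth).mean()
    assert agreement >= 0.99


def test_kmeans_k1_single_label():
    g = np.random.default_rng(0).normal(300, 10, size=(20, 20))
    assert set(np.unique(kmeans_segment(g, 1))) == {0}


def test_kmeans_objective_monotone(surface_scene):
    scene, _ = surface_scene
    _, _, history = kmeans_fit(scene.ms_stack.astype(float), 5)
    assert all(history[i + 1] <= history[i] + 1e-6 for i in range(len(history) - 1))


def test_isodata_degenerates_to_kmeans(surface_scene):
    scene, _ = surface_scene
    stack = scene.ms_stack.astype(float)
    km = kmeans_segment(stack, 3)
    iso = isodata_segment(stack, 3, min_cluster_size=1, split_sd=math.inf, merge_dist=0.0)
    assert np.array_equal(km, iso)


def test_isodata_splits_into_three_populations():
    rng = np.random.default_rng(3)
    g = np.concatenate([
        rng.normal(100, 3, 4000), rng.normal(300, 3, 4000), rng.normal(600, 3, 4000)
    ]).reshape(120, 100)
    labels = isodata_segment(g, 2, split_sd=30.0, min_cluster_size=1)
    assert len(np.unique(labels)) == 3


def test_isodata_discards_undersized_clusters():
    rng = np.random.default_rng(4)
    g = np.concatenate([
        rng.normal(100, 2, 5000), rng.normal(500, 2, 5000), rng.normal(900, 2, 5)
    ])
    rng.shuffle(g)
    g = g.reshape(-1, 1)
    labels = isodata_segment(g, 3, min_cluster_size=50)
    sizes = np.bincount(labels.ravel())
    assert (sizes[sizes > 0] >= 50).all()


# -- maximum likelihood ------------------------------------------------------


def test_pixel_at_class_mean_gets_that_class():
    sigs = [
        ClassSignature("a", np.array([10.0, 10.0]), np.eye(2)),
        ClassSignature("b", np.array([50.0, 50.0]), np.eye(2)),
    ]
    stack = np.array([[[10.0, 50.0]], [[10.0, 50.0]]])  # (2 bands, 1, 2)
    labels = maxlike_segment(stack, sigs)
    assert labels[0, 0] == 0 and labels[0, 1] == 1


def test_maxlike_matches_brute_force_likelihoods():
    rng = np.random.default_rng(17)
    stack = rng.normal(300, 40, size=(4, 10, 10))
    sigs = []
    for i in range(3):
        mean = rng.normal(300, 30, size=4)
        a = rng.normal(0, 1, size=(4, 4))
        sigs.append(ClassSignature(f"c{i}", mean, a @ a.T + 5 * np.eye(4)))
    labels = maxlike_segment(stack, sigs)
    x = stack.reshape(4, -1).T
    oracle = np.array([
        np.argmax([multivariate_normal.logpdf(px, s.mean_dn_per_band, s.covariance)
                   for s in sigs])
        for px in x
    ]).reshape(10, 10)
    assert np.array_equal(labels, oracle)


def test_singular_covariance_ridge_regularized():
    sigs = [
        ClassSignature("flat", np.array([10.0, 10.0]), np.zeros((2, 2))),
        ClassSignature("b", np.array([50.0, 50.0]), np.eye(2)),
    ]
    stack = np.full((2, 3, 3), 10.0)
    with pytest.warns(UserWarning, match="ridge"):
        labels = maxlike_segment(stack, sigs)
    assert (labels == 0).all()


# -- cross sections ----------------------------------------------------------


def test_cross_section_constant_grid_and_length(quiet_scene):
    scene, _ = quiet_scene
    profiles = band_cross_section(scene, (1.0, -1.0), (50.0, -1.0), 77)
    assert len(profiles) == 9
    assert all(len(p) == 77 for p in profiles.values())
    with pytest.raises(Exception, match="outside scene"):
        band_cross_section(scene, (0.0, 0.0), (1e5, 0.0), 10)


def test_cross_section_surface_vs_submerged_whale():
    base = SimulationConfig()
    lo, hi = band5_only_depth_window(base)
    for depth, expect_band5_only in [(0.0, False), (0.5 * (lo + hi), True)]:
        cfg = SimulationConfig(seed=6, n_whales=1, depth_range_m=(depth, depth),
                               whale_length_range_m=(12.0, 12.0),
                               water_noise_sd=0.0, pan_noise_sd=0.0,
                               surface_texture_amplitude_dn=0.0)
        scene, truth = simulate_scene(cfg)
        x, y = truth.annotations[0].centroid_xy_m
        profiles = band_cross_section(scene, (x - 15, y), (x + 15, y), 61)
        for name, prof in profiles.items():
            sd = base.pan_noise_sd if name == "pan" else base.water_noise_sd
            peak = prof.max() - cfg.water_mean_dn
            if expect_band5_only and name != "coastal":
                assert peak < sd
            else:
                assert peak >= 2 * sd


# -- classification and end-to-end -------------------------------------------


def test_classify_rule_application():
    whale = _mk_obj(10.0, 3.5, 9, grid="pan")
    whale.source = "threshold_pan"
    deep = _mk_obj(6.0, 2.5, 4, centroid=(60.0, -60.0))
    weak = _mk_obj(4.0, 2.0, 2, centroid=(120.0, -120.0))
    weak.source = "kmeans"
    out = classify_detections([whale], [deep], primary=[whale, deep, weak])
    assert whale.detection_class == "probable"
    assert deep.detection_class == "band5_only"
    assert weak.detection_class == "possible"


def test_detect_whales_unknown_method(surface_scene):
    with pytest.raises(ValueError, match="unknown method"):
        detect_whales(surface_scene[0], "random_forest")


def test_detect_whales_empty_scene_gives_empty_list():
    cfg = SimulationConfig(seed=0, n_whales=0, water_noise_sd=0.0, pan_noise_sd=0.0,
                           surface_texture_amplitude_dn=0.0, ms_shape=(48, 48))
    scene, _ = simulate_scene(cfg)
    assert detect_whales(scene, "threshold_band5") == []


def test_detect_whales_deterministic(surface_scene):
    scene, _ = surface_scene
    d1 = detect_whales(scene, "threshold_band5")
    d2 = detect_whales(scene, "threshold_band5")
    assert [(o.centroid_xy_m, o.detection_class) for o in d1] == [
        (o.centroid_xy_m, o.detection_class) for o in d2
    ]


def test_low_noise_surface_whales_all_probable():
    cfg = SimulationConfig(seed=5, n_whales=20, depth_range_m=(0.0, 0.0),
                           whale_length_range_m=(8.0, 15.0),
                           water_noise_sd=0.0, pan_noise_sd=0.0,
                           surface_texture_amplitude_dn=0.0)
    scene, truth = simulate_scene(cfg)
    dets = detect_whales(scene, "threshold_band5")
    assert len(dets) == 20
    assert all(d.detection_class == "probable" for d in dets)


def test_object_centroid_consistent_with_pixels(surface_scene):
    scene, _ = surface_scene
    for obj in detect_whales(scene, "threshold_band5"):
        gsd = scene.grid_gsd(obj.grid)
        r_bar = obj.pixels[:, 0].mean()
        c_bar = obj.pixels[:, 1].mean()
        cx = scene.origin_xy_m[0] + (c_bar + 0.5) * gsd
        cy = scene.origin_xy_m[1] - (r_bar + 0.5) * gsd
        assert obj.centroid_xy_m == pytest.approx((cx, cy))
        assert obj.major_axis_m >= obj.minor_axis_m


def test_maxlike_more_false_positives_than_thresholding(surface_scene):
    scene, truth = surface_scene
    rng = np.random.default_rng(0)
    flat = scene.ms_stack.reshape(8, -1).T.astype(float)
    water = flat[rng.choice(flat.shape[0], 400, replace=False)]
    whale_px = []
    from whalesat.scene import world_to_pixel

    for a in truth.annotations:
        r, c = world_to_pixel(scene, a.centroid_xy_m, "ms")
        whale_px.append(scene.ms_stack[:, r, c].astype(float))
    # deliberately broad/overlapping signatures
    water_sig = signature_from_pixels("water", water)
    whale_sig = signature_from_pixels("whale", np.array(whale_px))
    whale_sig.covariance = whale_sig.covariance + 400 * np.eye(8)
    dets_ml = detect_whales(scene, "maxlike",
                            DetectionConfig(signatures=[water_sig, whale_sig]))
    dets_th = detect_whales(scene, "threshold_band5")
    fp_ml = len(match_detections(dets_ml, truth.annotations).unmatched_detections)
    fp_th = len(match_detections(dets_th, truth.annotations).unmatched_detections)
    assert fp_ml >= fp_th
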