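"""Spot detection/localization, density QC, traces, bleach-step counting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from smtpipe.localize import (
    IntensityTrace,
    SpotDetection,
    count_bleach_steps,
    detect_spots,
    detect_stack,
    estimate_density,
    extract_trace,
)
from smtpipe.render import MovieSpec, render_movie
from smtpipe.simulate import Trajectory


def _one_emitter_movie(x_um, y_um, n_frames=1, poisson=True, seed=3, **kw):
    spec = MovieSpec(field_size=5.0, photons_per_spot=500.0, background=10.0, **kw)
    t = Trajectory(0, np.arange(max(n_frames, 2)),
                   np.full(max(n_frames, 2), x_um), np.full(max(n_frames, 2), y_um))
    stack, truth = render_movie([t], spec, seed=seed, n_frames=n_frames,
                                poisson=poisson)
    return stack, truth, spec


def test_background_only_frame_has_no_detections():
    spec = MovieSpec(field_size=5.0)
    stack, _ = render_movie([], spec, seed=4, n_frames=1)
    assert detect_spots(stack[0], spec.pixel_size, spec.psf_sigma) == []


def test_constant_image_is_empty_not_an_error():
    assert detect_spots(np.ones((64, 64)), 0.1, 0.1) == []


def test_noiseless_localization_bias_is_negligible():
    """On a noiseless symmetric spot (float image, no quantization) the
    fitted position is exact to better than 1e-3 px."""
    from smtpipe.render import _add_spot

    pixel_size, psf_sigma = 0.107, 0.1
    x_um, y_um = 2.4817, 2.5133
    img = np.full((48, 48), 10.0)
    _add_spot(img, x_um / pixel_size - 0.5, y_um / pixel_size - 0.5,
              psf_sigma / pixel_size, 500.0)
    dets = detect_spots(img, pixel_size, psf_sigma)
    assert len(dets) == 1
    assert abs(dets[0].x - x_um) / pixel_size < 1e-3
    assert abs(dets[0].y - y_um) / pixel_size < 1e-3


def test_single_emitter_localized_within_a_tenth_pixel():
    """Shot-noise-limited localization: median error over independent
    frames below 0.1 px at SNR ≈ 10."""
    stack, _, spec = _one_emitter_movie(2.4817, 2.5133, n_frames=15, seed=12)
    errs = []
    for f in range(stack.shape[0]):
        dets = detect_spots(stack[f], spec.pixel_size, spec.psf_sigma, frame=f)
        assert len(dets) == 1
        errs.append(np.hypot(dets[0].x - 2.4817, dets[0].y - 2.5133)
                    / spec.pixel_size)
    assert np.median(errs) < 0.1


def test_detection_recall_and_precision_at_study_density(field_movie):
    """At 0.2 spots/µm² recall and precision against ground truth are
    both ≥ 0.9 (match radius 2 px), away from the un-fittable border."""
    ms = field_movie["movie_spec"]
    truth = field_movie["truth"]
    dets = detect_stack(field_movie["stack"], ms.pixel_size, ms.psf_sigma,
                        frames=range(5))
    margin = 4 * ms.pixel_size  # fit window half-width
    r_match = 2 * ms.pixel_size
    tp = fp = fn = 0
    for f in range(5):
        g = truth[truth.frame == f]
        inside = g[(g.x_um > margin) & (g.x_um < 25.6 - margin)
                   & (g.y_um > margin) & (g.y_um < 25.6 - margin)]
        tree = cKDTree(inside[["x_um", "y_um"]].to_numpy())
        matched = set()
        for d in dets[f]:
            dist, idx = tree.query([d.x, d.y])
            if dist <= r_match and idx not in matched:
                matched.add(idx)
                tp += 1
            else:
                fp += 1
        fn += len(inside) - len(matched)
    assert tp / (tp + fn) >= 0.9
    assert tp / (tp + fp) >= 0.9


def test_density_arithmetic():
    dets = {0: [SpotDetection(0, 1.0, 1.0, 1.0, 0.1, 5.0)] * 131}
    assert estimate_density(dets, 25.6 * 25.6) == pytest.approx(131 / 655.36)
    assert estimate_density({0: []}, 100.0) == 0.0
    with pytest.raises(ValueError, match="area"):
        estimate_density(dets, 0.0)


def test_density_recovered_from_rendered_movie(field_movie):
    ms = field_movie["movie_spec"]
    dets = detect_stack(field_movie["stack"], ms.pixel_size, ms.psf_sigma,
                        frames=range(10))
    rho = estimate_density(dets, 25.6**2)
    assert rho == pytest.approx(0.2, rel=0.10)


def test_trace_constant_emitter_and_empty_region():
    stack, _, spec = _one_emitter_movie(2.5, 2.5, n_frames=20, seed=6)
    tr = extract_trace(stack, (2.5, 2.5), spec.pixel_size)
    assert tr.values.mean() == pytest.approx(500.0, rel=0.15)
    assert tr.values.std() < 0.2 * tr.values.mean()
    # empty corner: mean consistent with zero
    tr0 = extract_trace(stack, (0.8, 0.8), spec.pixel_size)
    assert abs(tr0.values.mean()) < 30.0
    assert tr0.clipped  # annulus runs off the edge


def test_trace_drops_after_bleach():
    spec = MovieSpec(field_size=5.0, photons_per_spot=500.0, background=10.0,
                     bleach_prob=0.15)
    t = Trajectory(0, np.arange(60), np.full(60, 2.5), np.full(60, 2.5))
    stack, truth = render_movie([t], spec, seed=21, n_frames=60)
    k = int(truth[truth.alive == 0]["frame"].min())
    assert 0 < k < 60  # bleaching did occur at this seed
    tr = extract_trace(stack, (2.5, 2.5), spec.pixel_size)
    assert tr.values[:k].mean() > 300.0
    assert abs(tr.values[k:].mean()) < 50.0


def test_bleach_step_counting():
    rng = np.random.default_rng(0)
    frames = np.arange(100)
    # constant + noise: no step
    flat = IntensityTrace(frames, 1000 + 30 * rng.normal(size=100))
    assert count_bleach_steps(flat)[0] == 0
    # single 1000 -> 0 step at frame 50, SNR 10
    v = np.where(frames < 50, 1000.0, 0.0) + 100 * rng.normal(size=100)
    n, steps = count_bleach_steps(IntensityTrace(frames, v))
    assert n == 1
    assert abs(steps[0] - 50) <= 1
    # two-emitter staircase: two steps
    f2 = np.arange(120)
    v2 = np.where(f2 < 40, 2000.0, np.where(f2 < 80, 1000.0, 0.0))
    v2 = v2 + 80 * rng.normal(size=120)
    n2, steps2 = count_bleach_steps(IntensityTrace(f2, v2))
    assert n2 == 2
    assert abs(steps2[0] - 40) <= 1 and abs(steps2[1] - 80) <= 1


def test_upward_jumps_are_not_bleach_steps():
    frames = np.arange(100)
    v = np.where(frames < 50, 0.0, 1000.0)  # an appearing emitter
    assert count_bleach_steps(IntensityTrace(frames, v))[0] == 0


def test_bleach_false_positive_rate_below_five_percent():
    rng = np.random.default_rng(77)
    fp = 0
    for _ in range(200):
        tr = IntensityTrace(np.arange(80), 500 + 40 * rng.normal(size=80))
        fp += count_bleach_steps(tr)[0] > 0
    assert fp / 200 <= 0.05


def test_short_trace_rejected():
    with pytest.raises(ValueError, match="short"):
        count_bleach_steps(IntensityTrace(np.arange(5), np.ones(5)))
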