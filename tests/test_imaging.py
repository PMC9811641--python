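"""Shadowgraph metrology on hand-built and rendered frames."""

import numpy as np
import pytest

from cavibridge import imaging
from cavibridge.imaging import FrameStack


PX = imaging.DEFAULT_PIXEL_SIZE


def disk_mask(shape, center, radius):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def bridge_frame(shape=(200, 300), center=(100, 160), radius=90):
    """Bright background with a dark bridge disk."""
    frame = np.full(shape, 230, dtype=np.uint8)
    frame[disk_mask(shape, center, radius)] = 60
    return frame, center, radius


class TestBinarize:
    def test_uniform_bright_frame_empty_mask(self):
        frame = np.full((50, 50), 240, dtype=np.uint8)
        assert not imaging.binarize(frame, "otsu").any()

    def test_rendered_disk_area_within_one_percent(self):
        frame, center, radius = bridge_frame()
        mask = imaging.binarize(frame, "otsu")
        truth = disk_mask(frame.shape, center, radius).sum()
        assert abs(mask.sum() - truth) / truth < 0.01

    def test_fixed_threshold_complement_involution(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, size=(40, 60)).astype(np.uint8)
        t = 128
        direct = imaging.binarize(frame, "fixed", t)
        flipped = imaging.binarize(255 - frame, "fixed", 256 - t)
        assert np.array_equal(flipped, ~direct)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            imaging.binarize(np.empty((0, 0), dtype=np.uint8))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            imaging.binarize(np.zeros((5, 5), dtype=np.uint8), "adaptive")


def render_parabolic_stack(u_c=10.0, n_frames=30, noise_sigma=0.0, seed=0):
    """Minimal renderer with exact ground truth for profile/front tests."""
    shape = (200, 300)
    origin = (100, 20)
    d_cb = 2 * 95 * PX
    bridge = disk_mask(shape, (100, 115), 95)
    a = 2e-3  # crater-law coefficient, m^2/s
    dt = imaging.DEFAULT_DT
    frames = np.empty((n_frames,) + shape, dtype=np.uint8)
    truth_front = np.full(n_frames, np.nan)
    cc = np.arange(shape[1])[None, :]
    rr = np.arange(shape[0])[:, None]
    for i in range(n_frames):
        t = i * dt
        frame = np.full(shape, 230, dtype=np.uint8)
        frame[bridge] = 60
        xi = (cc - origin[1]) * PX
        with np.errstate(invalid="ignore"):
            r_px = np.sqrt(np.clip(a * (t - xi / u_c), 0, None)) / PX
        cavity = bridge & (xi >= 0) & (xi <= u_c * t) & (np.abs(rr - origin[0]) <= r_px) & (r_px >= 0.5)
        frame[cavity] = 230
        occ = np.nonzero(cavity.any(axis=0)[origin[1]:])[0]
        if occ.size:
            truth_front[i] = occ.max() * PX
        frames[i] = frame
    if noise_sigma:
        rng = np.random.default_rng(seed)
        frames = np.clip(
            frames.astype(float) + rng.normal(0, noise_sigma, frames.shape), 0, 255
        ).astype(np.uint8)
    stack = FrameStack(frames, dt=dt, pixel_size=PX, origin=origin, axis=(0, 1))
    br = imaging.analytic_bridge_mask(shape, origin, (0, 1), d_cb, PX)
    return stack, br, a, truth_front


class TestCavityProfile:
    def test_pre_impact_frame_yields_empty_profile(self):
        frame, center, radius = bridge_frame()
        mask = imaging.binarize(frame, "otsu")
        x, r = imaging.extract_cavity_profile(mask, (100, 70), (0, 1))
        assert x.size == 0 and r.size == 0

    def test_rendered_parabola_recovered_to_one_pixel(self):
        stack, br, a, _ = render_parabolic_stack()
        i = 8
        t = i * stack.dt
        mask = imaging.binarize(stack.frames[i], "fixed", 128)
        x, r = imaging.extract_cavity_profile(
            mask, stack.origin, stack.axis, PX, bridge=br
        )
        u_c = 10.0
        expected = np.sqrt(np.clip(a * (t - x / u_c), 0, None))
        # compare away from the curved mouth, where the bridge boundary clips
        sel = (x > 0.15 * u_c * t) & (expected > 0)
        assert np.all(np.abs(r[sel] - expected[sel]) <= 1.5 * PX)

    def test_front_position_within_one_pixel(self):
        stack, br, _, truth_front = render_parabolic_stack()
        i = 8
        mask = imaging.binarize(stack.frames[i], "fixed", 128)
        x, r = imaging.extract_cavity_profile(
            mask, stack.origin, stack.axis, PX, bridge=br
        )
        assert abs(x[-1] - truth_front[i]) <= PX


class TestFrontVelocity:
    def test_noise_free_within_two_percent(self):
        stack, br, _, _ = render_parabolic_stack(u_c=10.0)
        m = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        u, err = imaging.fit_front_velocity(stack, m)
        assert u == pytest.approx(10.0, rel=0.02)

    def test_noisy_within_five_percent(self):
        stack, br, _, _ = render_parabolic_stack(u_c=10.0, noise_sigma=5.0, seed=3)
        m = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        u, err = imaging.fit_front_velocity(stack, m)
        assert u == pytest.approx(10.0, rel=0.05)

    def test_stationary_cavity_zero_velocity(self):
        stack, br, _, _ = render_parabolic_stack(u_c=10.0, n_frames=12)
        frames = np.repeat(stack.frames[8][None], 12, axis=0)
        frozen = FrameStack(frames, stack.dt, PX, stack.origin, stack.axis)
        m = imaging.analyze_stack(frozen, "fixed", 128, bridge=br)
        u, err = imaging.fit_front_velocity(frozen, m)
        assert u == 0.0

    def test_too_few_frames_rejected(self):
        stack, br, _, _ = render_parabolic_stack(n_frames=3)
        m = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        with pytest.raises(imaging.InsufficientDataError):
            imaging.fit_front_velocity(stack, m)


def blob_with_bubbles(bubbles, shape=(200, 300), blob_center=(100, 150), blob_radius=80):
    """Dark blob with bright circular holes; returns the dark mask."""
    dark = disk_mask(shape, blob_center, blob_radius)
    for center, radius in bubbles:
        dark &= ~disk_mask(shape, center, radius)
    return dark


class TestBubbleMetrology:
    def test_blank_region_no_bubbles(self):
        dark = blob_with_bubbles([])
        out = imaging.measure_bubbles(dark, PX)
        assert out.count == 0 and out.A_bubbles == 0.0 and out.ratio == 0.0

    def test_three_resolvable_bubbles_counted_exactly(self):
        spec = [((100, 110), 7), ((100, 150), 7), ((100, 190), 7)]  # 140 um dia
        dark = blob_with_bubbles(spec)
        truth_area = [disk_mask((200, 300), c, r).sum() for c, r in spec]
        out = imaging.measure_bubbles(dark, PX)
        assert out.count == 3
        measured = sorted(b.area_px for b in out.bubbles)
        assert measured == sorted(truth_area)
        assert out.A_total == pytest.approx(disk_mask((200, 300), (100, 150), 80).sum() * PX**2)

    def test_subresolution_cluster_merged_to_one(self):
        # two 60 um bubbles separated by a 30 um gap: one bubble, combined area
        spec = [((100, 141), 3), ((100, 150), 3)]
        dark = blob_with_bubbles(spec)
        out = imaging.measure_bubbles(dark, PX)
        assert out.count == 1
        combined = sum(disk_mask((200, 300), c, r).sum() for c, r in spec)
        assert out.bubbles[0].area_px == combined

    def test_isolated_subresolution_bubble_dropped(self):
        dark = blob_with_bubbles([((100, 150), 3)])  # 60 um diameter
        out = imaging.measure_bubbles(dark, PX)
        assert out.count == 0

    def test_idempotent(self):
        dark = blob_with_bubbles([((100, 120), 8), ((100, 180), 8)])
        a = imaging.measure_bubbles(dark, PX)
        b = imaging.measure_bubbles(dark, PX)
        assert a.count == b.count
        assert a.A_total == b.A_total
        assert [x.area_px for x in a.bubbles] == [x.area_px for x in b.bubbles]

    def test_area_scales_with_pixel_size(self):
        dark = blob_with_bubbles([((100, 150), 8)])
        fine = imaging.measure_bubbles(dark, PX)
        coarse = imaging.measure_bubbles(dark, 2 * PX)
        assert coarse.A_total == pytest.approx(4 * fine.A_total)
        assert coarse.count == fine.count == 1


class TestAreaSeries:
    def test_expansion_then_closure(self):
        stack, br, _, _ = render_parabolic_stack(u_c=10.0, n_frames=20)
        # append two repeats of the peak and one closed (bridge-only) frame
        closed = np.full((200, 300), 230, dtype=np.uint8)
        closed[disk_mask((200, 300), (100, 115), 95)] = 60
        frames = np.concatenate(
            [stack.frames, stack.frames[-1:], stack.frames[-1:], closed[None]]
        )
        full = FrameStack(frames, stack.dt, PX, stack.origin, stack.axis)
        A, A_max, t_col, open_ended = imaging.cavity_area_series(
            full, "fixed", 128, bridge=br
        )
        assert not open_ended
        assert t_col is not None and t_col <= 2 * stack.dt
        assert A_max == pytest.approx(A.max())

    def test_never_closing_stack_flagged(self):
        stack, br, _, _ = render_parabolic_stack(u_c=6.0, n_frames=20)
        A, A_max, t_col, open_ended = imaging.cavity_area_series(
            stack, "fixed", 128, bridge=br
        )
        assert open_ended and t_col is None

    def test_measurement_idempotence(self):
        stack, br, _, _ = render_parabolic_stack(noise_sigma=5.0, seed=7)
        m1 = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        m2 = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        assert np.array_equal(m1.area_m2, m2.area_m2)
        assert np.array_equal(m1.front_m, m2.front_m, equal_nan=True)


class TestAxisHandling:
    def test_flipped_axis_equivalent(self):
        stack, br, _, _ = render_parabolic_stack(u_c=10.0)
        flipped_frames = stack.frames[..., ::-1]
        w = stack.frames.shape[-1]
        flipped = FrameStack(
            np.ascontiguousarray(flipped_frames), stack.dt, PX,
            (stack.origin[0], w - 1 - stack.origin[1]), (0, -1),
        )
        m = imaging.analyze_stack(stack, "fixed", 128, bridge=br)
        mf = imaging.analyze_stack(
            flipped, "fixed", 128, bridge_diameter=2 * 95 * PX
        )
        assert np.allclose(m.front_m, mf.front_m, equal_nan=True)

    def test_non_pixel_axis_rejected(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((1, 4, 4), dtype=np.uint8), axis=(1, 1))
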