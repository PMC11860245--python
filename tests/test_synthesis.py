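"""The generation loop: padding, initialization, gradient steps, full runs."""

import numpy as np
import pytest

from stst.losses import ConfigError, LossSpec, texture_loss
from stst.synthesis import (
    OctaveSchedule,
    SynthesisConfig,
    blend_init,
    mirror_pad,
    normalize_gradient,
    optimize_frame,
    synthesize_video,
)
from stst.videoio import Video


def _single_octave(iters=50, lr=0.02, tv=0.1):
    return OctaveSchedule(octaves=[0], iterations=[iters], learning_rates=[lr], tv_weights=[tv])


def _spatial_only_cfg(iters=50, **kw):
    spec = LossSpec(beta=1.0, lam=0.0, omega=0.0, spatial_layers=["conv1", "conv2"],
                    routing={"spatial_texture": "target"})
    return SynthesisConfig(loss_spec=spec, schedule=_single_octave(iters), phi=0.95,
                           xi=0, seed=11, color_transfer=False, **kw)


class TestMirrorPad:
    def test_zero_padding_is_identity(self, tiny_texture):
        assert np.array_equal(mirror_pad(tiny_texture.video, 0).pixels, tiny_texture.video.pixels)

    def test_flip_and_prepend_rule(self):
        frames = np.stack([np.full((2, 2, 3), v) for v in (0.1, 0.2, 0.3)])
        padded = mirror_pad(Video(frames), 2)
        got = padded.pixels[:, 0, 0, 0]
        assert np.allclose(got, [0.2, 0.1, 0.1, 0.2, 0.3])

    def test_output_length(self, tiny_texture):
        for xi in (1, 2, 4):
            assert len(mirror_pad(tiny_texture.video, xi)) == len(tiny_texture.video) + xi

    def test_padding_longer_than_video_rejected(self, tiny_texture):
        with pytest.raises(ValueError):
            mirror_pad(tiny_texture.video, 99)


class TestBlendInit:
    def test_full_blend_copies_previous(self, rng):
        prev = rng.uniform(0, 1, (8, 8, 3))
        assert np.array_equal(blend_init(prev, 1.0, 0), prev)

    def test_expected_mean_with_bright_previous(self):
        prev = np.ones((64, 64, 3))
        out = blend_init(prev, 0.9, 0)
        assert abs(out.mean() - 0.95) < 0.01

    def test_seeded_determinism(self, rng):
        prev = rng.uniform(0, 1, (8, 8, 3))
        assert np.array_equal(blend_init(prev, 0.5, 42), blend_init(prev, 0.5, 42))

    def test_no_predecessor_gives_uniform_noise(self):
        out = blend_init(None, 0.95, 1, shape=(32, 32, 3))
        assert out.min() >= 0 and out.max() <= 1 and out.std() > 0.2


class TestNormalizeGradient:
    def test_unit_std_after_normalization(self, rng):
        grad = rng.standard_normal((3, 16, 16)) * 5.0
        out = normalize_gradient(grad, eps=1e-8, channel_axis=0)
        assert np.allclose(out.std(axis=(1, 2)), 1.0, atol=1e-6)

    def test_zero_gradient_stays_zero(self):
        assert np.array_equal(normalize_gradient(np.zeros((3, 4, 4))), np.zeros((3, 4, 4)))

    def test_matches_per_channel_division(self, rng):
        grad = rng.standard_normal((3, 8, 8))
        eps = 1e-8
        expected = np.stack([grad[c] / (grad[c].std() + eps) for c in range(3)])
        assert np.allclose(normalize_gradient(grad, eps, channel_axis=0), expected, atol=1e-12)


class TestOptimizeFrame:
    def test_zero_iterations_returns_init(self, rng, spatial_fixture_model, msoe_model, tiny_texture):
        cfg = _spatial_only_cfg(iters=0)
        g0 = rng.uniform(0, 1, (12, 12, 3))
        out = optimize_frame({"target": (tiny_texture.video.pixels[0], None)}, g0, None, cfg,
                             {"spatial": spatial_fixture_model, "temporal": msoe_model})
        assert np.allclose(out, g0)

    def test_spatial_texture_loss_halves(self, rng, spatial_fixture_model, msoe_model, tiny_texture):
        cfg = _spatial_only_cfg(iters=100)
        target = tiny_texture.video.pixels[0]
        g0 = np.random.default_rng(5).uniform(0, 1, (12, 12, 3))
        models = {"spatial": spatial_fixture_model, "temporal": msoe_model}
        out = optimize_frame({"target": (target, None)}, g0, None, cfg, models)

        def tex(frame):
            t = spatial_fixture_model.activations(target)
            g = spatial_fixture_model.activations(frame)
            return sum(texture_loss(t[l].value, g[l].value) for l in t)

        assert tex(out) <= 0.5 * tex(g0)
        assert out.min() >= 0 and out.max() <= 1

    def test_temporal_loss_without_predecessor_rejected(self, rng, spatial_fixture_model, msoe_model):
        spec = LossSpec(beta=0, lam=1, omega=0, temporal_layers=["concat"],
                        routing={"temporal_texture": "target"})
        cfg = SynthesisConfig(loss_spec=spec, schedule=_single_octave(1), xi=0, seed=0,
                              color_transfer=False)
        frame = rng.uniform(0, 1, (12, 12, 3))
        with pytest.raises(ConfigError):
            optimize_frame({"target": (frame, frame)}, frame, None, cfg,
                           {"spatial": spatial_fixture_model, "temporal": msoe_model})


class TestSynthesizeVideo:
    def _cfg(self, iters=50, color=True, seed=7):
        spec = LossSpec(beta=1.0, lam=1.0, spatial_layers=["conv1", "conv2"],
                        temporal_layers=["concat"],
                        routing={"spatial_texture": "target", "temporal_texture": "target"})
        return SynthesisConfig(loss_spec=spec, schedule=_single_octave(iters), phi=0.95,
                               xi=1, seed=seed, color_transfer=color, color_iterations=10)

    def test_zero_iterations_no_color_returns_blend_inits(self, spatial_fixture_model, msoe_model, tiny_texture):
        cfg = self._cfg(iters=0, color=False)
        out = synthesize_video({"target": tiny_texture.video}, cfg,
                               {"spatial": spatial_fixture_model, "temporal": msoe_model})
        rng = np.random.default_rng(cfg.seed)
        prev = None
        expected = []
        for _ in range(len(tiny_texture.video) + cfg.xi):
            from stst.synthesis import blend_init

            frame = blend_init(prev, cfg.phi, rng, shape=(12, 12, 3))
            expected.append(frame)
            prev = frame
        assert np.allclose(out.pixels, np.stack(expected[cfg.xi:]))

    def test_full_run_pixels_valid_and_loss_decreases(self, spatial_fixture_model, msoe_model, tiny_texture):
        trace = []
        out = synthesize_video({"target": tiny_texture.video}, self._cfg(iters=40),
                               {"spatial": spatial_fixture_model, "temporal": msoe_model},
                               trace=trace)
        assert out.shape == tiny_texture.video.shape
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1
        firsts, lasts = {}, {}
        for row in trace:
            firsts.setdefault(row["frame"], row["total"])
            lasts[row["frame"]] = row["total"]
        for f in firsts:
            assert lasts[f] <= firsts[f]

    def test_bitwise_determinism(self, spatial_fixture_model, msoe_model, tiny_texture):
        models = {"spatial": spatial_fixture_model, "temporal": msoe_model}
        a = synthesize_video({"target": tiny_texture.video}, self._cfg(iters=10), models)
        b = synthesize_video({"target": tiny_texture.video}, self._cfg(iters=10), models)
        assert np.array_equal(a.pixels, b.pixels)

    def test_distinct_routed_targets_supported(self, spatial_fixture_model, msoe_model, tiny_texture):
        from stst.fixtures import translating_texture

        other = translating_texture(12, 12, 4, speed=1.0, direction=np.pi / 2, seed=9)
        spec = LossSpec(beta=1.0, lam=1.0, spatial_layers=["conv1"], temporal_layers=["concat"],
                        routing={"spatial_texture": "A", "temporal_texture": "B"})
        cfg = SynthesisConfig(loss_spec=spec, schedule=_single_octave(5), xi=1, seed=3,
                              color_transfer=True, color_iterations=5)
        out = synthesize_video({"A": tiny_texture.video, "B": other.video}, cfg,
                               {"spatial": spatial_fixture_model, "temporal": msoe_model})
        assert len(out) == 4

    def test_temporal_loss_requires_padding(self, spatial_fixture_model, msoe_model, tiny_texture):
        cfg = self._cfg()
        cfg = SynthesisConfig(loss_spec=cfg.loss_spec, schedule=cfg.schedule, xi=0, seed=0)
        with pytest.raises(ConfigError):
            synthesize_video({"target": tiny_texture.video}, cfg,
                             {"spatial": spatial_fixture_model, "temporal": msoe_model})

    def test_missing_routed_target_rejected(self, spatial_fixture_model, msoe_model, tiny_texture):
        cfg = self._cfg()
        with pytest.raises(ConfigError):
            synthesize_video({"other": tiny_texture.video}, cfg,
                             {"spatial": spatial_fixture_model, "temporal": msoe_model})

    def test_generated_texture_closer_than_noise_init(self, spatial_fixture_model, msoe_model, tiny_texture):
        models = {"spatial": spatial_fixture_model, "temporal": msoe_model}
        out = synthesize_video({"target": tiny_texture.video}, self._cfg(iters=50), models)
        rng = np.random.default_rng(7)
        wins = 0
        for t in range(4):
            target = tiny_texture.video.pixels[t]
            tacts = spatial_fixture_model.activations(target)

            def tex(frame):
                g = spatial_fixture_model.activations(frame)
                return sum(texture_loss(tacts[l].value, g[l].value) for l in tacts)

            wins += tex(out.pixels[t]) < tex(rng.uniform(0, 1, target.shape))
        assert wins >= 3
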