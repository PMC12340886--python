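"""Architecture, baselines, readout, combined loss and phase assignment."""

import numpy as np
import pytest

from komplexnet import autodiff as ad
from komplexnet.autodiff import as_data
from komplexnet.model import (
    Model,
    ModelConfig,
    build_model,
    combined_loss,
    ideal_phase_assignment,
    init_phases,
    readout,
    bce_with_logits,
    MODEL_KINDS,
)
from komplexnet.synchrony import GroupMasks, cluster_synchrony_loss


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig()


@pytest.fixture(scope="module")
def scene_batch(clean_scenes):
    imgs = np.stack([s.image for s in clean_scenes[:6]])
    labels = np.stack([s.labels for s in clean_scenes[:6]])
    masks = [s.masks for s in clean_scenes[:6]]
    return imgs, labels, masks


class TestInitPhases:
    def test_deterministic(self):
        assert np.array_equal(init_phases((3, 4), 42), init_phases((3, 4), 42))

    def test_range(self):
        th = init_phases((1000,), 0)
        assert np.all((th > -np.pi) & (th <= np.pi))

    def test_uniformity_resultant(self):
        th = init_phases((100000,), 1)
        r = abs(np.exp(1j * th).mean())
        assert r < 0.02


class TestArchitecture:
    def test_shape_chain(self, cfg, scene_batch):
        imgs, _, _ = scene_batch
        m = build_model("komplexnet", cfg, seed=0)
        res = m.forward(imgs, T=2, phase_seed=0)
        st = res.final_state
        n = imgs.shape[0]
        assert st.z_L0.shape == (n, 8, 32, 32)
        assert st.z_L1.shape == (n, 8, 16, 16)
        assert st.z_L2.shape == (n, 50)
        assert st.z_L4.shape == (n, 10)
        assert as_data(st.scores).shape == (n, 10)
        assert len(res.scores_per_t) == 2

    def test_amplitudes_nonnegative_and_same_size(self, cfg, scene_batch):
        imgs, _, _ = scene_batch
        m = build_model("komplexnet", cfg, seed=0)
        amps = as_data(m.extract_amplitudes(imgs))
        assert amps.shape == (imgs.shape[0], 8, 32, 32)
        assert np.all(amps >= 0)

    def test_zero_image_gives_zero_scores(self, cfg):
        m = build_model("komplexnet", cfg, seed=0)
        res = m.forward(np.zeros((2, 32, 32), dtype=np.float32), T=3, phase_seed=1)
        for s in res.scores_per_t:
            assert np.allclose(as_data(s), 0.0, atol=1e-5)

    def test_global_phase_shift_leaves_scores_invariant(self, cfg, scene_batch):
        imgs, _, _ = scene_batch
        m = build_model("komplexnet", cfg, seed=0)
        th0 = init_phases((imgs.shape[0], 8, 32, 32), 3)
        from komplexnet.kuramoto import wrap_phase

        r1 = m.forward(imgs, T=4, theta0=th0)
        r2 = m.forward(imgs, T=4, theta0=wrap_phase(th0 + 1.9).astype(np.float32))
        for a, b in zip(r1.scores_per_t, r2.scores_per_t):
            assert np.allclose(as_data(a), as_data(b), atol=1e-4)

    def test_deterministic_forward(self, cfg, scene_batch):
        imgs, _, _ = scene_batch
        m = build_model("komplexnet_fb", cfg, seed=0)
        a = m.forward(imgs, T=3, phase_seed=5)
        b = m.forward(imgs, T=3, phase_seed=5)
        for x, y in zip(a.scores_per_t, b.scores_per_t):
            assert np.array_equal(as_data(x), as_data(y))


class TestBuildModel:
    def test_unknown_kind_rejected(self, cfg):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("transformer", cfg, seed=0)

    def test_all_kinds_share_layer_widths(self, cfg):
        for kind in MODEL_KINDS:
            m = build_model(kind, cfg, seed=0)
            assert m.params["conv0"].shape == (8, 1, 5, 5)
            assert m.params["conv1"].shape == (8, 8, 5, 5)
            assert m.params["dense2"].shape == (8 * 16 * 16, 50)
            assert m.params["dense4"].shape == (50, 10)

    def test_vanishing_gain_reduces_to_random_phase_model(self, scene_batch):
        imgs, _, _ = scene_batch
        cfg_eps = ModelConfig(eta_l0=1e-12, epsilon=0.0)
        kn = build_model("komplexnet", cfg_eps, seed=0)
        cr = build_model("complex_random", cfg_eps, seed=0)
        a = kn.forward(imgs, T=1, phase_seed=9)
        b = cr.forward(imgs, T=1, phase_seed=9)
        assert np.allclose(as_data(a.scores_per_t[-1]),
                           as_data(b.scores_per_t[-1]), atol=1e-5)

    def test_ideal_model_reaches_zero_csloss_untrained(self, cfg, scene_batch):
        imgs, _, masks = scene_batch
        m = build_model("complex_ideal", cfg, seed=0)
        res = m.forward(imgs, masks=masks, T=1, phase_seed=2)
        th = as_data(res.theta_last)
        cs = np.mean([cluster_synchrony_loss(th[b], masks[b])
                      for b in range(len(masks))])
        assert cs < 1e-6


class TestIdealPhaseAssignment:
    def two_group_masks(self):
        m1 = np.zeros((8, 8), np.uint8); m1[1:3, 1:3] = 1
        m2 = np.zeros((8, 8), np.uint8); m2[5:7, 5:7] = 1
        return GroupMasks(masks=[m1, m2])

    def test_two_groups_antipodal(self):
        gm = self.two_group_masks()
        th = ideal_phase_assignment(gm, seed=0)
        v1 = th[1, 1]
        v2 = th[5, 5]
        assert abs(np.angle(np.exp(1j * (v1 - v2)))) == pytest.approx(np.pi, abs=1e-5)

    def test_three_groups_equidistant(self):
        ms = []
        for i in range(3):
            m = np.zeros((8, 8), np.uint8)
            m[i * 2, i * 2] = 1
            ms.append(m)
        th = ideal_phase_assignment(GroupMasks(masks=ms), seed=1)
        vals = [th[0, 0], th[2, 2], th[4, 4]]
        diffs = sorted(abs(np.angle(np.exp(1j * (a - b))))
                       for a, b in [(vals[0], vals[1]), (vals[1], vals[2]), (vals[0], vals[2])])
        assert np.allclose(diffs, 2 * np.pi / 3, atol=1e-5)

    def test_overlap_pixels_get_circular_mean_tiebreak(self):
        # two groups forced antipodal; the excluded overlap region between
        # them must get first-parent value + pi/2 (degenerate-mean tie-break)
        m1 = np.zeros((8, 8), np.uint8); m1[2, 1:3] = 1
        m2 = np.zeros((8, 8), np.uint8); m2[2, 5:7] = 1
        ov = np.zeros((8, 8), np.uint8); ov[2, 3:5] = 1
        gm = GroupMasks(masks=[m1, m2, ov], excluded_flags=[False, False, True])
        th = ideal_phase_assignment(gm, seed=3)
        v1, vo = th[2, 1], th[2, 3]
        d = abs(np.angle(np.exp(1j * (vo - v1))))
        assert d == pytest.approx(np.pi / 2, abs=1e-5)

    def test_background_pixels_randomized(self):
        gm = self.two_group_masks()
        th = ideal_phase_assignment(gm, seed=4)
        bg = np.ones((8, 8), bool)
        for m in gm.masks:
            bg &= ~m.astype(bool)
        assert np.std(th[bg]) > 0.5


class TestReadoutAndLoss:
    def test_sigmoid_of_logits(self):
        logits = np.array([5.0, -5.0])
        p = ad.sigmoid(logits)
        assert p[0] == pytest.approx(0.9933, abs=1e-4)
        assert p[1] == pytest.approx(0.0067, abs=1e-4)

    def test_bce_matches_closed_form(self, rng):
        x = rng.normal(size=(4, 10))
        y = (rng.random((4, 10)) > 0.7).astype(float)
        p = 1 / (1 + np.exp(-x))
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(as_data(bce_with_logits(x, y))) == pytest.approx(expected, rel=1e-6)

    def test_tau_zero_is_pure_accumulated_bce(self, rng):
        scores = [rng.normal(size=(3, 10)) for _ in range(4)]
        y = np.eye(10)[:3]
        total = combined_loss(scores, y, None, None, tau=0.0)
        expected = sum(float(as_data(bce_with_logits(s, y))) for s in scores)
        assert float(as_data(total)) == pytest.approx(expected, rel=1e-6)

    def test_identical_scores_double_with_two_steps(self, rng):
        s = rng.normal(size=(2, 10))
        y = np.eye(10)[:2]
        one = combined_loss([s], y, None, None, tau=0.0)
        two = combined_loss([s, s], y, None, None, tau=0.0)
        assert float(as_data(two)) == pytest.approx(2 * float(as_data(one)), rel=1e-6)

    def test_tau_without_masks_rejected(self, rng):
        with pytest.raises(ValueError, match="masks"):
            combined_loss([rng.normal(size=(1, 10))], np.eye(10)[:1],
                          np.zeros((1, 1, 2, 2)), None, tau=1.0)


class TestGradients:
    def test_gradient_reaches_coupling_kernel(self, cfg, scene_batch):
        """Directional finite-difference check through the unrolled dynamic."""
        imgs, labels, masks = scene_batch
        imgs, labels, masks = imgs[:2], labels[:2], masks[:2]
        m = build_model("komplexnet", cfg, seed=0)
        params = m.trainable()

        def loss_with(r_data):
            p = dict(params)
            p["kuramoto_r"] = ad.Tensor(r_data, requires_grad=False)
            res = m.forward(imgs, T=3, phase_seed=11, params=p)
            return float(as_data(combined_loss(res.scores_per_t, labels,
                                               res.theta_last, masks, tau=2.0)))

        res = m.forward(imgs, T=3, phase_seed=11, params=params)
        L = combined_loss(res.scores_per_t, labels, res.theta_last, masks, tau=2.0)
        L.backward()
        g = params["kuramoto_r"].grad
        assert g is not None and np.abs(g).max() > 0

        rng = np.random.default_rng(0)
        d = rng.normal(size=g.shape).astype(np.float32)
        d /= np.linalg.norm(d)
        eps = 1e-3
        r0 = params["kuramoto_r"].data
        fd = (loss_with(r0 + eps * d) - loss_with(r0 - eps * d)) / (2 * eps)
        analytic = float((g * d).sum())
        assert fd == pytest.approx(analytic, rel=2e-2, abs=1e-4)


class TestCheckpoint:
    def test_save_load_roundtrip(self, cfg, tmp_path, scene_batch):
        imgs, _, _ = scene_batch
        m = build_model("komplexnet_fb", cfg, seed=3)
        path = tmp_path / "model.npz"
        m.save(path)
        back = Model.load(path)
        assert back.kind == "komplexnet_fb"
        assert back.config == m.config
        for k in m.params:
            assert np.array_equal(m.params[k], back.params[k])
        a = m.forward(imgs[:2], T=2, phase_seed=1)
        b = back.forward(imgs[:2], T=2, phase_seed=1)
        assert np.array_equal(as_data(a.scores_per_t[-1]), as_data(b.scores_per_t[-1]))
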