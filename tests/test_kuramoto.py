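"""Lateral Kuramoto dynamic, its brute-force oracle and the graph form."""

import numpy as np
import pytest

from komplexnet.kuramoto import (
    CouplingKernel,
    OscillatorGraph,
    graph_kuramoto_step,
    init_gaussian_kernel,
    kuramoto_energy,
    kuramoto_step,
    kuramoto_step_bruteforce,
    wrap_phase,
)


class TestGaussianKernel:
    def test_degenerate_1x1_kernel(self):
        k = init_gaussian_kernel(3, 1, 1, sigma=2.0, scale=0.7)
        assert k.r.shape == (3, 3, 1, 1)
        assert np.allclose(k.r, 0.7)

    def test_center_peak_and_monotone_radial_decay(self):
        k = init_gaussian_kernel(1, 7, 7, sigma=1.5, scale=0.5)
        g = k.r[0, 0]
        assert g[3, 3] == pytest.approx(0.5)
        ys, xs = np.mgrid[0:7, 0:7]
        d = np.hypot(ys - 3, xs - 3)
        order = np.argsort(d.ravel())
        vals = g.ravel()[order]
        # values sorted by radius are non-increasing
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(g > 0)

    def test_slice_sum_closed_form(self):
        sigma, scale = 2.0, 0.3
        k = init_gaussian_kernel(2, 5, 5, sigma=sigma, scale=scale)
        offs = np.arange(5) - 2
        d2 = offs[:, None] ** 2 + offs[None, :] ** 2
        expected = scale * np.exp(-d2 / (2 * sigma**2)).sum()
        assert k.r[1, 0].sum() == pytest.approx(expected, rel=1e-12)

    def test_even_dims_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            init_gaussian_kernel(1, 4, 5, 1.0, 1.0)


class TestKuramotoStep:
    def kernel(self, **kw):
        args = dict(r=np.full((1, 1, 1, 3), 1.0), epsilon=0.0, eta=0.1)
        args.update(kw)
        return CouplingKernel(**args)

    def test_equal_phases_are_fixed_point(self):
        theta = np.full((1, 2, 2), 0.8)
        a = np.ones_like(theta)
        upd, new = kuramoto_step(theta, a, self.kernel(r=np.ones((1, 1, 3, 3))))
        assert np.allclose(upd.total, 0.0, atol=1e-7)
        assert np.allclose(new, theta, atol=1e-7)

    def test_zero_amplitudes_freeze_dynamics(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (1, 3, 3)).astype(np.float64)
        upd, new = kuramoto_step(theta, np.zeros_like(theta), self.kernel(r=np.ones((1, 1, 3, 3)), epsilon=0.3))
        assert np.allclose(upd.total, 0.0)
        assert np.allclose(new, theta)

    def test_two_oscillator_hand_values(self):
        # r=1 over both sites, eps=0, eta=0.1, tanh(a)~1, theta = (0, pi/2)
        theta = np.array([[[0.0, np.pi / 2]]])
        a = np.full((1, 1, 2), 50.0)  # tanh saturates to 1
        upd, new = kuramoto_step(theta, a, self.kernel())
        assert np.allclose(upd.total, [[[0.1, -0.1]]], atol=1e-6)
        assert np.allclose(new, [[[0.1, np.pi / 2 - 0.1]]], atol=1e-6)

    def test_translation_invariance(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (2, 6, 6))
        a = rng.uniform(0, 2, (2, 6, 6))
        k = CouplingKernel(r=rng.normal(0, 0.2, (2, 2, 3, 3)), epsilon=0.05, eta=0.5)
        u1, t1 = kuramoto_step(theta, a, k)
        u2, t2 = kuramoto_step(wrap_phase(theta + 2.5), a, k)
        assert np.allclose(u1.total, u2.total, atol=1e-6)
        assert np.allclose(np.exp(1j * (t2 - t1)), np.exp(1j * 2.5), atol=1e-6)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(5):
            theta = rng.uniform(-np.pi, np.pi, (2, 8, 8))
            a = rng.uniform(0, 2, (2, 8, 8))
            k = CouplingKernel(r=rng.normal(0, 0.3, (2, 2, 3, 5)),
                               epsilon=float(rng.uniform(0.01, 0.2)), eta=0.7)
            fast, _ = kuramoto_step(theta, a, k)
            slow, _ = kuramoto_step_bruteforce(theta, a, k)
            assert np.abs(fast.total - slow.total).max() < 1e-5

    def test_empty_kernel_equilibria(self):
        # r = 0 everywhere, eps > 0: equal phases and antipodal pairs are
        # both stationary (sin 0 = sin pi = 0)
        k = CouplingKernel(r=np.zeros((1, 1, 1, 1)), epsilon=0.2, eta=1.0)
        same = np.full((1, 1, 2), 0.4)
        upd, _ = kuramoto_step_bruteforce(same, np.ones_like(same), k)
        assert np.allclose(upd.total, 0.0, atol=1e-12)
        anti = np.array([[[0.0, np.pi]]])
        upd, _ = kuramoto_step_bruteforce(anti, np.ones_like(anti), k)
        assert np.allclose(upd.total, 0.0, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        theta = np.array([[[np.nan, 0.0]]])
        with pytest.raises(ValueError, match="finite"):
            kuramoto_step(theta, np.ones_like(theta), self.kernel())

    def test_kernel_invariants(self):
        with pytest.raises(ValueError):
            CouplingKernel(r=np.ones((1, 1, 2, 3)), epsilon=0.0, eta=1.0)
        with pytest.raises(ValueError):
            CouplingKernel(r=np.ones((1, 1, 3, 3)), epsilon=-0.1, eta=1.0)
        with pytest.raises(ValueError):
            CouplingKernel(r=np.ones((1, 1, 3, 3)), epsilon=0.0, eta=0.0)


class TestWrapPhase:
    @pytest.mark.parametrize("x,expected", [
        (np.pi, np.pi),
        (-np.pi, np.pi),
        (7 * np.pi / 2, -np.pi / 2),
        (0.0, 0.0),
    ])
    def test_values(self, x, expected):
        assert wrap_phase(np.array([x]))[0] == pytest.approx(expected, abs=1e-12)

    def test_equal_mod_2pi(self, rng):
        x = rng.normal(0, 10, 100)
        w = wrap_phase(x)
        assert np.all((w > -np.pi) & (w <= np.pi))
        assert np.allclose(np.exp(1j * w), np.exp(1j * x), atol=1e-12)


class TestGraphKuramoto:
    def two_node(self):
        return OscillatorGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_synchronized_pair_unchanged(self):
        g = self.two_node()
        assert np.allclose(graph_kuramoto_step(np.zeros(2), g, 0.1), 0.0)

    def test_two_node_hand_values(self):
        new = graph_kuramoto_step(np.array([0.0, np.pi / 2]), self.two_node(), 0.1)
        assert np.allclose(new, [0.1, np.pi / 2 - 0.1], atol=1e-12)

    def test_common_natural_frequency_drifts_both(self):
        g = OscillatorGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
                            natural_freq=np.array([0.5, 0.5]))
        th = np.array([0.2, 1.0])
        new = graph_kuramoto_step(th, g, 0.1)
        base = graph_kuramoto_step(th, self.two_node(), 0.1)
        assert np.allclose(new - base, 0.05)

    def test_asymmetric_weights_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            OscillatorGraph(weights=np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_energy_hand_values_and_shift_invariance(self, rng):
        g = self.two_node()
        assert kuramoto_energy(np.array([0.0, 0.0]), g) == pytest.approx(-2.0)
        assert kuramoto_energy(np.array([0.0, np.pi]), g) == pytest.approx(2.0)
        w = rng.normal(size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g5 = OscillatorGraph(weights=w)
        th = rng.uniform(-np.pi, np.pi, 5)
        assert kuramoto_energy(th, g5) == pytest.approx(kuramoto_energy(th + 1.7, g5))

    def test_energy_descends_along_trajectory(self, rng):
        for _ in range(3):
            n = 12
            w = rng.normal(size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            g = OscillatorGraph(weights=w)
            th = rng.uniform(-np.pi, np.pi, n)
            e = kuramoto_energy(th, g)
            for _ in range(100):
                th = graph_kuramoto_step(th, g, eta=0.01)
                e_new = kuramoto_energy(th, g)
                assert e_new <= e + 1e-8
                e = e_new


def test_cluster_formation_two_blobs():
    """Two separated amplitude blobs synchronize internally and split apart."""
    from komplexnet.synchrony import circular_stats

    k0 = init_gaussian_kernel(1, 11, 11, sigma=2.0, scale=0.1)
    k = CouplingKernel(r=k0.r, epsilon=float(np.mean(k0.r)), eta=1.0)
    a = np.zeros((1, 16, 16))
    a[0, 2:6, 2:6] = 1.0
    a[0, 10:14, 10:14] = 1.0
    m1 = np.zeros((16, 16), bool); m1[2:6, 2:6] = True
    m2 = np.zeros((16, 16), bool); m2[10:14, 10:14] = True

    theta = np.random.default_rng(5).uniform(-np.pi, np.pi, (1, 16, 16))
    for _ in range(50):
        _, theta = kuramoto_step(theta, a, k)
    s1, s2 = circular_stats(theta[0][m1]), circular_stats(theta[0][m2])
    assert s1.circ_variance < 0.1 and s2.circ_variance < 0.1
    sep = np.angle(np.exp(1j * (s1.circ_mean - s2.circ_mean)))
    assert abs(sep) > np.pi / 2
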