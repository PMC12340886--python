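"""Top-down phase coupling from higher layers into the first-layer dynamic.

Deeper layers carry increasingly abstract information about the objects in the
scene; feeding their phases back into the first-layer Kuramoto update lets
that information refine the low-level grouping.  Each feeding layer
contributes a Kuramoto-style term

    sum_k r_l[k, (c,i,j)] * sin(theta_l[k] - theta_L0[c,i,j]) * tanh(m_l[k])

scaled by a per-layer gain.  The strided convolutional layer L1 feeds back
through a spatial kernel applied in transposed orientation (undoing the
stride-2 subsampling), so it still provides spatially structured pull; the
dense layers couple every one of their units to every first-layer site of a
given channel, providing spatially unstructured identity information.  There
is no global desynchronization term on the feedback paths, and the kernels
are initialized near zero so negative (desynchronizing) couplings are easy to
reach during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import as_data


@dataclass
class FeedbackCouplings:
    """Learnable feedback kernels and per-layer gains.

    ``r_conv``: (C, C, h1, w1) spatial kernel from L1 (source channel first,
    like the lateral kernel).  ``r_dense[l]``: (C, D_l) coupling from each
    dense layer's units to the first-layer channels.  ``eta_fb``: one gain per
    feeding layer, conv layer first.
    """

    r_conv: object
    r_dense: List[object]
    eta_fb: Sequence[float]
    stride: int = 2

    def __post_init__(self):
        if len(self.eta_fb) != 1 + len(self.r_dense):
            raise ValueError("need one gain per feeding layer (conv + dense)")

    @property
    def n_layers(self) -> int:
        return 1 + len(self.r_dense)


def init_feedback(C: int, kernel_hw, dense_widths: Sequence[int], seed: int = 0,
                  sigma: float = 1e-3, eta_fb: Optional[Sequence[float]] = None) -> FeedbackCouplings:
    """Feedback couplings with entries ~ N(0, sigma^2), reproducible by seed."""
    rng = np.random.default_rng(seed)
    h1, w1 = kernel_hw if isinstance(kernel_hw, tuple) else (kernel_hw, kernel_hw)
    r_conv = rng.normal(0.0, sigma, (C, C, h1, w1)).astype(np.float32)
    r_dense = [rng.normal(0.0, sigma, (C, d)).astype(np.float32) for d in dense_widths]
    if eta_fb is None:
        eta_fb = [1.0] * (1 + len(dense_widths))
    return FeedbackCouplings(r_conv=r_conv, r_dense=r_dense, eta_fb=list(eta_fb))


def _flip_transpose(r):
    """(C_src, C_dst, h, w) kernel -> conv weight applying it transposed."""
    if isinstance(r, ad.Tensor):
        rd = r.data
        c0, c1, h, w = rd.shape
        flat = ad.reshape(r, (c0 * c1, h, w))
        idx = np.arange(c0 * c1).reshape(c0, c1).T.ravel()
        swapped = flat[idx]
        flipped = swapped[:, ::-1, ::-1]
        return ad.reshape(flipped, (c1, c0, h, w))
    rr = np.asarray(r)
    return rr.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1].copy()


def feedback_update(theta_l0, layer_states, fb: FeedbackCouplings):
    """Additive phase-update field on L0 from the previous timestep's layers.

    ``layer_states`` is the network state computed at t-1: it must expose
    ``z_L1`` (amplitude/phase on the strided grid) and the dense layers'
    activations ``z_L2``, ``z_L4``.  All inputs may be batched (leading N).
    """
    batched = as_data(theta_l0).ndim == 4
    th0 = theta_l0 if batched else ad.reshape(theta_l0, (1,) + as_data(theta_l0).shape)
    n, C, H, W = as_data(th0).shape
    sin0, cos0 = ad.sin(th0), ad.cos(th0)

    # spatial feedback from L1, transposed-kernel upsampling
    z1 = layer_states.z_L1
    th1 = z1.phase if as_data(z1.phase).ndim == 4 else ad.reshape(z1.phase, (1,) + as_data(z1.phase).shape)
    m1 = z1.amplitude if as_data(z1.amplitude).ndim == 4 else ad.reshape(z1.amplitude, (1,) + as_data(z1.amplitude).shape)
    g1 = ad.tanh(m1)
    s1 = ad.dilate2d(ad.sin(th1) * g1, fb.stride, (H, W))
    c1 = ad.dilate2d(ad.cos(th1) * g1, fb.stride, (H, W))
    w_t = _flip_transpose(fb.r_conv)
    kh, kw = as_data(fb.r_conv).shape[2:]
    pad = (kh // 2, kw // 2)
    u_s = ad.conv2d(s1, w_t, stride=1, padding=pad)
    u_c = ad.conv2d(c1, w_t, stride=1, padding=pad)
    update = fb.eta_fb[0] * (cos0 * u_s - sin0 * u_c)

    # dense feedback: no spatial structure, broadcast over all sites
    dense_states = [layer_states.z_L2, layer_states.z_L4]
    for r_d, eta_l, z_l in zip(fb.r_dense, fb.eta_fb[1:], dense_states):
        th_l = z_l.phase if as_data(z_l.phase).ndim == 2 else ad.reshape(z_l.phase, (1,) + as_data(z_l.phase).shape)
        m_l = z_l.amplitude if as_data(z_l.amplitude).ndim == 2 else ad.reshape(z_l.amplitude, (1,) + as_data(z_l.amplitude).shape)
        g_l = ad.tanh(m_l)
        s_proj = _dense_proj(ad.sin(th_l) * g_l, r_d)  # (N, C)
        c_proj = _dense_proj(ad.cos(th_l) * g_l, r_d)
        s_b = ad.reshape(s_proj, (n, C, 1, 1))
        c_b = ad.reshape(c_proj, (n, C, 1, 1))
        update = update + eta_l * (cos0 * s_b - sin0 * c_b)

    if not batched:
        update = ad.reshape(update, (C, H, W))
    return update


def _dense_proj(x, r_d):
    # x: (N, D), r_d: (C, D) -> (N, C)
    if isinstance(x, ad.Tensor) or isinstance(r_d, ad.Tensor):
        return ad.matmul(x, _transpose2d(r_d))
    return np.asarray(x) @ np.asarray(r_d).T


def _transpose2d(r):
    if isinstance(r, ad.Tensor):
        c, d = r.data.shape
        flat = ad.reshape(r, (c * d,))
        idx = np.arange(c * d).reshape(c, d).T.ravel()
        return ad.reshape(flat[idx], (d, c))
    return np.asarray(r).T
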