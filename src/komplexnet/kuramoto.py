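"""Kuramoto phase dynamics on the first layer, plus graph-level diagnostics.

Each first-layer unit carries an oscillator phase ``theta[c, i, j]``.  One
update step pulls every phase toward its spatial neighbors — weighted by a
learnable coupling kernel ``r`` over all channel pairs within the kernel's
support — and pushes it away from the whole population through a global
desynchronization constant ``epsilon``:

    dtheta[c,i,j] = eta * sum_k (r[k,(c,i,j)] - eps) * sin(theta_k - theta[c,i,j]) * tanh(a_k)

where ``a_k`` is the (fixed, nonnegative) amplitude of unit ``k``; the
``-eps`` repulsion runs over all units, the ``r`` attraction only over the
kernel neighborhood.  Amplitude gating via ``tanh`` makes silent units inert.
The efficient implementation expands the sine of a difference into a
convolution (local part) plus global resultant sums (repulsive part); the
brute-force double loop is kept as an independent oracle.

The classical graph form (arbitrary symmetric couplings ``w_ij``) and its
energy function ``E = -sum_{i!=j} w_ij cos(theta_i - theta_j)`` are provided
for verification: with zero natural frequencies the graph dynamic is a
gradient flow that never increases ``E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _fast, autodiff as ad
from .autodiff import as_data


def wrap_phase(theta):
    """Wrap to (-pi, pi]; equal to the input modulo 2*pi; idempotent."""
    return ad.wrap_angle(theta)


@dataclass
class CouplingKernel:
    """Lateral coupling weights ``r`` with desynchronization and gain.

    ``r`` has shape (C, C, h, w): ``r[k, c, u, v]`` couples source channel
    ``k`` at spatial offset ``(u - h//2, v - w//2)`` into target channel
    ``c``.  ``h`` and ``w`` must be odd so neighborhoods are centered.
    """

    r: object
    epsilon: float
    eta: float

    def __post_init__(self):
        rd = as_data(self.r)
        if rd.ndim != 4 or rd.shape[0] != rd.shape[1]:
            raise ValueError("coupling kernel must have shape (C, C, h, w)")
        h, w = rd.shape[2:]
        if h % 2 == 0 or w % 2 == 0:
            raise ValueError("kernel spatial dims must be odd")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")


@dataclass
class PhaseUpdate:
    """Per-unit phase velocity: lateral term and total (lateral + feedback)."""

    lateral: object
    total: object


def init_gaussian_kernel(C: int, h: int, w: int, sigma: float, scale: float,
                         epsilon: float = 0.0, eta: float = 1.0) -> CouplingKernel:
    """Coupling kernel whose every C x C slice is one centered 2-D Gaussian.

    The Gaussian (peak value ``scale``, spatial std ``sigma``) biases the
    untrained dynamic toward attracting close neighbors, which is what lets
    phase clusters form before any training.
    """
    if h % 2 == 0 or w % 2 == 0:
        raise ValueError("kernel spatial dims must be odd")
    uy = np.arange(h) - h // 2
    ux = np.arange(w) - w // 2
    d2 = uy[:, None] ** 2 + ux[None, :] ** 2
    g = scale * np.exp(-d2 / (2.0 * sigma**2))
    r = np.broadcast_to(g, (C, C, h, w)).copy()
    return CouplingKernel(r=r, epsilon=epsilon, eta=eta)


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(as_data(a))):
            raise ValueError("non-finite input to Kuramoto step")


def kuramoto_update(theta, a, k: CouplingKernel, feedback=None) -> PhaseUpdate:
    """Phase velocity field for one step (without applying it).

    ``theta`` and ``a`` are (C, H, W) or batched (N, C, H, W); ``feedback`` is
    an optional additive field of the same shape (top-down coupling term).
    """
    _check_finite(theta, a)
    batched = as_data(theta).ndim == 4
    th = theta if batched else ad.reshape(theta, (1,) + as_data(theta).shape)
    am = a if batched else ad.reshape(a, (1,) + as_data(a).shape)

    rd = k.r
    h, w = as_data(rd).shape[2:]
    # out channel c sums over source channels k: conv weight[c, k] = r[k, c]
    weight = _transpose01(rd)
    pad = (h // 2, w // 2)

    on_graph = any(isinstance(x, ad.Tensor) for x in (th, am, rd))
    if not on_graph and _fast.HAVE_NUMBA:
        th_c = np.ascontiguousarray(th)
        lateral = _fast.fused_lateral(
            th_c, np.tanh(np.ascontiguousarray(am)),
            lambda f: ad.conv2d(f, weight, stride=1, padding=pad),
            float(k.epsilon), float(k.eta))
    else:
        g = ad.tanh(am)
        sin_t, cos_t = ad.sin(th), ad.cos(th)
        s_field, c_field = sin_t * g, cos_t * g
        s_loc = ad.conv2d(s_field, weight, stride=1, padding=pad)
        c_loc = ad.conv2d(c_field, weight, stride=1, padding=pad)
        local = cos_t * s_loc - sin_t * c_loc
        s_tot = ad.summation(s_field, axis=(1, 2, 3), keepdims=True)
        c_tot = ad.summation(c_field, axis=(1, 2, 3), keepdims=True)
        global_rep = cos_t * s_tot - sin_t * c_tot
        lateral = k.eta * (local - k.epsilon * global_rep)

    if not batched:
        lateral = ad.reshape(lateral, as_data(lateral).shape[1:])
    total = lateral if feedback is None else lateral + feedback
    return PhaseUpdate(lateral=lateral, total=total)


def _transpose01(r):
    if isinstance(r, ad.Tensor):
        rd = r.data
        flat = ad.reshape(r, (rd.shape[0] * rd.shape[1],) + rd.shape[2:])
        idx = np.arange(rd.shape[0] * rd.shape[1]).reshape(rd.shape[:2]).T.ravel()
        return ad.reshape(flat[idx], (rd.shape[1], rd.shape[0]) + rd.shape[2:])
    return np.asarray(r).transpose(1, 0, 2, 3)


def kuramoto_step(theta, a, k: CouplingKernel, feedback=None):
    """One explicit Euler step of the lateral dynamic.

    Returns ``(PhaseUpdate, new_theta)`` with ``new_theta`` wrapped to
    (-pi, pi].  The integration step size is absorbed into the gain ``eta``.
    """
    upd = kuramoto_update(theta, a, k, feedback=feedback)
    return upd, wrap_phase(theta + upd.total)


def kuramoto_step_bruteforce(theta, a, k: CouplingKernel):
    """O(N^2) double-loop oracle for :func:`kuramoto_step` (small fields)."""
    th = np.asarray(as_data(theta), dtype=float)
    am = np.asarray(as_data(a), dtype=float)
    _check_finite(th, am)
    C, H, W = th.shape
    r = np.asarray(as_data(k.r), dtype=float)
    h, w = r.shape[2:]
    g = np.tanh(am)
    dtheta = np.zeros_like(th)
    units = [(c, i, j) for c in range(C) for i in range(H) for j in range(W)]
    for (c, i, j) in units:
        acc = 0.0
        for (ck, ik, jk) in units:
            coupling = -k.epsilon
            du, dv = ik - i + h // 2, jk - j + w // 2
            if 0 <= du < h and 0 <= dv < w:
                coupling += r[ck, c, du, dv]
            acc += coupling * np.sin(th[ck, ik, jk] - th[c, i, j]) * g[ck, ik, jk]
        dtheta[c, i, j] = k.eta * acc
    return PhaseUpdate(lateral=dtheta, total=dtheta), wrap_phase(th + dtheta)


# -- graph form ------------------------------------------------------------

@dataclass
class OscillatorGraph:
    """Kuramoto system on an arbitrary weighted graph.

    ``weights`` must be symmetric with a zero diagonal so that the zero-
    frequency dynamic is the gradient flow of the energy function.
    """

    weights: np.ndarray
    natural_freq: Optional[np.ndarray] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("weights must have a zero diagonal")
        self.weights = w
        if self.natural_freq is None:
            self.natural_freq = np.zeros(w.shape[0])
        else:
            self.natural_freq = np.asarray(self.natural_freq, dtype=float)
            if self.natural_freq.shape != (w.shape[0],):
                raise ValueError("natural_freq length must match node count")


def graph_kuramoto_step(theta: np.ndarray, g: OscillatorGraph, eta: float) -> np.ndarray:
    """One Euler step of ``dtheta_i = omega_i + sum_j w_ij sin(theta_j - theta_i)``."""
    th = np.asarray(theta, dtype=float)
    if th.shape != (g.weights.shape[0],):
        raise ValueError("theta length must match node count")
    s, c = np.sin(th), np.cos(th)
    dtheta = g.natural_freq + c * (g.weights @ s) - s * (g.weights @ c)
    return wrap_phase(th + eta * dtheta)


def kuramoto_energy(theta: np.ndarray, g: OscillatorGraph) -> float:
    """``E = -sum over ordered pairs i != j of w_ij cos(theta_i - theta_j)``.

    Each undirected pair is counted twice (the diagonal is zero by the graph
    invariant, so it contributes nothing).
    """
    th = np.asarray(theta, dtype=float)
    diff = th[:, None] - th[None, :]
    return float(-(g.weights * np.cos(diff)).sum())
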