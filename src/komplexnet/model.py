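"""The KomplexNet architecture, its baselines, readout and combined loss.

Layer chain (default configuration):

=====  =============================  ==================
layer  operation                      activity shape
=====  =============================  ==================
L0     real conv (8 ch) + Kuramoto    complex 8 x 32 x 32
L1     complex conv, stride 2         complex 8 x 16 x 16
L2     complex dense                  complex 50
L4     complex dense (readout)        complex 10
=====  =============================  ==================

The amplitudes at L0 are extracted once per image by a rectified real
convolution and held fixed; only the phases evolve, one Kuramoto step per
network timestep, and the complex activity is re-propagated bottom-up at
every step with shared weights.  The readout takes the last layer's gated
magnitude after normalization but before rectification as 10 per-class
logits (rectified magnitudes would be one-sidedly nonnegative and saturate
the sigmoids).  Training minimizes the per-timestep binary cross-entropy
accumulated over all timesteps plus ``tau`` times the cluster synchrony loss
of the final phases.

Model kinds:

* ``komplexnet`` — lateral Kuramoto dynamic at L0;
* ``komplexnet_fb`` — same plus top-down feedback coupling from L1/L2/L4;
* ``complex_random`` — phases frozen at their random initialization (no
  dynamic; the lower reference);
* ``complex_ideal`` — phases assigned from ground-truth masks to equidistant
  values on the unit circle (upper baseline);
* ``real`` — a real-valued network with the same shapes and normalization
  placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import as_data
from .complex_core import (
    ComplexActivation,
    LayerTrace,
    amplitude_activation,
    complex_apply,
    make_complex,
    normalize,
    synchrony_gate,
    wrap_phase,
)
from .feedback import FeedbackCouplings, feedback_update, init_feedback
from .kuramoto import CouplingKernel, init_gaussian_kernel, kuramoto_step
from .synchrony import GroupMasks, cluster_synchrony_loss

MODEL_KINDS = ("real", "complex_random", "complex_ideal", "komplexnet", "komplexnet_fb")


@dataclass
class ModelConfig:
    """Architecture and dynamic hyperparameters (defaults shipped here).

    The Kuramoto constants (``scale_l0``, ``epsilon``, ``eta_l0``) were set
    once by simulating the untrained dynamic on generated scenes until phase
    clusters formed within the default 15 timesteps; see the methods note.
    """

    n_classes: int = 10
    channels: int = 8
    canvas: int = 32
    k_conv0: int = 5      # real feature-extraction conv (same padding)
    k_l0: int = 7         # lateral Kuramoto kernel
    sigma_l0: float = 1.5
    scale_l0: float = 0.02
    epsilon: float = 0.0033
    eta_l0: float = 1.0
    k_l1: int = 5         # complex conv, stride 2
    hidden: int = 50
    timesteps: int = 15
    tau: float = 2.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    # feedback
    k_fb: int = 5
    fb_sigma: float = 1e-3
    eta_fb: Sequence[float] = (0.2, 0.05, 0.05)
    dtype: str = "float32"

    def __post_init__(self):
        self.eta_fb = tuple(self.eta_fb)


@dataclass
class NetworkState:
    """Per-timestep activities of every layer plus the class scores."""

    z_L0: ComplexActivation
    z_L1: ComplexActivation
    z_L2: ComplexActivation
    z_L4: ComplexActivation
    trace_L4: LayerTrace
    scores: object  # logits (N, n_classes)
    t: int = 0


@dataclass
class LossSpec:
    """Loss balance ``tau`` and the multi-hot target labels."""

    tau: float
    labels: np.ndarray

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if np.asarray(self.labels).sum() < 1:
            raise ValueError("labels must mark at least one class")


@dataclass
class ForwardResult:
    scores_per_t: List[object]          # T entries of (N, n_classes) logits
    thetas_per_t: Optional[List[object]]  # L0 phases per timestep (dynamic kinds)
    final_state: NetworkState
    theta_last: Optional[object]


def init_phases(shape, seed: int) -> np.ndarray:
    """I.i.d. uniform phases on (-pi, pi], reproducible by seed."""
    rng = np.random.default_rng(seed)
    return (-rng.uniform(-np.pi, np.pi, size=shape)).astype(np.float32)


def ideal_phase_assignment(masks: GroupMasks, seed: int) -> np.ndarray:
    """Ground-truth phases: equidistant group values on the unit circle.

    A random global offset and a random group-to-value permutation are drawn
    from ``seed``; group ``l`` gets ``offset + 2*pi*perm(l)/N`` on all its
    pixels.  Overlap (excluded) regions get the circular mean of their two
    parents' values — when the parents are antipodal the mean is degenerate
    and the tie is broken deterministically to the first parent's value plus
    pi/2.  Background pixels get fresh uniform random phases.
    """
    rng = np.random.default_rng(seed)
    included = masks.included()
    n_groups = len(included)
    if n_groups < 1:
        raise ValueError("need at least one non-excluded group")
    offset = -rng.uniform(-np.pi, np.pi)
    perm = rng.permutation(n_groups)
    values = wrap_phase(offset + 2.0 * np.pi * perm / n_groups)

    h, w = included[0].shape
    fieldv = (-rng.uniform(-np.pi, np.pi, size=(h, w))).astype(np.float64)
    for val, m in zip(values, included):
        fieldv[m.astype(bool)] = val

    excluded = [m for m, ex in zip(masks.masks, masks.excluded_flags) if ex]
    if excluded and n_groups >= 2:
        from scipy import ndimage

        for exm in excluded:
            grown = ndimage.binary_dilation(exm.astype(bool), iterations=2)
            contact = [np.logical_and(grown, m.astype(bool)).sum() for m in included]
            parents = np.argsort(contact)[::-1][:2]
            v1, v2 = values[parents[0]], values[parents[1]]
            z = np.exp(1j * v1) + np.exp(1j * v2)
            if abs(z) < 1e-9:
                mean_val = wrap_phase(values[min(parents)] + np.pi / 2)
            else:
                mean_val = float(np.angle(z))
            fieldv[exm.astype(bool)] = mean_val
    return wrap_phase(fieldv).astype(np.float32)


def _he(rng, shape, fan_in, dtype):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(dtype)


class Model:
    """One network (any kind) with its parameters and forward pass."""

    def __init__(self, kind: str, config: ModelConfig, seed: int = 0):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind '{kind}'; choose from {MODEL_KINDS}")
        self.kind = kind
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config.channels
        dt = config.dtype
        flat1 = c * (config.canvas // 2) ** 2
        self.params: Dict[str, np.ndarray] = {
            "conv0": _he(rng, (c, 1, config.k_conv0, config.k_conv0), config.k_conv0**2, dt),
            "conv1": _he(rng, (c, c, config.k_l1, config.k_l1), c * config.k_l1**2, dt),
            "dense2": _he(rng, (flat1, config.hidden), flat1, dt),
            "dense4": _he(rng, (config.hidden, config.n_classes), config.hidden, dt),
        }
        if kind in ("komplexnet", "komplexnet_fb"):
            self.params["kuramoto_r"] = init_gaussian_kernel(
                c, config.k_l0, config.k_l0, config.sigma_l0, config.scale_l0
            ).r.astype(dt)
        if kind == "komplexnet_fb":
            fb = init_feedback(c, config.k_fb, (config.hidden, config.n_classes),
                               seed=seed + 1, sigma=config.fb_sigma, eta_fb=config.eta_fb)
            self.params["fb_conv"] = fb.r_conv
            self.params["fb_d2"] = fb.r_dense[0]
            self.params["fb_d4"] = fb.r_dense[1]

    # -- building blocks ---------------------------------------------------
    def extract_amplitudes(self, images, params=None):
        """Rectified same-size real convolution of the input image(s)."""
        p = params or self.params
        x = images if as_data(images).ndim == 4 else _add_chan(images)
        return ad.relu(ad.conv2d(x, p["conv0"], stride=1, padding=self.config.k_conv0 // 2))

    def propagate(self, amplitudes, theta, params=None, t: int = 0) -> NetworkState:
        """Bottom-up pass through the complex layers from a given L0 phase."""
        p = params or self.params
        cfg = self.config
        n = as_data(amplitudes).shape[0]
        z0 = ComplexActivation(amplitudes, theta)

        f1 = lambda x: ad.conv2d(x, p["conv1"], stride=2, padding=cfg.k_l1 // 2)
        z1_lin = complex_apply(z0, f1)
        tr1 = synchrony_gate(z1_lin, z0, f1)
        z1 = amplitude_activation(tr1, (-2, -1))

        flat = (n, -1)
        z1f = ComplexActivation(ad.reshape(z1.amplitude, flat), ad.reshape(z1.phase, flat))
        f2 = lambda x: ad.matmul(x, p["dense2"])
        z2_lin = complex_apply(z1f, f2)
        tr2 = synchrony_gate(z2_lin, z1f, f2)
        z2 = amplitude_activation(tr2, (-1,))

        f4 = lambda x: ad.matmul(x, p["dense4"])
        z4_lin = complex_apply(z2, f4)
        tr4 = synchrony_gate(z4_lin, z2, f4)
        logits = readout(tr4)
        z4 = ComplexActivation(ad.relu(logits), tr4.z1.phase)
        tr4.z3 = z4
        return NetworkState(z_L0=z0, z_L1=z1, z_L2=z2, z_L4=z4,
                            trace_L4=tr4, scores=logits, t=t)

    def _real_forward(self, images, params=None):
        p = params or self.params
        cfg = self.config
        x = images if as_data(images).ndim == 4 else _add_chan(images)
        h0 = ad.relu(ad.conv2d(x, p["conv0"], stride=1, padding=cfg.k_conv0 // 2))
        h1 = ad.relu(normalize(ad.conv2d(h0, p["conv1"], stride=2, padding=cfg.k_l1 // 2), (-2, -1)))
        n = as_data(h1).shape[0]
        h1f = ad.reshape(h1, (n, -1))
        h2 = ad.relu(normalize(ad.matmul(h1f, p["dense2"]), (-1,)))
        return normalize(ad.matmul(h2, p["dense4"]), (-1,))

    def coupling(self, params=None) -> CouplingKernel:
        p = params or self.params
        return CouplingKernel(r=p["kuramoto_r"], epsilon=self.config.epsilon,
                              eta=self.config.eta_l0)

    def feedback_couplings(self, params=None) -> FeedbackCouplings:
        p = params or self.params
        return FeedbackCouplings(r_conv=p["fb_conv"], r_dense=[p["fb_d2"], p["fb_d4"]],
                                 eta_fb=list(self.config.eta_fb))

    # -- forward -----------------------------------------------------------
    def forward(self, images, masks: Optional[Sequence[GroupMasks]] = None,
                T: Optional[int] = None, phase_seed: int = 0,
                params=None, theta0: Optional[np.ndarray] = None,
                grad_window: Optional[int] = None) -> ForwardResult:
        """Full unrolled pass; returns per-timestep scores and phases.

        ``masks`` is required by the ideal-phase kind; ``phase_seed`` makes
        the random phase initialization reproducible, and ``theta0``
        overrides it with an explicit initial phase field.  Models without a
        phase dynamic compute one step and repeat its scores at every
        timestep.

        ``grad_window=k`` (training only, with tensor ``params``) runs the
        first ``T - k`` timesteps of the phase dynamic gradient-free and
        builds the autodiff graph only over the last ``k`` steps — the
        regime where the phases have organized into clusters.  Scores and
        phases are then reported for those last ``k`` steps only.
        """
        cfg = self.config
        T = T or cfg.timesteps
        if T < 1:
            raise ValueError("T must be >= 1")
        imgs = np.asarray(as_data(images), dtype=cfg.dtype)
        if imgs.ndim == 2:
            imgs = imgs[None]
        n = imgs.shape[0]

        if self.kind == "real":
            logits = self._real_forward(imgs, params=params)
            return ForwardResult(scores_per_t=[logits] * T, thetas_per_t=None,
                                 final_state=None, theta_last=None)

        amps = self.extract_amplitudes(imgs, params=params)
        shape = (n, cfg.channels, cfg.canvas, cfg.canvas)

        if self.kind in ("complex_random", "complex_ideal"):
            if self.kind == "complex_random":
                theta = theta0 if theta0 is not None else init_phases(shape, phase_seed)
            else:
                if masks is None:
                    raise ValueError("complex_ideal requires ground-truth masks")
                per_px = np.stack([
                    ideal_phase_assignment(m, seed=phase_seed + i)
                    for i, m in enumerate(masks)
                ])
                theta = np.broadcast_to(per_px[:, None], shape).copy()
            state = self.propagate(amps, theta, params=params)
            return ForwardResult(scores_per_t=[state.scores] * T,
                                 thetas_per_t=[theta] * T,
                                 final_state=state, theta_last=theta)

        # kuramoto-driven kinds
        kernel = self.coupling(params)
        fb = self.feedback_couplings(params) if self.kind == "komplexnet_fb" else None
        theta = theta0 if theta0 is not None else init_phases(shape, phase_seed)
        scores_per_t, thetas_per_t = [], []
        state = None

        n_free = 0
        if grad_window is not None and 0 < grad_window < T:
            # gradient-free phase chain over the early steps, on plain arrays
            n_free = T - grad_window
            amps_nd = as_data(amps)
            kernel_nd = CouplingKernel(r=as_data(kernel.r), epsilon=kernel.epsilon,
                                       eta=kernel.eta)
            fb_nd = None
            if fb is not None:
                fb_nd = FeedbackCouplings(
                    r_conv=as_data(fb.r_conv),
                    r_dense=[as_data(r) for r in fb.r_dense],
                    eta_fb=fb.eta_fb)
            params_nd = {k: as_data(v) for k, v in (params or self.params).items()}
            theta_nd = as_data(theta)
            state_nd = None
            for t in range(n_free):
                fb_field = None
                if fb_nd is not None and state_nd is not None:
                    fb_field = feedback_update(theta_nd, state_nd, fb_nd)
                _, theta_nd = kuramoto_step(theta_nd, amps_nd, kernel_nd,
                                            feedback=fb_field)
                if fb_nd is not None:
                    state_nd = self.propagate(amps_nd, theta_nd, params=params_nd, t=t)
            theta = theta_nd
            if fb is not None:
                state = state_nd

        for t in range(n_free, T):
            fb_field = None
            if fb is not None and state is not None:
                fb_field = feedback_update(theta, state, fb)
            _, theta = kuramoto_step(theta, amps, kernel, feedback=fb_field)
            state = self.propagate(amps, theta, params=params, t=t)
            scores_per_t.append(state.scores)
            thetas_per_t.append(theta)
        return ForwardResult(scores_per_t=scores_per_t, thetas_per_t=thetas_per_t,
                             final_state=state, theta_last=theta)

    # -- training plumbing -------------------------------------------------
    def trainable(self) -> Dict[str, ad.Tensor]:
        """Parameters wrapped as autodiff tensors (shared storage refresh
        happens through :meth:`commit`)."""
        return {k: ad.Tensor(v) for k, v in self.params.items()}

    def commit(self, tensors: Dict[str, ad.Tensor]) -> None:
        for k, t in tensors.items():
            self.params[k] = t.data

    def save(self, path) -> None:
        """Single-file checkpoint: weight arrays plus a config echo."""
        meta = json.dumps({"kind": self.kind, "seed": self.seed,
                           "config": _config_dict(self.config)})
        np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            model = cls(meta["kind"], cfg, seed=meta["seed"])
            for k in model.params:
                model.params[k] = data[k]
        return model


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    d["eta_fb"] = list(d["eta_fb"])
    return d


def _add_chan(images):
    x = as_data(images)
    return x.reshape(x.shape[0], 1, *x.shape[1:]) if x.ndim == 3 else x[None, None]


def build_model(kind: str, config: Optional[ModelConfig] = None, seed: int = 0) -> Model:
    """Construct any of the five model kinds with a shared architecture."""
    return Model(kind, config or ModelConfig(), seed=seed)


def readout(final_trace: LayerTrace):
    """Class logits: the gated magnitude of the last layer, normalized per
    sample over units, without rectification."""
    return normalize(final_trace.m2, (-1,))


def bce_with_logits(logits, labels):
    """Mean over classes (and batch) of per-class binary cross-entropy."""
    y = as_data(labels).astype(as_data(logits).dtype)
    x = logits
    return ad.mean(ad.relu(x) - x * y + ad.log(1.0 + ad.exp(-ad.absolute(x))))


def combined_loss(scores_per_t, labels, theta_T, masks: Sequence[GroupMasks], tau: float,
                  bce_weight: float = 1.0):
    """Accumulated per-timestep BCE plus ``tau`` times the final-step
    cluster synchrony loss (averaged over the batch).  ``bce_weight``
    rescales the accumulated BCE when the score list covers only a window
    of the unrolled timesteps."""
    total = 0.0
    for scores in scores_per_t:
        total = total + bce_weight * bce_with_logits(scores, labels)
    if tau > 0:
        if masks is None:
            raise ValueError("tau > 0 requires ground-truth masks")
        cs = 0.0
        for b, m in enumerate(masks):
            cs = cs + cluster_synchrony_loss(theta_T[b], m)
        total = total + tau * cs / len(masks)
    return total
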