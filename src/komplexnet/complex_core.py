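"""Complex-valued activations and the shared layer operations.

A unit's activity is a complex number ``z = m * exp(i*theta)``: the amplitude
``m`` carries feature strength exactly as in a real-valued network, while the
phase ``theta`` tags object membership.  Layers keep real-valued weights and
act on the complex activity through three steps:

1. *linear application* — the same real weights are applied to the real and
   imaginary parts, rotating and scaling the activity jointly;
2. *synchrony gating* — the resulting magnitude is averaged with the "classic"
   term ``chi = f(|z|)`` (the response the layer would give to phase-aligned
   input), so out-of-phase inputs are attenuated instead of acting like
   inhibition from negative weights;
3. *normalized rectification* — the gated magnitude is standardized and passed
   through a ReLU, while the phase from step 1 is kept unchanged.

All functions accept plain numpy arrays or autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _fast, autodiff as ad
from .autodiff import as_data

_AMP_EPS = 1e-24  # inside sqrt: keeps the magnitude differentiable at z=0
_NORM_EPS = 1e-5  # stabilizer on the standard deviation


def wrap_phase(theta):
    """Wrap phases to (-pi, pi]; idempotent, gradient-transparent."""
    return ad.wrap_angle(theta)


@dataclass
class ComplexActivation:
    """Amplitude/phase representation of a complex-valued activity field.

    Invariants: ``amplitude >= 0``, ``phase`` in (-pi, pi], equal shapes.
    """

    amplitude: object
    phase: object

    @property
    def shape(self):
        return as_data(self.amplitude).shape

    def real(self):
        return self.amplitude * ad.cos(self.phase)

    def imag(self):
        return self.amplitude * ad.sin(self.phase)

    def rotated(self, phi: float) -> "ComplexActivation":
        """Multiply by the unit complex number exp(i*phi)."""
        return ComplexActivation(self.amplitude, wrap_phase(self.phase + phi))


@dataclass
class LayerTrace:
    """Intermediate quantities of one complex layer.

    ``z1`` is the post-linear activity, ``chi`` the classic (phase-blind)
    modulation term, ``m2 = (|z1| + chi) / 2`` the gated magnitude and ``z3``
    the layer output once the normalized rectification has been applied.
    """

    z1: ComplexActivation
    chi: object
    m2: object
    z3: Optional[ComplexActivation] = None


def make_complex(amplitude, phase) -> ComplexActivation:
    """Build a validated activation from an amplitude and a phase field."""
    amp_d, ph_d = as_data(amplitude), as_data(phase)
    if amp_d.shape != ph_d.shape:
        raise ValueError(f"shape mismatch: amplitude {amp_d.shape} vs phase {ph_d.shape}")
    if not (np.all(np.isfinite(amp_d)) and np.all(np.isfinite(ph_d))):
        raise ValueError("non-finite entries in amplitude or phase")
    if np.any(amp_d < 0):
        raise ValueError("amplitude must be nonnegative everywhere")
    return ComplexActivation(amplitude, wrap_phase(phase))


def complex_apply(z: ComplexActivation, f: Callable) -> ComplexActivation:
    """Apply a bias-free real-valued linear map to a complex activity.

    The map acts separately on the real and imaginary parts with the same
    weights; the result is converted back to amplitude/phase form.  The phase
    of a zero-modulus output is set to 0 (inert, since the amplitude is 0).
    """
    if not isinstance(z.amplitude, ad.Tensor) and not isinstance(z.phase, ad.Tensor) \
            and _fast.HAVE_NUMBA:
        re0, im0 = _fast.polar_to_cart(np.asarray(z.amplitude), np.asarray(z.phase))
        re, im = f(re0), f(im0)
    else:
        re = f(z.real())
        im = f(z.imag())
    amplitude = ad.sqrt(re * re + im * im + _AMP_EPS)
    phase = ad.arctan2(im, re)
    return ComplexActivation(amplitude, phase)


def synchrony_gate(z1: ComplexActivation, z_in: ComplexActivation, f: Callable) -> LayerTrace:
    """Gate the post-linear magnitude by phase agreement.

    ``chi = f(|z_in|)`` is the response to a perfectly phase-aligned version of
    the input; averaging it with ``|z1|`` transmits in-phase inputs fully and
    attenuates out-of-phase inputs without making them inhibitory.
    """
    chi = f(z_in.amplitude)
    m2 = 0.5 * (z1.amplitude + chi)
    return LayerTrace(z1=z1, chi=chi, m2=m2)


def normalize(x, axes):
    """Standardize over ``axes`` (mean 0, unit variance, stabilized sd)."""
    mu = ad.mean(x, axis=axes, keepdims=True)
    centered = x - mu
    var = ad.mean(centered * centered, axis=axes, keepdims=True)
    return centered / (ad.sqrt(var) + _NORM_EPS)


def amplitude_activation(trace: LayerTrace, norm_axes) -> ComplexActivation:
    """Normalize the gated magnitude, rectify it, keep the post-linear phase.

    ``norm_axes`` selects the normalization population: the spatial axes for
    convolutional layers (instance style, per channel) or the unit axis for
    dense layers (per sample).  The result is stored on the trace as ``z3``.
    """
    if not np.all(np.isfinite(as_data(trace.m2))):
        raise ValueError("non-finite gated magnitude")
    out_amp = ad.relu(normalize(trace.m2, norm_axes))
    z3 = ComplexActivation(out_amp, trace.z1.phase)
    trace.z3 = z3
    return z3
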