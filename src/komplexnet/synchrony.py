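"""Circular statistics and the cluster synchrony loss.

Phases live on the unit circle, so dispersion is measured through the
resultant vector: for phases ``theta_1..theta_n`` the resultant length is
``R = |mean_k exp(i*theta_k)|``, the circular mean is the argument of the sum,
and the circular variance is ``V = 1 - R`` (0 for identical phases, 1 for
fully dispersed or antipodal sets).

The cluster synchrony loss scores a phase field against ground-truth object
groups:

    CSLoss = 1/2 * (1/G) * sum_l V_l  +  1/(2G) * | sum_l exp(i*<theta>_l) |^2

The first term rewards tight phases within each group; the second rewards
group centroids that cancel on the unit circle, i.e. clusters spread apart
(two groups end up antipodal, three at 120 degrees, ...).  Groups flagged as
excluded (the overlap region between two objects) contribute to neither term
and do not count toward G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import as_data

_RESULTANT_TOL = 1e-9


@dataclass
class GroupPhaseStats:
    """Resultant length, circular mean and circular variance of a phase set."""

    resultant_length: float
    circ_mean: float  # nan when mean_defined is False
    circ_variance: float
    mean_defined: bool = True


@dataclass
class GroupMasks:
    """Per-scene object membership masks over the image grid.

    ``masks[i]`` is a binary H x W field; ``excluded_flags[i]`` marks groups
    (overlap regions) that are left out of the synchrony loss.  Non-excluded
    masks must be pairwise disjoint and every mask must be non-empty; the
    background belongs to no mask.
    """

    masks: List[np.ndarray]
    excluded_flags: List[bool] = None

    def __post_init__(self):
        self.masks = [np.asarray(m) for m in self.masks]
        if self.excluded_flags is None:
            self.excluded_flags = [False] * len(self.masks)
        if len(self.excluded_flags) != len(self.masks):
            raise ValueError("one excluded flag per mask required")
        shape = None
        for m in self.masks:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")
            if m.sum() < 1:
                raise ValueError("every mask needs at least one active pixel")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("masks must share one shape")
        active = [m for m, ex in zip(self.masks, self.excluded_flags) if not ex]
        if len(active) > 1 and np.max(sum(active)) > 1:
            raise ValueError("non-excluded masks must be pairwise disjoint")

    @property
    def group_count(self) -> int:
        """Number of non-excluded groups (G in the loss)."""
        return sum(not ex for ex in self.excluded_flags)

    def included(self) -> List[np.ndarray]:
        return [m for m, ex in zip(self.masks, self.excluded_flags) if not ex]


def circular_stats(phases: Sequence[float]) -> GroupPhaseStats:
    """Resultant-vector statistics of a multiset of phases (radians)."""
    ph = np.asarray(phases, dtype=float).ravel()
    if ph.size < 1:
        raise ValueError("at least one phase required")
    s, c = np.sin(ph).sum(), np.cos(ph).sum()
    norm = float(np.hypot(s, c))
    resultant = norm / ph.size
    defined = norm >= _RESULTANT_TOL
    mean = float(np.arctan2(s, c)) if defined else float("nan")
    return GroupPhaseStats(
        resultant_length=resultant,
        circ_mean=mean,
        circ_variance=1.0 - resultant,
        mean_defined=defined,
    )


def cluster_synchrony_loss(theta, m: GroupMasks):
    """Cluster synchrony loss of a phase field against object masks.

    ``theta`` is a (C, H, W) phase field (numpy array or autodiff tensor);
    each group's phase multiset pools all C channels over the group's pixels.
    Raises if a group's circular mean is undefined (zero resultant), since
    the inter-cluster term needs a direction for every centroid.
    """
    included = m.included()
    G = len(included)
    if G < 1:
        raise ValueError("need at least one non-excluded group")
    th = theta
    C = as_data(th).shape[0]
    sin_t, cos_t = ad.sin(th), ad.cos(th)

    var_sum = 0.0
    cx_sum = 0.0
    cy_sum = 0.0
    for mask in included:
        mk = mask.astype(float)[None, :, :]
        n = C * float(mask.sum())
        s = ad.summation(sin_t * mk)
        c = ad.summation(cos_t * mk)
        norm = ad.sqrt(s * s + c * c)
        if float(as_data(norm)) < _RESULTANT_TOL:
            raise ValueError(
                "undefined circular mean: a group's phases cancel exactly "
                "(zero resultant); perturb the phases or drop the group"
            )
        var_sum = var_sum + (1.0 - norm / n)
        cx_sum = cx_sum + c / norm
        cy_sum = cy_sum + s / norm

    intra = 0.5 * var_sum / G
    inter = (cx_sum * cx_sum + cy_sum * cy_sum) / (2.0 * G)
    loss = intra + inter
    return loss if isinstance(loss, ad.Tensor) else float(loss)
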