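"""Multi-object scene synthesis with ground-truth grouping masks.

Scenes emulate the Multi-MNIST recipe: a black canvas (default 32 x 32), K
glyphs of distinct classes composited by maximum, each placed fully inside
the frame with a bounded pairwise overlap (fraction of each glyph's active
pixels).  Every scene carries one binary membership mask per object; when two
objects overlap, the shared pixels are moved into an extra mask flagged as
excluded, so the object masks stay disjoint and the ambiguous region never
enters the synchrony loss.  The background belongs to no mask.

A built-in bank of synthetic glyphs — compact, 4-connected, mostly vertical
stroke shapes in 10 classes — lets the whole pipeline run without downloads;
external glyph bitmaps (e.g. exported MNIST digits) can be loaded into the
same bank structure.  Perturbations: additive Gaussian pixel noise, smoothed
procedural background textures, and multi-frame motion (translating glyphs)
for video evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .synchrony import GroupMasks

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class GlyphBank:
    """Per-class lists of grayscale glyph bitmaps in [0, 1]."""

    glyphs: List[List[np.ndarray]]
    source: str = "synthetic"

    @property
    def n_classes(self) -> int:
        return len(self.glyphs)

    def pick(self, cls: int, rng: np.random.Generator) -> np.ndarray:
        options = self.glyphs[cls]
        return options[rng.integers(len(options))]


@dataclass
class SceneSample:
    """One generated scene: image, multi-hot labels, masks and metadata."""

    image: np.ndarray
    labels: np.ndarray
    masks: GroupMasks
    meta: Dict = field(default_factory=dict)


# -- synthetic glyphs ------------------------------------------------------

# Stroke templates in (row, col) fractions of the glyph box; the box is
# deliberately narrower than tall (width factor below) so glyphs come out
# mostly vertical, like handwritten digits.
_TEMPLATES: List[List[Tuple[Tuple[float, float], Tuple[float, float]]]] = [
    [((0.05, 0.5), (0.95, 0.5))],  # vertical bar
    [((0.05, 0.15), (0.05, 0.85)), ((0.05, 0.85), (0.95, 0.85)),
     ((0.95, 0.85), (0.95, 0.15)), ((0.95, 0.15), (0.05, 0.15))],  # O
    [((0.05, 0.2), (0.95, 0.2)), ((0.95, 0.2), (0.95, 0.9))],  # L
    [((0.05, 0.15), (0.95, 0.15)), ((0.95, 0.15), (0.95, 0.85)),
     ((0.95, 0.85), (0.05, 0.85))],  # U
    [((0.05, 0.1), (0.05, 0.9)), ((0.05, 0.5), (0.95, 0.5))],  # T
    [((0.05, 0.1), (0.05, 0.9)), ((0.05, 0.9), (0.95, 0.1)),
     ((0.95, 0.1), (0.95, 0.9))],  # Z
    [((0.05, 0.15), (0.95, 0.15)), ((0.5, 0.15), (0.5, 0.85)),
     ((0.05, 0.85), (0.95, 0.85))],  # H
    [((0.05, 0.1), (0.05, 0.9)), ((0.05, 0.9), (0.95, 0.4))],  # 7
    [((0.05, 0.15), (0.95, 0.85)), ((0.05, 0.85), (0.95, 0.15))],  # X
    [((0.05, 0.15), (0.95, 0.15)), ((0.05, 0.15), (0.05, 0.85)),
     ((0.5, 0.15), (0.5, 0.75)), ((0.95, 0.15), (0.95, 0.85))],  # E
]

_WIDTH_FACTOR = 0.68  # glyph box width relative to its height


def make_synthetic_glyphs(n_classes: int = 10, size: int = 14, per_class: int = 30,
                          seed: int = 0) -> GlyphBank:
    """Deterministic bank of stroke-drawn glyphs with per-instance jitter.

    Each instance draws its class template with endpoint jitter, dilates the
    strokes with a cross element (which also makes them 4-connected) and
    applies a random intensity.  Reproducible as a pure function of the
    arguments.
    """
    if size < 8:
        raise ValueError("glyph size must be >= 8")
    if n_classes > len(_TEMPLATES):
        raise ValueError(f"at most {len(_TEMPLATES)} synthetic classes available")
    rng = np.random.default_rng(seed)
    width = max(5, int(round(size * _WIDTH_FACTOR)))
    bank: List[List[np.ndarray]] = []
    for cls in range(n_classes):
        instances = []
        for _ in range(per_class):
            canvas = np.zeros((size, width), dtype=bool)
            for (r0, c0), (r1, c1) in _TEMPLATES[cls]:
                jit = rng.integers(-1, 2, size=4)
                rr0 = int(np.clip(round(r0 * (size - 1)) + jit[0], 0, size - 1))
                cc0 = int(np.clip(round(c0 * (width - 1)) + jit[1], 0, width - 1))
                rr1 = int(np.clip(round(r1 * (size - 1)) + jit[2], 0, size - 1))
                cc1 = int(np.clip(round(c1 * (width - 1)) + jit[3], 0, width - 1))
                rr, cc = draw_line(rr0, cc0, rr1, cc1)
                canvas[rr, cc] = True
            canvas = ndimage.binary_dilation(canvas, structure=_CROSS)
            if rng.random() < 0.25:
                canvas = ndimage.binary_dilation(canvas, structure=_CROSS)
            intensity = rng.uniform(0.75, 1.0)
            texture = rng.uniform(0.85, 1.0, size=canvas.shape)
            glyph = np.where(canvas, intensity * texture, 0.0)
            instances.append(glyph.astype(np.float32))
        bank.append(instances)
    return GlyphBank(glyphs=bank, source="synthetic")


def load_glyph_dir(path, size: int = 14) -> GlyphBank:
    """Load an external glyph bank from ``<path>/<class>/<image>`` files."""
    from PIL import Image

    root = Path(path)
    classes = sorted(p for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories under {root}")
    bank = []
    for cdir in classes:
        instances = []
        for f in sorted(cdir.iterdir()):
            img = Image.open(f).convert("L").resize((size, size))
            arr = np.asarray(img, dtype=np.float32) / 255.0
            arr[arr < 0.2] = 0.0
            if arr.max() > 0:
                instances.append(arr / arr.max())
        if not instances:
            raise ValueError(f"no usable glyphs in {cdir}")
        bank.append(instances)
    return GlyphBank(glyphs=bank, source="external")


# -- scene composition -----------------------------------------------------

def glyph_size_for(n_objects: int) -> int:
    """Downsampling target: 14 px glyphs for 2-3 objects, 10 px for more."""
    return 14 if n_objects <= 3 else 10


def _place(canvas: int, glyph: np.ndarray, top: int, left: int) -> np.ndarray:
    full = np.zeros((canvas, canvas), dtype=np.float32)
    gh, gw = glyph.shape
    full[top : top + gh, left : left + gw] = glyph
    return full


def compose_scene(bank: GlyphBank, n_objects: int, max_overlap: float,
                  canvas: int = 32, seed: int = 0, min_overlap: float = 0.0,
                  max_retries: int = 500) -> SceneSample:
    """Compose one scene of ``n_objects`` distinct-class glyphs.

    Placement is rejection-sampled: every glyph lies fully inside the canvas,
    and for every pair the intersection covers at most ``max_overlap`` of
    each glyph's active pixels.  ``min_overlap > 0`` additionally requires
    each glyph after the first to overlap the previously placed ones by at
    least that fraction of its own pixels (used by the overlap protocol to
    guarantee genuinely ambiguous scenes).  The first glyph lands in the
    upper-left quadrant of the admissible region.
    """
    if n_objects > bank.n_classes:
        raise ValueError("n_objects exceeds the number of distinct classes")
    rng = np.random.default_rng(seed)
    classes = rng.choice(bank.n_classes, size=n_objects, replace=False)
    glyphs = [bank.pick(c, rng) for c in classes]

    fields: List[np.ndarray] = []
    actives: List[np.ndarray] = []
    positions: List[Tuple[int, int]] = []
    for idx, glyph in enumerate(glyphs):
        gh, gw = glyph.shape
        if gh > canvas or gw > canvas:
            raise ValueError("glyph larger than canvas")
        hi_t, hi_l = canvas - gh, canvas - gw
        placed = False
        for _ in range(max_retries):
            if idx == 0:
                top = int(rng.integers(0, hi_t // 2 + 1))
                left = int(rng.integers(0, hi_l // 2 + 1))
            else:
                top = int(rng.integers(0, hi_t + 1))
                left = int(rng.integers(0, hi_l + 1))
            full = _place(canvas, glyph, top, left)
            act = full > 0
            ok = True
            for other in actives:
                inter = np.logical_and(act, other).sum()
                if inter / act.sum() > max_overlap or inter / other.sum() > max_overlap:
                    ok = False
                    break
            if ok and idx > 0 and min_overlap > 0:
                union = np.logical_or.reduce(actives)
                if np.logical_and(act, union).sum() / act.sum() < min_overlap:
                    ok = False
            if ok:
                fields.append(full)
                actives.append(act)
                positions.append((top, left))
                placed = True
                break
        if not placed:
            constraint = "min_overlap" if min_overlap > 0 else "max_overlap"
            raise RuntimeError(
                f"placement retry budget exhausted for object {idx} "
                f"(constraint: {constraint}={min_overlap if min_overlap > 0 else max_overlap})"
            )

    image = np.max(np.stack(fields), axis=0)
    coverage = np.sum(np.stack(actives).astype(int), axis=0)

    masks: List[np.ndarray] = []
    flags: List[bool] = []
    overlap_fracs = []
    for act in actives:
        own = np.logical_and(act, coverage == 1)
        masks.append(own.astype(np.uint8))
        flags.append(False)
        overlap_fracs.append(float(np.logical_and(act, coverage > 1).sum() / act.sum()))
    for i in range(n_objects):
        for j in range(i + 1, n_objects):
            inter = np.logical_and(actives[i], actives[j])
            if inter.any():
                masks.append(inter.astype(np.uint8))
                flags.append(True)

    n_classes = bank.n_classes
    labels = np.zeros(n_classes, dtype=np.uint8)
    labels[classes] = 1
    meta = {
        "classes": [int(c) for c in classes],
        "positions": [list(map(int, p)) for p in positions],
        "overlap_fractions": overlap_fracs,
        "noise_sigma": 0.0,
        "background": False,
    }
    return SceneSample(image=image, labels=labels,
                       masks=GroupMasks(masks=masks, excluded_flags=flags), meta=meta)


def add_gaussian_noise(s: SceneSample, sigma: float, seed: int = 0) -> SceneSample:
    """Additive i.i.d. pixel noise N(0, sigma^2), clipped to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return s
    rng = np.random.default_rng(seed)
    noisy = np.clip(s.image + rng.normal(0.0, sigma, s.image.shape), 0.0, 1.0)
    meta = dict(s.meta, noise_sigma=float(sigma))
    return SceneSample(image=noisy.astype(np.float32), labels=s.labels, masks=s.masks, meta=meta)


def make_texture(shape: Tuple[int, int], seed: int, smoothness: float = 2.0) -> np.ndarray:
    """Smoothed-noise grayscale texture in [0, 1] with spatial correlation."""
    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.uniform(size=shape), smoothness)
    lo, hi = raw.min(), raw.max()
    return ((raw - lo) / max(hi - lo, 1e-12)).astype(np.float32)


def add_background_texture(s: SceneSample, seed: int = 0, b_max: float = 0.4,
                           background: Optional[np.ndarray] = None) -> SceneSample:
    """Composite the scene over a textured background (max compositing).

    The texture is procedurally generated smoothed noise scaled to
    [0, b_max]; an explicit grayscale ``background`` image can be supplied
    instead.  Masks and labels are unchanged — the background is never an
    object.
    """
    if background is None:
        tex = make_texture(s.image.shape, seed) * b_max
    else:
        tex = np.asarray(background, dtype=np.float32)
        if tex.shape != s.image.shape:
            raise ValueError("background shape must match the scene")
        tex = np.clip(tex, 0.0, 1.0) * b_max
    out = np.maximum(s.image, tex)
    meta = dict(s.meta, background=True)
    return SceneSample(image=out.astype(np.float32), labels=s.labels, masks=s.masks, meta=meta)


def make_video(bank: GlyphBank, n_objects: int, n_frames: int,
               velocities: Sequence[Tuple[int, int]], canvas: int = 32,
               seed: int = 0, max_retries: int = 500) -> List[SceneSample]:
    """Sequence of scenes with the same glyph instances translating per frame.

    Starting positions are rejection-sampled so that every trajectory stays
    fully inside the canvas; each frame records its per-object overlap
    fractions and the whole clip records the index of the maximum-overlap
    frame in every frame's metadata.
    """
    if len(velocities) != n_objects:
        raise ValueError("one (dy, dx) velocity per object required")
    rng = np.random.default_rng(seed)
    classes = rng.choice(bank.n_classes, size=n_objects, replace=False)
    glyphs = [bank.pick(c, rng) for c in classes]

    starts = []
    for glyph, (vy, vx) in zip(glyphs, velocities):
        gh, gw = glyph.shape
        lo_t = max(0, -(n_frames - 1) * vy)
        hi_t = min(canvas - gh, canvas - gh - (n_frames - 1) * vy)
        lo_l = max(0, -(n_frames - 1) * vx)
        hi_l = min(canvas - gw, canvas - gw - (n_frames - 1) * vx)
        if hi_t < lo_t or hi_l < lo_l:
            raise ValueError("trajectory leaves the canvas for every start position")
        starts.append((int(rng.integers(lo_t, hi_t + 1)), int(rng.integers(lo_l, hi_l + 1))))

    n_classes = bank.n_classes
    labels = np.zeros(n_classes, dtype=np.uint8)
    labels[classes] = 1

    frames: List[SceneSample] = []
    max_fracs = []
    for f in range(n_frames):
        fields, actives = [], []
        for glyph, (t0, l0), (vy, vx) in zip(glyphs, starts, velocities):
            top, left = t0 + f * vy, l0 + f * vx
            full = _place(canvas, glyph, top, left)
            fields.append(full)
            actives.append(full > 0)
        image = np.max(np.stack(fields), axis=0)
        coverage = np.sum(np.stack(actives).astype(int), axis=0)
        masks, flags, fracs = [], [], []
        for act in actives:
            own = np.logical_and(act, coverage == 1)
            if not own.any():  # fully occluded glyph: keep its densest pixel
                own = np.zeros_like(act)
                idx = np.unravel_index(np.argmax(act), act.shape)
                own[idx] = True
            masks.append(own.astype(np.uint8))
            flags.append(False)
            fracs.append(float(np.logical_and(act, coverage > 1).sum() / act.sum()))
        for i in range(n_objects):
            for j in range(i + 1, n_objects):
                inter = np.logical_and(actives[i], actives[j])
                inter = np.logical_and(inter, coverage > 1)
                if inter.any():
                    masks.append(inter.astype(np.uint8))
                    flags.append(True)
        max_fracs.append(max(fracs))
        meta = {
            "classes": [int(c) for c in classes],
            "frame": f,
            "overlap_fractions": fracs,
            "noise_sigma": 0.0,
            "background": False,
        }
        frames.append(SceneSample(image=image, labels=labels,
                                  masks=GroupMasks(masks=masks, excluded_flags=flags),
                                  meta=meta))
    peak = int(np.argmax(max_fracs))
    for fr in frames:
        fr.meta["max_overlap_frame"] = peak
    return frames


def make_dataset(bank: GlyphBank, n_samples: int, n_objects: int = 2,
                 max_overlap: float = 0.0, canvas: int = 32, seed: int = 0,
                 min_overlap: float = 0.0, noise_sigma: float = 0.0,
                 background: bool = False) -> List[SceneSample]:
    """Generate a deterministic list of scenes from one master seed."""
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(3 * n_samples, dtype=np.uint32)
    samples = []
    for i in range(n_samples):
        s = compose_scene(bank, n_objects, max_overlap, canvas=canvas,
                          seed=int(child_seeds[3 * i]), min_overlap=min_overlap)
        if background:
            s = add_background_texture(s, seed=int(child_seeds[3 * i + 1]))
        if noise_sigma > 0:
            s = add_gaussian_noise(s, noise_sigma, seed=int(child_seeds[3 * i + 2]))
        samples.append(s)
    return samples


# -- container io ----------------------------------------------------------

def write_dataset(samples: Sequence[SceneSample], path) -> None:
    """Write scenes to ``<path>`` (npz arrays) plus a ``<path>.json`` sidecar."""
    path = Path(path)
    n = len(samples)
    if n == 0:
        raise ValueError("no samples to write")
    h, w = samples[0].image.shape
    gmax = max(len(s.masks.masks) for s in samples)
    n_classes = samples[0].labels.shape[0]
    images = np.zeros((n, h, w), dtype=np.float32)
    labels = np.zeros((n, n_classes), dtype=np.uint8)
    masks = np.zeros((n, gmax, h, w), dtype=np.uint8)
    excluded = np.zeros((n, gmax), dtype=np.uint8)
    counts = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(samples):
        images[i] = s.image
        labels[i] = s.labels
        g = len(s.masks.masks)
        counts[i] = g
        for j, (m, ex) in enumerate(zip(s.masks.masks, s.masks.excluded_flags)):
            masks[i, j] = m
            excluded[i, j] = 1 if ex else 0
    np.savez(path, images=images, labels=labels, masks=masks,
             excluded=excluded, group_counts=counts)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps([s.meta for s in samples]))


def read_dataset(path) -> List[SceneSample]:
    """Inverse of :func:`write_dataset`; raises naming any missing field."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        for key in ("images", "labels", "masks", "excluded", "group_counts"):
            if key not in data:
                raise ValueError(f"malformed dataset container: missing field '{key}'")
        images, labels = data["images"], data["labels"]
        masks, excluded, counts = data["masks"], data["excluded"], data["group_counts"]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        sidecar = Path(str(path).removesuffix(".npz") + ".json")
    metas = json.loads(sidecar.read_text()) if sidecar.exists() else [{}] * len(images)
    samples = []
    for i in range(len(images)):
        g = int(counts[i])
        gm = GroupMasks(masks=[masks[i, j] for j in range(g)],
                        excluded_flags=[bool(excluded[i, j]) for j in range(g)])
        samples.append(SceneSample(image=images[i], labels=labels[i], masks=gm,
                                   meta=metas[i]))
    return samples
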