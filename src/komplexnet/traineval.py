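"""Training loop, per-timestep evaluation and the study protocols.

Training minimizes the combined objective (accumulated per-timestep binary
cross-entropy plus ``tau`` times the final-step cluster synchrony loss) with
Adam over mini-batches, backpropagating through the unrolled phase dynamic.
A fixed fraction of the training set is held out for validation and the
parameters with the best validation loss are kept.

Evaluation scores every timestep: set-match accuracy (the top-K predicted
classes must equal the true K-object label set), per-label accuracy, and the
mean cluster synchrony loss of the first-layer phases.  Models without a
phase dynamic produce constant curves.

Protocols mirror the study conditions: ``in_dist`` (clean, non-overlapping
scenes), ``overlap`` (up to 25% pairwise overlap at test time on models
trained without overlap), ``noise`` (additive Gaussian pixel noise),
``background`` (textured backgrounds), ``n_objects`` (2..9 objects at test
time) and ``video`` (translating objects, curves indexed relative to the
maximum-overlap frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, as_data
from .datagen import (
    GlyphBank,
    SceneSample,
    add_gaussian_noise,
    glyph_size_for,
    make_dataset,
    make_synthetic_glyphs,
    make_video,
)
from .model import Model, ModelConfig, build_model, combined_loss
from .synchrony import cluster_synchrony_loss

PROTOCOLS = ("in_dist", "overlap", "noise", "n_objects", "background", "video")

# defaults of the perturbation protocols
OVERLAP_MAX = 0.25
OVERLAP_MIN = 0.05
NOISE_SIGMA = 0.1


@dataclass
class TrainConfig:
    """Optimization settings for one training run."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 3
    timesteps: int = 15
    train_timesteps: int = 0   # 0: unroll all `timesteps` during training
    grad_window: int = 0       # >0: backprop only through the last k steps
    tau: float = 2.0
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")


@dataclass
class EvalReport:
    """Per-timestep curves aggregated over one dataset."""

    accuracy_per_t: np.ndarray          # set-match accuracy, length T
    label_accuracy_per_t: np.ndarray    # per-label (elementwise) accuracy
    csloss_per_t: np.ndarray            # mean cluster synchrony loss
    protocol: str = "in_dist"
    model_kind: str = ""
    n_samples: int = 0

    @property
    def final_accuracy(self) -> float:
        return float(self.accuracy_per_t[-1])

    @property
    def final_csloss(self) -> float:
        return float(self.csloss_per_t[-1])


def accuracy_setmatch(scores: np.ndarray, labels: np.ndarray) -> int:
    """1 iff the top-K scores pick exactly the true K-label set.

    K is the number of active labels of this scene; score ties are broken
    toward the lower class index (stable sort on negated scores).
    """
    labels = np.asarray(labels)
    k = int(labels.sum())
    if k < 1:
        raise ValueError("at least one true label required")
    order = np.argsort(-np.asarray(scores), kind="stable")
    return int(set(order[:k]) == set(np.flatnonzero(labels)))


def _batches(n: int, size: int):
    for i in range(0, n, size):
        yield slice(i, min(i + size, n))


def _stack(samples: Sequence[SceneSample]):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    labels = np.stack([s.labels for s in samples])
    masks = [s.masks for s in samples]
    return imgs, labels, masks


def train(model: Model, dataset: Sequence[SceneSample], cfg: TrainConfig,
          log_path: Optional[str] = None) -> Dict:
    """Train ``model`` in place; returns a log of per-epoch loss terms.

    Requires masks (carried by every :class:`SceneSample`) whenever
    ``tau > 0``.  The best-validation-loss parameters are restored at the
    end.  Deterministic for fixed config and seeds.
    """
    if cfg.tau > 0 and any(s.masks is None for s in dataset):
        raise ValueError("tau > 0 requires datasets with group masks")
    rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_set = [dataset[i] for i in train_idx]
    val_set = [dataset[i] for i in val_idx]

    params = model.trainable()
    opt = Adam(params.values(), lr=cfg.learning_rate)
    log = {"epoch": [], "bce": [], "csloss": [], "total": [], "val_total": []}
    best_val, best_params = np.inf, {k: v.data.copy() for k, v in params.items()}
    from .model import bce_with_logits

    static = model.kind in ("real", "complex_random", "complex_ideal")
    # static kinds repeat one step; dynamic kinds may train on a shorter
    # unroll (train_timesteps) or backprop only through the last
    # `grad_window` steps of the full unroll (late-window BPTT)
    T_train = 1 if static else (cfg.train_timesteps or cfg.timesteps)
    gwin = None if static or not cfg.grad_window else cfg.grad_window

    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        ep_total = ep_bce = ep_cs = 0.0
        n_b = 0
        for sl in _batches(len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[sl]]
            imgs, labels, masks = _stack(batch)
            opt.zero_grad()
            res = model.forward(imgs, masks=masks, T=T_train,
                                phase_seed=cfg.seed * 100003 + step, params=params,
                                grad_window=gwin)
            scores = _per_step_scores(res, static, cfg.timesteps)
            tau = cfg.tau if model.kind != "real" else 0.0
            bw = (cfg.timesteps / len(scores)) if gwin else 1.0
            loss = combined_loss(scores, labels, res.theta_last, masks, tau=tau,
                                 bce_weight=bw)
            loss.backward()
            opt.step()
            total_v = float(as_data(loss))
            bce_v = float(sum(float(as_data(bce_with_logits(as_data(s_), labels)))
                              for s_ in scores))
            ep_total += total_v
            ep_bce += bce_v
            ep_cs += (total_v - bce_v) / tau if tau > 0 else 0.0
            step += 1
            n_b += 1
        model.commit(params)

        val_total = _validation_loss(model, val_set, cfg) if val_set else ep_total
        log["epoch"].append(epoch)
        log["bce"].append(ep_bce / max(1, n_b))
        log["csloss"].append(ep_cs / max(1, n_b))
        log["total"].append(ep_total / max(1, n_b))
        log["val_total"].append(val_total)
        if val_total < best_val:
            best_val = val_total
            best_params = {k: v.data.copy() for k, v in params.items()}

    model.params = best_params
    if log_path:
        _write_log(log, log_path)
    return log


def _per_step_scores(res, static: bool, timesteps: int):
    """Per-timestep score list entering the loss; a static model's single
    step stands in for every timestep (its scores are constant over time),
    and a truncated unroll keeps its own length."""
    if static:
        return res.scores_per_t[:1] * timesteps
    return res.scores_per_t


def _validation_loss(model: Model, val_set, cfg: TrainConfig) -> float:
    imgs, labels, masks = _stack(val_set)
    static = model.kind in ("real", "complex_random", "complex_ideal")
    T = 1 if static else (cfg.train_timesteps or cfg.timesteps)
    gwin = None if static or not cfg.grad_window else cfg.grad_window
    res = model.forward(imgs, masks=masks, T=T, phase_seed=cfg.seed + 777,
                        grad_window=gwin)
    scores = _per_step_scores(res, static, cfg.timesteps)
    tau = cfg.tau if model.kind != "real" else 0.0
    bw = (cfg.timesteps / len(scores)) if gwin else 1.0
    loss = combined_loss(scores, labels, res.theta_last, masks, tau=tau,
                         bce_weight=bw)
    return float(as_data(loss))


def _write_log(log: Dict, path) -> None:
    path = Path(path)
    keys = list(log.keys())
    lines = ["\t".join(keys)]
    for i in range(len(log["epoch"])):
        lines.append("\t".join(str(log[k][i]) for k in keys))
    path.write_text("\n".join(lines) + "\n")


def evaluate(model: Model, dataset: Sequence[SceneSample], T: int,
             phase_seed: int = 0, protocol: str = "in_dist",
             batch_size: int = 64) -> EvalReport:
    """Per-timestep accuracy and synchrony curves over a dataset."""
    acc = np.zeros(T)
    lab_acc = np.zeros(T)
    cs = np.zeros(T)
    n = len(dataset)
    can_cs = model.kind != "real"
    for sl in _batches(n, batch_size):
        batch = dataset[sl]
        imgs, labels, masks = _stack(batch)
        res = model.forward(imgs, masks=masks, T=T, phase_seed=phase_seed + sl.start)
        for t in range(T):
            scores_t = as_data(res.scores_per_t[t])
            for b in range(len(batch)):
                acc[t] += accuracy_setmatch(scores_t[b], labels[b])
            preds = (scores_t > 0).astype(int)
            lab_acc[t] += float((preds == labels).mean()) * len(batch)
            if can_cs:
                th_t = as_data(res.thetas_per_t[t])
                cs[t] += float(np.sum([
                    cluster_synchrony_loss(th_t[b], masks[b]) for b in range(len(batch))
                ]))
    acc /= n
    lab_acc /= n
    cs = cs / n if can_cs else np.full(T, np.nan)
    return EvalReport(accuracy_per_t=acc, label_accuracy_per_t=lab_acc,
                      csloss_per_t=cs, protocol=protocol,
                      model_kind=model.kind, n_samples=n)


def evaluate_video(model: Model, frames_per_clip: List[List[SceneSample]],
                   phase_seed: int = 0) -> Dict:
    """Accuracy per frame, indexed relative to the maximum-overlap frame.

    The phase state is carried across frames (one Kuramoto step per frame on
    the new frame's amplitudes), so earlier, less ambiguous frames can inform
    the grouping at peak overlap.  Static models are scored per frame.
    """
    from .kuramoto import kuramoto_step
    from .model import init_phases

    offsets: Dict[int, List[float]] = {}
    for ci, clip in enumerate(frames_per_clip):
        peak = clip[0].meta["max_overlap_frame"]
        labels = clip[0].labels
        if model.kind in ("real", "complex_random", "complex_ideal"):
            for f, fr in enumerate(clip):
                res = model.forward(fr.image[None], masks=[fr.masks], T=1,
                                    phase_seed=phase_seed + ci)
                a = accuracy_setmatch(as_data(res.scores_per_t[-1])[0], labels)
                offsets.setdefault(f - peak, []).append(a)
        else:
            cfg = model.config
            amps0 = as_data(model.extract_amplitudes(clip[0].image[None]))
            theta = init_phases(amps0.shape, phase_seed + ci)
            kernel = model.coupling()
            fb = model.feedback_couplings() if model.kind == "komplexnet_fb" else None
            state = None
            for f, fr in enumerate(clip):
                amps = as_data(model.extract_amplitudes(fr.image[None]))
                fb_field = None
                if fb is not None and state is not None:
                    from .feedback import feedback_update

                    fb_field = feedback_update(theta, state, fb)
                _, theta = kuramoto_step(theta, amps, kernel, feedback=fb_field)
                state = model.propagate(amps, theta, t=f)
                a = accuracy_setmatch(as_data(state.scores)[0], labels)
                offsets.setdefault(f - peak, []).append(a)
    return {off: float(np.mean(v)) for off, v in sorted(offsets.items())}


def run_protocol(tag: str, models: Dict[str, Model], bank: GlyphBank,
                 n_samples: int = 200, T: int = 15, seed: int = 0,
                 n_objects: int = 2) -> Dict[str, EvalReport]:
    """Evaluate every model on one protocol's dataset variant.

    Returns a mapping from model name to its :class:`EvalReport`; for
    ``n_objects`` the reports of each object count are keyed
    ``"<name>@<k>"``, and for ``video`` per-offset accuracy dictionaries are
    returned instead.
    """
    if tag not in PROTOCOLS:
        raise ValueError(f"unknown protocol '{tag}'; choose from {PROTOCOLS}")
    reports: Dict[str, EvalReport] = {}
    if tag == "in_dist":
        data = make_dataset(bank, n_samples, n_objects, 0.0, seed=seed + 50)
        for name, m in models.items():
            reports[name] = evaluate(m, data, T, phase_seed=seed, protocol=tag)
    elif tag == "overlap":
        data = make_dataset(bank, n_samples, n_objects, OVERLAP_MAX,
                            min_overlap=OVERLAP_MIN, seed=seed + 60)
        for name, m in models.items():
            reports[name] = evaluate(m, data, T, phase_seed=seed, protocol=tag)
    elif tag == "noise":
        data = make_dataset(bank, n_samples, n_objects, 0.0,
                            noise_sigma=NOISE_SIGMA, seed=seed + 70)
        for name, m in models.items():
            reports[name] = evaluate(m, data, T, phase_seed=seed, protocol=tag)
    elif tag == "background":
        data = make_dataset(bank, n_samples, n_objects, 0.0, background=True,
                            seed=seed + 80)
        for name, m in models.items():
            reports[name] = evaluate(m, data, T, phase_seed=seed, protocol=tag)
    elif tag == "n_objects":
        for k in range(2, 10):
            bank_k = bank
            if glyph_size_for(k) != glyph_size_for(n_objects):
                bank_k = make_synthetic_glyphs(bank.n_classes, glyph_size_for(k),
                                               per_class=30, seed=seed + 90)
            data = make_dataset(bank_k, max(20, n_samples // 4), k, OVERLAP_MAX,
                                seed=seed + 90 + k)
            for name, m in models.items():
                reports[f"{name}@{k}"] = evaluate(m, data, T, phase_seed=seed,
                                                  protocol=tag)
    elif tag == "video":
        rng = np.random.default_rng(seed + 95)
        clips = []
        for i in range(max(10, n_samples // 10)):
            v = int(rng.integers(1, 3))
            clips.append(make_video(bank, 2, n_frames=7,
                                    velocities=[(0, v), (0, -v)],
                                    seed=seed + 1000 + i))
        for name, m in models.items():
            reports[name] = evaluate_video(m, clips, phase_seed=seed)
    return reports


@dataclass
class StudyScale:
    """Desk-scale study conditions for the training-ordering experiments.

    One instance of the full training/evaluation pipeline at a size a
    single CPU can run: synthetic glyphs, two-object scenes, a truncated
    training unroll (end-to-end BPTT through ``train_timesteps`` Kuramoto
    steps) and full-length evaluation.  See docs/methods.md for the
    reasoning behind each value.
    """

    n_train: int = 4000
    epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 6e-3
    timesteps: int = 15
    grad_window: int = 1
    tau: float = 2.0
    n_eval: int = 100
    kinds: Sequence[str] = ("complex_random", "complex_ideal", "komplexnet")
    protocols: Sequence[str] = ("in_dist", "overlap", "noise")


def synchrony_comparison_scale() -> "StudyScale":
    """Paired feedforward-vs-feedback run for the synchrony comparison.

    The synchrony organization (driven by the cluster-synchrony term through
    the late-window gradient) converges with far fewer optimization steps
    than the classifier, so this paired comparison runs at a smaller data
    size than the accuracy study; both models get identical conditions.
    """
    return StudyScale(n_train=1500, epochs=1,
                      kinds=("komplexnet", "komplexnet_fb"),
                      protocols=("in_dist",))


def run_ordering_study(seeds: Sequence[int], scale: Optional[StudyScale] = None,
                       model_config: Optional[ModelConfig] = None,
                       verbose: bool = False) -> Dict:
    """Train every model kind per seed and evaluate the study protocols.

    Returns ``{seed: {"models": {kind: Model}, "reports": {protocol:
    {kind: EvalReport}}}}``.  All randomness derives from the seed list and
    the fixed glyph-bank seed, so reports are reproducible.
    """
    scale = scale or StudyScale()
    mcfg = model_config or ModelConfig(timesteps=scale.timesteps, tau=scale.tau)
    bank = make_synthetic_glyphs(10, 14, 30, seed=0)
    out: Dict = {}
    for seed in seeds:
        train_set = make_dataset(bank, scale.n_train, 2, 0.0, seed=seed + 10)
        tcfg = TrainConfig(learning_rate=scale.learning_rate,
                           batch_size=scale.batch_size, epochs=scale.epochs,
                           timesteps=scale.timesteps,
                           grad_window=scale.grad_window,
                           tau=scale.tau, seed=seed)
        models = {}
        for kind in scale.kinds:
            m = build_model(kind, mcfg, seed=seed)
            train(m, train_set, tcfg)
            models[kind] = m
            if verbose:
                print(f"[seed {seed}] trained {kind}", flush=True)
        reports = {}
        for tag in scale.protocols:
            reports[tag] = run_protocol(tag, models, bank,
                                        n_samples=scale.n_eval,
                                        T=scale.timesteps, seed=seed)
            if verbose:
                print(f"[seed {seed}] evaluated {tag}", flush=True)
        out[seed] = {"models": models, "reports": reports}
    return out


def study_summary(study: Dict) -> Dict:
    """Mean final-timestep accuracy and synchrony loss per kind/protocol."""
    seeds = list(study)
    kinds = list(study[seeds[0]]["reports"][
        list(study[seeds[0]]["reports"])[0]].keys())
    summary: Dict = {}
    for tag in study[seeds[0]]["reports"]:
        summary[tag] = {}
        for kind in kinds:
            accs = [study[s]["reports"][tag][kind].final_accuracy for s in seeds]
            css = [study[s]["reports"][tag][kind].final_csloss for s in seeds]
            summary[tag][kind] = {
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_per_seed": [float(a) for a in accs],
                "csloss_mean": float(np.mean(css)),
                "csloss_per_seed": [float(c) for c in css],
            }
    return summary


def pairwise_differences(reports: Dict[str, EvalReport], reference: str) -> Dict[str, float]:
    """Final-timestep accuracy difference of every model against a reference."""
    ref = reports[reference].final_accuracy
    return {name: r.final_accuracy - ref for name, r in reports.items()
            if name != reference}
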