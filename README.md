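# komplexnet

Complex-valued convolutional networks with Kuramoto phase synchronization
for multi-object scenes.

## The problem

When several objects share an image, an ordinary network entangles their
features — the *binding problem*. This package implements a synchrony-based
answer: every unit carries a complex activity `z = m·e^{iθ}` whose amplitude
`m` encodes feature strength (as in any CNN) and whose phase `θ` tags object
membership. A Kuramoto oscillator dynamic on the first layer,

    θ̇_cij = η · Σ_k (r_{k,cij} − ε) · sin(θ_k − θ_cij) · tanh(a_k),

with a learnable local coupling kernel `r` and a global desynchronizing
constant `ε`, pulls phases of nearby active features together and pushes
distinct groups apart, so each object settles into its own phase cluster.
Complex-valued layer operations (shared real weights on Re/Im, a synchrony
gate that attenuates out-of-phase input, normalization + ReLU on the
amplitude only) propagate the grouping to a 10-way multi-label readout.
A feedback variant couples the phases of deeper layers back into the
first-layer dynamic. Phase quality is measured by the cluster synchrony
loss

    CSLoss(θ) = 1/2 · (1/G) Σ_l V_l(θ) + 1/(2G) · ‖Σ_l e^{i⟨θ⟩_l}‖²

(within-group circular variance plus a penalty on group centroids failing
to cancel on the unit circle), which also enters training alongside the
accumulated per-timestep binary cross-entropy.

The package ships the full study apparatus: the model family (KomplexNet,
KomplexNet-with-feedback, and real-valued / random-phase / ideal-phase
baselines), a download-free Multi-MNIST-style scene generator with
ground-truth grouping masks, training with backpropagation through the
unrolled dynamic, and the evaluation protocols (clean, overlapping digits,
noise, textured background, 2–9 objects, moving-object videos). It targets
researchers studying binding-by-synchrony mechanisms in artificial networks.

## Worked example

```python
import numpy as np
from komplexnet import datagen as dg
from komplexnet.model import ModelConfig, build_model
from komplexnet.synchrony import cluster_synchrony_loss

bank = dg.make_synthetic_glyphs(n_classes=10, size=14, per_class=30, seed=0)
scene = dg.compose_scene(bank, n_objects=2, max_overlap=0.0, seed=7)
print(sorted(scene.meta["classes"]))

model = build_model("komplexnet", ModelConfig(), seed=0)
res = model.forward(scene.image[None], T=15, phase_seed=1)

theta = res.theta_last[0]          # (8, 32, 32) first-layer phases
for t in (0, 7, 14):
    cs = cluster_synchrony_loss(np.asarray(res.thetas_per_t[t])[0], scene.masks)
    print(f"t={t:2d}  CSLoss={cs:.3f}")
```

prints (untrained model, Gaussian coupling kernel):

```
[6, 8]
t= 0  CSLoss=1.136
t= 7  CSLoss=0.466
t=14  CSLoss=0.316
```

The two glyphs' phases start fully disordered (CSLoss at the random level
≈ 1) and, without any training, the Kuramoto dynamic pulls each object into
its own cluster and the clusters apart (CSLoss falling toward 0, the
ideal-phase value). Training the coupling kernel with the synchrony loss
tightens this further and trains the classifier on top.

CLI equivalents: `komplexnet scenegen --n-objects 2 --n-samples 1000 --out
scenes.npz`, `komplexnet train --data scenes.npz --model komplexnet --out
run/`, `komplexnet eval --checkpoint run/checkpoint.npz --protocol overlap
--out run/`.

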