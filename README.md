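# glcnet

Decoding imagined movements and cognitive tasks from non-invasive brain
recordings is the core problem of magnetoencephalography (MEG) and EEG
brain–computer interfaces. Task execution leaves band-limited,
spatially specific power changes (event-related
desynchronization/synchronization) in the sensor array, but single
trials are noisy, highly variable, and scarce. `glcnet` is a library +
CLI implementing **GLCNet**, a multi-branch neural decoder for epoched
multichannel signals, together with a synthetic-data generator that
plants exactly the signatures the decoder exploits — so the entire
method can be exercised, tested, and benchmarked without any recordings.

It is aimed at BCI/neural-decoding researchers who want a transparent,
fully seeded reference implementation: the network (forward passes,
backpropagation, Adam) is written in numpy and checked against finite
differences and independent oracles throughout the test suite.

## The model

An epoch `x ∈ R^{C×T}` (C channels, T samples) is first decomposed by a
**filter bank** of nine non-overlapping Chebyshev Type II band-passes
(4–8, 8–12, …, 36–40 Hz), giving a multi-view tensor `(9, C, T)`. Three
branches extract features:

1. **Graph branch (F1).** A temporal convolution front-end
   (kernel (1,10), batch-norm, max-pool (1,10), dropout) feeds two graph
   convolution layers over the sensor graph,

   `H^{l+1} = σ( D̃^{-1/2} (A+I) D̃^{-1/2} H^l W^l )`,  `D̃_ii = Σ_j (A+I)_ij`,

   with feature dimensions (64, 5). The adjacency `A` is the **phase
   lag index** (PLI) matrix — `PLI_jk = |⟨sign(φ_j(t) − φ_k(t))⟩|` —
   estimated on the *training partition only*, or alternatively
   `A_jk = 1 − d(S_j, S_k)` from min-max-normalized sensor distances. A
   channel-aggregating (C,1) convolution then produces 288 feature maps.
2. **Spatial branch (F3).** A grouped (C,1) spatial convolution (one
   group of 32 filters per band, 288 total), batch-norm, and
   non-overlapping temporal averaging (window T/5).
3. **Recurrent branch (F2).** A single-layer LSTM (standard
   input/forget/output gates and cell state) over the averaged spatial
   sequence, with a per-step linear readout back to 288 dimensions.

F1, F2, F3 are fused by elementwise summation, flattened (288·5 = 1440
features by default) and classified by a fully connected layer with
log-softmax. Training minimizes the **enhanced cross-entropy**

`H(p, q) = − Σ_x (1 − q(x))² p(x) ln q(x)`,

a focal-style reweighting that down-weights confidently correct trials,
and follows a **two-stage protocol**: stage 1 early-stops on validation
accuracy (patience 50, ≤100 epochs by default) and restores the
best-validation weights; stage 2 merges the validation set into
training and stops once the loss on the former validation trials drops
below stage 1's best validation loss. Accuracy, Cohen's kappa
`κ = (acc − p_e)/(1 − p_e)` and macro-F1 are derived from the confusion
matrix. Each of the three branches can be ablated independently.

## Worked example

```python
import numpy as np
from glcnet import (SynthConfig, generate_epochs, split_epochs, SplitSpec,
                    compute_pli_adjacency, ModelConfig, build_glcnet,
                    TrainConfig, train_two_stage, evaluate)

epochs = generate_epochs(SynthConfig(n_trials_per_class=40, n_classes=2,
                                     n_channels=16, duration_s=2.0, seed=42))
train, val, test = split_epochs(epochs, SplitSpec(seed=0))

adjacency = compute_pli_adjacency(train)          # sensor graph from train only
config = ModelConfig(n_channels=16, n_times=500, n_classes=2,
                     avg_window=100, spatial_filters=72, gcn_dims=(16, 5),
                     adjacency=adjacency)
model = build_glcnet(config, seed=0)
print(f"trainable parameters: {sum(model.parameter_registry().values()):,}")

model, history = train_two_stage(
    model, train, val,
    TrainConfig(max_epochs_stage1=8, patience=4, max_epochs_stage2=4,
                batch_size=16, seed=0))
print(f"stage-1 best validation accuracy: {history.best_val_accuracy:.3f} "
      f"(epoch {history.best_epoch})")
print(f"stage-2 stop criterion met: {history.stage2_criterion_met}")

report = evaluate(model, test)
print(f"held-out accuracy {report.accuracy:.3f}, "
      f"kappa {report.kappa:.3f}, macro-F1 {report.f1:.3f} "
      f"on n={report.n} trials")
```

Output:

```
trainable parameters: 30,228
stage-1 best validation accuracy: 1.000 (epoch 2)
stage-2 stop criterion met: True
held-out accuracy 1.000, kappa 1.000, macro-F1 1.000 on n=16 trials
```

The two classes differ only in which narrow band carries extra power on
which channel subset; perfect held-out recovery says the pipeline finds
exactly that planted structure.

The same pipeline is available from the shell:

```bash
glcnet simulate --seed 1 --out epochs.h5
glcnet train --config experiment.yaml --out run/
glcnet ablate --config experiment.yaml --out run_ablation/   # + comparison.csv
glcnet evaluate --checkpoint run/full/checkpoint.h5 --data epochs.h5
glcnet export-features --checkpoint run/full/checkpoint.h5 \
       --data epochs.h5 --layer fused --out features.csv
glcnet filterbank-check --sfreq 250 --out response.csv
glcnet inspect run/full/checkpoint.h5
```

Epoch files use a simple HDF5 layout (`/data`, `/labels`, `/sfreq`,
`/channel_names`, optional `/positions`); standard FIF epoch files are
read through `mne`.

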