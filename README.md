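# sensornet

Adaptive attention-convolution networks for multi-channel sensor
time-series classification — wearable IMU windows, EEG epochs, and similar
fixed-rate signals.

Pretrained networks port badly across sensing applications: the number of
sensor channels varies (a 6-axis IMU here, three EEG/EOG electrodes there),
so a convolutional first layer must be rebuilt and retrained per task, and
signal lengths vary, which changes every downstream feature-map size.
`sensornet` addresses both at the architecture level. Raw windows
`X ∈ R^{C×L}` become fixed-size log-magnitude spectrogram stacks
`S ∈ R^{C×H×W}` (so L drops out), and the network's trunk is built from
*cross-channel patch-wise self-attention* whose parameters are independent
of C (so the channel count drops out too). One trained trunk runs unchanged
on inputs with any number of channels; adapting to a new task replaces only
the final classification layer.

The trunk stacks three iterations. 1×1 convolutions over the head axis
generate query/key/value multi-head tensors (`M` heads); a sliding 2×2
*attention kernel* unfolds each head's maps into patch groups, and for each
group `b` the channels attend to each other:

    A[i, j, b] = softmax_j( sigmoid(q_i)_b · (k_j)_b ),
    out_i = Σ_j A[i, j, b] (v_j)_b

Patches fold back to maps, adaptive average pooling reduces them, and the
last iteration pools the channel axis away entirely, leaving one scalar per
head (256 by default). A learned sigmoid gate (head-importance learning)
re-weights the heads before a small MLP classifier. Generating and mixing
heads with 1×1 convolutions instead of concatenation plus a fully connected
layer is what keeps the default model at 0.83 M parameters (≈3.3 MB on
disk as float32). See `docs/methods.md` for the full model description and
parameter accounting.

The network (and its training loop — Adam, cross-entropy, last-layer-only
fine-tuning) is implemented on a compact reverse-mode autodiff core over
numpy, with every adjoint verified by finite differences in the test suite.

## Worked example

Generate a synthetic 3-class dataset (600 windows, 3 channels × 512 samples
at 64 Hz; classes with narrow / harmonic / broadband spectral signatures),
convert it to 16×16 spectrograms, train a reduced configuration, and
evaluate:

```sh
sensornet synth --out data.h5 --seed 3
sensornet convert --in data.h5 --size 16 --out spec.h5
sensornet train --config cfg.yaml --data spec.h5 --out model.ckpt
sensornet evaluate --ckpt model.ckpt --data spec.h5
```

with `cfg.yaml`:

```yaml
spectrogram_size: [16, 16]
heads: [16, 32, 64]
hidden: 128
n_classes: 3
epochs: 50
batch_size: 128
seed: 123
```

The train command logs one line per epoch and split; with these settings the
run ends with

```
epoch=50 split=train loss=0.2811 accuracy=0.9000
epoch=50 split=val loss=0.3503 accuracy=0.8500
```

— the held-out fifth of the windows is classified at 85% after 50 epochs
(the exact figure moves a few points with the data seed; the seed-7 study
conditions used in the test suite end at 90.8%). Evaluation over the full
container then prints

```
accuracy=0.8817
per_class_accuracy=[0.89  0.825 0.93 ]
confusion_matrix=[[178, 22, 0], [24, 165, 11], [0, 14, 186]]
```

showing most confusion between the harmonic class and its spectral
neighbours, and

```sh
sensornet params --ckpt model.ckpt
# total_parameters=21747
# trunk_parameters=21360
```

prints the exact trainable-parameter count by enumeration; the trunk count
is what stays fixed when the model is moved to a dataset with a different
channel or class count.

The same API drives transfer: `sensornet.fine_tune(trunk, new_dataset, cfg)`
(or `sensornet finetune` on the command line) loads every trunk weight from
the checkpoint bit-exactly, re-initialises only the final layer, and trains
at the reduced fine-tuning learning rate (1e-4 versus 1e-3 from scratch).

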