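# lpggnet

Hierarchical local–partition–global graph learning for 4-class
motor-imagery EEG decoding, implemented as a tested library and CLI in pure
scientific Python (NumPy/SciPy; the network and its training loop run on a
small built-in reverse-mode autodiff engine, so no deep-learning framework
is required).

The pipeline:

1. **Preprocessing** — 6th-order zero-phase Butterworth band-pass
   (0.5–40 Hz) and per-trace z-score normalization of epoched EEG
   (trials × channels × samples, HDF5 container).
2. **Local branch** — per-trial MVAR models → partial directed coherence
   (PDC, column-normalized), band/trial-averaged into a directed adjacency,
   symmetrically normalized; two temporal convolutions (1×85, 1×30, with
   max-pooling) feed a first-order graph convolution over that adjacency.
3. **Partition branch** — the 22 electrodes are split into four overlapping
   task-driven partitions (sizes 7, 10, 7, 10); each partition gets a
   Gaussian-median-distance adjacency (exp(−d²/δ²), hard zero beyond the
   median pairwise distance δ) and a random-walk Laplacian filter
   F = I − D⁻¹A applied to the signals before unpooled temporal
   convolutions. Channels shared by several partitions are fused by
   arithmetic averaging into a single 22-node feature map.
4. **Global branch** — local and partition features are concatenated per
   node; two residual graph convolutions use a cosine-similarity adjacency
   recomputed from their own inputs on every forward pass.
5. **Classifier** — two fully connected layers with softmax; Adam with the
   stated hyper-parameters (lr 0.001, dropout 0.5, batch 64, weight decay
   0.01, plus an L2 penalty with coefficient 0.069 on graph-layer weights).

A seeded synthetic-EEG module generates class-balanced motor-imagery-like
sessions (1/f background, ERD-style mu-rhythm attenuation at class-specific
focal electrodes, injectable directed VAR couplings as PDC ground truth) and
is the test bed for everything else.

## CLI

```bash
lpggnet simulate --config sim.yaml --seed 1 --out session.h5
lpggnet preprocess --epochs session.h5 --out pre.h5
lpggnet connectivity --epochs pre.h5 --order 5 --band 8 30 --out adjacency.tsv
lpggnet graphs --out-dir graphs/          # per-partition GMD adjacency + filters
lpggnet train --epochs-train a.h5 --epochs-test b.h5 --out results/
lpggnet ablate --epochs-train a.h5 --epochs-test b.h5 --out results/
lpggnet demo --seed 0                     # end-to-end smoke run (~2 min, CPU)
```

Every command writes a `manifest.json` (config snapshot, seed, input
digests). Exit codes: 0 success, 3 schema error, 4 validation error,
5 numerical/training failure.

## Layout

```
src/lpggnet/
  montage.py        electrode geometry, 4-partition scheme, overlap index
  preprocessing.py  epochs container, band-pass, z-score
  connectivity.py   MVAR fit, PDC, PDC adjacency
  graphs.py         GMD adjacency, graph filter, cosine adjacency, normalization
  autodiff.py       minimal reverse-mode autodiff on NumPy arrays
  layers.py         conv/batch-norm/linear/dropout layers
  model.py          the three-branch network and classifier
  training.py       Adam, training loop, metrics, ablation grid
  synthetic.py      seeded 4-class MI-like EEG generator
  io.py             HDF5/TSV/YAML I/O and run manifests
  cli.py            click command-line interface
```
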