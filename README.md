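# seizpred

Seizure prediction from multichannel scalp EEG: synchrosqueezed-wavelet
time–frequency imaging, preictal/interictal segment labeling, a
multi-level-feature CNN (MLF-CNN) classifier, and segment-based evaluation
(accuracy, sensitivity, specificity, FPR/h) under patient-specific
stratified 5-fold cross-validation.

## Pipeline

1. **eeg_io** — EDF/EDF+ reading and writing (self-contained 16-bit
   reader/writer), seizure annotation CSVs, channel-name canonicalization,
   montage selection (built-in 18-channel bipolar and 16-channel
   referential montages).
2. **segmentation** — period labeling (15-min preictal before each onset,
   interictal at least 4 h from every seizure, ictal/postictal excluded),
   fixed-length segment extraction (1 s / 3 s), 1:1 class balancing.
3. **synchrosqueezing** — analytic-Morlet CWT on a log scale grid
   (FFT-based, with an `sqrt(a)` L2 normalization), spectral phase
   transform, and reassignment onto a linear frequency grid with the
   log-uniform scale measure. Per-column reassignment mass is conserved to
   machine precision.
4. **tf_image** — 0–50 Hz band limit, magnitude, half-pixel-center bilinear
   resize to 128×128, per-channel min–max normalization; channels stacked
   in montage order.
5. **mlf_cnn** — five VGG-style conv blocks, per-block 1×1 projections,
   transposed-convolution upsampling (stride-2 projection for block 1) to a
   common 32×32 fusion size, channel concatenation, FC/dropout/softmax
   head. Implemented directly on NumPy (manual backprop, Adam), fully
   deterministic per seed, CPU-scale.
6. **evaluation** — confusion matrices (positive = preictal), percentage
   metrics with NaN for empty denominators, FPR per interictal hour,
   per-patient aggregation with unweighted "Average" rows.
7. **synthetic** — annotated synthetic EEG (1/f^β background, additive
   preictal rhythm/chirp, ictal bursts) written as EDF fixtures so every
   stage is testable without external data.

## CLI

```sh
seizpred fixtures --out fixtures --patients 2 --duration 1800 --seizure 1400 1430
seizpred run-all --config config.yaml        # read → segment → images → CV → metrics
seizpred segment --config config.yaml --out segments.csv
seizpred evaluate --results results/results.csv
```

The YAML config mirrors `seizpred.pipeline.PipelineConfig` (paths, montage,
segment length, transform `swt`/`cwt`, grid parameters, seeds) with a
`model` section mapping to `seizpred.mlf_cnn.ModelConfig`. `run-all` writes
`results.csv` (per patient + Average), `folds.csv` and a reproducibility
manifest with input hashes.

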