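# specattn

Attention-enhanced 1-D convolutional networks for hyperspectral reflectance
spectra, with the full supporting pipeline: reflectance calibration against
white/dark reference frames, grid-ROI mean-spectrum extraction, standard
normal variate (SNV) normalization, a synthetic spectra/hypercube generator,
training/evaluation protocol, and classical baselines (SVM, MLP, random
forest).

The network is a six-block 1-D CNN (kernels 9,7,5,3,3,3; channels
16,16,32,64,64,32; batch norm before each convolution; same-padded stride-1
convolutions; halving max pools) with three optional attention modules
inserted after conv/pool blocks:

- **CAM** (channel attention): gates whole channels from global average- and
  max-pooled channel statistics pushed through a shared two-layer 1×1-conv
  bottleneck with per-branch sigmoids, applied residually (`Y + Y·Z*`).
- **SAM** (spectral attention): gates individual band positions with a
  channel-collapsing 1×1 convolution and ReLU, applied residually
  (`Y + T*·Y`).
- **CSAM**: SAM followed by CAM.

Everything runs on a small pure-NumPy reverse-mode autodiff engine
(`specattn.engine`) — no deep-learning framework required.

## CLI

```bash
# synthetic 8-class dataset (desk-scale counts; --full-scale for survey-size)
specattn generate --lens swir --per-class 100 --seed 1 --out spectra.csv

# raw/white/dark ENVI cube trio -> calibrated grid-ROI mean spectra (+ SNV)
specattn generate --lens vnir --per-class 4 --cube-dir cubes --out tmp.csv
specattn preprocess --raw cubes/raw.hdr --white cubes/white.hdr \
    --dark cubes/dark.hdr --cells 4x4 --labels cubes/roi_labels.csv \
    --snv --out roi.csv

# train one variant (plain|cam|sam|csam) with repeated random 90/10 splits
specattn train --data spectra.csv --arch csam --runs 5 --epochs 50 \
    --seed 0 --out runs/

# evaluate a checkpoint
specattn evaluate --ckpt runs/model.npz --data spectra.csv --out eval/

# baselines + all four CNN variants, table + confusion matrix
specattn benchmark --data spectra.csv --runs 5 --epochs 50 --seed 0 --out bench/
```

Every subcommand writes a JSON run manifest (resolved config, seeds, paths,
version, timestamp) next to its outputs. A plain `key=value` config file can
be passed with `--config`; explicit flags win over the file, the file wins
over defaults.

## Library layout

| module | contents |
|---|---|
| `specattn.synthetic` | `SyntheticConfig`, `make_wavelength_grid`, `class_template`, `generate_dataset`, `generate_hypercube` |
| `specattn.preprocess` | `WavelengthGrid`/`Spectrum`/`SpectraDataset`/`HyperCube`, `correct_reflectance`, `grid_roi_mean_spectra`, `snv`, `snv_dataset` |
| `specattn.envi` | minimal ENVI raster reader/writer (BSQ/BIL/BIP + wavelength header) |
| `specattn.attention` | `CamParams`/`SamParams`, `cam_forward`, `sam_forward`, `csam_forward` (numpy or autodiff tensors) |
| `specattn.network` | `build_architecture`, `shape_chain`, `conv_block_forward`, `fully_connected_forward`, `softmax`, `model_forward`, `Model`, checkpoints |
| `specattn.train_eval` | `TrainConfig`, `split_dataset`, `train_model`, `compute_metrics`, `repeated_runs`, `fit_baselines` |
| `specattn.engine` | Tensor autodiff, conv/pool/batch-norm/dropout ops, Adam |

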