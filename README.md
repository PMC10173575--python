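# renalseg

Cascaded 2.5D segmentation of kidney, tumor and cyst in abdominal CT, with
KiTS-style Dice / Surface Dice evaluation. The package implements:

- **2.5D sampling** — each training/inference sample is a stack of `k`
  adjacent axial slices (k odd, 3 or 5 typical); the network predicts the
  middle slice's mask, and per-slice predictions are reassembled into a 3D
  label volume (`renalseg.slicing`).
- **A dual-path attention-gated U-shaped network** (`renalseg.model`) built
  from residual convolution blocks: a 1×1 projection followed by two additive
  residual units whose outputs are *summed* (not chained). The encoder's
  second path repeatedly max-pools the raw input stack and concatenates it
  with the first path's features; the decoder mirrors this with bilinear
  upsampling, and skip connections pass through additive attention gates.
  A plain double-conv block is available as an ablation (`--block plain`),
  and the gates can be disabled (`--no-attention`).
- **A coarse-to-fine cascade** (`renalseg.cascade`) — stage 1 segments
  kidney-vs-background on whole slices; the foreground bounding box (plus a
  margin) is cropped and stage 2 labels tumor/cyst inside it; fine labels are
  pasted back into full-volume coordinates (coarse kidney is kept where the
  fine stage predicts background).
- **Evaluation** (`renalseg.metrics`) — +1-smoothed Dice
  `(2|A∩B|+1)/(|A|+|B|+1)`, tolerance-based Surface Dice with
  spacing-aware distance transforms, and the hierarchical evaluation classes:
  KiTS21 kidney {1,2,3} / mass {2,3} / tumor {2} / cyst {3}; KiTS19
  kidney {1,2} / tumor {2}.
- **Training** (`renalseg.training`) — cross-entropy (optionally
  class-weighted) + soft Dice loss, Adam, lesion-biased slice sampling,
  early stopping after a configurable number of epochs without improvement,
  deterministic under a seed.
- **Synthetic phantoms** (`renalseg.phantoms`) — deterministic KiTS-like
  cases (ellipsoidal kidneys, spherical lesions, HU-like intensities, NIfTI
  case layout) so everything is testable without downloading data.

The networks run on a small numpy reverse-mode autodiff engine bundled as
`renalseg.nn` (conv2d / batch norm / pooling / bilinear resizing / losses,
all gradient-checked); no GPU or deep-learning framework is required.

## CLI

```sh
# 1. generate a synthetic cohort in the KiTS case layout
renalseg make-fixtures --n 20 --seed 1 --out data/

# 2. train the two cascade stages (small CPU-sized defaults)
renalseg train coarse --data data/ --out runs/ --k 3 --epochs 10 --patience 10
renalseg train fine   --data data/ --out runs/ --k 3 --epochs 10 --patience 10

# 3. run inference on one volume
renalseg predict --image data/case_00000/imaging.nii.gz \
    --coarse runs/coarse.npz --fine runs/fine.npz --out pred/case_00000/

# 4. score predictions per HEC (Dice + Surface Dice, CSV + JSON report)
renalseg evaluate --pred pred/ --labels data/ --vocabulary kits21 --out report/
```

Every command writes a `manifest.json` recording its resolved arguments and
seed. Checkpoints are single `.npz` files with the network config and the
frozen normalization statistics embedded.

Volumes follow the KiTS convention: NIfTI, shape `(num_slices, height,
width)`, labels 0=background, 1=kidney, 2=tumor, 3=cyst (KiTS19 has no
cyst). Intensities are clipped to a configurable HU window (default
[-200, 500]) and standardized by foreground mean/std of the training split.

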