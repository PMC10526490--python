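# eegdcn

EEG emotion classification from differential-entropy feature grids, built
around a residual network with deformable convolution and efficient channel
attention, bottom-up feature-pyramid fusion, and a bidirectional GRU head.
The whole pipeline is testable offline: a synthetic-EEG generator produces
band-limited recordings whose per-band power depends on a latent class.

The network stack (including training) is implemented in pure NumPy on a
small reverse-mode autodiff engine (`eegdcn.nn.autodiff`), so no deep-learning
framework is required.

## Pipeline

1. **Synthesize or load** multi-channel EEG (`eegdcn.synthetic`, plus readers
   for a simple array-container format, EDF, and DEAP-style per-subject
   pickles).
2. **Featurize** (`eegdcn.features`): drop the pre-stimulus baseline, cut
   trials into 1-s windows, band-limit each window with zero-phase Butterworth
   filters into theta (4–8 Hz), alpha (8–14 Hz), beta (14–31 Hz) and gamma
   (31–45 Hz), take the Gaussian closed-form differential entropy
   `0.5·ln(2πe·σ²)` per channel and band, and scatter the values onto a 9×9
   electrode grid (`eegdcn.montage`), producing one 9×9×4 tensor per segment.
3. **Classify** (`eegdcn.nn`): four-stage residual backbone (3×3 stride-1
   stem, stage strides 1/2/2/2) with a channel-attention gate in every block
   and deformable 3×3 convolutions in a configurable stage; 1×1 lateral
   projections and iterative stride-2 downsample-and-add fusion into a single
   enriched map; its spatial positions unrolled as a BiGRU sequence; linear +
   softmax output.
4. **Evaluate** (`eegdcn.evaluation`): stratified k-fold (default k=5) or
   leave-one-subject-out cross-validation; accuracy/precision/recall/F-score
   in percent from one-vs-rest confusion counts, macro-averaged for more than
   two classes; Adam + cross-entropy training (lr 0.001, batch 128, 100
   epochs by default — scale down with `--epochs` for desk runs).

## CLI

```bash
# generate a synthetic subject (40 trials x 63 s at 128 Hz, 32 channels)
eegdcn simulate --out rec.eegarc --trials 40 --seconds 63 --seed 1

# differential-entropy feature tensors on the 9x9 layout
eegdcn featurize --recording rec.eegarc --out feats.eegarc --window 1 --step 1 --layout deap9x9

# 5-fold cross-validation with a reduced model
eegdcn crossval --features feats.eegarc --scheme kfold:5 --epochs 10 \
    --model-json '{"stage_widths": [8, 16, 32, 32], "lateral_channels": 16, "gru_hidden": 8}'

# or the whole thing, cached and reproducible from the config alone
eegdcn run --set seed=1 --set epochs=10
```

`eegdcn train` / `eegdcn evaluate` handle single-split training and
checkpoint evaluation; `--config run.yaml` feeds `eegdcn run` a persisted
configuration (see `eegdcn.config.RunConfig`).

## Layout

- `src/eegdcn/synthetic.py` — band-limited synthetic EEG with known classes
- `src/eegdcn/features.py` — segmentation, Butterworth filterbank, DE, grids
- `src/eegdcn/montage.py`, `src/eegdcn/layouts/` — electrode placements (data)
- `src/eegdcn/nn/` — autodiff, layers (deformable conv, ECA, BiGRU), model, Adam
- `src/eegdcn/evaluation.py` — folds, metrics, training loop
- `src/eegdcn/storage.py`, `edf.py`, `deap.py` — file formats
- `src/eegdcn/config.py`, `pipeline.py`, `cli.py` — orchestration and CLI
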