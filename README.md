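# gaitphase

Gait-phase detection from bilateral shank-mounted IMU signals, built as a
tested, reusable pipeline:

1. **Synthetic gait generator** (`gaitphase.synthetic`) — bilateral trials
   with ~60% stance duty cycle, half-cycle left/right offset,
   phase-locked signal morphology, subject-level variability and known
   ground-truth events/phases.
2. **Event detection & labeling** (`gaitphase.events`) — heel-strike /
   toe-off extraction from foot-contact channels (with debouncing) and
   four-phase labeling (LR, LS, PSw, Sw) over half-open event intervals.
3. **Dataset builder** (`gaitphase.datasets`) — 200→100 Hz resampling,
   subject-wise train/val/test splitting, per-channel standardization
   (train statistics only), sliding-window one-step-ahead samples
   (w=20, offset +1, exactly n−w windows per fully labeled trial) and
   minority-class undersampling of the training pool.
4. **Models** (`gaitphase.nn`) — a 1D CNN, a hybrid LSTM→LSTM→GRU network
   and an encoder-only Transformer (multi-head attention, sinusoidal
   positional encoding, position-wise FFN), implemented on a small NumPy
   reverse-mode autodiff engine so no deep-learning framework is needed.
5. **Training & evaluation** (`gaitphase.training`, `gaitphase.metrics`) —
   fixed-epoch Adam/AdamW training with loss histories, confusion matrices
   (counts + row-normalized %) and macro precision/recall/F1.

## CLI

A YAML config drives a run directory (see `tests/test_io_cli.py` for a
complete example config):

```bash
gaitphase simulate       --config config.yaml --out runs/demo
gaitphase label          --config config.yaml --out runs/demo
gaitphase build-dataset  --config config.yaml --out runs/demo
gaitphase train          --config config.yaml --out runs/demo
gaitphase evaluate       --config config.yaml --out runs/demo
gaitphase verify-reference-metrics
```

Stages write canonical trial CSVs (`time_s`, 12 `{side}_{acc|gyro}_{x|y|z}`
columns, `contact_left`, `contact_right`), label CSVs, `.npz` window
archives with JSON manifests, checkpoints and JSON/CSV evaluation
reports. Exit codes: 0 success, 2 config error, 3 missing upstream
dependency, 4 verification failure.

`verify-reference-metrics` recomputes the macro recall of each published
reference confusion matrix (bundled in
`src/gaitphase/data/reference_results.json`) and checks it against the
independently reported value.

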