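{
  "description": "Published reference test-set results for the three architectures on the NONAN GaitPrint recordings: row-normalized confusion matrices (%) with rows/columns ordered LR, LS, PSw, Sw, and the reported summary metrics (%).",
  "class_order": ["LR", "LS", "PSw", "Sw"],
  "models": {
    "cnn": {
      "confusion_row_pct": [
        [95.67, 0.94, 0.14, 3.25],
        [5.31, 93.16, 1.28, 0.24],
        [1.37, 1.18, 94.41, 3.04],
        [2.08, 0.8, 5.28, 91.84]
      ],
      "reported": {"acc": 93.09, "macro_pr": 89.11, "macro_rc": 93.77, "macro_f1": 91.08}
    },
    "hybrid": {
      "confusion_row_pct": [
        [95.28, 0.91, 0.8, 3.02],
        [3.5, 94.76, 1.56, 0.18],
        [0.16, 0.89, 97.83, 1.12],
        [2.69, 0.57, 4.37, 92.37]
      ],
      "reported": {"acc": 94.25, "macro_pr": 90.61, "macro_rc": 95.06, "macro_f1": 92.52}
    },
    "transformer": {
      "confusion_row_pct": [
        [94.54, 1.38, 0.79, 3.3],
        [3.64, 94.93, 0.99, 0.43],
        [0.42, 2.13, 92.87, 4.58],
        [2.16, 0.47, 2.3, 95.07]
      ],
      "reported": {"acc": 94.7, "macro_pr": 91.86, "macro_rc": 94.35, "macro_f1": 92.99}
    }
  },
  "hyperparameters": {
    "cnn": {
      "ranges": {"n_filters": [32, 64, 128], "kernel_size": [1, 3, 5], "learning_rate": [1e-05, 0.0005]},
      "best": {"n_filters": 32, "kernel_size": 1, "learning_rate": 0.0001}
    },
    "hybrid": {
      "ranges": {"lstm_units_1": [100, 200], "lstm_units_2": [100, 200], "gru_units": [128, 256, 512], "dense_units": [128, 256, 512], "learning_rate": [0.0001, 0.01]},
      "best": {"lstm_units_1": 100, "lstm_units_2": 100, "gru_units": 256, "dense_units": 128, "learning_rate": 0.0022}
    },
    "transformer": {
      "ranges": {"d_model": [128, 256], "n_heads": [1, 2], "n_layers": [2, 4], "d_ff": [512, 1024], "learning_rate": [2e-05, 5e-05]},
      "best": {"d_model": 256, "n_heads": 1, "n_layers": 2, "d_ff": 512, "learning_rate": 2.92e-05}
    }
  }
}
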