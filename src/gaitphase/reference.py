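"""Access to the bundled published reference results.

The package ships the row-normalized test-set confusion matrices and
summary metrics reported for the three architectures on the original
recordings, so consistency checks never need the source document.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from gaitphase.metrics import macro_recall_from_row_pct

MODEL_NAMES = ("cnn", "hybrid", "transformer")


def load_reference_results() -> dict:
    path = resources.files("gaitphase").joinpath("data/reference_results.json")
    return json.loads(path.read_text())


def recompute_macro_recalls() -> dict[str, dict[str, float]]:
    """Macro recall re-derived from each reference confusion matrix,
    alongside the independently reported value."""
    ref = load_reference_results()
    out = {}
    for name in MODEL_NAMES:
        entry = ref["models"][name]
        row_pct = np.array(entry["confusion_row_pct"])
        out[name] = {
            "recomputed_rc": round(macro_recall_from_row_pct(row_pct), 2),
            "reported_rc": entry["reported"]["macro_rc"],
        }
    return out


def verify_reference_metrics(tolerance: float = 0.005) -> tuple[bool, dict]:
    """True iff every recomputed macro recall matches the reported one to
    two decimals (|difference| <= tolerance)."""
    results = recompute_macro_recalls()
    ok = all(
        abs(v["recomputed_rc"] - v["reported_rc"]) <= tolerance
        for v in results.values()
    )
    return ok, results
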