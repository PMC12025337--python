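"""Figure output: model-vs-data bar panels for fMRI responses and the
model-predicted duration thresholds."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .nma import CONDITION_NAMES

_LABELS = {
    "center_only": "center",
    "narrow_same": "narrow\nsame",
    "narrow_opp": "narrow\nopp",
    "wide_same": "wide\nsame",
    "wide_opp": "wide\nopp",
}


def model_vs_data_panels(
    data_normalized: dict,
    model_normalized: dict,
    predicted_threshold_ms: dict,
    path: str | Path,
) -> Path:
    """Two panels: normalized fMRI response (data bars, model dots) and the
    model-predicted duration thresholds per condition."""
    names = [n for n in CONDITION_NAMES if n in data_normalized]
    xs = range(len(names))
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0.bar(xs, [data_normalized[n] for n in names], color="0.8",
            edgecolor="0.3", label="data")
    ax0.plot(xs, [model_normalized[n] for n in names], "o", color="crimson",
             label="model")
    ax0.set_xticks(list(xs), [_LABELS.get(n, n) for n in names])
    ax0.set_ylabel("normalized response")
    ax0.legend(frameon=False)
    ax1.bar(xs, [predicted_threshold_ms[n] for n in names], color="steelblue",
            edgecolor="0.3")
    ax1.set_xticks(list(xs), [_LABELS.get(n, n) for n in names])
    ax1.set_ylabel("predicted threshold (ms)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return path
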