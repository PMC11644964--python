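"""Optional bar-chart rendering of scenario comparison reports.

Requires matplotlib (``pip install gluforecast[plot]``); purely cosmetic —
all quantitative output lives in the JSON/CSV report writers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

__all__ = ["plot_scenario_bars"]


def plot_scenario_bars(reports: Sequence, path: str | Path,
                       metric: str = "rmse") -> Path:
    """Grouped bars of RMSE (or MAE) per model across scenarios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    kinds = sorted({k for r in reports for k in r.metrics})
    x = np.arange(len(reports))
    width = 0.8 / max(len(kinds), 1)
    fig, ax = plt.subplots(figsize=(1.8 * len(reports) + 2, 4))
    for j, kind in enumerate(kinds):
        vals = [getattr(r.metrics[kind], metric) if kind in r.metrics
                else np.nan for r in reports]
        ax.bar(x + j * width, vals, width, label=kind)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([r.label for r in reports])
    ax.set_ylabel(f"{metric.upper()} (mmol/L)")
    ax.set_xlabel("forecasting scenario")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
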