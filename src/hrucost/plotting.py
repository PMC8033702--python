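"""Strip plots of per-participant 30-day costs (optional; needs matplotlib).

Participants with $0 cost are not plotted; their counts appear beneath
each study's strip, since the zero mass would otherwise dominate the
panel and hide the cost distribution among utilizers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def cost_strip_plot(
    participant_costs: pd.DataFrame, measure_id: str, path: Path, *, seed: int = 0
) -> None:
    """One jittered strip per study of nonzero participant costs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    studies = sorted(set(participant_costs["study_id"]))
    fig, ax = plt.subplots(figsize=(1.8 * max(3, len(studies)), 4.0))
    for i, sid in enumerate(studies):
        sub = participant_costs[participant_costs["study_id"] == sid]
        nonzero = sub.loc[sub["cost_per_30d"] > 0, "cost_per_30d"]
        x = i + rng.uniform(-0.25, 0.25, size=len(nonzero))
        ax.plot(x, nonzero, "o", ms=3, alpha=0.6)
        n_zero = int((sub["cost_per_30d"] == 0).sum())
        ax.annotate(
            f"$0: n={n_zero}", (i, 0), xytext=(0, -28),
            textcoords="offset points", ha="center", fontsize=8,
        )
    ax.set_xticks(range(len(studies)))
    ax.set_xticklabels(studies)
    ax.set_ylabel("Cost per participant per 30 days (2017 USD)")
    ax.set_title(measure_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
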