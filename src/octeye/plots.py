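"""Response-curve panels (normalized % change vs time, one line per
parameter) for a measured run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dynamics import PARAMS, compute_baseline, normalize
from .scenario import OsmoticScenario


def plot_responses(records: pd.DataFrame, scenario: OsmoticScenario,
                   path: str | Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records.sort_values("t_min")
    base = compute_baseline(df, scenario.baseline_repeats)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for p in PARAMS:
        if p in df and p in base.index and base.loc[p, "mean"] > 0:
            ax.plot(df["t_min"], normalize(df[p].to_numpy(), float(base.loc[p, "mean"])),
                    marker="o", ms=3, lw=1, label=p)
    for t0, _, phase in scenario.phase_windows():
        ax.axvline(t0, color="0.8", lw=0.8)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized change (%)")
    ax.set_title(scenario.name)
    ax.legend(fontsize=8, ncol=3)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
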