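"""Optional presentational output: z-score heatmap of selected motifs."""
from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_zscore_heatmap(
    zscores: pd.DataFrame,
    out_path,
    sample_groups: dict[str, str] | None = None,
    title: str = "Z-scored normalized motif abundance",
) -> Path:
    """Render a motifs x samples heatmap of z-scored abundances.

    ``sample_groups`` (sample id -> group label) annotates columns. Rows
    are labelled in RNA space. Purely presentational; returns the path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    df = zscores.copy()
    df.index = [m.replace("T", "U") for m in df.index]
    if sample_groups:
        df.columns = [f"{c}\n({sample_groups.get(c, '?')})" for c in df.columns]
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * df.shape[1] + 2), max(3.0, 0.35 * df.shape[0] + 1.5))
    )
    sns.heatmap(df, cmap="vlag", center=0.0, ax=ax, cbar_kws={"label": "z-score"})
    ax.set_title(title)
    ax.set_xlabel("sample")
    ax.set_ylabel("motif")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
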