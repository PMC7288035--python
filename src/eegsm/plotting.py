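"""CSV and heatmap output for correlation matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .correlation import CorrelationMatrix
from .montage import Montage, default_montage


def matrix_to_csv(m: CorrelationMatrix, path) -> None:
    """16x16 CSV with channel names as header row and column."""
    pd.DataFrame(m.values, index=m.montage.names,
                 columns=m.montage.names).to_csv(path)


def matrix_from_csv(path, montage: Montage | None = None,
                    provenance: str = "single_recording") -> CorrelationMatrix:
    montage = montage or default_montage()
    df = pd.read_csv(path, index_col=0)
    if tuple(df.columns) != montage.names:
        raise ValueError("CSV channel names do not match the montage")
    return CorrelationMatrix(df.to_numpy(), montage, provenance=provenance)


def plot_heatmap(m: CorrelationMatrix, path, title: str | None = None) -> None:
    """Correlation heatmap; difference matrices get a symmetric colour scale
    at +-max |entry|, others the full [-1, 1] range."""
    bound = m.colorscale_bound
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(m.values, cmap="jet", vmin=-bound, vmax=bound)
    ax.set_xticks(range(len(m.montage)), m.montage.names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(m.montage)), m.montage.names, fontsize=7)
    ax.set_title(title or (m.category or m.provenance))
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
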