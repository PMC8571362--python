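"""Plot helpers for screen results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen import CONTROL_LABEL


def screen_heatmap(ztable: pd.DataFrame, out_path=None):
    """Heatmap of the median robust Z per gene pair (singles on the margins).

    Rows/columns are the panel genes plus the control; each cell shows the
    median robust Z of the corresponding (pair or single) treatment across
    replicates.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = ztable.groupby("treatment")["z"].median()
    genes = sorted({
        g for t in med.index for g in t.split("__") if g not in (CONTROL_LABEL, "INCENP")
    })
    labels = [CONTROL_LABEL] + genes
    mat = np.full((len(labels), len(labels)), np.nan)
    for t, z in med.items():
        a, b = t.split("__")
        if a in labels and b in labels:
            i, j = labels.index(a), labels.index(b)
            mat[i, j] = mat[j, i] = z
    fig, ax = plt.subplots(figsize=(0.25 * len(labels) + 2,) * 2)
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-np.nanmax(np.abs(mat)),
                   vmax=np.nanmax(np.abs(mat)))
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="median robust Z")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
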