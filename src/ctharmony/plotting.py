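"""Optional visualization helpers (no numeric contract).

UMAP embedding delegates to ``umap-learn``; both it and matplotlib are
optional extras.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KEY_COLUMNS = ["group", "scan", "roi"]


def umap_embedding(table: pd.DataFrame, seed: int = 0, **umap_kwargs) -> pd.DataFrame:
    """2D UMAP embedding of standardized feature rows.

    Returns the key columns plus ``umap1``/``umap2``.
    """
    import umap  # optional dependency

    features = [c for c in table.columns if c not in KEY_COLUMNS]
    X = table[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    emb = umap.UMAP(n_components=2, random_state=seed, **umap_kwargs).fit_transform(X)
    out = table[KEY_COLUMNS].copy()
    out["umap1"], out["umap2"] = emb[:, 0], emb[:, 1]
    return out


def plot_embedding(embedding: pd.DataFrame, color_key: str = "group", path=None):
    """Scatter an embedding colored by a key column; saves PNG if path given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for value, sub in embedding.groupby(color_key):
        ax.scatter(sub["umap1"], sub["umap2"], s=8, label=str(value))
    ax.legend(title=color_key, fontsize=7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
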