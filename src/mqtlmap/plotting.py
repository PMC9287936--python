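"""Basic diagnostic plots: AIC profiles and expression heat maps."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def plot_aic_profile(results, ax=None):
    """AIC versus K for a fitted selection, the chosen K highlighted."""
    import matplotlib.pyplot as plt

    if results.aic_profile is None:
        raise ValueError("results carry no AIC profile; use select()")
    if ax is None:
        _, ax = plt.subplots()
    prof = results.aic_profile
    ax.plot(prof["k"], prof["aic"], marker="o", color="0.3")
    ax.axvline(results.k, color="tab:red", linestyle="--", label=f"K = {results.k}")
    ax.set_xlabel("number of components K")
    ax.set_ylabel("AIC")
    ax.legend()
    return ax


def plot_expression_heatmap(
    fpkm: pd.DataFrame, gene_ids: Optional[Sequence[str]] = None, ax=None
):
    """Max-normalised expression over days after pollination, one row per gene."""
    import matplotlib.pyplot as plt

    if gene_ids is not None:
        fpkm = fpkm.loc[[g for g in gene_ids if g in fpkm.index]]
    values = fpkm.to_numpy(dtype=float)
    peak = values.max(axis=1, keepdims=True)
    normalized = np.divide(values, peak, out=np.zeros_like(values), where=peak > 0)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(fpkm))))
    im = ax.imshow(normalized, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(fpkm.columns)))
    ax.set_xticklabels([f"{float(c):g}" for c in fpkm.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(fpkm)))
    ax.set_yticklabels(fpkm.index, fontsize=6)
    ax.set_xlabel("days after pollination")
    ax.figure.colorbar(im, ax=ax, label="FPKM / max FPKM")
    return ax
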