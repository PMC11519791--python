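"""PNG rendering of feature maps (headless matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def export_heatmap(
    values: np.ndarray,
    path: str | Path,
    *,
    title: str = "",
    units: str = "",
    cmap: str = "viridis",
) -> Path:
    """Render a per-pixel scalar grid as a PNG heat map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(np.asarray(values, dtype=float), cmap=cmap, origin="upper")
    cbar = fig.colorbar(im, ax=ax)
    if units:
        cbar.set_label(units)
    if title:
        ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def export_curve(
    x: np.ndarray,
    y: np.ndarray,
    path: str | Path,
    *,
    fit_x: np.ndarray | None = None,
    fit_y: np.ndarray | None = None,
    xlabel: str = "",
    ylabel: str = "",
    logx: bool = False,
    title: str = "",
) -> Path:
    """Render a scatter plus optional fitted curve (dose-response, gating, I-V)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.plot(x, y, "o", color="tab:blue", label="data")
    if fit_x is not None and fit_y is not None:
        ax.plot(fit_x, fit_y, "-", color="tab:red", label="fit")
        ax.legend(fontsize=8)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
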