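"""Topographic visualisation of Block-structured fNIRS examples."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .structures import BLOCK_GROUPS, BlockDataset

_GROUP_NAMES = {(1, "none"): "NN1", (2, "horizontal"): "NN2-h", (2, "vertical"): "NN2-v"}


def plot_task_average(
    block: BlockDataset, label: str, path, components=("HbO", "Hb")
) -> None:
    """Task-averaged topographic maps, one panel per (component, group) layer.

    Averages all examples with the given label over examples and time,
    masking unoccupied voxels, and writes a PNG.
    """
    sel = block.labels == label
    if not sel.any():
        raise ValueError(f"no examples labelled {label!r}")
    mean_img = block.values[sel].mean(axis=(0, 2))  # [layers, H, W]
    n_groups = block.n_groups
    n_comp = mean_img.shape[0] // n_groups
    fig, axes = plt.subplots(
        n_comp, n_groups, figsize=(4 * n_groups, 2.2 * n_comp), squeeze=False
    )
    vmax = np.abs(mean_img).max() or 1.0
    for k in range(n_comp):
        for g in range(n_groups):
            ax = axes[k][g]
            img = np.where(block.mask[g], mean_img[k * n_groups + g], np.nan)
            im = ax.imshow(img, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="upper")
            comp = components[k] if k < len(components) else f"comp{k}"
            ax.set_title(f"{comp} {_GROUP_NAMES.get(BLOCK_GROUPS[g], g)}", fontsize=9)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.suptitle(f"task-averaged response: {label}")
    fig.colorbar(im, ax=[a for row in axes for a in row], shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
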