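"""The three input representations for the classifiers, plus flip augmentation.

*Block* places every channel's time-series at its midpoint voxel on the
half-pitch lattice, one image layer per (component, channel-group) pair -
groups are NN1, NN2-horizontal, NN2-vertical - yielding a
``[layers, time, height, width]`` video-like tensor per example, with a
validity mask for unoccupied voxels (zero-filled).  *Flat* stacks each
(channel, component) series as an independent row.  *S-by-D* arranges the
same values on a source-index x detector-index grid, which deliberately
carries no spatial information.

Because the dual-pad layout is mirror-symmetric, flipping a Block example
along the width axis swaps the hemispheres; relabelling left <-> right
gives a physically plausible new training example (contralateral
dominance).  Augmentation is restricted to training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ChannelTable
from .preprocess import WindowedDataset

#: channel groups imaged as Block layers, in layer order
BLOCK_GROUPS = ((1, "none"), (2, "horizontal"), (2, "vertical"))
_FLIP = {"left": "right", "right": "left", "rest": "rest"}


@dataclass
class BlockDataset:
    """Examples as stacked topographic voxel images.

    ``values``: [n, layers, time, height, width]; layer order is
    component-major: (component 0, NN1), (component 0, NN2-h), ...
    ``channel_map``: (layer % n_groups, row, col) -> channel_id, recorded in
    ``voxels`` as (group_index, row, col, channel_id) tuples.
    """

    values: np.ndarray
    mask: np.ndarray  # [n_groups, height, width] voxel occupancy per group
    labels: np.ndarray
    subject_ids: np.ndarray
    run_ids: np.ndarray
    voxels: list  # (group_index, row, col, channel_id)
    components: tuple[str, ...]
    split: str | None = None

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(BLOCK_GROUPS)

    def subset(self, idx, split: str | None = None) -> "BlockDataset":
        idx = np.asarray(idx)
        return BlockDataset(
            self.values[idx],
            self.mask,
            self.labels[idx],
            self.subject_ids[idx],
            self.run_ids[idx],
            self.voxels,
            self.components,
            split=split if split is not None else self.split,
        )


@dataclass
class FlatDataset:
    """Examples as (channel x component) rows by time columns."""

    values: np.ndarray  # [n, rows, time]
    row_keys: list  # (channel_id, component)
    labels: np.ndarray
    subject_ids: np.ndarray
    run_ids: np.ndarray
    split: str | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx, split: str | None = None) -> "FlatDataset":
        idx = np.asarray(idx)
        return FlatDataset(
            self.values[idx],
            self.row_keys,
            self.labels[idx],
            self.subject_ids[idx],
            self.run_ids[idx],
            split=split if split is not None else self.split,
        )


@dataclass
class SByDDataset:
    """Examples on a source-index x detector-index grid (non-spatial)."""

    values: np.ndarray  # [n, components, time, n_sources, n_detectors]
    mask: np.ndarray  # [n_sources, n_detectors]
    labels: np.ndarray
    subject_ids: np.ndarray
    run_ids: np.ndarray
    source_ids: list
    detector_ids: list
    split: str | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx, split: str | None = None) -> "SByDDataset":
        idx = np.asarray(idx)
        return SByDDataset(
            self.values[idx],
            self.mask,
            self.labels[idx],
            self.subject_ids[idx],
            self.run_ids[idx],
            self.source_ids,
            self.detector_ids,
            split=split if split is not None else self.split,
        )


def _frame_shape(table: ChannelTable) -> tuple[int, int]:
    cols = [r.midpoint[0] for r in table]
    rows = [r.midpoint[1] for r in table]
    if min(cols) != 0 or min(rows) != 0:
        raise ValueError("channel midpoints do not start at the frame origin")
    return (max(rows) + 1, max(cols) + 1)


def to_block(dataset: WindowedDataset) -> BlockDataset:
    """Arrange windowed examples as Block voxel-image stacks.

    Distinct NN2 channels of the same orientation can share a midpoint
    voxel (the two diagonal directions overlap at their centre points);
    such co-located, equal-separation channels are averaged into the
    shared voxel, as is standard for HD-DOT grids.
    """
    table = dataset.table
    height, width = _frame_shape(table)
    n, n_ch, n_comp, n_t = dataset.values.shape
    n_groups = len(BLOCK_GROUPS)
    values = np.zeros((n, n_comp * n_groups, n_t, height, width), dtype=np.float32)
    mask = np.zeros((n_groups, height, width), dtype=bool)
    occupancy = np.zeros((n_groups, height, width), dtype=np.int32)
    voxels = []
    for rec in table:
        if rec.group not in BLOCK_GROUPS:
            raise ValueError(
                f"channel {rec.channel_id} group {rec.group} has no Block layer"
            )
        g = BLOCK_GROUPS.index(rec.group)
        col, row = rec.midpoint
        mask[g, row, col] = True
        occupancy[g, row, col] += 1
        voxels.append((g, row, col, rec.channel_id))
        for k in range(n_comp):
            values[:, k * n_groups + g, :, row, col] += dataset.values[
                :, rec.channel_id, k, :
            ]
    occ = np.maximum(occupancy, 1).astype(np.float32)
    values /= np.tile(occ, (n_comp, 1, 1))[None, :, None, :, :]
    return BlockDataset(
        values,
        mask,
        dataset.labels.copy(),
        dataset.subject_ids.copy(),
        dataset.run_ids.copy(),
        voxels,
        dataset.components,
        split=dataset.split,
    )


def block_to_channels(block: BlockDataset, n_components: int | None = None) -> np.ndarray:
    """Invert :func:`to_block` via the channel map.

    Bit-exact for channels that occupy a voxel alone; channels sharing a
    voxel read back the cell mean.
    """
    n_comp = n_components or len(block.components)
    n_groups = block.n_groups
    n_ch = len(block.voxels)
    n, _, n_t, _, _ = block.values.shape
    out = np.empty((n, n_ch, n_comp, n_t), dtype=block.values.dtype)
    for g, row, col, ch in block.voxels:
        for k in range(n_comp):
            out[:, ch, k, :] = block.values[:, k * n_groups + g, :, row, col]
    return out


def to_flat(dataset: WindowedDataset) -> FlatDataset:
    """Arrange examples as a (channels x components) x time matrix.

    Row order follows the canonical channel order (pad, NN, row-major
    midpoint), component-minor, so the representation is independent of
    any permutation of the input channel axis labels.
    """
    n, n_ch, n_comp, n_t = dataset.values.shape
    values = dataset.values.reshape(n, n_ch * n_comp, n_t).copy()
    row_keys = [
        (rec.channel_id, comp) for rec in dataset.table for comp in dataset.components
    ]
    return FlatDataset(
        values,
        row_keys,
        dataset.labels.copy(),
        dataset.subject_ids.copy(),
        dataset.run_ids.copy(),
        split=dataset.split,
    )


def to_sbyd(dataset: WindowedDataset) -> SByDDataset:
    """Arrange examples on the source-index x detector-index grid."""
    table = dataset.table
    source_ids = sorted({r.source_id for r in table})
    detector_ids = sorted({r.detector_id for r in table})
    s_index = {s: i for i, s in enumerate(source_ids)}
    d_index = {d: i for i, d in enumerate(detector_ids)}
    n, n_ch, n_comp, n_t = dataset.values.shape
    values = np.zeros(
        (n, n_comp, n_t, len(source_ids), len(detector_ids)), dtype=np.float32
    )
    mask = np.zeros((len(source_ids), len(detector_ids)), dtype=bool)
    for rec in table:
        si, di = s_index[rec.source_id], d_index[rec.detector_id]
        if mask[si, di]:
            raise ValueError(f"duplicate (source, detector) cell ({si}, {di})")
        mask[si, di] = True
        values[:, :, :, si, di] = dataset.values[:, rec.channel_id, :, :]
    return SByDDataset(
        values,
        mask,
        dataset.labels.copy(),
        dataset.subject_ids.copy(),
        dataset.run_ids.copy(),
        source_ids,
        detector_ids,
        split=dataset.split,
    )


def flip_block(block: BlockDataset) -> BlockDataset:
    """Width-reversed copy of every example, labels left <-> right."""
    flipped_mask = block.mask[:, :, ::-1]
    if not np.array_equal(flipped_mask, block.mask):
        raise ValueError("layout is not mirror-symmetric; flip augmentation undefined")
    return BlockDataset(
        block.values[:, :, :, :, ::-1].copy(),
        block.mask,
        np.array([_FLIP[l] for l in block.labels]),
        block.subject_ids.copy(),
        block.run_ids.copy(),
        block.voxels,
        block.components,
        split=block.split,
    )


def flip_augment(block: BlockDataset) -> BlockDataset:
    """Append mirror-flipped, label-swapped copies of task examples.

    Rest examples are not duplicated.  Refuses to touch held-out data:
    the dataset must be tagged as training data (``split='train'``).
    """
    if block.split != "train":
        raise ValueError(
            "flip augmentation is training-only; tag the dataset split='train'"
        )
    task = np.flatnonzero(np.isin(block.labels, ("left", "right")))
    flipped = flip_block(block.subset(task))
    return BlockDataset(
        np.concatenate([block.values, flipped.values]),
        block.mask,
        np.concatenate([block.labels, flipped.labels]),
        np.concatenate([block.subject_ids, flipped.subject_ids]),
        np.concatenate([block.run_ids, flipped.run_ids]),
        block.voxels,
        block.components,
        split=block.split,
    )
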