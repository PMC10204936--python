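"""Block / Flat / S-by-D representations and mirror-flip augmentation."""

import numpy as np
import pytest

from nirsblock.geometry import build_motor_layout, enumerate_channels
from nirsblock.preprocess import WindowedDataset
from nirsblock.structures import (
    block_to_channels,
    flip_augment,
    flip_block,
    to_block,
    to_flat,
    to_sbyd,
)


@pytest.fixture(scope="module")
def table():
    return enumerate_channels(build_motor_layout(), max_nn=2)


@pytest.fixture(scope="module")
def dataset(table):
    rng = np.random.default_rng(42)
    n = 12
    values = rng.normal(size=(n, len(table), 2, 20)).astype(np.float32)
    labels = np.array(
        ["left", "right", "rest"] * (n // 3)
    )
    return WindowedDataset(
        values=values,
        labels=labels,
        subject_ids=np.repeat(np.arange(3), n // 3),
        run_ids=np.tile(np.arange(n // 3), 3),
        window_index=np.arange(n),
        table=table,
    )


class TestBlock:
    def test_shape_and_layers(self, dataset):
        block = to_block(dataset)
        n, layers, t, h, w = block.values.shape
        assert (n, layers, t) == (len(dataset), 6, 20)
        assert (h, w) == (7, 33)
        assert block.mask.shape == (3, 7, 33)

    def test_round_trip_exact_for_solo_voxels_mean_for_shared(self, dataset):
        block = to_block(dataset)
        back = block_to_channels(block)
        from collections import Counter

        occ = Counter((g, r, c) for g, r, c, _ in block.voxels)
        cellmates = {}
        for g, r, c, ch in block.voxels:
            cellmates.setdefault((g, r, c), []).append(ch)
        for (cell, chans) in cellmates.items():
            if len(chans) == 1:
                ch = chans[0]
                assert np.array_equal(back[:, ch], dataset.values[:, ch])
            else:
                expected = dataset.values[:, chans].mean(axis=1)
                for ch in chans:
                    assert np.allclose(back[:, ch], expected, atol=1e-6)
        # overlapping NN2 centre points exist on the checkerboard
        assert max(occ.values()) == 2

    def test_values_outside_mask_are_zero(self, dataset):
        block = to_block(dataset)
        for g in range(3):
            for k in range(2):
                layer = block.values[:, k * 3 + g]
                assert np.all(layer[:, :, ~block.mask[g]] == 0)

    def test_zero_example_gives_zero_tensor(self, dataset, table):
        ds = WindowedDataset(
            np.zeros((1, len(table), 2, 20), np.float32),
            np.array(["rest"]),
            np.zeros(1, int),
            np.zeros(1, int),
            np.zeros(1, int),
            table,
        )
        assert np.all(to_block(ds).values == 0)

    def test_channel_map_covers_all_channels(self, dataset):
        block = to_block(dataset)
        cells = {(g, r, c) for g, r, c, _ in block.voxels}
        chans = {ch for _, _, _, ch in block.voxels}
        assert len(block.voxels) == len(dataset.table)  # one cell per channel
        assert chans == set(range(len(dataset.table)))
        assert block.mask.sum() == len(cells)  # mask marks distinct cells

    def test_lateralised_pattern_lands_on_right_pad(self, table):
        """A synthetic right-hemisphere NN2 response appears in right-half voxels."""
        values = np.zeros((1, len(table), 2, 20), np.float32)
        for rec in table:
            if rec.pad == "right" and rec.nn_class == 2:
                values[0, rec.channel_id, 0, :] = 1.0
        ds = WindowedDataset(
            values, np.array(["left"]), np.zeros(1, int), np.zeros(1, int),
            np.arange(1), table,
        )
        block = to_block(ds)
        width = block.values.shape[-1]
        hbo_nn2 = block.values[0, 1:3].sum(axis=(0, 1))  # HbO NN2-h + NN2-v
        peak_col = np.unravel_index(np.argmax(hbo_nn2), hbo_nn2.shape)[1]
        assert peak_col > width // 2


class TestFlat:
    def test_row_count_is_twice_channels(self, dataset):
        flat = to_flat(dataset)
        assert flat.values.shape == (len(dataset), 2 * len(dataset.table), 20)
        assert len(flat.row_keys) == 2 * len(dataset.table)

    def test_round_trip_exact(self, dataset):
        flat = to_flat(dataset)
        back = flat.values.reshape(len(dataset), len(dataset.table), 2, 20)
        assert np.array_equal(back, dataset.values)

    def test_canonical_row_order_under_channel_permutation(self, dataset):
        """Row order is defined by the table, not by input array order."""
        flat = to_flat(dataset)
        ids = [ch for ch, _ in flat.row_keys[::2]]
        assert ids == sorted(ids)


class TestSByD:
    def test_mask_sum_equals_channel_count(self, dataset):
        sbyd = to_sbyd(dataset)
        assert int(sbyd.mask.sum()) == len(dataset.table)
        assert sbyd.values.shape[1:3] == (2, 20)

    def test_round_trip_on_valid_cells(self, dataset):
        sbyd = to_sbyd(dataset)
        s_index = {s: i for i, s in enumerate(sbyd.source_ids)}
        d_index = {d: i for i, d in enumerate(sbyd.detector_ids)}
        for rec in dataset.table:
            cell = sbyd.values[:, :, :, s_index[rec.source_id], d_index[rec.detector_id]]
            assert np.array_equal(cell, dataset.values[:, rec.channel_id])

    def test_grid_adjacency_disagrees_with_spatial_adjacency(self, dataset):
        """The S-by-D arrangement carries no usable spatial neighbourhood.

        Channels whose midpoints are adjacent voxels routinely sit in
        distant matrix cells, and matrix-adjacent cells hold channels whose
        midpoints are not adjacent voxels - so 3x3 convolution kernels on
        this grid do not see spatial neighbours.
        """
        sbyd = to_sbyd(dataset)
        table = dataset.table
        s_index = {s: i for i, s in enumerate(sbyd.source_ids)}
        d_index = {d: i for i, d in enumerate(sbyd.detector_ids)}
        grid_pos = {
            r.channel_id: (s_index[r.source_id], d_index[r.detector_id]) for r in table
        }
        spatially_adjacent_far_cells = 0
        cell_adjacent_far_midpoints = 0
        recs = list(table)
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                dmid = max(
                    abs(a.midpoint[0] - b.midpoint[0]),
                    abs(a.midpoint[1] - b.midpoint[1]),
                )
                ga, gb = grid_pos[a.channel_id], grid_pos[b.channel_id]
                dgrid = max(abs(ga[0] - gb[0]), abs(ga[1] - gb[1]))
                if dmid <= 1 and dgrid > 3:
                    spatially_adjacent_far_cells += 1
                if dgrid <= 1 and dmid > 2:
                    cell_adjacent_far_midpoints += 1
        assert spatially_adjacent_far_cells > 0
        assert cell_adjacent_far_midpoints > 0


class TestFlipAugment:
    def test_flip_is_involution(self, dataset):
        block = to_block(dataset)
        twice = flip_block(flip_block(block))
        assert np.array_equal(twice.values, block.values)
        assert np.array_equal(twice.labels, block.labels)

    def test_counts_double_for_task_rest_unchanged(self, dataset):
        block = to_block(dataset)
        block.split = "train"
        aug = flip_augment(block)
        for lab in ("left", "right"):
            assert (aug.labels == lab).sum() == 2 * (block.labels == lab).sum()
        assert (aug.labels == "rest").sum() == (block.labels == "rest").sum()

    def test_left_count_after_augmentation(self, dataset):
        block = to_block(dataset)
        block.split = "train"
        aug = flip_augment(block)
        n_left = (block.labels == "left").sum()
        n_right = (block.labels == "right").sum()
        assert (aug.labels == "left").sum() == n_left + n_right

    def test_flipped_copies_have_swapped_labels_and_mirrored_values(self, dataset):
        block = to_block(dataset)
        block.split = "train"
        aug = flip_augment(block)
        n = len(block)
        task = np.flatnonzero(np.isin(block.labels, ("left", "right")))
        for j, i in enumerate(task[:4]):
            assert aug.labels[n + j] == {"left": "right", "right": "left"}[
                block.labels[i]
            ]
            assert np.array_equal(
                aug.values[n + j], block.values[i][:, :, :, ::-1]
            )

    def test_refuses_test_data(self, dataset):
        block = to_block(dataset)
        block.split = "test"
        with pytest.raises(ValueError, match="training-only"):
            flip_augment(block)
        block.split = None
        with pytest.raises(ValueError):
            flip_augment(block)

    def test_flip_commutes_with_build(self, dataset):
        """Flipping the voxel frame equals building from mirrored channels."""
        block = to_block(dataset)
        flipped = flip_block(block)
        # mirror the channel table mapping: channel at col -> width-1-col;
        # shared cells mirror as their cell mean
        width = block.values.shape[-1]
        table = dataset.table
        mirrored_values = np.empty_like(dataset.values)
        for rec in table:
            partners = table.by_position_all(
                rec.nn_class,
                rec.orientation,
                (width - 1 - rec.midpoint[0], rec.midpoint[1]),
            )
            ids = [p.channel_id for p in partners]
            mirrored_values[:, rec.channel_id] = dataset.values[:, ids].mean(axis=1)
        ds_m = WindowedDataset(
            mirrored_values, dataset.labels, dataset.subject_ids,
            dataset.run_ids, dataset.window_index, table,
        )
        rebuilt = to_block(ds_m)
        assert np.array_equal(rebuilt.values, flipped.values)

    def test_flip_commutes_with_zscore(self, dataset):
        """z-scoring then flipping equals flipping then z-scoring."""
        block = to_block(dataset)
        v = block.values
        mu = v.mean(axis=2, keepdims=True)
        sd = v.std(axis=2, keepdims=True) + 1e-9
        z_then_flip = ((v - mu) / sd)[:, :, :, :, ::-1]
        flipped = flip_block(block).values
        mu2 = flipped.mean(axis=2, keepdims=True)
        sd2 = flipped.std(axis=2, keepdims=True) + 1e-9
        assert np.allclose((flipped - mu2) / sd2, z_then_flip, atol=1e-6)
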