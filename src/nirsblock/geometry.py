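"""High-density optode layout and measurement-channel enumeration.

A high-density diffuse-optical array is a checkerboard of sources and
detectors on a square lattice (pitch 13 mm by default).  Every
source-detector pair whose separation matches one of the nearest-neighbour
reference distances becomes a measurement channel:

* NN1: one lattice step, 13 mm - shallow, scalp-dominated sensitivity
* NN2: a (2, 1) knight-step, 13*sqrt(5) ~ 29 mm - cortical sensitivity;
  split into horizontally and vertically oriented channels
* NN3: three lattice steps, 39 mm - enumerated but typically discarded
  (photon counts too low for PMT dynamic range)

Channel position is summarised by the source-detector midpoint, which for a
checkerboard always lands on a half-pitch (6.5 mm) lattice, so channels can
be imaged as voxels with no interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SOURCE = "source"
DETECTOR = "detector"
LEFT = "left"
RIGHT = "right"

#: NN reference distances in units of the lattice pitch.
NN_REFERENCE_FACTORS = {1: 1.0, 2: math.sqrt(5.0), 3: 3.0}

# 8-neighbourhoods on the half-pitch midpoint lattices, as (dcol, drow)
# offsets.  NN1 (and NN3) midpoints live on the 45-degree "diamond"
# sub-lattice (col+row odd); NN2 midpoints of a given orientation live on a
# stride-2 rectangular sub-lattice.
_DIAMOND_OFFSETS = (
    (1, 1), (1, -1), (-1, 1), (-1, -1), (2, 0), (-2, 0), (0, 2), (0, -2),
)
_RECT_OFFSETS = (
    (2, 0), (-2, 0), (0, 2), (0, -2), (2, 2), (2, -2), (-2, 2), (-2, -2),
)


@dataclass(frozen=True)
class Optode:
    """A single source or detector in the pad plane (x right, y down, mm)."""

    optode_id: int
    role: str
    pad: str
    x_mm: float
    y_mm: float


@dataclass
class OptodeLayout:
    """A set of optodes on a square lattice, possibly spanning two pads."""

    optodes: list[Optode]
    pitch_mm: float
    pad_gap_mm: float = 0.0

    @property
    def sources(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == SOURCE]

    @property
    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == DETECTOR]

    def frame_width_mm(self) -> float:
        xs = [o.x_mm for o in self.optodes]
        return (min(xs) + max(xs)) if xs else 0.0

    def mirrored(self) -> "OptodeLayout":
        """Reflect the layout about its vertical midline (x -> width - x)."""
        w = self.frame_width_mm()
        swap = {LEFT: RIGHT, RIGHT: LEFT}
        opt = [
            replace(o, x_mm=w - o.x_mm, pad=swap.get(o.pad, o.pad))
            for o in self.optodes
        ]
        return OptodeLayout(opt, self.pitch_mm, self.pad_gap_mm)

    def to_json(self) -> str:
        doc = {
            "pitch_mm": self.pitch_mm,
            "pad_gap_mm": self.pad_gap_mm,
            "optodes": [
                {
                    "id": o.optode_id,
                    "role": o.role,
                    "pad": o.pad,
                    "x_mm": o.x_mm,
                    "y_mm": o.y_mm,
                }
                for o in self.optodes
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "OptodeLayout":
        doc = json.loads(text)
        optodes = [
            Optode(d["id"], d["role"], d["pad"], d["x_mm"], d["y_mm"])
            for d in doc["optodes"]
        ]
        return cls(optodes, doc["pitch_mm"], doc.get("pad_gap_mm", 0.0))


@dataclass(frozen=True)
class ChannelRecord:
    """One source-detector measurement channel."""

    channel_id: int
    source_id: int
    detector_id: int
    pad: str
    sds_mm: float
    nn_class: int
    orientation: str  # 'none' | 'horizontal' | 'vertical'
    midpoint: tuple[int, int]  # (col, row) on the half-pitch lattice

    @property
    def group(self) -> tuple[int, str]:
        return (self.nn_class, self.orientation)


class ChannelTable:
    """Ordered, indexed collection of :class:`ChannelRecord`.

    Ordering is deterministic: (pad, nn_class, orientation, row-major
    midpoint).  Lookup by ``(source_id, detector_id)`` and by
    ``(nn_class, orientation, midpoint)``.
    """

    def __init__(self, records: Sequence[ChannelRecord]):
        key = lambda r: (
            0 if r.pad == LEFT else 1,
            r.nn_class,
            r.orientation,
            r.midpoint[1],
            r.midpoint[0],
        )
        ordered = sorted(records, key=key)
        self.records: list[ChannelRecord] = [
            replace(r, channel_id=i) for i, r in enumerate(ordered)
        ]
        self._by_pair = {(r.source_id, r.detector_id): r for r in self.records}
        # NN2 centre points can overlap (the two diagonal directions share
        # midpoints), so a cell may hold more than one channel
        self._by_pos: dict = {}
        for r in self.records:
            self._by_pos.setdefault((r.nn_class, r.orientation, r.midpoint), []).append(r)
        if len(self._by_pair) != len(self.records):
            raise ValueError("duplicate (source, detector) pair in channel table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx: int) -> ChannelRecord:
        return self.records[idx]

    def by_pair(self, source_id: int, detector_id: int) -> ChannelRecord:
        return self._by_pair[(source_id, detector_id)]

    def by_position(
        self, nn_class: int, orientation: str, midpoint: tuple[int, int]
    ) -> ChannelRecord | None:
        """First channel at a cell (canonical order); see ``by_position_all``."""
        recs = self._by_pos.get((nn_class, orientation, midpoint))
        return recs[0] if recs else None

    def by_position_all(
        self, nn_class: int, orientation: str, midpoint: tuple[int, int]
    ) -> list[ChannelRecord]:
        return list(self._by_pos.get((nn_class, orientation, midpoint), []))

    def select(self, predicate) -> "ChannelTable":
        return ChannelTable([r for r in self.records if predicate(r)])

    @property
    def sds_mm(self) -> np.ndarray:
        return np.array([r.sds_mm for r in self.records])

    @property
    def nn_class(self) -> np.ndarray:
        return np.array([r.nn_class for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": [r.channel_id for r in self.records],
                "source": [r.source_id for r in self.records],
                "detector": [r.detector_id for r in self.records],
                "pad": [r.pad for r in self.records],
                "sds_mm": [r.sds_mm for r in self.records],
                "nn": [r.nn_class for r in self.records],
                "orientation": [r.orientation for r in self.records],
                "vox_col": [r.midpoint[0] for r in self.records],
                "vox_row": [r.midpoint[1] for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChannelTable":
        df = pd.read_csv(path, sep="\t")
        recs = [
            ChannelRecord(
                int(row.channel_id),
                int(row.source),
                int(row.detector),
                str(row.pad),
                float(row.sds_mm),
                int(row.nn),
                str(row.orientation),
                (int(row.vox_col), int(row.vox_row)),
            )
            for row in df.itertuples()
        ]
        return cls(recs)


def build_checkerboard_pad(
    rows: int,
    cols: int,
    pitch_mm: float = 13.0,
    corner_role: str = SOURCE,
    pad: str = LEFT,
    masked: Iterable[tuple[int, int]] = (),
    x_offset_mm: float = 0.0,
    id_offset: int = 0,
) -> OptodeLayout:
    """Build one rows x cols checkerboard pad.

    Roles alternate from ``corner_role`` at lattice position (row 0, col 0).
    ``masked`` lists (row, col) lattice positions to omit, e.g. to realise a
    16-source / 15-detector pad from a 4 x 8 grid.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"pad dimensions must be >= 1, got {rows}x{cols}")
    if pitch_mm <= 0:
        raise ValueError(f"pitch must be positive, got {pitch_mm}")
    other = DETECTOR if corner_role == SOURCE else SOURCE
    masked = set(masked)
    optodes = []
    oid = id_offset
    for r in range(rows):
        for c in range(cols):
            if (r, c) in masked:
                continue
            role = corner_role if (r + c) % 2 == 0 else other
            optodes.append(
                Optode(oid, role, pad, x_offset_mm + c * pitch_mm, r * pitch_mm)
            )
            oid += 1
    return OptodeLayout(optodes, pitch_mm)


def build_motor_layout(
    rows: int = 4,
    cols: int = 8,
    pitch_mm: float = 13.0,
    pad_gap_mm: float = 26.0,
    masked_corner: tuple[int, int] | None = (0, 7),
) -> OptodeLayout:
    """Two mirror-image checkerboard pads over left and right motor cortex.

    The default 4 x 8 pad with one detector corner masked yields 16 sources
    and 15 detectors per pad.  The right pad is the exact mirror image of
    the left about the frame midline, so mirror-flip augmentation is well
    defined.  ``pad_gap_mm`` must be a multiple of the half pitch and keeps
    the full frame midline on a half-pitch voxel column.
    """
    half = pitch_mm / 2.0
    gap_hp = pad_gap_mm / half
    if abs(gap_hp - round(gap_hp)) > 1e-9 or int(round(gap_hp)) % 2 != 0:
        raise ValueError("pad_gap_mm must be an even multiple of the half pitch")
    masked = [masked_corner] if masked_corner is not None else []
    if masked_corner is not None:
        r, c = masked_corner
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"masked corner {masked_corner} outside {rows}x{cols} pad")
    left = build_checkerboard_pad(
        rows, cols, pitch_mm, corner_role=SOURCE, pad=LEFT, masked=masked
    )
    width = 2 * (cols - 1) * pitch_mm + pad_gap_mm
    swapped = []
    oid = len(left.optodes)
    for o in left.optodes:
        swapped.append(Optode(oid, o.role, RIGHT, width - o.x_mm, o.y_mm))
        oid += 1
    layout = OptodeLayout(left.optodes + swapped, pitch_mm, pad_gap_mm)
    return layout


def _classify_distance(
    dist_mm: float, pitch_mm: float, max_nn: int, tolerance_mm: float
) -> int | None:
    hits = [
        nn
        for nn, f in NN_REFERENCE_FACTORS.items()
        if nn <= max_nn and abs(dist_mm - f * pitch_mm) <= tolerance_mm
    ]
    if len(hits) > 1:
        raise ValueError(
            f"distance {dist_mm:.3f} mm is within tolerance of NN classes {hits}"
        )
    return hits[0] if hits else None


def enumerate_channels(
    layout: OptodeLayout, max_nn: int = 3, tolerance_mm: float = 0.5
) -> ChannelTable:
    """Enumerate all same-pad source-detector pairs at NN1..NN``max_nn``.

    NN2 channels are oriented: horizontal when the source-detector
    displacement is longer along x than along y, vertical otherwise.
    Midpoints are stored on the half-pitch lattice and must be exactly
    representable there.
    """
    if max_nn not in (1, 2, 3):
        raise ValueError(f"max_nn must be 1, 2 or 3, got {max_nn}")
    half = layout.pitch_mm / 2.0
    records = []
    for s in layout.sources:
        for d in layout.detectors:
            if s.pad != d.pad:
                continue
            dx = d.x_mm - s.x_mm
            dy = d.y_mm - s.y_mm
            dist = math.hypot(dx, dy)
            nn = _classify_distance(dist, layout.pitch_mm, max_nn, tolerance_mm)
            if nn is None:
                continue
            orientation = "none"
            if nn == 2:
                orientation = "horizontal" if abs(dx) > abs(dy) else "vertical"
            mid_col = (s.x_mm + d.x_mm) / 2.0 / half
            mid_row = (s.y_mm + d.y_mm) / 2.0 / half
            if abs(mid_col - round(mid_col)) > 1e-6 or abs(mid_row - round(mid_row)) > 1e-6:
                raise ValueError(
                    f"midpoint of pair ({s.optode_id},{d.optode_id}) not on the "
                    "half-pitch lattice"
                )
            records.append(
                ChannelRecord(
                    channel_id=-1,
                    source_id=s.optode_id,
                    detector_id=d.optode_id,
                    pad=s.pad,
                    sds_mm=dist,
                    nn_class=nn,
                    orientation=orientation,
                    midpoint=(int(round(mid_col)), int(round(mid_row))),
                )
            )
    return ChannelTable(records)


def block_neighbourhood(
    channel: ChannelRecord, table: ChannelTable
) -> list[ChannelRecord]:
    """The <= 8 channels adjoining ``channel`` in its group's native grid.

    Groups are (nn_class, orientation); neighbours are the channels whose
    midpoints are adjacent or diagonal on the group's sub-lattice.  Used
    both for poor-channel interpolation and to define the voxel image
    neighbourhood.
    """
    offsets = _RECT_OFFSETS if channel.nn_class == 2 else _DIAMOND_OFFSETS
    col, row = channel.midpoint
    out = []
    for dc, dr in offsets:
        out.extend(
            table.by_position_all(
                channel.nn_class, channel.orientation, (col + dc, row + dr)
            )
        )
    # a co-located channel (shared centre point) also counts as a neighbour
    out.extend(
        r
        for r in table.by_position_all(
            channel.nn_class, channel.orientation, channel.midpoint
        )
        if r.channel_id != channel.channel_id
    )
    return out


def frame_shape(table: ChannelTable) -> tuple[int, int]:
    """(height, width) in half-pitch voxels of the frame spanning all midpoints."""
    if len(table) == 0:
        return (0, 0)
    cols = [r.midpoint[0] for r in table]
    rows = [r.midpoint[1] for r in table]
    return (max(rows) + 1, max(cols) + 1)
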