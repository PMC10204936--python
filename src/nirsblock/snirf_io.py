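"""SNIRF (HDF5) reading and writing for simulated FD-fNIRS runs.

Runs are stored in the community SNIRF layout: one ``/nirs`` group with a
single data block whose columns are described by ``measurementList``
entries (frequency-domain amplitude dataType 101, phase dataType 102),
probe geometry (2D optode positions, wavelengths), stimulus groups per
condition, and metadata tags carrying subject/run identity and the
sampling and modulation frequencies.  A BIDS-style events table
(onset / duration / trial_type TSV) mirrors the stimulus groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py

from .geometry import ChannelTable, Optode, OptodeLayout
from .simulate import Event, Paradigm, RunRecording

FORMAT_VERSION = "1.0"
DT_AMPLITUDE_FD = 101
DT_PHASE_FD = 102


def _str_dataset(group, name, value):
    group.create_dataset(name, data=np.bytes_(value))


def write_events_tsv(paradigm: Paradigm, path) -> None:
    rows = [
        {"onset": e.onset_s, "duration": e.duration_s, "trial_type": e.label}
        for e in paradigm.events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> Paradigm:
    df = pd.read_csv(path, sep="\t")
    events = [
        Event(str(r.trial_type), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    total = max(e.onset_s + e.duration_s for e in events)
    return Paradigm(events, total)


def write_snirf(
    run: RunRecording, table: ChannelTable, layout: OptodeLayout, path
) -> None:
    """Write one run as a SNIRF-conformant HDF5 file."""
    source_ids = sorted({r.source_id for r in table})
    detector_ids = sorted({r.detector_id for r in table})
    s_index = {s: i + 1 for i, s in enumerate(source_ids)}  # SNIRF is 1-based
    d_index = {d: i + 1 for i, d in enumerate(detector_ids)}
    opt = {o.optode_id: o for o in layout.optodes}

    n_ch = len(table)
    n_t = run.n_times
    # column order: channel-major, then wavelength, then (amplitude, phase)
    cols = np.empty((n_t, n_ch * 4), dtype=np.float32)
    ml = []
    c = 0
    for rec in table:
        for w in range(2):
            for dtype, block in ((DT_AMPLITUDE_FD, run.intensity), (DT_PHASE_FD, run.phase)):
                cols[:, c] = block[rec.channel_id, w, :]
                ml.append((s_index[rec.source_id], d_index[rec.detector_id], w + 1, dtype))
                c += 1

    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", FORMAT_VERSION)
        nirs = f.create_group("/nirs1")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", f"sub-{run.subject_id:02d}")
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "mm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        meta.create_dataset("RunID", data=int(run.run_id))
        meta.create_dataset("ModulationFrequency", data=float(run.mod_freq_hz))

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=cols)
        data.create_dataset("time", data=np.arange(n_t) / run.fs_hz)
        for i, (si, di, wi, dtype) in enumerate(ml, start=1):
            g = data.create_group(f"measurementList{i}")
            g.create_dataset("sourceIndex", data=si)
            g.create_dataset("detectorIndex", data=di)
            g.create_dataset("wavelengthIndex", data=wi)
            g.create_dataset("dataType", data=dtype)
            g.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(run.wavelengths_nm))
        probe.create_dataset(
            "sourcePos2D",
            data=np.array([(opt[s].x_mm, opt[s].y_mm) for s in source_ids]),
        )
        probe.create_dataset(
            "detectorPos2D",
            data=np.array([(opt[d].x_mm, opt[d].y_mm) for d in detector_ids]),
        )

        for k, cond in enumerate(("left", "right", "rest"), start=1):
            ev = [e for e in run.paradigm.events if e.label == cond]
            if not ev:
                continue
            stim = nirs.create_group(f"stim{k}")
            _str_dataset(stim, "name", cond)
            stim.create_dataset(
                "data",
                data=np.array([(e.onset_s, e.duration_s, 1.0) for e in ev]),
            )


def read_snirf(path, table: ChannelTable | None = None) -> RunRecording:
    """Read a SNIRF file back into a :class:`RunRecording`.

    If ``table`` is given, channels are aligned to it via their
    (source, detector) indices; otherwise file order defines the channel
    order.  Files without phase columns load with ``has_phase=False`` and
    zero phase.
    """
    with h5py.File(path, "r") as f:
        if "nirs1" in f:
            nirs = f["nirs1"]
        elif "nirs" in f:
            nirs = f["nirs"]
        else:
            raise ValueError(f"{path}: no /nirs group; not a SNIRF file")
        if "data1" not in nirs:
            raise ValueError(f"{path}: missing /nirs/data1 block")
        data = nirs["data1"]
        cols = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / np.median(np.diff(time))
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise ValueError(f"{path}: no measurementList entries")
        entries = []
        for name in ml_names:
            g = data[name]
            entries.append(
                (
                    int(g["sourceIndex"][()]),
                    int(g["detectorIndex"][()]),
                    int(g["wavelengthIndex"][()]),
                    int(g["dataType"][()]),
                )
            )
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())

        # group columns into channels
        pairs = []
        for si, di, wi, dt in entries:
            if (si, di) not in pairs:
                pairs.append((si, di))
        n_ch = len(pairs)
        pair_pos = {p: i for i, p in enumerate(pairs)}
        n_t = cols.shape[0]
        intensity = np.zeros((n_ch, 2, n_t), dtype=np.float32)
        phase = np.zeros((n_ch, 2, n_t), dtype=np.float32)
        has_phase = any(dt == DT_PHASE_FD for _, _, _, dt in entries)
        for c, (si, di, wi, dt) in enumerate(entries):
            ch = pair_pos[(si, di)]
            if dt == DT_PHASE_FD:
                phase[ch, wi - 1] = cols[:, c]
            else:
                intensity[ch, wi - 1] = cols[:, c]

        if table is not None:
            source_ids = sorted({r.source_id for r in table})
            detector_ids = sorted({r.detector_id for r in table})
            order = []
            for rec in table:
                key = (
                    source_ids.index(rec.source_id) + 1,
                    detector_ids.index(rec.detector_id) + 1,
                )
                if key not in pair_pos:
                    raise ValueError(f"channel {key} missing from {path}")
                order.append(pair_pos[key])
            intensity = intensity[order]
            phase = phase[order]

        events = []
        for k in sorted(nirs.keys()):
            if not k.startswith("stim"):
                continue
            stim = nirs[k]
            name = stim["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            for onset, dur, _ in np.atleast_2d(np.asarray(stim["data"])):
                events.append(Event(name, float(onset), float(dur)))
        events.sort(key=lambda e: e.onset_s)
        # the recording itself bounds the paradigm length; foreign files may
        # carry stimulus events that do not span the whole recording
        total = n_t / fs
        if events:
            total = max(total, max(e.onset_s + e.duration_s for e in events))
        total = round(total * fs) / fs
        paradigm = Paradigm(events, total)

        meta = nirs["metaDataTags"] if "metaDataTags" in nirs else {}
        sub = 0
        if "SubjectID" in meta:
            raw = meta["SubjectID"][()]
            raw = raw.decode() if isinstance(raw, bytes) else str(raw)
            digits = "".join(ch for ch in raw if ch.isdigit())
            sub = int(digits) if digits else 0
        run_id = int(meta["RunID"][()]) if "RunID" in meta else 0
        mod = float(meta["ModulationFrequency"][()]) if "ModulationFrequency" in meta else 0.0

    if not has_phase:
        import warnings

        warnings.warn(f"{path}: no phase columns; loaded amplitude only", stacklevel=2)
    return RunRecording(
        intensity=intensity,
        phase=phase,
        fs_hz=float(round(fs, 6)),
        wavelengths_nm=wavelengths,
        mod_freq_hz=mod,
        paradigm=paradigm,
        subject_id=sub,
        run_id=run_id,
        has_phase=has_phase,
    )


def validate_snirf(path) -> list[str]:
    """Light-weight conformance check; returns a list of problems (empty = ok)."""
    problems = []
    with h5py.File(path, "r") as f:
        if "formatVersion" not in f:
            problems.append("missing /formatVersion")
        nirs = f.get("nirs1") or f.get("nirs")
        if nirs is None:
            return problems + ["missing /nirs group"]
        data = nirs.get("data1")
        if data is None:
            return problems + ["missing data1"]
        n_cols = data["dataTimeSeries"].shape[1]
        ml = [k for k in data.keys() if k.startswith("measurementList")]
        if len(ml) != n_cols:
            problems.append(
                f"measurementList count {len(ml)} != data columns {n_cols}"
            )
        if "time" not in data:
            problems.append("missing time vector")
        probe = nirs.get("probe")
        if probe is None or "wavelengths" not in probe:
            problems.append("missing probe/wavelengths")
        else:
            n_wl = len(probe["wavelengths"])
            for k in ml:
                wi = int(data[k]["wavelengthIndex"][()])
                if not 1 <= wi <= n_wl:
                    problems.append(f"{k}: wavelengthIndex {wi} out of range")
                    break
    return problems
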