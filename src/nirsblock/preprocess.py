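"""Preprocessing chain from raw FD-fNIRS runs to labelled 20-frame examples.

Fixed stage order (each stage preserves channel indexing):

    delta-OD / delta-phase -> channel QC -> discard SDS > 30 mm ->
    band-pass 0.01-0.5 Hz -> chromophore conversion -> resample to 2 Hz ->
    z-score -> interpolate poor channels -> window into 20-frame examples

Difference measures are taken against the run mean: dOD = -ln(i / mean(i)),
dph = ph - mean(ph).  Channel quality uses the coefficient of variation
(std/mean) of raw intensity; a channel with CV >= 7.5 is poor, and a run
in which more than 30% of the short (SDS < 30 mm) channels are poor is
rejected (mis-seated cap).  Chromophore conversion solves the two-
wavelength modified Beer-Lambert system with effective pathlengths from
the frequency-domain semi-infinite model; a pass-through mode forwards
the processed intensity and phase measures unconverted.  Standardisation
uses the population z-score over the whole run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .geometry import ChannelTable, block_neighbourhood
from .optics import EXTINCTION_690_830, OpticalProperties, effective_pathlength
from .simulate import RunRecording

logger = logging.getLogger(__name__)

CHROMOPHORES = ("HbO", "Hb")
PASSTHROUGH_COMPONENTS = ("od690", "od830", "ph690", "ph830")


@dataclass
class ODSeries:
    """Optical-density and phase-shift difference measures."""

    delta_od: np.ndarray  # [channel, wavelength, time]
    delta_phase: np.ndarray  # [channel, wavelength, time], radians
    fs_hz: float


@dataclass
class QCReport:
    cv: np.ndarray  # std/mean per channel (max over wavelengths)
    poor: np.ndarray  # bool per channel
    rejected: bool
    frac_poor_short: float


@dataclass
class ChromophoreSeries:
    """Per-channel component time-series (HbO/Hb, or pass-through measures)."""

    conc: np.ndarray  # [channel, component, time]
    fs_hz: float
    components: tuple[str, ...] = CHROMOPHORES
    z_scored: bool = False


@dataclass
class WindowedRun:
    """Labelled 20-frame examples from one run."""

    values: np.ndarray  # [n_examples, channel, component, frames]
    labels: np.ndarray  # 'left' | 'right' | 'rest'
    subject_id: int
    run_id: int
    window_index: np.ndarray


@dataclass
class WindowedDataset:
    """Examples pooled over runs, with provenance for group-aware splitting."""

    values: np.ndarray  # [n, channel, component, frames]
    labels: np.ndarray
    subject_ids: np.ndarray
    run_ids: np.ndarray
    window_index: np.ndarray
    table: ChannelTable
    components: tuple[str, ...] = CHROMOPHORES
    split: str | None = None  # 'train' | 'test' | None; guards augmentation

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def session_keys(self) -> np.ndarray:
        """(subject, run) collection-session key per example."""
        return np.array(
            [f"s{s}r{r}" for s, r in zip(self.subject_ids, self.run_ids)]
        )

    def subset(self, idx, split: str | None = None) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            self.values[idx],
            self.labels[idx],
            self.subject_ids[idx],
            self.run_ids[idx],
            self.window_index[idx],
            self.table,
            self.components,
            split=split if split is not None else self.split,
        )

    @classmethod
    def from_runs(
        cls, runs: list[WindowedRun], table: ChannelTable, components=CHROMOPHORES
    ) -> "WindowedDataset":
        if not runs:
            raise ValueError("no accepted runs to pool")
        return cls(
            np.concatenate([r.values for r in runs]).astype(np.float32),
            np.concatenate([r.labels for r in runs]),
            np.concatenate([np.full(len(r.labels), r.subject_id) for r in runs]),
            np.concatenate([np.full(len(r.labels), r.run_id) for r in runs]),
            np.concatenate([r.window_index for r in runs]),
            table,
            tuple(components),
        )


@dataclass
class PreprocessConfig:
    cv_threshold: float = 7.5
    frac_threshold: float = 0.30
    short_sds_mm: float = 30.0
    max_sds_mm: float = 30.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.5
    filter_order: int = 3
    target_fs_hz: float = 2.0
    frames_per_example: int = 20
    conversion: str = "mbll"  # 'mbll' | 'passthrough'
    optical_properties: OpticalProperties = field(default_factory=OpticalProperties)


# ---------------------------------------------------------------------------
# individual stages


def delta_od(intensity: np.ndarray) -> np.ndarray:
    """dOD = -ln(i / run-mean), per channel and wavelength."""
    if np.any(intensity <= 0):
        ch, w, t = np.unravel_index(
            int(np.argmax(intensity <= 0)), intensity.shape
        )
        raise ValueError(
            f"non-positive intensity at channel {ch}, wavelength {w}, sample {t}"
        )
    mu = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mu)


def delta_phase(phase: np.ndarray) -> np.ndarray:
    """dph = ph - run-mean, per channel and wavelength."""
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase contains non-finite samples")
    return phase - phase.mean(axis=-1, keepdims=True)


def qc_flag(
    run: RunRecording,
    table: ChannelTable,
    cv_threshold: float = 7.5,
    frac_threshold: float = 0.30,
    short_sds_mm: float = 30.0,
) -> QCReport:
    """Coefficient-of-variation QC on raw intensity, before any filtering."""
    mean = run.intensity.mean(axis=-1)
    std = run.intensity.std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_w = np.where(mean > 0, std / mean, np.inf)
    cv = cv_w.max(axis=1)
    poor = cv >= cv_threshold
    short = table.sds_mm < short_sds_mm
    frac = float(poor[short].mean()) if short.any() else 0.0
    rejected = frac > frac_threshold
    logger.info(
        "QC: %d/%d channels poor (%.0f%% of short channels)%s",
        int(poor.sum()),
        len(poor),
        100 * frac,
        "; RUN REJECTED" if rejected else "",
    )
    return QCReport(cv=cv, poor=poor, rejected=rejected, frac_poor_short=frac)


def discard_long_channels(
    table: ChannelTable, *arrays: np.ndarray, max_sds_mm: float = 30.0
):
    """Drop channels with SDS > ``max_sds_mm`` (NN3) from table and arrays."""
    keep = np.array([r.sds_mm <= max_sds_mm for r in table])
    if not keep.any():
        raise ValueError("no channels remain after discarding long separations")
    reduced = ChannelTable([r for r, k in zip(table, keep) if k])
    out = tuple(a[keep] for a in arrays)
    return (reduced, *out)


def bandpass(
    x: np.ndarray,
    fs_hz: float,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not (0 < low_hz < high_hz < fs_hz / 2):
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] at fs={fs_hz}")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def to_chromophores(
    od: ODSeries,
    table: ChannelTable,
    props: OpticalProperties | None = None,
    pathlengths_mm: np.ndarray | None = None,
    extinction: np.ndarray = EXTINCTION_690_830,
    mode: str = "mbll",
    mod_freq_hz: float = 141e6,
) -> ChromophoreSeries:
    """Invert the two-wavelength modified Beer-Lambert system per channel.

    dOD_w = L_w * (eps_w,HbO dHbO + eps_w,Hb dHb); effective pathlengths
    come from the frequency-domain semi-infinite model unless supplied.
    ``mode='passthrough'`` skips conversion and stacks dOD and dphase as
    four components instead.
    """
    if mode == "passthrough":
        conc = np.concatenate([od.delta_od, od.delta_phase], axis=1)
        return ChromophoreSeries(conc, od.fs_hz, PASSTHROUGH_COMPONENTS)
    if mode != "mbll":
        raise ValueError(f"unknown conversion mode {mode!r}")
    if props is None:
        props = OpticalProperties()
    sds = table.sds_mm
    if pathlengths_mm is None:
        pathlengths_mm = np.stack(
            [effective_pathlength(sds, props, mod_freq_hz, w) for w in range(2)],
            axis=1,
        )  # [channel, wavelength]
    # A[ch, w, k] = L[ch, w] * eps[w, k]
    A = pathlengths_mm[:, :, None] * extinction[None, :, :]
    det = np.linalg.det(A)
    if np.any(np.abs(det) < 1e-18):
        raise np.linalg.LinAlgError("singular Beer-Lambert system")
    conc = np.einsum("ckw,cwt->ckt", np.linalg.inv(A), od.delta_od)
    return ChromophoreSeries(conc, od.fs_hz, CHROMOPHORES)


def resample(x: np.ndarray, fs_hz: float, target_fs_hz: float = 2.0) -> np.ndarray:
    """Anti-aliased polyphase decimation along the last axis."""
    if target_fs_hz > fs_hz:
        raise ValueError("target rate above source rate")
    from fractions import Fraction

    frac = Fraction(target_fs_hz / fs_hz).limit_denominator(1000)
    return resample_poly(
        x, frac.numerator, frac.denominator, axis=-1, padtype="line"
    )


def zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score along the last axis; constant series map to zero."""
    mu = x.mean(axis=-1, keepdims=True)
    sigma = x.std(axis=-1, keepdims=True)
    flat = sigma <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant series mapped to zero in z-scoring",
            stacklevel=2,
        )
    return np.where(flat, 0.0, (x - mu) / np.where(flat, 1.0, sigma))


def interpolate_poor(
    series: ChromophoreSeries, qc: QCReport, table: ChannelTable
) -> ChromophoreSeries:
    """Replace poor channels by the mean of their good block neighbours.

    Neighbours are the <= 8 adjoining/diagonal channels of the same NN
    class (and NN2 orientation), same component.
    """
    poor_idx = np.flatnonzero(qc.poor)
    if poor_idx.size == 0:
        return series
    conc = series.conc.copy()
    for ch in poor_idx:
        rec = table[int(ch)]
        nbs = [
            nb.channel_id
            for nb in block_neighbourhood(rec, table)
            if not qc.poor[nb.channel_id]
        ]
        if not nbs:
            raise ValueError(
                f"poor channel {rec.channel_id} (S{rec.source_id}-D{rec.detector_id}) "
                "has no good neighbours to interpolate from"
            )
        conc[ch] = series.conc[nbs].mean(axis=0)
    logger.info("interpolated %d poor channels", poor_idx.size)
    return ChromophoreSeries(conc, series.fs_hz, series.components, series.z_scored)


def window(
    series: ChromophoreSeries,
    paradigm,
    subject_id: int,
    run_id: int,
    frames: int = 20,
) -> WindowedRun:
    """Split a 2 Hz run into labelled 20-frame (10 s) examples.

    One window per 10 s task block (labelled by hand) and one per
    inter-task rest interval, aligned to the rest onset; the rest interval
    after the final block merges into the closing 30 s rest and is not
    windowed.  A default run therefore yields 16 + 15 = 31 examples.
    """
    fs = series.fs_hz
    n_t = series.conc.shape[-1]
    values, labels, widx = [], [], []
    task_events = paradigm.task_events
    for i, ev in enumerate(task_events):
        starts = [(ev.onset_s, ev.label)]
        if i < len(task_events) - 1:
            starts.append((ev.onset_s + ev.duration_s, "rest"))
        for onset_s, label in starts:
            i0 = int(round(onset_s * fs))
            if i0 + frames > n_t:
                raise ValueError(
                    f"window at {onset_s:.1f}s extends past the recording"
                )
            values.append(series.conc[:, :, i0 : i0 + frames])
            labels.append(label)
            widx.append(len(widx))
    return WindowedRun(
        values=np.stack(values).astype(np.float32),
        labels=np.array(labels),
        subject_id=subject_id,
        run_id=run_id,
        window_index=np.array(widx),
    )


# ---------------------------------------------------------------------------
# pipeline


def preprocess_run(
    run: RunRecording,
    table: ChannelTable,
    config: PreprocessConfig | None = None,
) -> tuple[WindowedRun | None, QCReport]:
    """Full chain for one run; returns (None, report) for rejected runs."""
    cfg = config or PreprocessConfig()
    # full-rate stages run in float32 for speed; everything after the 2 Hz
    # resample is float64 so standardisation is exact
    od = ODSeries(
        delta_od(np.asarray(run.intensity, dtype=np.float32)),
        delta_phase(np.asarray(run.phase, dtype=np.float32)),
        run.fs_hz,
    )
    qc = qc_flag(
        run, table, cfg.cv_threshold, cfg.frac_threshold, cfg.short_sds_mm
    )
    if qc.rejected:
        return None, qc
    table_r, d_od, d_ph, poor = discard_long_channels(
        table, od.delta_od, od.delta_phase, qc.poor, max_sds_mm=cfg.max_sds_mm
    )
    qc_r = QCReport(qc.cv[table.sds_mm <= cfg.max_sds_mm], poor, False, qc.frac_poor_short)
    d_od = bandpass(d_od, run.fs_hz, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
    d_ph = bandpass(d_ph, run.fs_hz, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
    series = to_chromophores(
        ODSeries(d_od, d_ph, run.fs_hz),
        table_r,
        props=cfg.optical_properties,
        mode=cfg.conversion,
        mod_freq_hz=run.mod_freq_hz,
    )
    conc = resample(series.conc, run.fs_hz, cfg.target_fs_hz)
    conc = zscore(conc)
    series = ChromophoreSeries(conc, cfg.target_fs_hz, series.components, z_scored=True)
    series = interpolate_poor(series, qc_r, table_r)
    return (
        window(series, run.paradigm, run.subject_id, run.run_id, cfg.frames_per_example),
        qc,
    )


def preprocess_cohort(
    runs: list[RunRecording],
    table: ChannelTable,
    config: PreprocessConfig | None = None,
) -> tuple[WindowedDataset, list[QCReport]]:
    """Preprocess many runs, dropping rejected ones, and pool the examples."""
    cfg = config or PreprocessConfig()
    windowed, reports = [], []
    retained_table = None
    for run in runs:
        wr, qc = preprocess_run(run, table, cfg)
        reports.append(qc)
        if wr is not None:
            windowed.append(wr)
            if retained_table is None:
                retained_table = discard_long_channels(
                    table, max_sds_mm=cfg.max_sds_mm
                )[0]
    components = (
        CHROMOPHORES if cfg.conversion == "mbll" else PASSTHROUGH_COMPONENTS
    )
    dataset = WindowedDataset.from_runs(windowed, retained_table, components)
    logger.info(
        "preprocessed %d/%d runs -> %d examples", len(windowed), len(runs), len(dataset)
    )
    return dataset, reports
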