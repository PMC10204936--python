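"""Synthetic frequency-domain fNIRS runs for the finger-opposition paradigm.

Emulates a dual-pad high-density FD-fNIRS acquisition over the motor
cortices: a 16-block left/right finger-opposition paradigm, contralateral
double-gamma haemodynamic responses with subject-specific amplitude,
latency, spatial extent and probe-placement offset, systemic sinusoids
(cardiac / respiratory / Mayer waves), separation-dependent shot-like
noise, and optional poor-quality channels.

Channel intensities follow the frequency-domain semi-infinite forward
model: a task- or systemic-induced absorption change ``dmua`` perturbs the
baseline amplitude via the effective pathlength ``L`` (intensity =
A0 * exp(-L * dmua)) and the phase via the phase-absorption sensitivity.
Cortical (task) changes weight NN2 channels more than NN1; superficial
(systemic) changes weight NN1 at least as much as NN2, mimicking the
depth-sensitivity difference between short and long channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .geometry import LEFT, RIGHT, ChannelTable, OptodeLayout
from .optics import (
    EXTINCTION_690_830,
    WAVELENGTHS_NM,
    OpticalProperties,
    effective_pathlength,
    fd_semiinfinite_response,
    phase_absorption_sensitivity,
)

FS_HZ = 39.0
MOD_FREQ_HZ = 141e6
TASK_S = 10.0
REST_S = 15.0
LEAD_REST_S = 30.0
N_BLOCKS = 16

#: depth weights by NN class: cortical (task) and superficial (systemic)
CORTICAL_WEIGHT = {1: 0.3, 2: 1.0, 3: 1.0}
SUPERFICIAL_WEIGHT = {1: 1.0, 2: 0.6, 3: 0.5}

#: the task hand activates the opposite hemisphere's pad
CONTRALATERAL = {"left": RIGHT, "right": LEFT}


@dataclass(frozen=True)
class Event:
    label: str  # 'left' | 'right' | 'rest'
    onset_s: float
    duration_s: float


@dataclass
class Paradigm:
    """Timeline of one experimental run (460 s by default).

    30 s rest, then 16 blocks of 10 s task + 15 s rest (8 left / 8 right,
    pseudo-randomised, first block left, at most 3 consecutive same-hand
    blocks), then a final 30 s rest.
    """

    events: list[Event]
    total_duration_s: float

    @property
    def task_events(self) -> list[Event]:
        return [e for e in self.events if e.label in ("left", "right")]

    def label_at(self, t_s: float) -> str:
        for e in self.events:
            if e.onset_s <= t_s < e.onset_s + e.duration_s:
                return e.label
        return "rest"

    def hand_indicator(self, hand: str, fs_hz: float) -> np.ndarray:
        """Boxcar time-series (1 during ``hand`` task blocks) at ``fs_hz``."""
        n = int(round(self.total_duration_s * fs_hz))
        out = np.zeros(n)
        for e in self.task_events:
            if e.label == hand:
                i0 = int(round(e.onset_s * fs_hz))
                i1 = int(round((e.onset_s + e.duration_s) * fs_hz))
                out[i0:i1] = 1.0
        return out


def make_paradigm(seed: int) -> Paradigm:
    """Pseudo-randomised block order: first block left, <= 3 consecutive same hand."""
    rng = np.random.default_rng(seed)
    while True:
        rest_labels = ["left"] * 7 + ["right"] * 8
        rng.shuffle(rest_labels)
        order = ["left"] + rest_labels
        runs = 1
        ok = True
        for a, b in zip(order, order[1:]):
            runs = runs + 1 if a == b else 1
            if runs > 3:
                ok = False
                break
        if ok:
            break
    events = [Event("rest", 0.0, LEAD_REST_S)]
    t = LEAD_REST_S
    for hand in order:
        events.append(Event(hand, t, TASK_S))
        t += TASK_S
        events.append(Event("rest", t, REST_S))
        t += REST_S
    events.append(Event("rest", t, LEAD_REST_S))
    t += LEAD_REST_S
    return Paradigm(events, t)


@dataclass
class SubjectProfile:
    """Subject-level generative parameters.

    ``locus_offset_mm`` jitters the centre of activation relative to each
    pad, emulating probe-placement and physiological variation between
    subjects - the property that distinguishes positionally invariant
    models from per-channel ones.
    """

    subject_id: int
    hrf_amplitude_uM: float = 1.0  # peak task-block delta-HbO
    hrf_latency_s: float = 6.0
    activation_sigma_mm: float = 12.0
    locus_offset_mm: dict = field(
        default_factory=lambda: {LEFT: (0.0, 0.0), RIGHT: (0.0, 0.0)}
    )
    hbr_ratio: float = 1.0 / 3.0  # |delta-Hb| / delta-HbO
    coupling_sigma: float = 0.1  # log-sd of per-channel coupling factors

    def __post_init__(self):
        if self.hrf_amplitude_uM < 0:
            raise ValueError("hrf_amplitude_uM must be >= 0")


def draw_subject_profiles(
    n_subjects: int,
    seed: int,
    locus_jitter_mm: float = 10.0,
    amplitude_mean_uM: float = 1.0,
    amplitude_sd_uM: float = 0.25,
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles; ``locus_jitter_mm`` = 0 disables offsets."""
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(n_subjects):
        amp = float(np.clip(rng.normal(amplitude_mean_uM, amplitude_sd_uM), 0.4, 2.0))
        lat = float(np.clip(rng.normal(6.0, 0.5), 4.5, 7.5))
        sig = float(np.clip(rng.normal(12.0, 2.0), 8.0, 18.0))
        offsets = {
            pad: tuple(np.clip(rng.normal(0.0, locus_jitter_mm, 2), -20.0, 20.0))
            for pad in (LEFT, RIGHT)
        }
        profiles.append(
            SubjectProfile(
                subject_id=s,
                hrf_amplitude_uM=amp,
                hrf_latency_s=lat,
                activation_sigma_mm=sig,
                locus_offset_mm=offsets,
            )
        )
    return profiles


@dataclass
class NoiseConfig:
    """Systemic oscillation and measurement-noise levels.

    Systemic amplitudes are superficial absorption changes (mm^-1); the
    noise floor is the relative intensity noise of the brightest (NN1)
    channels, scaled up for dimmer channels as 1 / sqrt(amplitude).
    """

    cardiac_hz: float = 1.1
    cardiac_dmua: float = 1e-4
    respiratory_hz: float = 0.25
    respiratory_dmua: float = 3e-5
    mayer_hz: float = 0.1
    mayer_dmua: float = 6e-5
    #: band-limited local scalp-haemodynamic fluctuations, independent per
    #: channel, RMS absorption change (mm^-1); sits inside the analysis band
    #: and is the main reason single channels are unreliable
    local_dmua: float = 8e-5
    local_cutoff_hz: float = 0.35
    #: trial-to-trial response variability: multiplicative gain and onset
    #: latency jitter of the haemodynamic response per task block
    trial_gain_sd: float = 0.35
    trial_latency_sd_s: float = 0.5
    noise_floor: float = 0.003
    phase_noise_rad: float = 2e-3


@dataclass
class RunRecording:
    """One run of raw FD-fNIRS data: intensity and phase per channel/wavelength."""

    intensity: np.ndarray  # [channel, wavelength, time], a.u., > 0
    phase: np.ndarray  # [channel, wavelength, time], radians
    fs_hz: float
    wavelengths_nm: tuple[float, float]
    mod_freq_hz: float
    paradigm: Paradigm
    subject_id: int
    run_id: int
    has_phase: bool = True  # False when loaded from an amplitude-only file

    def __post_init__(self):
        if self.intensity.shape != self.phase.shape:
            raise ValueError("intensity and phase shapes differ")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phases must be finite")
        n_expected = int(round(self.paradigm.total_duration_s * self.fs_hz))
        if self.intensity.shape[-1] != n_expected:
            raise ValueError(
                f"time axis {self.intensity.shape[-1]} != paradigm length {n_expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[-1]


def canonical_hrf(
    t_s: np.ndarray, profile: SubjectProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Double-gamma haemodynamic response kernel (delta-HbO, delta-Hb) in uM.

    The HbO response peaks at ``profile.hrf_latency_s`` with amplitude
    ``profile.hrf_amplitude_uM`` and has a late undershoot; delta-Hb is an
    inverted, scaled copy (washout of deoxygenated blood).
    """
    t = np.asarray(t_s, dtype=float)
    b = profile.hrf_latency_s / 5.0
    x = np.clip(t, 0.0, None) / b

    def gamma_pdf(x, a):
        from scipy.special import gammaln

        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((a - 1) * np.log(x[pos]) - x[pos] - gammaln(a))
        return out

    h = gamma_pdf(x, 6.0) - gamma_pdf(x, 16.0) / 6.0
    # normalise so the kernel peak equals the profile amplitude
    grid = np.linspace(0.0, 30.0, 3001) / b
    peak = np.max(gamma_pdf(grid, 6.0) - gamma_pdf(grid, 16.0) / 6.0)
    hbo = profile.hrf_amplitude_uM * h / peak
    hb = -profile.hbr_ratio * hbo
    return hbo, hb


def _channel_positions_mm(table: ChannelTable, pitch_mm: float) -> np.ndarray:
    half = pitch_mm / 2.0
    return np.array([(r.midpoint[0] * half, r.midpoint[1] * half) for r in table])


def _pad_centres_mm(layout: OptodeLayout) -> dict:
    centres = {}
    for pad in (LEFT, RIGHT):
        pts = [(o.x_mm, o.y_mm) for o in layout.optodes if o.pad == pad]
        if pts:
            centres[pad] = np.mean(np.array(pts), axis=0)
    return centres


def simulate_run(
    layout: OptodeLayout,
    table: ChannelTable,
    paradigm: Paradigm,
    profile: SubjectProfile,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    props: OpticalProperties | None = None,
    subject_id: int | None = None,
    run_id: int = 0,
) -> RunRecording:
    """Simulate one raw FD-fNIRS run on ``layout`` under ``paradigm``."""
    if noise is None:
        noise = NoiseConfig()
    if props is None:
        props = OpticalProperties()
    rng = np.random.default_rng(seed)
    fs = FS_HZ
    n_t = int(round(paradigm.total_duration_s * fs))
    n_ch = len(table)
    if n_ch == 0:
        raise ValueError("channel table is empty")
    t = np.arange(n_t) / fs

    # --- task-evoked chromophore response per channel -----------------
    from dataclasses import replace as _dc_replace

    kernel_t = np.arange(0.0, 30.0, 1.0 / fs)
    hbo_unit, _ = canonical_hrf(kernel_t, _dc_replace(profile, hrf_amplitude_uM=1.0))
    single_block = fftconvolve(
        np.ones(int(TASK_S * fs)), hbo_unit, mode="full"
    )
    block_norm = max(float(np.max(single_block)), 1e-12)

    pos = _channel_positions_mm(table, layout.pitch_mm)
    centres = _pad_centres_mm(layout)
    hbo_ch = np.zeros((n_ch, n_t), dtype=np.float32)
    for hand in ("left", "right"):
        pad = CONTRALATERAL[hand]
        locus = centres[pad] + np.asarray(profile.locus_offset_mm[pad])
        d2 = np.sum((pos - locus) ** 2, axis=1)
        spatial = np.exp(-d2 / (2.0 * profile.activation_sigma_mm**2))
        # boxcar with per-trial response gain and onset-latency jitter
        box = np.zeros(n_t)
        for ev in paradigm.task_events:
            if ev.label != hand:
                continue
            gain = max(0.0, 1.0 + noise.trial_gain_sd * rng.standard_normal())
            onset = ev.onset_s + noise.trial_latency_sd_s * rng.standard_normal()
            i0 = max(0, int(round(onset * fs)))
            i1 = min(n_t, int(round((onset + ev.duration_s) * fs)))
            box[i0:i1] = gain
        resp = fftconvolve(box, hbo_unit)[:n_t] / block_norm
        hbo_ch += (profile.hrf_amplitude_uM * spatial[:, None] * resp[None, :]).astype(
            np.float32
        )
    hb_ch = -np.float32(profile.hbr_ratio) * hbo_ch

    # --- absorption changes: cortical task + superficial systemic -----
    w_cortex = np.array([CORTICAL_WEIGHT[r.nn_class] for r in table])
    w_sup = np.array([SUPERFICIAL_WEIGHT[r.nn_class] for r in table])
    sys_dmua = np.zeros(n_t)
    for f_hz, amp in (
        (noise.cardiac_hz, noise.cardiac_dmua),
        (noise.respiratory_hz, noise.respiratory_dmua),
        (noise.mayer_hz, noise.mayer_dmua),
    ):
        sys_dmua += amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))

    # band-limited local scalp fluctuations, independent per channel and
    # coherent across wavelengths (a real haemodynamic change would be)
    if noise.local_dmua > 0:
        from scipy.signal import butter, sosfilt

        sos = butter(2, noise.local_cutoff_hz, fs=fs, output="sos")
        local = sosfilt(
            sos, rng.standard_normal((n_ch, n_t), dtype=np.float32), axis=-1
        ).astype(np.float32)
        local *= np.float32(noise.local_dmua) / (
            local.std(axis=-1, keepdims=True) + np.float32(1e-30)
        )
    else:
        local = np.zeros((n_ch, n_t), dtype=np.float32)

    sds = table.sds_mm
    intensity = np.empty((n_ch, 2, n_t), dtype=np.float32)
    phase = np.empty((n_ch, 2, n_t), dtype=np.float32)
    coupling = np.exp(rng.normal(0.0, profile.coupling_sigma, n_ch))
    f32 = np.float32
    for w in range(2):
        eps_hbo, eps_hb = EXTINCTION_690_830[w]
        task_dmua = f32(eps_hbo) * hbo_ch + f32(eps_hb) * hb_ch  # [ch, t], mm^-1
        dmua = (
            w_cortex.astype(f32)[:, None] * task_dmua
            + w_sup.astype(f32)[:, None] * sys_dmua.astype(f32)[None, :]
            + w_sup.astype(f32)[:, None] * local
        )
        amp0, ph0 = fd_semiinfinite_response(sds, props, MOD_FREQ_HZ, w)
        L = effective_pathlength(sds, props, MOD_FREQ_HZ, w)
        dph = phase_absorption_sensitivity(sds, props, MOD_FREQ_HZ, w)
        clean = (coupling * amp0).astype(f32)[:, None] * np.exp(
            -L.astype(f32)[:, None] * dmua
        )
        sigma_rel = noise.noise_floor * np.sqrt(np.max(amp0) / amp0)
        eta = rng.standard_normal((n_ch, n_t), dtype=f32) * sigma_rel.astype(f32)[:, None]
        intensity[:, w] = clean * np.maximum(f32(1.0) + eta, f32(0.05))
        phase[:, w] = (
            ph0.astype(f32)[:, None]
            + dph.astype(f32)[:, None] * dmua
            + rng.standard_normal((n_ch, n_t), dtype=f32) * f32(noise.phase_noise_rad)
        )

    return RunRecording(
        intensity=intensity,
        phase=phase,
        fs_hz=fs,
        wavelengths_nm=WAVELENGTHS_NM,
        mod_freq_hz=MOD_FREQ_HZ,
        paradigm=paradigm,
        subject_id=profile.subject_id if subject_id is None else subject_id,
        run_id=run_id,
    )


def inject_bad_channels(
    run: RunRecording, fraction: float, seed: int = 0
) -> tuple[RunRecording, np.ndarray]:
    """Contaminate a random ``fraction`` of channels so std/mean >= 7.5.

    Returns the modified recording and the injected channel indices.
    Contamination replaces the channel with heavy-tailed (log-normal)
    flicker around its mean, the signature of a detached or hair-blocked
    optode.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n_bad = int(round(fraction * run.n_channels))
    rng = np.random.default_rng(seed)
    idx = rng.choice(run.n_channels, size=n_bad, replace=False)
    if n_bad == 0:
        return run, idx
    intensity = run.intensity.copy()
    phase = run.phase.copy()
    for ch in idx:
        base = intensity[ch].mean(axis=-1, keepdims=True)
        intensity[ch] = base * np.exp(rng.normal(0.0, 2.5, (2, run.n_times)))
        phase[ch] = rng.uniform(-np.pi, np.pi, (2, run.n_times))
    out = RunRecording(
        intensity=intensity,
        phase=phase,
        fs_hz=run.fs_hz,
        wavelengths_nm=run.wavelengths_nm,
        mod_freq_hz=run.mod_freq_hz,
        paradigm=run.paradigm,
        subject_id=run.subject_id,
        run_id=run.run_id,
    )
    return out, np.sort(idx)


def study_cohort_plan(
    seed: int = 0,
    n_subjects: int = 7,
    n_runs: int = 5,
    n_contaminated: int = 2,
    locus_jitter_mm: float = 10.0,
):
    """Subject profiles and the (subject, run) pairs chosen for contamination."""
    profiles = draw_subject_profiles(
        n_subjects, seed=seed, locus_jitter_mm=locus_jitter_mm
    )
    pick_rng = np.random.default_rng(seed + 991)
    all_pairs = [(s, r) for s in range(n_subjects) for r in range(n_runs)]
    bad = {
        all_pairs[i]
        for i in pick_rng.choice(len(all_pairs), size=n_contaminated, replace=False)
    }
    return profiles, sorted(bad)


def iter_study_runs(
    layout: OptodeLayout,
    table: ChannelTable,
    seed: int = 0,
    n_subjects: int = 7,
    n_runs: int = 5,
    n_contaminated: int = 2,
    locus_jitter_mm: float = 10.0,
    noise: NoiseConfig | None = None,
):
    """Yield the study's runs one at a time (a raw run is ~80 MB; a full
    cohort held in memory is not)."""
    profiles, bad = study_cohort_plan(
        seed, n_subjects, n_runs, n_contaminated, locus_jitter_mm
    )
    bad = set(bad)
    for prof in profiles:
        for r in range(n_runs):
            sub_seed = (seed * 1_000_003 + prof.subject_id * 101 + r) % (2**31 - 1)
            paradigm = make_paradigm(sub_seed)
            run = simulate_run(
                layout, table, paradigm, prof, noise=noise, seed=sub_seed, run_id=r
            )
            if (prof.subject_id, r) in bad:
                run, _ = inject_bad_channels(run, 0.5, seed=sub_seed + 1)
            yield run


def simulate_study_cohort(
    layout: OptodeLayout,
    table: ChannelTable,
    seed: int = 0,
    n_subjects: int = 7,
    n_runs: int = 5,
    n_contaminated: int = 2,
    locus_jitter_mm: float = 10.0,
    noise: NoiseConfig | None = None,
):
    """The full study acquisition: 7 subjects x 5 runs, two runs unusable.

    ``n_contaminated`` randomly chosen runs receive heavy bad-channel
    contamination so that downstream QC rejects them, leaving 33 accepted
    runs (and 33 x 31 = 1023 labelled examples after windowing).
    Returns (runs, profiles, contaminated (subject, run) pairs).  Prefer
    :func:`iter_study_runs` when the runs are consumed one at a time.
    """
    profiles, bad = study_cohort_plan(
        seed, n_subjects, n_runs, n_contaminated, locus_jitter_mm
    )
    runs = list(
        iter_study_runs(
            layout, table, seed, n_subjects, n_runs, n_contaminated,
            locus_jitter_mm, noise,
        )
    )
    return runs, profiles, bad


def simulate_cohort(
    layout: OptodeLayout,
    table: ChannelTable,
    n_subjects: int = 7,
    n_runs: int = 5,
    seed: int = 0,
    locus_jitter_mm: float = 10.0,
    noise: NoiseConfig | None = None,
    bad_channel_fraction: float = 0.0,
) -> tuple[list[RunRecording], list[SubjectProfile]]:
    """Simulate a full cohort (default 7 subjects x 5 runs)."""
    profiles = draw_subject_profiles(n_subjects, seed=seed, locus_jitter_mm=locus_jitter_mm)
    runs = []
    for prof in profiles:
        for r in range(n_runs):
            sub_seed = (seed * 1_000_003 + prof.subject_id * 101 + r) % (2**31 - 1)
            paradigm = make_paradigm(sub_seed)
            run = simulate_run(
                layout, table, paradigm, prof, noise=noise, seed=sub_seed, run_id=r
            )
            if bad_channel_fraction > 0:
                run, _ = inject_bad_channels(run, bad_channel_fraction, seed=sub_seed + 1)
            runs.append(run)
    return runs, profiles
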