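"""Seeded synthetic motor-imagery EEG sessions with ground truth.

Emulates the cue-based two-class protocol: 6 runs x 30 trials (phases 1 and
2 of three runs each), 8 dry electrodes (FP1, FP2, Fz, Cz, C3, C4, O1, O2)
at 512 Sa/s.  Each trial is 7 s (fixation 0-2 s, cue at 2 s, imagery window
2.5-6.0 s) followed by a 1.00-2.00 s randomized RELAX gap.

Signal model, per channel:

* 1/f ("pink") background noise with configurable spectral exponent;
* band-limited mu (8-12 Hz) and beta (16-26 Hz) rhythms, generated as
  bandpass-filtered noise so their power (not phase) carries information,
  largest over the sensorimotor electrodes C3/C4;
* event-related desynchronization (ERD): during the imagery interval the
  rhythm amplitude on the central channel contralateral to the imagined
  hand is suppressed by ``erd_depth`` (C3 for right-hand imagery, C4 for
  left), with 0.25 s raised-cosine ramps at the interval edges.  A
  ``laterality`` parameter optionally applies a fraction of the same
  suppression ipsilaterally (bilateral ERD);
* artifact families typical of dry-electrode recordings: eye blinks
  (frontal), cardiac pulse artifacts (occipital), and broadband vibration
  bursts.

Every run draws from an independent RNG stream derived from
``(seed, run_index)``, so identical seeds give bitwise-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import signal as sig

from .io_epochs import DEFAULT_CHANNELS, EventMarkers, RawRecording

#: per-channel RMS amplitude (microvolt) of each rhythm, sensorimotor-dominant
_DEFAULT_MU_AMPL = {
    "FP1": 0.5, "FP2": 0.5, "Fz": 2.0, "Cz": 3.0,
    "C3": 5.0, "C4": 5.0, "O1": 3.0, "O2": 3.0,
}
_DEFAULT_BETA_AMPL = {ch: a / 2 for ch, a in _DEFAULT_MU_AMPL.items()}


class ConfigError(ValueError):
    """A simulation-config field failed validation (message names the field)."""


@dataclass
class RhythmBand:
    name: str
    low_hz: float
    high_hz: float
    amplitudes: dict  # channel label -> RMS microvolt


def default_rhythm_bands() -> list:
    return [
        RhythmBand("mu", 8.0, 12.0, dict(_DEFAULT_MU_AMPL)),
        RhythmBand("beta", 16.0, 26.0, dict(_DEFAULT_BETA_AMPL)),
    ]


@dataclass
class SimulationConfig:
    """Full description of one simulated session.

    ``erd_depth`` is the fractional rhythm-amplitude suppression in [0, 1]
    on the contralateral central channel during ``mi_interval``;
    ``laterality`` in [0, 1] is the fraction of that suppression applied to
    the ipsilateral central channel as well (0 = purely contralateral).
    ``artifact_rates`` are events/min; the cardiac artifact is periodic at
    ``pulse_rate_bpm`` rather than Poisson.
    """

    n_runs: int = 6
    n_trials_per_run: int = 30
    fs: float = 512.0
    channels: tuple = DEFAULT_CHANNELS
    trial_length: float = 7.0
    cue_onset: float = 2.0
    mi_interval: tuple = (2.5, 6.0)
    rhythm_bands: list = field(default_factory=default_rhythm_bands)
    erd_depth: float = 0.6
    laterality: float = 0.0
    erd_ramp_s: float = 0.25
    noise_exponent: float = 1.0
    noise_rms_uv: float = 8.0
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 10.0, "heartbeat": 72.0, "vibration": 2.0}
    )
    pulse_rate_bpm: float = 72.0
    relax_range_s: tuple = (1.0, 2.0)
    n_phase1_runs: int | None = None  # default: first half of the runs
    lead_in_s: float = 6.0  # artifact-free head of each run (ASR baseline)
    tail_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.n_trials_per_run < 1:
            raise ConfigError("n_trials_per_run must be >= 1")
        if self.n_trials_per_run % 2:
            raise ConfigError("n_trials_per_run must be even for balanced classes")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channels must have unique labels")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigError("erd_depth must lie in [0, 1]")
        if not 0.0 <= self.laterality <= 1.0:
            raise ConfigError("laterality must lie in [0, 1]")
        lo, hi = self.mi_interval
        if not (0.0 <= lo < hi <= self.trial_length):
            raise ConfigError("mi_interval must be inside [0, trial_length]")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ConfigError("artifact_rates must be non-negative")
        for band in self.rhythm_bands:
            if not 0 < band.low_hz < band.high_hz < self.fs / 2:
                raise ConfigError(f"rhythm band {band.name} has invalid edges")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_length * self.fs))


@dataclass
class GroundTruth:
    """Per-trial labels and ERD intervals plus the injected artifact log."""

    labels: list  # one 'left'/'right' per trial, session order
    erd_intervals: list  # (run, trial, start_sample, stop_sample) in run samples
    artifacts: list  # dicts: run, kind, time_s, sample
    config: SimulationConfig | None = None

    def to_json(self) -> str:
        d = {
            "labels": self.labels,
            "erd_intervals": self.erd_intervals,
            "artifacts": self.artifacts,
        }
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["channels"] = list(cfg["channels"])
            d["config"] = cfg
        return json.dumps(d, indent=1)


def _contralateral(trial_class: str) -> str:
    # right-hand imagery desynchronizes the left hemisphere (C3) and vice versa
    if trial_class == "right":
        return "C3"
    if trial_class == "left":
        return "C4"
    raise ValueError(f"unknown class label {trial_class!r}")


def apply_erd_envelope(trial_class: str, config: SimulationConfig) -> np.ndarray:
    """Amplitude envelope over one trial, shape (n_channels, n_bands, n_samples).

    Base amplitude everywhere; during ``mi_interval`` the contralateral
    central channel is scaled by (1 - erd_depth) with raised-cosine ramps of
    ``erd_ramp_s`` at the interval edges (and the ipsilateral channel by
    (1 - laterality * erd_depth)).
    """
    contra = _contralateral(trial_class)
    ipsi = "C4" if contra == "C3" else "C3"
    n = config.trial_samples
    t = np.arange(n) / config.fs
    lo, hi = config.mi_interval
    ramp = config.erd_ramp_s

    # suppression profile: 0 outside interval, 1 in the flat middle
    prof = np.zeros(n)
    core = (t >= lo + ramp) & (t <= hi - ramp)
    prof[core] = 1.0
    up = (t >= lo) & (t < lo + ramp)
    prof[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - lo) / ramp))
    down = (t > hi - ramp) & (t <= hi)
    prof[down] = 0.5 * (1 - np.cos(np.pi * (hi - t[down]) / ramp))

    n_bands = len(config.rhythm_bands)
    env = np.empty((len(config.channels), n_bands, n))
    for ci, ch in enumerate(config.channels):
        if ch == contra:
            depth = config.erd_depth
        elif ch == ipsi:
            depth = config.laterality * config.erd_depth
        else:
            depth = 0.0
        env[ci] = 1.0 - depth * prof  # same modulation for every rhythm band
    return env


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    n_f = n // 2 + 1
    spec = rng.standard_normal(n_f) + 1j * rng.standard_normal(n_f)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros(n_f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


def _band_noise(n, low, high, fs, rng) -> np.ndarray:
    sos = sig.butter(4, [low, high], btype="bandpass", output="sos", fs=fs)
    x = sig.sosfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


# -- artifact templates ------------------------------------------------------

_BLINK_WEIGHTS = {"FP1": 1.0, "FP2": 0.95, "Fz": 0.4, "Cz": 0.15,
                  "C3": 0.05, "C4": 0.05, "O1": 0.0, "O2": 0.0}
_CARDIAC_WEIGHTS = {"O1": 1.0, "O2": 0.9}  # all other channels zero
_BLINK_AMPL_UV = 120.0
_CARDIAC_AMPL_UV = 25.0
_VIBRATION_AMPL_UV = 60.0


def _blink_template(fs: float) -> np.ndarray:
    n = int(round(0.35 * fs))
    return np.hanning(n) ** 2


def _cardiac_template(fs: float) -> np.ndarray:
    # sharp biphasic deflection, ~80 ms
    n = int(round(0.08 * fs))
    t = np.linspace(0, 1, n)
    return np.sin(2 * np.pi * t) * np.hanning(n)


def inject_artifacts(
    recording: RawRecording,
    config: SimulationConfig,
    rng: np.random.Generator,
    protect_lead_in: bool = True,
):
    """Superimpose blink / cardiac / vibration artifacts; return (recording, log).

    Blinks and vibration bursts are Poisson processes at the configured
    events/min; the cardiac artifact is periodic at ``pulse_rate_bpm`` with a
    random initial phase.  ``protect_lead_in`` keeps the first ``lead_in_s``
    seconds clean so an artifact-free ASR baseline always exists.
    """
    x = recording.samples.copy()
    fs = recording.fs
    n = x.shape[1]
    duration_min = n / fs / 60.0
    t0 = config.lead_in_s if protect_lead_in else 0.0
    log = []
    chan_index = {ch: i for i, ch in enumerate(recording.channel_labels)}

    def add_events(kind, times_s, template, weights, ampl, jitter_gain):
        for t_ev in times_s:
            s = int(round(t_ev * fs))
            seg = slice(s, min(s + len(template), n))
            m = seg.stop - seg.start
            if m <= 0:
                continue
            gain = ampl * (1.0 + 0.2 * jitter_gain())
            for ch, w in weights.items():
                if ch in chan_index and w:
                    x[chan_index[ch], seg] += gain * w * template[:m]
            log.append({"run": recording.run_id, "kind": kind,
                        "time_s": float(t_ev), "sample": s})

    rate = config.artifact_rates.get("blink", 0.0)
    if rate > 0:
        n_ev = rng.poisson(rate * duration_min)
        times = np.sort(rng.uniform(t0, n / fs - 0.5, n_ev))
        add_events("blink", times, _blink_template(fs), _BLINK_WEIGHTS,
                   _BLINK_AMPL_UV, lambda: rng.standard_normal())

    rate = config.artifact_rates.get("heartbeat", 0.0)
    if rate > 0:
        period = 60.0 / config.pulse_rate_bpm
        phase = rng.uniform(0, period)
        times = np.arange(t0 + phase, n / fs - 0.2, period)
        add_events("heartbeat", times, _cardiac_template(fs), _CARDIAC_WEIGHTS,
                   _CARDIAC_AMPL_UV, lambda: 0.1 * rng.standard_normal())

    rate = config.artifact_rates.get("vibration", 0.0)
    if rate > 0:
        n_ev = rng.poisson(rate * duration_min)
        times = np.sort(rng.uniform(t0, n / fs - 0.5, n_ev))
        burst_n = int(round(0.3 * fs))
        for t_ev in times:
            s = int(round(t_ev * fs))
            seg = slice(s, min(s + burst_n, n))
            m = seg.stop - seg.start
            if m <= 0:
                continue
            win = np.hanning(m)
            for ci in range(x.shape[0]):
                x[ci, seg] += (_VIBRATION_AMPL_UV * rng.uniform(0.5, 1.0)
                               * win * rng.standard_normal(m))
            log.append({"run": recording.run_id, "kind": "vibration",
                        "time_s": float(t_ev), "sample": s})

    out = RawRecording(x, fs, recording.channel_labels,
                       recording.run_id, recording.phase)
    return out, log


# -- session generation ------------------------------------------------------


def _generate_run(config: SimulationConfig, run_id: int, phase: int,
                  labels: list, rng: np.random.Generator):
    fs = config.fs
    nt = config.trial_samples
    gaps = rng.uniform(*config.relax_range_s, size=len(labels))
    trial_starts = []
    pos = int(round(config.lead_in_s * fs))
    for g in gaps:
        trial_starts.append(pos)
        pos += nt + int(round(g * fs))
    n = pos + int(round(config.tail_s * fs))

    n_ch = len(config.channels)
    x = np.empty((n_ch, n))
    for ci in range(n_ch):
        x[ci] = config.noise_rms_uv * _pink_noise(n, config.noise_exponent, rng)

    # rhythm carriers, continuous over the run, amplitude-modulated per trial
    erd_intervals = []
    for bi, band in enumerate(config.rhythm_bands):
        carriers = np.stack(
            [_band_noise(n, band.low_hz, band.high_hz, fs, rng) for _ in range(n_ch)]
        )
        modulation = np.ones((n_ch, n))
        for ti, (start, cls) in enumerate(zip(trial_starts, labels)):
            env = apply_erd_envelope(cls, config)  # (ch, band, nt)
            modulation[:, start : start + nt] = env[:, bi, :]
            if bi == 0:
                lo, hi = config.mi_interval
                erd_intervals.append(
                    (run_id, ti, start + int(round(lo * fs)),
                     start + int(round(hi * fs)))
                )
        ampl = np.array([band.amplitudes.get(ch, 0.0) for ch in config.channels])
        x += ampl[:, None] * carriers * modulation

    rec = RawRecording(x, fs, config.channels, run_id, phase)
    rec, artifact_log = inject_artifacts(rec, config, rng)
    cue_samples = [s + int(round(config.cue_onset * fs)) for s in trial_starts]
    events = [(s, cls, run_id, phase) for s, cls in zip(cue_samples, labels)]
    return rec, events, erd_intervals, artifact_log


def generate_session(config: SimulationConfig):
    """Simulate a full session.

    Returns ``(recordings, markers, truth)`` where ``recordings`` is one
    continuous :class:`RawRecording` per run (runs 1..n_runs; the first half
    is phase 1, the second phase 2), ``markers`` holds one cue marker per
    trial with balanced randomized classes per run, and ``truth`` logs
    labels, ERD intervals and artifact events.
    """
    recordings, events, erd_all, art_all, labels_all = [], [], [], [], []
    half = config.n_phase1_runs
    if half is None:
        half = config.n_runs // 2 if config.n_runs > 1 else 1
    for run_id in range(1, config.n_runs + 1):
        rng = np.random.default_rng([config.seed, run_id])
        nt = config.n_trials_per_run
        labels = ["left"] * (nt // 2) + ["right"] * (nt // 2)
        labels = [labels[i] for i in rng.permutation(nt)]
        phase = 1 if run_id <= half else 2
        rec, ev, erd, art = _generate_run(config, run_id, phase, labels, rng)
        recordings.append(rec)
        events.extend(ev)
        erd_all.extend(erd)
        art_all.extend(art)
        labels_all.extend(labels)
    markers = EventMarkers(events)
    truth = GroundTruth(labels_all, erd_all, art_all, config)
    return recordings, markers, truth
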