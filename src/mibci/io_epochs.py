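"""Recording / marker / epoch containers and their on-disk formats.

The experimental protocol delivers a continuous 8-channel EEG stream per run
together with a table of cue markers (one per trial, left or right hand).
This module cuts the stream into fixed-length trials on the grid used by the
sliding-window analysis: trial time 0 is the fixation onset, the cue appears
at 2.00 s, and a full trial spans 0.00-7.00 s.

Formats: EDF (16-bit, physical units microvolt) or a documented CSV dialect
for signals; TSV for markers; a JSON-header + raw float32 container for
epoch sets.  EDF is read through :func:`mne.io.read_raw_edf`; writing uses a
minimal EDF encoder (plain EDF, one 1-second data record per second, final
record zero-padded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = ("FP1", "FP2", "Fz", "Cz", "C3", "C4", "O1", "O2")
#: trial time of the cue relative to fixation onset, seconds
CUE_TIME_S = 2.0
#: full trial span relative to fixation onset, seconds
TRIAL_SPAN_S = (0.0, 7.0)


class DialectError(ValueError):
    """Unknown or unsupported recording file dialect."""


class EpochingError(ValueError):
    """A marker's trial window does not fit inside the recording."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG segment.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Sa/s.
    channel_labels : tuple of str
        Electrode labels in row order (10-20 positions).
    run_id : int
        1-based run index within the session.
    phase : int
        Experimental phase, 1 (pure motor imagery) or 2 (feedback runs for
        the neurofeedback arm).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple = DEFAULT_CHANNELS
    run_id: int = 1
    phase: int = 1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if len(self.channel_labels) == 0:
            raise ValueError("channel list must not be empty")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"label count {len(self.channel_labels)} != "
                f"row count {self.samples.shape[0]}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventMarkers:
    """Cue markers for one or more runs.

    Each row is ``(sample, cls, run, phase)`` where ``sample`` is the
    0-based index of the cue onset in the run's recording and ``cls`` is
    ``"left"`` or ``"right"``.
    """

    events: list = field(default_factory=list)

    def __post_init__(self):
        by_run: dict = {}
        for sample, cls, run, phase in self.events:
            if cls not in ("left", "right"):
                raise ValueError(f"unknown class label {cls!r}")
            by_run.setdefault(run, []).append(int(sample))
        for run, idx in by_run.items():
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"marker sample indices not strictly increasing in run {run}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def for_run(self, run_id: int) -> "EventMarkers":
        return EventMarkers([e for e in self.events if e[2] == run_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["sample", "class", "run", "phase"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventMarkers":
        rows = [
            (int(r["sample"]), str(r["class"]), int(r["run"]), int(r["phase"]))
            for _, r in df.iterrows()
        ]
        return cls(rows)


@dataclass
class EpochSet:
    """Per-trial EEG segments with labels and provenance.

    ``data`` has shape (n_trials, n_channels, n_samples) covering trial time
    ``t_start``..``t_end`` seconds (fixation onset = 0).  ``provenance`` is a
    DataFrame with one row per trial (run, phase, and optionally subject /
    session identifiers).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: tuple = DEFAULT_CHANNELS
    t_start: float = TRIAL_SPAN_S[0]
    provenance: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {"run": [0] * len(self.labels), "phase": [1] * len(self.labels)}
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_to_sample(self, t: float) -> int:
        """Trial time (s, fixation origin) to 0-based sample offset."""
        return int(round((t - self.t_start) * self.fs))

    def save(self, path) -> None:
        """Single-file container: JSON header line + raw float32 payload."""
        header = {
            "fs": self.fs,
            "channels": list(self.channel_labels),
            "t_start": self.t_start,
            "shape": list(self.data.shape),
            "labels": [str(x) for x in self.labels],
            "provenance": self.provenance.to_dict(orient="list"),
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(np.ascontiguousarray(self.data, dtype="<f4").tobytes())

    @classmethod
    def load(cls, path) -> "EpochSet":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            payload = np.frombuffer(fh.read(), dtype="<f4")
        data = payload.reshape(header["shape"]).astype(float)
        return cls(
            data=data,
            labels=np.array(header["labels"], dtype=object),
            fs=header["fs"],
            channel_labels=tuple(header["channels"]),
            t_start=header["t_start"],
            provenance=pd.DataFrame(header["provenance"]),
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_PHYS_MIN = -3200.0  # microvolt; generous range for blinks / bursts
_EDF_PHYS_MAX = 3200.0
_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767

#: worst-case EDF round-trip error: one digital step
EDF_QUANTIZATION_UV = (_EDF_PHYS_MAX - _EDF_PHYS_MIN) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path) -> None:
    """Write plain EDF, 16-bit, one 1 s data record per second.

    The final partial second is zero-padded (EDF data records have fixed
    duration); the true sample count is recoverable from the marker file and
    is irrelevant to epoching since markers always point inside real data.
    """
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    nchan = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((nchan, n_records * fs))
    padded[:, : rec.n_samples] = rec.samples
    clipped = np.clip(padded, _EDF_PHYS_MIN, _EDF_PHYS_MAX)
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (_EDF_PHYS_MAX - _EDF_PHYS_MIN)
    digital = np.round((clipped - _EDF_PHYS_MIN) * scale + _EDF_DIG_MIN).astype("<i2")

    hdr = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field(f"run {rec.run_id} phase {rec.phase}", 80),  # patient id
            _edf_field("mibci synthetic session", 80),  # recording id
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + nchan), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),  # record duration s
            _edf_field(nchan, 4),
        ]
    )
    per = lambda vals, w: b"".join(_edf_field(v, w) for v in vals)
    labels = [lbl for lbl in rec.channel_labels]
    hdr += per(labels, 16)
    hdr += per(["dry EEG"] * nchan, 80)
    hdr += per(["uV"] * nchan, 8)
    hdr += per([_EDF_PHYS_MIN] * nchan, 8)
    hdr += per([_EDF_PHYS_MAX] * nchan, 8)
    hdr += per([_EDF_DIG_MIN] * nchan, 8)
    hdr += per([_EDF_DIG_MAX] * nchan, 8)
    hdr += per([""] * nchan, 80)  # prefiltering
    hdr += per([fs] * nchan, 8)
    hdr += per([""] * nchan, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # channel-sequential within record


def read_edf(path, run_id: int = 1, phase: int = 1) -> RawRecording:
    """Read an EDF file via MNE and return microvolt samples."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return RawRecording(
        samples=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        run_id=run_id,
        phase=phase,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_csv(rec: RawRecording, path) -> None:
    """CSV dialect: '#'-prefixed metadata lines, then one column per channel."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n# run_id={rec.run_id}\n# phase={rec.phase}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.6f", delimiter=",")


def read_csv(path) -> RawRecording:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return RawRecording(
        samples=df.to_numpy().T,
        fs=float(meta.get("fs", 512)),
        channel_labels=tuple(df.columns),
        run_id=int(meta.get("run_id", 1)),
        phase=int(meta.get("phase", 1)),
    )


def write_recording(rec: RawRecording, path, dialect: str | None = None) -> None:
    dialect = dialect or _infer_dialect(path)
    if dialect == "edf":
        write_edf(rec, path)
    elif dialect == "csv":
        write_csv(rec, path)
    else:
        raise DialectError(f"unknown dialect {dialect!r} (expected 'edf' or 'csv')")


def read_recording(path, dialect: str | None = None, **kw) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "edf":
        return read_edf(path, **kw)
    if dialect == "csv":
        return read_csv(path)
    raise DialectError(f"unknown dialect {dialect!r} (expected 'edf' or 'csv')")


def _infer_dialect(path) -> str:
    return "edf" if str(path).lower().endswith(".edf") else "csv"


def write_markers(markers: EventMarkers, path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers(path) -> EventMarkers:
    return EventMarkers.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


def epoch_trials(
    recording: RawRecording,
    markers: EventMarkers,
    t_start: float = TRIAL_SPAN_S[0],
    t_end: float = TRIAL_SPAN_S[1],
    cue_time: float = CUE_TIME_S,
) -> EpochSet:
    """Cut one epoch per marker on the fixation-onset time axis.

    Markers point at cue onsets; the cue occurs at ``cue_time`` seconds of
    trial time, so the epoch for a marker at sample ``s`` covers samples
    ``[s + (t_start - cue_time)*fs, s + (t_end - cue_time)*fs)`` (half-open,
    0-based).  A trial that does not fit inside the recording raises
    :class:`EpochingError` naming the offending trials.
    """
    fs = recording.fs
    n_len = int(round((t_end - t_start) * fs))
    rows, labels, prov = [], [], []
    bad = []
    events = [e for e in markers.events if e[2] == recording.run_id] or markers.events
    for i, (sample, cls, run, phase) in enumerate(events):
        start = int(sample) + int(round((t_start - cue_time) * fs))
        stop = start + n_len
        if start < 0 or stop > recording.n_samples:
            bad.append(i)
            continue
        rows.append(recording.samples[:, start:stop])
        labels.append(cls)
        prov.append({"run": run, "phase": phase, "marker_sample": int(sample)})
    if bad:
        raise EpochingError(
            f"trial(s) {bad} do not fit inside the recording "
            f"({recording.n_samples} samples at {fs} Sa/s)"
        )
    data = (
        np.stack(rows)
        if rows
        else np.empty((0, recording.n_channels, n_len))
    )
    return EpochSet(
        data=data,
        labels=np.array(labels, dtype=object),
        fs=fs,
        channel_labels=recording.channel_labels,
        t_start=t_start,
        provenance=pd.DataFrame(prov, columns=["run", "phase", "marker_sample"]),
    )


def pool_phase(epoch_sets: list) -> EpochSet:
    """Concatenate runs of one phase into a single trial pool (90 trials for
    three 30-trial runs), preserving run order."""
    if not epoch_sets:
        raise ValueError("no epoch sets to pool")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channel_labels != first.channel_labels:
            raise ValueError("montage mismatch across epoch sets")
        if es.fs != first.fs:
            raise ValueError("sampling-rate mismatch across epoch sets")
        if set(es.provenance["phase"]) != set(first.provenance["phase"]):
            raise ValueError("mixed phases cannot be pooled")
    ordered = sorted(epoch_sets, key=lambda es: tuple(es.provenance["run"][:1]))
    return EpochSet(
        data=np.concatenate([es.data for es in ordered]),
        labels=np.concatenate([es.labels for es in ordered]),
        fs=first.fs,
        channel_labels=first.channel_labels,
        t_start=first.t_start,
        provenance=pd.concat(
            [es.provenance for es in ordered], ignore_index=True
        ),
    )
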