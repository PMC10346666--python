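"""Artifact subspace reconstruction (ASR) for offline pre-processing.

ASR calibrates on an artifact-free baseline segment: the baseline covariance
is eigendecomposed into a fixed component basis, and the distribution of
windowed component RMS values yields a per-component rejection threshold
(mean + cutoff * std).  At apply time the signal is processed in sliding,
raised-cosine-blended windows; any component whose windowed RMS exceeds its
threshold is replaced by its conditional expectation under the baseline
model.  Because the basis diagonalizes the baseline covariance, components
are uncorrelated under that model and the conditional expectation given the
retained components is zero — flagged components are therefore removed and
the channel signal is rebuilt from the retained subspace.

This is an offline step only: the simulated online loop never calls it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io_epochs import RawRecording

DEFAULT_CUTOFF = 20.0
DEFAULT_WINDOW_S = 0.5
DEFAULT_OVERLAP = 0.5


class CalibrationError(ValueError):
    """Baseline unusable for ASR calibration (too short / rank-deficient)."""


@dataclass
class AsrCalibration:
    """Baseline statistics: component basis and per-component RMS thresholds."""

    covariance: np.ndarray  # channels x channels, baseline
    basis: np.ndarray  # columns = components (eigenvectors of covariance)
    thresholds: np.ndarray  # per-component RMS rejection threshold
    window_s: float
    cutoff: float
    channel_labels: tuple

    def to_json(self) -> str:
        return json.dumps(
            {
                "covariance": self.covariance.tolist(),
                "basis": self.basis.tolist(),
                "thresholds": self.thresholds.tolist(),
                "window_s": self.window_s,
                "cutoff": self.cutoff,
                "channel_labels": list(self.channel_labels),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AsrCalibration":
        d = json.loads(text)
        return cls(
            covariance=np.array(d["covariance"]),
            basis=np.array(d["basis"]),
            thresholds=np.array(d["thresholds"]),
            window_s=d["window_s"],
            cutoff=d["cutoff"],
            channel_labels=tuple(d["channel_labels"]),
        )


def _windowed_rms(y: np.ndarray, win: int, step: int) -> np.ndarray:
    """RMS of each component over sliding windows; shape (n_windows, n_comp)."""
    n = y.shape[1]
    starts = range(0, max(n - win + 1, 1), step)
    return np.stack([np.sqrt(np.mean(y[:, s : s + win] ** 2, axis=1)) for s in starts])


def calibrate_asr(
    baseline: RawRecording,
    window_s: float = DEFAULT_WINDOW_S,
    cutoff: float = DEFAULT_CUTOFF,
) -> AsrCalibration:
    """Fit the component basis and RMS thresholds on an artifact-free segment.

    The baseline must be at least ``10 * window_s`` long and full rank; a
    zero-variance channel raises :class:`CalibrationError`.
    """
    x = baseline.samples - baseline.samples.mean(axis=1, keepdims=True)
    fs = baseline.fs
    if x.shape[1] < 10 * window_s * fs:
        raise CalibrationError(
            f"baseline of {x.shape[1] / fs:.2f} s is shorter than "
            f"10 x window_s = {10 * window_s:.2f} s"
        )
    cov = x @ x.T / x.shape[1]
    evals, basis = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] < 1e-12 * evals[-1]:
        raise CalibrationError("rank-deficient baseline covariance "
                               "(zero-variance or linearly dependent channel)")
    win = int(round(window_s * fs))
    rms = _windowed_rms(basis.T @ x, win, max(win // 2, 1))
    thresholds = rms.mean(axis=0) + cutoff * rms.std(axis=0, ddof=1)
    return AsrCalibration(
        covariance=cov,
        basis=basis,
        thresholds=thresholds,
        window_s=window_s,
        cutoff=cutoff,
        channel_labels=baseline.channel_labels,
    )


def apply_asr(
    recording: RawRecording,
    calib: AsrCalibration,
    window_s: float | None = None,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> RawRecording:
    """Clean a recording with a fitted calibration.

    Sliding windows (raised-cosine blended at ``overlap_fraction``) are
    projected onto the calibration basis; components whose windowed RMS
    exceeds their threshold are zeroed in component space and the window is
    rebuilt from the retained components.  Channel count and length are
    unchanged; output is finite everywhere.
    """
    if recording.channel_labels != calib.channel_labels:
        raise ValueError("montage mismatch between recording and calibration")
    window_s = calib.window_s if window_s is None else window_s
    fs = recording.fs
    x = recording.samples
    n = x.shape[1]
    win = int(round(window_s * fs))
    win = min(win, n)
    step = max(int(round(win * (1.0 - overlap_fraction))), 1)
    taper = np.hanning(win) if win > 1 else np.ones(1)
    if taper.sum() == 0:
        taper = np.ones(win)

    out = np.zeros_like(x)
    weight = np.zeros(n)
    starts = list(range(0, max(n - win, 0) + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)
    basis_t = calib.basis.T
    for s in starts:
        seg = x[:, s : s + win]
        y = basis_t @ seg
        rms = np.sqrt(np.mean(y**2, axis=1))
        keep = rms <= calib.thresholds
        y = y * keep[:, None]  # conditional mean of flagged comps is 0
        rebuilt = calib.basis @ y
        out[:, s : s + win] += rebuilt * taper
        weight[s : s + win] += taper
    # edges where the taper never reached full weight
    weight[weight < 1e-12] = 1.0
    out /= weight
    assert np.all(np.isfinite(out))
    return RawRecording(out, fs, recording.channel_labels,
                        recording.run_id, recording.phase)


def select_baseline(
    recording: RawRecording,
    window_s: float = DEFAULT_WINDOW_S,
    quantile: float = 0.1,
    min_duration_s: float | None = None,
) -> RawRecording:
    """Heuristic artifact-free baseline: lowest-RMS windows of a recording.

    Ranks non-overlapping ``window_s`` windows by total RMS and concatenates
    the lowest ``quantile`` (at least ``10 * window_s`` worth) into a
    calibration segment.  Used for data without a designated clean segment.
    """
    fs = recording.fs
    win = int(round(window_s * fs))
    n_win = recording.n_samples // win
    if n_win < 1:
        raise CalibrationError("recording shorter than one baseline window")
    segs = recording.samples[:, : n_win * win].reshape(recording.n_channels, n_win, win)
    rms = np.sqrt((segs**2).mean(axis=(0, 2)))
    need = int(np.ceil((min_duration_s or 10 * window_s) / window_s))
    k = max(int(np.ceil(quantile * n_win)), need)
    k = min(k, n_win)
    order = np.sort(np.argsort(rms, kind="stable")[:k])
    chunk = np.concatenate([segs[:, i, :] for i in order], axis=1)
    return RawRecording(chunk, fs, recording.channel_labels,
                        recording.run_id, recording.phase)
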