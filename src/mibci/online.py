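"""Simulated online loop: sliding-window decoding and positively biased feedback.

During a feedback trial the decoder consumes a causal 2.00 s buffer: the
system starts acquiring at trial time 2.50 s, so the first decision is
available at 4.50 s, and further decisions follow every 0.25 s until 6.00 s
(7 decisions).  Each decision is turned into a feedback command under the
positive-bias rule: feedback moves only when the decoded label matches the
cued task, with magnitude mapped linearly from the informative posterior
range ((p - 0.5)/0.5, clipped to [0, 1]); otherwise no feedback is given.

``simulate_nf_session`` reproduces one subject-session of the neurofeedback
arm end to end: phase-1 runs are generated and used to train a fresh
pipeline (best-window selection included), then phase-2 trials are streamed
through the online decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import fbcsp, synthdata, windows
from .io_epochs import RawRecording, epoch_trials, pool_phase


@dataclass
class OnlineConfig:
    window_width_s: float = 2.0
    acquisition_start_s: float = 2.5
    decision_step_s: float = 0.25
    feedback_interval_s: tuple = (4.5, 6.0)
    #: posterior -> magnitude map: (p - p0) / (1 - p0), clipped to [0, 1]
    magnitude_origin: float = 0.5

    def __post_init__(self):
        first = self.acquisition_start_s + self.window_width_s
        if abs(first - self.feedback_interval_s[0]) > 1e-9:
            raise ValueError(
                "first decision (acquisition start + window width = "
                f"{first} s) must open the feedback interval "
                f"{self.feedback_interval_s}"
            )

    @property
    def decision_times_s(self) -> np.ndarray:
        lo, hi = self.feedback_interval_s
        n = int(round((hi - lo) / self.decision_step_s)) + 1
        return lo + self.decision_step_s * np.arange(n)


@dataclass
class Decision:
    time_s: float
    label: str
    probability: float


@dataclass
class FeedbackCommand:
    """Direction and magnitude driving the virtual ball / vibration motors."""

    time_s: float
    direction: str  # 'left' | 'right' | 'none'
    magnitude: float

    def __post_init__(self):
        if self.direction == "none" and self.magnitude != 0.0:
            raise ValueError("no-feedback command must have zero magnitude")


def _magnitude(p: float, origin: float) -> float:
    return float(np.clip((p - origin) / (1.0 - origin), 0.0, 1.0))


def run_online_trial(stream, pipeline: fbcsp.TrainedPipeline, cue: str,
                     config: OnlineConfig = None, t0: float = 0.0):
    """Decode one streamed trial and emit positively biased feedback.

    ``stream`` is a single-trial RawRecording (or a (channels, samples)
    array) whose sample 0 corresponds to trial time ``t0`` (fixation onset
    origin).  Causality: the decision at time t uses samples from
    [t - width, t) only.  Returns a list of (Decision, FeedbackCommand).
    """
    config = config or OnlineConfig()
    data = stream.samples if isinstance(stream, RawRecording) else np.asarray(stream)
    fs = stream.fs if isinstance(stream, RawRecording) else pipeline.spec.fs
    if cue not in ("left", "right"):
        raise ValueError(f"unknown cue {cue!r}")
    needed = config.feedback_interval_s[1] - t0
    if data.shape[1] < int(round(needed * fs)):
        raise ValueError("stream shorter than the feedback interval")

    width_n = int(round(config.window_width_s * fs))
    out = []
    for t in config.decision_times_s:
        stop = int(round((t - t0) * fs))
        buf = data[:, stop - width_n : stop]  # samples strictly before t
        label, prob = fbcsp.classify_window(pipeline, buf, mode="causal")
        decision = Decision(time_s=float(t), label=label, probability=prob)
        if label == cue:  # positive bias: only matching labels move feedback
            cmd = FeedbackCommand(float(t), cue,
                                  _magnitude(prob, config.magnitude_origin))
        else:
            cmd = FeedbackCommand(float(t), "none", 0.0)
        out.append((decision, cmd))
    return out


def majority_label(decisions: list) -> str:
    """Per-trial online label: majority vote over the in-trial decisions,
    summed posterior as the tie-break."""
    votes = {"left": 0, "right": 0}
    weight = {"left": 0.0, "right": 0.0}
    for d in decisions:
        votes[d.label] += 1
        weight[d.label] += d.probability
    if votes["left"] != votes["right"]:
        return max(votes, key=votes.get)
    return max(weight, key=weight.get)


@dataclass
class SessionResult:
    """One simulated subject-session of the neurofeedback arm."""

    best_window: tuple
    phase1_cv_accuracy: float  # best-window CV accuracy on training data, %
    online_accuracy: float  # majority-vote accuracy over phase-2 trials, %
    offline_phase2_accuracy: float  # best-window CV re-score of phase 2, %
    n_phase2_trials: int
    trial_logs: list = field(default_factory=list)  # per trial: (cue, decisions, commands)
    window_scores: list = field(default_factory=list)


def simulate_nf_session(sim_config: synthdata.SimulationConfig = None,
                        subject_seed: int = 0,
                        online_config: OnlineConfig = None,
                        folds: int = 5, reps: int = 5,
                        m: int = 2, k: int = 4,
                        rescore_phase2: bool = True) -> SessionResult:
    """Simulate a full neurofeedback subject-session.

    A fresh pipeline is trained from scratch on the session's own phase-1
    runs (no state persists across sessions): window-grid CV picks the best
    2 s window, the final pipeline is fit on all phase-1 trials at that
    window, and every phase-2 trial is then streamed through the online
    decoder.  Per-trial online labels are majority votes over the in-trial
    decisions; phase 2 is additionally re-scored offline with the same
    best-window CV procedure when ``rescore_phase2`` is set.
    """
    online_config = online_config or OnlineConfig()
    if sim_config is None:
        sim_config = synthdata.SimulationConfig(seed=subject_seed)
    elif sim_config.seed != subject_seed:
        sim_config = replace(sim_config, seed=subject_seed)
    recordings, markers, truth = synthdata.generate_session(sim_config)

    phase1 = [r for r in recordings if r.phase == 1]
    phase2 = [r for r in recordings if r.phase == 2]
    ep1 = pool_phase([
        epoch_trials(r, markers.for_run(r.run_id), cue_time=sim_config.cue_onset)
        for r in phase1
    ])
    best, best_score, scores = windows.best_window_analysis(
        ep1, folds=folds, reps=reps, seed=subject_seed, m=m, k=k
    )
    pipeline = fbcsp.train_pipeline(ep1, window=best, m=m, k=k)

    trial_logs = []
    hits = 0
    n_trials = 0
    fs = sim_config.fs
    trial_n = sim_config.trial_samples
    for rec in phase2:
        for sample, cue, run, phase in markers.for_run(rec.run_id).events:
            start = sample - int(round(sim_config.cue_onset * fs))
            trial = RawRecording(rec.samples[:, start : start + trial_n], fs,
                                 rec.channel_labels, run, phase)
            steps = run_online_trial(trial, pipeline, cue, online_config)
            decisions = [d for d, _ in steps]
            commands = [c for _, c in steps]
            if majority_label(decisions) == cue:
                hits += 1
            n_trials += 1
            trial_logs.append({"run": run, "cue": cue,
                               "decisions": decisions, "commands": commands})

    offline2 = float("nan")
    if rescore_phase2 and phase2:
        ep2 = pool_phase([
            epoch_trials(r, markers.for_run(r.run_id),
                         cue_time=sim_config.cue_onset)
            for r in phase2
        ])
        _, s2, _ = windows.best_window_analysis(
            ep2, folds=folds, reps=reps, seed=subject_seed + 1, m=m, k=k
        )
        offline2 = s2.mean_acc

    return SessionResult(
        best_window=best,
        phase1_cv_accuracy=best_score.mean_acc,
        online_accuracy=100.0 * hits / max(n_trials, 1),
        offline_phase2_accuracy=offline2,
        n_phase2_trials=n_trials,
        trial_logs=trial_logs,
        window_scores=scores,
    )


def commands_to_rows(trial_logs: list) -> list:
    """Flatten per-trial logs into TSV rows (run, cue, time, direction,
    magnitude, posterior)."""
    rows = []
    for log in trial_logs:
        for d, c in zip(log["decisions"], log["commands"]):
            rows.append({"run": log["run"], "cue": log["cue"],
                         "time_s": d.time_s, "direction": c.direction,
                         "magnitude": c.magnitude, "posterior": d.probability})
    return rows
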