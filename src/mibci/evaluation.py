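"""Evaluation: exact-binomial chance level, type-A uncertainty, ERSP maps,
and the group-comparison statistics battery.

Chance model: a random two-class classifier over n trials is Binomial(n,
0.5).  For n = 90 the central 95% coverage interval runs from 40% and the
one-sided non-randomness threshold is 59%: only accuracies strictly above
it reject randomness at alpha = 5%.  Two tail conventions are involved and
both are documented in the output: the lower bound is the smallest k with
CDF >= alpha/2, while the significance threshold is the largest k whose
upper-tail probability P(X >= k) is still >= alpha.

Type-A uncertainty of a group-mean accuracy is the standard error of the
mean across subjects.

The statistics battery mirrors the published branching: Jarque-Bera
normality check, then either repeated-measures/one-way ANOVA (Bartlett
homoscedasticity check, Welch correction on violation) or Kruskal-Wallis;
Mann-Whitney U for unpaired scale comparisons and Wilcoxon signed-rank for
paired ones; alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy import stats

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Chance level
# ---------------------------------------------------------------------------


@dataclass
class ChanceInterval:
    n: int
    alpha: float
    mean_pct: float
    lower_pct: float
    threshold_pct: float
    lower_k: int
    threshold_k: int
    conventions: str = (
        "lower = 100*q/n with q the smallest k s.t. CDF(k) >= alpha/2; "
        "threshold = 100*k*/n with k* the largest k s.t. P(X >= k) >= alpha "
        "(accuracies strictly above are non-random at one-sided alpha); "
        "percentages rounded to the nearest percent"
    )

    def astuple(self):
        return (self.mean_pct, self.lower_pct, self.threshold_pct)


def chance_interval(n: int, alpha: float = ALPHA) -> ChanceInterval:
    """Chance mean, lower 95% bound and non-randomness threshold, in percent.

    Degenerate boundary: for n = 1 the coverage interval spans {0%, 100%}
    and k* = 1 (P(X >= 1) = 0.5 >= alpha), so the threshold is 100% — no
    single-trial accuracy can strictly exceed it, i.e. one correct trial is
    never significant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ks = np.arange(n + 1)
    cdf = stats.binom.cdf(ks, n, 0.5)
    lower_k = int(ks[cdf >= alpha / 2][0])
    upper_tail = stats.binom.sf(ks - 1, n, 0.5)  # P(X >= k)
    threshold_k = int(ks[upper_tail >= alpha][-1])
    return ChanceInterval(
        n=n,
        alpha=alpha,
        mean_pct=round(50.0),
        lower_pct=round(100.0 * lower_k / n),
        threshold_pct=round(100.0 * threshold_k / n),
        lower_k=lower_k,
        threshold_k=threshold_k,
    )


def type_a_uncertainty(values) -> float:
    """Standard error of the mean across subjects (type-A evaluation)."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("type-A uncertainty needs >= 2 observations")
    return float(values.std(ddof=1) / np.sqrt(values.size))


# ---------------------------------------------------------------------------
# Accuracy bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class AccuracyResult:
    subject: str
    session: int
    phase: int
    n_trials: int
    accuracy: float  # percent
    acc_left: float
    acc_right: float

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        for a in (self.accuracy, self.acc_left, self.acc_right):
            if not 0.0 <= a <= 100.0:
                raise ValueError("accuracies must lie in [0, 100]")


def accuracy_matrix(results: list) -> pd.DataFrame:
    """Subjects x sessions accuracy matrix for one phase (NaN = missing)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.pivot_table(index="subject", columns="session",
                          values="accuracy", aggfunc="first")


# ---------------------------------------------------------------------------
# ERSP
# ---------------------------------------------------------------------------


@dataclass
class ErspMap:
    """Trial-averaged time-frequency power change in dB vs pre-cue baseline.

    Negative values mark event-related desynchronization (power decrease),
    positive values synchronization.
    """

    channel: str
    freqs_hz: np.ndarray
    times_s: np.ndarray
    power_db: np.ndarray  # (freqs, times)
    baseline_s: tuple


def compute_ersp(epochs, channel: str, baseline_s: tuple = (0.0, 2.0),
                 freq_range_hz: tuple = (4.0, 40.0),
                 window_s: float = 0.5, overlap: float = 0.9) -> ErspMap:
    """Short-time Fourier ERSP of one channel.

    Per-trial spectrograms (Hann window of ``window_s``, ``overlap``
    fractional overlap) are averaged across trials, then each frequency row
    is expressed in dB relative to its geometric-mean power over
    ``baseline_s`` — so the baseline-interval mean is 0 dB per frequency by
    construction.
    """
    if channel not in epochs.channel_labels:
        raise ValueError(f"channel {channel!r} not in montage")
    t0, t1 = baseline_s
    t_end = epochs.t_start + epochs.n_samples / epochs.fs
    if not (epochs.t_start <= t0 < t1 <= t_end):
        raise ValueError(f"baseline {baseline_s} outside trial "
                         f"[{epochs.t_start}, {t_end}] s")
    ci = epochs.channel_labels.index(channel)
    nper = int(round(window_s * epochs.fs))
    nover = int(round(overlap * nper))
    f, t, sxx = sig.spectrogram(epochs.data[:, ci, :], fs=epochs.fs,
                                window="hann", nperseg=nper,
                                noverlap=nover, axis=-1)
    mean_power = sxx.mean(axis=0)  # (freqs, times)
    times = epochs.t_start + t
    sel = (f >= freq_range_hz[0]) & (f <= freq_range_hz[1])
    mean_power = mean_power[sel]
    f = f[sel]
    base = (times >= t0) & (times <= t1)
    if not base.any():
        raise ValueError("baseline interval contains no spectrogram frames")
    log_power = np.log10(np.maximum(mean_power, 1e-300))
    ref = log_power[:, base].mean(axis=1, keepdims=True)
    power_db = 10.0 * (log_power - ref)
    return ErspMap(channel=channel, freqs_hz=f, times_s=times,
                   power_db=power_db, baseline_s=baseline_s)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass
class StatReport:
    """Outcome of the branched statistics battery for one comparison."""

    test: str  # name of the test ultimately applied
    statistic: float
    p_value: float
    significant: bool
    normality_p: dict = field(default_factory=dict)  # group -> Jarque-Bera p
    normal: bool = True
    homoscedasticity_p: float | None = None
    homoscedastic: bool | None = None
    alpha: float = ALPHA


def _jarque_bera_all(groups: dict, alpha: float):
    pvals = {}
    for name, x in groups.items():
        pvals[name] = float(stats.jarque_bera(np.asarray(x, float)).pvalue)
    return pvals, all(p > alpha for p in pvals.values())


def group_compare(groups: dict, paired: bool = False,
                  alpha: float = ALPHA) -> StatReport:
    """Compare accuracy (or score) samples across groups with the published
    branching.

    ``groups`` maps group/condition name to a 1-D sample.  Branches:

    * normality rejected (Jarque-Bera) -> Kruskal-Wallis (unpaired) or
      Wilcoxon signed-rank (paired, two conditions);
    * normal + homoscedastic (Bartlett) -> one-way ANOVA (unpaired) or
      repeated-measures ANOVA (paired);
    * normal, heteroscedastic -> Welch ANOVA (Welch t-test for two groups).
    """
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    samples = list(groups.values())
    degenerate = all(np.ptp(x) == 0 for x in samples)
    if degenerate:
        # identical constants within every group: no variance to test
        means = [x.mean() for x in samples]
        same = max(means) - min(means) == 0
        return StatReport(test="degenerate (zero within-group variance)",
                          statistic=float("nan"),
                          p_value=1.0 if same else 0.0,
                          significant=not same, normal=True, alpha=alpha)

    norm_p, normal = _jarque_bera_all(groups, alpha)
    if not normal:
        if paired:
            if len(samples) != 2:
                raise ValueError("paired non-parametric branch supports "
                                 "exactly two conditions")
            res = stats.wilcoxon(samples[0], samples[1])
            name = "Wilcoxon signed-rank"
        else:
            res = stats.kruskal(*samples)
            name = "Kruskal-Wallis"
        return StatReport(test=name, statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          significant=bool(res.pvalue <= alpha),
                          normality_p=norm_p, normal=False, alpha=alpha)

    bart = stats.bartlett(*samples)
    homosc = bool(bart.pvalue > alpha)
    if homosc:
        if paired:
            res_df = _rm_anova(groups)
            name, statv, p = "repeated-measures ANOVA", res_df[0], res_df[1]
        else:
            res = stats.f_oneway(*samples)
            name, statv, p = "one-way ANOVA", res.statistic, res.pvalue
    else:
        if len(samples) == 2 and not paired:
            res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            name, statv, p = "Welch t-test", res.statistic, res.pvalue
        else:
            name, statv, p = _welch_anova(groups)
    return StatReport(test=name, statistic=float(statv), p_value=float(p),
                      significant=bool(p <= alpha), normality_p=norm_p,
                      normal=True, homoscedasticity_p=float(bart.pvalue),
                      homoscedastic=homosc, alpha=alpha)


def _long_frame(groups: dict) -> pd.DataFrame:
    rows = []
    for cond, x in groups.items():
        for subj, v in enumerate(x):
            rows.append({"subject": subj, "condition": cond, "value": v})
    return pd.DataFrame(rows)


def _rm_anova(groups: dict):
    import pingouin as pg

    n = {len(v) for v in groups.values()}
    if len(n) != 1:
        raise ValueError("paired comparison needs equal-length samples")
    aov = pg.rm_anova(data=_long_frame(groups), dv="value", within="condition",
                      subject="subject", detailed=False)
    return float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])


def _welch_anova(groups: dict):
    import pingouin as pg

    aov = pg.welch_anova(data=_long_frame(groups), dv="value",
                         between="condition")
    return "Welch ANOVA", float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])


def mann_whitney(a, b, alpha: float = ALPHA) -> StatReport:
    """Unpaired scale comparison (questionnaire-style scores)."""
    res = stats.mannwhitneyu(np.asarray(a, float), np.asarray(b, float))
    return StatReport(test="Mann-Whitney U", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      significant=bool(res.pvalue <= alpha), alpha=alpha)


def wilcoxon_paired(a, b, alpha: float = ALPHA) -> StatReport:
    res = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return StatReport(test="Wilcoxon signed-rank",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      significant=bool(res.pvalue <= alpha), alpha=alpha)


def report_to_dict(report: StatReport) -> dict:
    return {
        "test": report.test,
        "statistic": report.statistic,
        "p_value": report.p_value,
        "significant": bool(report.significant),
        "normality_p": report.normality_p,
        "normal": bool(report.normal),
        "homoscedasticity_p": report.homoscedasticity_p,
        "homoscedastic": report.homoscedastic,
        "alpha": report.alpha,
    }
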