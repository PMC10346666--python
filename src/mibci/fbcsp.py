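"""Filter-bank CSP feature extraction and naive-Bayes-Parzen classification.

The decoding chain for two-class motor imagery:

1. a bank of 17 overlapped order-10 Chebyshev type II bandpass filters
   covering 4-40 Hz (4 Hz wide bands stepped by 2 Hz);
2. per-band common spatial patterns (CSP): spatial filters obtained by joint
   diagonalization of the two class covariances, sorted by generalized
   eigenvalue, keeping the m most discriminative pairs;
3. log-variance features: per band, the log of each retained projection's
   variance normalized by the sum over retained projections;
4. mutual-information-based best-individual-feature (MIBIF) selection with
   CSP-pair closure;
5. a naive Bayes classifier with per-feature Parzen (Gaussian kernel)
   class-conditional densities, returning the winning class and its
   posterior probability.

Offline filtering is zero-phase (forward-backward); the online path uses
the same coefficients causally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy.special import logsumexp

CLASSES = ("left", "right")
DEFAULT_FS = 512.0
#: transition width from nominal band edge to the Chebyshev-II stopband edge
STOPBAND_MARGIN_HZ = 2.0


class FilterBankError(ValueError):
    pass


@dataclass
class FilterBankSpec:
    """Band grid and Chebyshev type II designs (second-order sections)."""

    bands: list  # (low_hz, high_hz) pairs
    order: int
    attenuation_db: float
    fs: float
    sos: list = field(default_factory=list, repr=False)  # per-band SOS arrays

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def design_filter_bank(
    f_lo: float = 4.0,
    f_hi: float = 40.0,
    n_bands: int = 17,
    band_width: float = 4.0,
    band_step: float = 2.0,
    order: int = 10,
    attenuation_db: float = 40.0,
    fs: float = DEFAULT_FS,
) -> FilterBankSpec:
    """Overlapped uniform band grid: (4,8), (6,10), ..., (36,40) by default.

    The grid must tile [f_lo, f_hi] exactly: f_lo + band_step*(n_bands-1) +
    band_width == f_hi.  Filters are designed as cascaded second-order
    sections with stopband edges ``STOPBAND_MARGIN_HZ`` outside each band.
    """
    if n_bands < 1 or f_lo >= f_hi:
        raise FilterBankError("need n_bands >= 1 and f_lo < f_hi")
    span = f_lo + band_step * (n_bands - 1) + band_width
    if abs(span - f_hi) > 1e-9:
        raise FilterBankError(
            f"band grid infeasible: {n_bands} bands of {band_width} Hz stepped "
            f"by {band_step} Hz span {span} Hz, not {f_hi - f_lo + f_lo} Hz"
        )
    if order % 2:
        raise FilterBankError("bandpass order must be even")
    bands = [
        (f_lo + i * band_step, f_lo + i * band_step + band_width)
        for i in range(n_bands)
    ]
    sos_list = []
    for low, high in bands:
        ws = [max(low - STOPBAND_MARGIN_HZ, 0.25), min(high + STOPBAND_MARGIN_HZ,
                                                       fs / 2 * 0.99)]
        sos = sig.cheby2(order // 2, attenuation_db, ws, btype="bandpass",
                         output="sos", fs=fs)
        _, poles, _ = sig.sos2zpk(sos)
        if np.max(np.abs(poles)) >= 1.0:
            raise FilterBankError(f"unstable design for band {(low, high)}")
        sos_list.append(sos)
    return FilterBankSpec(bands=bands, order=order,
                          attenuation_db=attenuation_db, fs=fs, sos=sos_list)


def apply_filter_bank(window: np.ndarray, spec: FilterBankSpec,
                      mode: str = "zero-phase") -> np.ndarray:
    """Filter ``window`` through every band.

    ``window`` is (channels, samples) or (trials, channels, samples); the
    output inserts a leading band axis: (bands, ...) shaped accordingly
    ((trials, bands, channels, samples) for 3-D input).  ``mode`` is
    ``"zero-phase"`` (offline, forward-backward) or ``"causal"`` (online).
    """
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 3 * spec.order:
        raise ValueError(
            f"window of {window.shape[-1]} samples shorter than filter "
            f"warm-up (3 x order = {3 * spec.order})"
        )
    if mode == "zero-phase":
        out = [sig.sosfiltfilt(s, window, axis=-1) for s in spec.sos]
    elif mode == "causal":
        out = [sig.sosfilt(s, window, axis=-1) for s in spec.sos]
    else:
        raise ValueError(f"unknown filtering mode {mode!r}")
    stacked = np.stack(out)  # (bands, ...)
    if window.ndim == 3:
        stacked = np.moveaxis(stacked, 0, 1)  # (trials, bands, ch, samples)
    return stacked


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------


@dataclass
class CspModel:
    """Per-band CSP filters, rows sorted by descending generalized eigenvalue
    (variance ratio of the first class against the pooled covariance)."""

    filters: np.ndarray  # (bands, ch, ch), rows are spatial filters
    eigenvalues: np.ndarray  # (bands, ch), descending
    m: int

    @property
    def n_bands(self) -> int:
        return self.filters.shape[0]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    def selected_rows(self) -> np.ndarray:
        """Indices of the 2m retained rows: m top then m bottom."""
        c = self.n_channels
        return np.r_[np.arange(self.m), np.arange(c - self.m, c)]

    def selected_filters(self, band: int) -> np.ndarray:
        return self.filters[band][self.selected_rows()]


def _csp_batch(cov_a: np.ndarray, cov_b: np.ndarray):
    """Generalized eigendecomposition of cov_a against cov_a + cov_b for a
    stack of bands, via whitening: composite = U S U^T, P = S^-1/2 U^T,
    then the symmetric problem P cov_a P^T = V L V^T gives W = V^T P with
    W composite W^T = I.  Rows sorted by descending eigenvalue."""
    composite = cov_a + cov_b
    s, u = np.linalg.eigh(composite)
    if np.any(s <= 0):
        raise ValueError("class covariance sum is not positive definite")
    p = (s[..., :, None] ** -0.5) * np.swapaxes(u, -1, -2)
    m_sym = p @ cov_a @ np.swapaxes(p, -1, -2)
    lam, v = np.linalg.eigh(m_sym)  # ascending
    w = np.swapaxes(v, -1, -2)[..., ::-1, :] @ p
    return w, lam[..., ::-1]


def fit_csp_single(cov_a: np.ndarray, cov_b: np.ndarray):
    """CSP for one band: returns (W, eigenvalues) with rows of W sorted by
    descending eigenvalue of cov_a against cov_a + cov_b, and
    W (cov_a + cov_b) W.T = I."""
    w, lam = _csp_batch(np.asarray(cov_a, float)[None],
                        np.asarray(cov_b, float)[None])
    return w[0], lam[0]


def shrink_covariance(cov: np.ndarray, weight: float = 1e-3) -> np.ndarray:
    """Shrinkage toward scaled identity to guarantee positive definiteness."""
    c = np.asarray(cov, float)
    target = np.trace(c) / c.shape[0] * np.eye(c.shape[0])
    return (1 - weight) * c + weight * target


def class_covariances(trial_covs: np.ndarray, labels: np.ndarray,
                      shrinkage: float = 1e-3):
    """Average trace-normalized per-trial covariances per class.

    ``trial_covs`` is (trials, bands, ch, ch).  Returns (cov_left,
    cov_right), each (bands, ch, ch), shrunk toward scaled identity.
    """
    labels = np.asarray(labels)
    tr = np.trace(trial_covs, axis1=-2, axis2=-1)
    normed = trial_covs / np.maximum(tr, 1e-300)[..., None, None]
    n_ch = trial_covs.shape[-1]
    eye = np.eye(n_ch)
    out = []
    for cls in CLASSES:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"no trials of class {cls!r}")
        mean = normed[mask].mean(axis=0)  # (bands, ch, ch)
        tr = np.trace(mean, axis1=-2, axis2=-1) / n_ch
        out.append((1 - shrinkage) * mean + shrinkage * tr[:, None, None] * eye)
    return out[0], out[1]


def fit_csp(cov_left: np.ndarray, cov_right: np.ndarray, m: int = 2) -> CspModel:
    """Fit CSP for every band from the two class covariance stacks."""
    cov_left = np.asarray(cov_left, float)
    cov_right = np.asarray(cov_right, float)
    if cov_left.ndim == 2:
        cov_left = cov_left[None]
    if cov_right.ndim == 2:
        cov_right = cov_right[None]
    n_ch = cov_left.shape[-1]
    if 2 * m > n_ch:
        raise ValueError(f"m={m} pairs need at least {2 * m} channels")
    w, lam = _csp_batch(cov_left, cov_right)
    return CspModel(filters=w, eigenvalues=lam, m=m)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def trial_covariances(banded: np.ndarray, start: int | None = None,
                      stop: int | None = None) -> np.ndarray:
    """Unnormalized covariances X X.T of (a window slice of) banded trials.

    ``banded`` is (trials, bands, ch, samples); returns (trials, bands, ch, ch).
    """
    seg = banded[..., slice(start, stop)]
    return np.einsum("tbcs,tbds->tbcd", seg, seg, optimize=True)


def features_from_covs(trial_covs: np.ndarray, csp: CspModel) -> np.ndarray:
    """Band-major log normalized-variance features, shape (trials, bands*2m).

    The variance of a spatially filtered window w X equals w C w.T, so
    features computed from per-trial covariances are identical to filtering
    the samples explicitly.
    """
    rows = csp.selected_rows()
    v = csp.filters[:, rows, :]  # (bands, 2m, ch)
    var = np.einsum("tbij,bai,baj->tba", trial_covs, v, v, optimize=True)
    var = np.maximum(var, 1e-300)
    var /= var.sum(axis=2, keepdims=True)
    return np.log(var).reshape(trial_covs.shape[0], -1)


def extract_features(window: np.ndarray, csp: CspModel, spec: FilterBankSpec,
                     mode: str = "zero-phase") -> np.ndarray:
    """Feature vector (length bands * 2m) for one raw (channels, samples) window."""
    banded = apply_filter_bank(window[None], spec, mode=mode)
    covs = trial_covariances(banded)
    return features_from_covs(covs, csp)[0]


# ---------------------------------------------------------------------------
# Mutual information + MIBIF selection
# ---------------------------------------------------------------------------


def _parzen_bandwidths(x: np.ndarray) -> np.ndarray:
    """Silverman's rule per column for a univariate Gaussian kernel;
    guarded for (near-)constant samples."""
    x = np.atleast_2d(np.asarray(x, float).T).T
    n = x.shape[0]
    s = x.std(axis=0, ddof=1) if n > 1 else np.zeros(x.shape[1])
    h = s * (4.0 / (3.0 * n)) ** 0.2
    fallback = 1e-6 * np.maximum(np.abs(x).max(axis=0), 1.0)
    return np.where(h > 0, h, fallback)


def _parzen_bandwidth(x: np.ndarray) -> float:
    return float(_parzen_bandwidths(np.asarray(x, float)[:, None])[0])


def _parzen_density(x_eval: np.ndarray, train: np.ndarray, h) -> np.ndarray:
    """Gaussian-kernel density of column features.

    ``x_eval`` (n_eval, d) or (n,), ``train`` (n_train, d) or (n_train,),
    ``h`` per-feature bandwidths; returns densities of the same leading
    shape as ``x_eval``.
    """
    flat = np.asarray(x_eval).ndim == 1
    x_eval = np.atleast_2d(np.asarray(x_eval, float).T).T
    train = np.atleast_2d(np.asarray(train, float).T).T
    h = np.broadcast_to(np.asarray(h, float), (x_eval.shape[1],))
    z = (x_eval[:, None, :] - train[None, :, :]) / h
    k = np.exp(-0.5 * z**2).mean(axis=1) / (np.sqrt(2 * np.pi) * h)
    return k[:, 0] if flat else k


def estimate_mi(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mutual information (bits) of each scalar feature with the class label.

    I(f; y) = H(y) - H(y|f), with p(f|y) from per-class Parzen densities and
    H(y|f) averaged over the sample.  Estimates are clipped at zero.
    """
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    classes = [c for c in CLASSES if (labels == c).any()]
    if len(classes) < 2:
        raise ValueError("mutual information needs samples from both classes")
    masks = {c: labels == c for c in classes}
    if any(m.sum() < 2 for m in masks.values()):
        raise ValueError("need >= 2 samples per class")
    priors = {c: masks[c].mean() for c in classes}
    h_y = -sum(p * np.log2(p) for p in priors.values())

    n, d = features.shape
    cond = np.zeros((n, d, len(classes)))
    for ci, c in enumerate(classes):
        train = features[masks[c]]
        h = _parzen_bandwidths(train)
        dens = _parzen_density(features, train, h)
        cond[:, :, ci] = priors[c] * dens
    tot = cond.sum(axis=2, keepdims=True)
    post = cond / np.maximum(tot, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(post > 0, post * np.log2(post), 0.0).sum(axis=2)
    return np.maximum(h_y - ent.mean(axis=0), 0.0)


@dataclass
class MibifSelection:
    """Top-k features by MI, closed under CSP pairing."""

    ranked: np.ndarray  # all feature indices, best first
    selected: np.ndarray  # sorted selected indices (k..2k after closure)
    k: int
    m: int

    def __len__(self) -> int:
        return len(self.selected)


def csp_pair_partner(index: int, m: int) -> int:
    """Partner of a feature within its band: filter j pairs with 2m-1-j."""
    band, j = divmod(index, 2 * m)
    return band * 2 * m + (2 * m - 1 - j)


def select_features_mibif(mi_scores: np.ndarray, k: int, m: int) -> MibifSelection:
    """Rank by (-MI, index) — a stable, documented tie-break — take the top
    k, and add each selected feature's CSP pair partner."""
    mi_scores = np.asarray(mi_scores, float)
    d = len(mi_scores)
    if not 1 <= k <= d:
        raise ValueError(f"k={k} outside [1, {d}]")
    ranked = np.lexsort((np.arange(d), -mi_scores))
    chosen = set(ranked[:k].tolist())
    for idx in list(chosen):
        chosen.add(csp_pair_partner(idx, m))
    return MibifSelection(ranked=ranked, selected=np.array(sorted(chosen)),
                          k=k, m=m)


# ---------------------------------------------------------------------------
# Naive Bayes Parzen window classifier
# ---------------------------------------------------------------------------


@dataclass
class NbpwModel:
    """Stored training samples per class, per-feature kernel bandwidths
    (Silverman on the pooled training set), and class priors."""

    train: dict  # class -> (n_c, d) array
    bandwidths: np.ndarray  # (d,)
    priors: dict  # class -> float
    classes: tuple = CLASSES


def fit_nbpw(features: np.ndarray, labels: np.ndarray,
             bandwidths: np.ndarray | None = None) -> NbpwModel:
    features = np.atleast_2d(np.asarray(features, float))
    labels = np.asarray(labels)
    present = [c for c in CLASSES if (labels == c).any()]
    if len(present) < 2:
        raise ValueError("training needs both classes")
    counts = {c: int((labels == c).sum()) for c in present}
    if bandwidths is None:
        if min(counts.values()) < 2:
            raise ValueError("need >= 2 training samples per class")
        bandwidths = np.array(
            [_parzen_bandwidth(features[:, j]) for j in range(features.shape[1])]
        )
    else:
        bandwidths = np.broadcast_to(
            np.asarray(bandwidths, float), (features.shape[1],)
        ).copy()
        if np.any(bandwidths <= 0):
            raise ValueError("bandwidths must be positive")
    n = len(labels)
    return NbpwModel(
        train={c: features[labels == c] for c in present},
        bandwidths=bandwidths,
        priors={c: counts[c] / n for c in present},
        classes=tuple(present),
    )


def _class_log_likelihood(model: NbpwModel, x: np.ndarray, cls: str) -> np.ndarray:
    """Naive log-likelihood of (n_eval, d) points under one class: sum over
    features of the log mean Gaussian-kernel density (stable log-sum-exp)."""
    t = model.train[cls]  # (n_c, d)
    h = model.bandwidths
    z = (x[:, None, :] - t[None, :, :]) / h  # (n_eval, n_c, d)
    log_k = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(h)
    m = log_k.max(axis=1, keepdims=True)
    log_mean = m[:, 0, :] + np.log(
        np.maximum(np.exp(log_k - m).mean(axis=1), 1e-300)
    )
    return log_mean.sum(axis=1)


def predict_nbpw_batch(model: NbpwModel, features: np.ndarray) -> np.ndarray:
    """Posterior matrix (n_eval, n_classes) for a batch of feature vectors."""
    x = np.atleast_2d(np.asarray(features, float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature input")
    log_post = np.stack(
        [_class_log_likelihood(model, x, c) + np.log(model.priors[c])
         for c in model.classes], axis=1
    )
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def predict_nbpw(model: NbpwModel, feature_vector: np.ndarray):
    """Return (class, posterior) for one feature vector; posteriors sum to 1."""
    post = predict_nbpw_batch(model, np.asarray(feature_vector, float)[None])[0]
    best = int(np.argmax(post))
    return model.classes[best], float(post[best])


def posterior_nbpw(model: NbpwModel, feature_vector: np.ndarray) -> dict:
    post = predict_nbpw_batch(model, np.asarray(feature_vector, float)[None])[0]
    return dict(zip(model.classes, post))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class TrainedPipeline:
    """Everything needed to classify a raw 2 s window."""

    spec: FilterBankSpec
    csp: CspModel
    selection: MibifSelection
    nbpw: NbpwModel
    window: tuple  # (start_s, width_s) in trial time
    channel_labels: tuple
    m: int
    k: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "bands": self.spec.bands,
                "order": self.spec.order,
                "attenuation_db": self.spec.attenuation_db,
                "fs": self.spec.fs,
                "csp_filters": self.csp.filters.tolist(),
                "csp_eigenvalues": self.csp.eigenvalues.tolist(),
                "selection_ranked": self.selection.ranked.tolist(),
                "selection_selected": self.selection.selected.tolist(),
                "nbpw_train": {c: v.tolist() for c, v in self.nbpw.train.items()},
                "nbpw_bandwidths": self.nbpw.bandwidths.tolist(),
                "nbpw_priors": self.nbpw.priors,
                "window": list(self.window),
                "channel_labels": list(self.channel_labels),
                "m": self.m,
                "k": self.k,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedPipeline":
        d = json.loads(text)
        spec = design_filter_bank(
            f_lo=d["bands"][0][0], f_hi=d["bands"][-1][1],
            n_bands=len(d["bands"]), order=d["order"],
            attenuation_db=d["attenuation_db"], fs=d["fs"],
        )
        csp = CspModel(filters=np.array(d["csp_filters"]),
                       eigenvalues=np.array(d["csp_eigenvalues"]), m=d["m"])
        selection = MibifSelection(
            ranked=np.array(d["selection_ranked"]),
            selected=np.array(d["selection_selected"]), k=d["k"], m=d["m"],
        )
        nbpw = NbpwModel(
            train={c: np.array(v) for c, v in d["nbpw_train"].items()},
            bandwidths=np.array(d["nbpw_bandwidths"]),
            priors=d["nbpw_priors"],
            classes=tuple(d["nbpw_train"].keys()),
        )
        return cls(spec=spec, csp=csp, selection=selection, nbpw=nbpw,
                   window=tuple(d["window"]),
                   channel_labels=tuple(d["channel_labels"]),
                   m=d["m"], k=d["k"])


def train_pipeline(epochs, window=(2.5, 2.0), m: int = 2, k: int = 4,
                   spec: FilterBankSpec | None = None,
                   shrinkage: float = 1e-3) -> TrainedPipeline:
    """Fit the whole chain on labelled epochs at one training window.

    ``window`` is (start_s, width_s) in trial time (fixation onset = 0).
    Epochs are bandpass-filtered zero-phase over their full length and the
    window is sliced out for covariance estimation.
    """
    start_s, width_s = window
    if spec is None:
        spec = design_filter_bank(fs=epochs.fs)
    banded = apply_filter_bank(epochs.data, spec, mode="zero-phase")
    s0 = epochs.time_to_sample(start_s)
    s1 = s0 + int(round(width_s * epochs.fs))
    if s0 < 0 or s1 > epochs.n_samples:
        raise ValueError(f"training window {window} outside the trial")
    covs = trial_covariances(banded, s0, s1)
    cov_l, cov_r = class_covariances(covs, epochs.labels, shrinkage)
    csp = fit_csp(cov_l, cov_r, m=m)
    feats = features_from_covs(covs, csp)
    mi = estimate_mi(feats, epochs.labels)
    selection = select_features_mibif(mi, k=k, m=m)
    nbpw = fit_nbpw(feats[:, selection.selected], epochs.labels)
    return TrainedPipeline(spec=spec, csp=csp, selection=selection, nbpw=nbpw,
                           window=(start_s, width_s),
                           channel_labels=epochs.channel_labels, m=m, k=k)


def classify_window(pipeline: TrainedPipeline, window: np.ndarray,
                    mode: str = "causal"):
    """Classify one raw (channels, samples) window; returns (class, posterior).

    Online operation filters causally; pass ``mode="zero-phase"`` to mirror
    the offline training path exactly.
    """
    window = np.asarray(window, float)
    if window.shape[0] != len(pipeline.channel_labels):
        raise ValueError("channel count does not match the trained pipeline")
    feats = extract_features(window, pipeline.csp, pipeline.spec, mode=mode)
    return predict_nbpw(pipeline.nbpw, feats[pipeline.selection.selected])
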