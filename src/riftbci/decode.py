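"""Online spectral decoding of covert attention.

The decoder sees a 1-s, 7-channel MEG window every 100 ms.  For each channel
it computes the raw DFT power at the two tagging frequencies,

    P(f) = | sum_{j=1}^{n} X(j) * W_n^{(j-1)(f-1)} |^2,   W_n = exp(-2*pi*i/n),

i.e. the squared magnitude of a single rectangular-window DFT bin with no
taper and no normalization.  The index ``f`` above is the 1-based DFT bin;
a physical frequency maps to it as ``bin = freq * n / srate`` (so on a 1-s
window at 1000 Hz every integer frequency is exactly one bin).  The 7 sensors
x 2 frequencies = 14 powers form the feature vector of a linear SVM trained
with stratified 4-fold cross-validation; the sign of the decision score gives
the attended side, and the score itself is exposed for display.

The online path deliberately uses no taper; the Hanning taper belongs to the
offline time-frequency analysis only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

TAG_FREQS_HZ = (56.0, 60.0)
N_SENSORS = 7
N_FEATURES = N_SENSORS * len(TAG_FREQS_HZ)

#: side encoded by the sign of the decision score
SIDE_OF_SIGN = {1: "left", -1: "right"}
SIGN_OF_SIDE = {"left": 1, "right": -1}

DECODER_FORMAT_VERSION = 1


def psd_at(signal: np.ndarray, freq: float, srate: float) -> float:
    """Raw DFT power of a single-channel window at one bin-aligned frequency.

    Equals the squared magnitude of the DFT bin ``freq * n / srate`` computed
    with a rectangular window.  For a unit-amplitude sinusoid exactly on a bin
    this is (n/2)**2.

    Raises
    ------
    ValueError
        If ``freq`` does not align to a DFT bin of the window, or the window
        is shorter than 2 samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = x.size
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    k_float = freq * n / srate
    k = int(round(k_float))
    if abs(k_float - k) > 1e-9:
        raise ValueError(
            f"frequency {freq} Hz does not align to a DFT bin "
            f"(freq*n/srate = {k_float} is not an integer)"
        )
    coeff = np.exp(-2j * np.pi * k * np.arange(n) / n) @ x
    return float(np.abs(coeff) ** 2)


def _psd_bins(window: np.ndarray, freqs, srate: float) -> np.ndarray:
    """Vectorized Eq.-1 power for each row of ``window`` at each frequency."""
    w = np.atleast_2d(np.asarray(window, dtype=float))
    n = w.shape[1]
    spec = np.fft.rfft(w, axis=1)
    out = np.empty((w.shape[0], len(freqs)))
    for i, f in enumerate(freqs):
        k_float = f * n / srate
        k = int(round(k_float))
        if abs(k_float - k) > 1e-9:
            raise ValueError(f"frequency {f} Hz is not bin-aligned for n={n}")
        out[:, i] = np.abs(spec[:, k]) ** 2
    return out


def extract_features(
    window: np.ndarray,
    srate: float,
    freqs=TAG_FREQS_HZ,
    channel_names=None,
    layout_order=None,
) -> np.ndarray:
    """14-dimensional feature vector from a 7-channel 1-s window.

    Feature ordering is fixed: for each sensor in layout order, power at 56 Hz
    then power at 60 Hz.  If ``channel_names`` and ``layout_order`` are given,
    the input rows are reordered by name first, so channel order in memory is
    irrelevant as long as the names match.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] != N_SENSORS:
        raise ValueError(f"expected {N_SENSORS} channels, got shape {w.shape}")
    if channel_names is not None and layout_order is not None:
        if set(channel_names) != set(layout_order):
            raise ValueError("channel names do not match the layout")
        idx = [list(channel_names).index(name) for name in layout_order]
        w = w[idx]
    return _psd_bins(w, freqs, srate).ravel()


@dataclass
class TrainedDecoder:
    """Linear two-class model over the 14 spectral-power features.

    ``weights`` and ``bias`` define the hyperplane in *standardized* feature
    space; ``mean`` and ``scale`` are the per-feature training statistics.
    Positive decision scores map to "left", negative to "right"; a score of
    exactly zero keeps the previously decoded side (hysteresis), tracked in
    ``last_side``.
    """

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    scale: np.ndarray
    cv_accuracy: float
    channel_order: list
    freqs: tuple = TAG_FREQS_HZ
    folds: int = 4
    last_side: str = field(default="left")

    def to_json(self, path) -> None:
        payload = {
            "format_version": DECODER_FORMAT_VERSION,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "cv_accuracy": self.cv_accuracy,
            "channel_order": list(self.channel_order),
            "freqs": list(self.freqs),
            "folds": self.folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path, expected_channel_order=None) -> "TrainedDecoder":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != DECODER_FORMAT_VERSION:
            raise ValueError("unsupported decoder file version")
        if expected_channel_order is not None and list(expected_channel_order) != list(
            payload["channel_order"]
        ):
            raise ValueError("decoder channel order does not match the recording")
        return cls(
            weights=np.asarray(payload["weights"]),
            bias=float(payload["bias"]),
            mean=np.asarray(payload["mean"]),
            scale=np.asarray(payload["scale"]),
            cv_accuracy=float(payload["cv_accuracy"]),
            channel_order=list(payload["channel_order"]),
            freqs=tuple(payload["freqs"]),
            folds=int(payload["folds"]),
        )


def _standardize_stats(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def train_decoder(
    features: np.ndarray,
    labels,
    folds: int = 4,
    seed: int = 0,
    C: float = 1.0,
    channel_order=None,
) -> TrainedDecoder:
    """Train the linear SVM with stratified k-fold cross-validation.

    ``features`` is (n_trials, 14); ``labels`` is a sequence of "left"/"right".
    Features are z-scored with training statistics before the SVM (raw DFT
    powers span orders of magnitude).  ``cv_accuracy`` is the mean held-out
    accuracy over the stratified folds; the returned model is refit on all
    trials.  Deterministic under a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([SIGN_OF_SIDE[str(l)] for l in labels])
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training set")
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        mean, scale = _standardize_stats(X[train_idx])
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train_idx] - mean) / scale, y[train_idx])
        accs.append(clf.score((X[test_idx] - mean) / scale, y[test_idx]))

    mean, scale = _standardize_stats(X)
    clf = SVC(kernel="linear", C=C)
    clf.fit((X - mean) / scale, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    if channel_order is None:
        channel_order = [f"ch{i}" for i in range(N_SENSORS)]
    return TrainedDecoder(
        weights=w,
        bias=b,
        mean=mean,
        scale=scale,
        cv_accuracy=float(np.mean(accs)),
        channel_order=list(channel_order),
        folds=folds,
    )


def classify(decoder: TrainedDecoder, fv: np.ndarray):
    """Classify one feature vector.

    Returns ``(side, score)`` where ``score`` is the signed distance of the
    standardized feature vector to the hyperplane.  ``score == 0`` keeps the
    previously decoded side (hysteresis) instead of chattering.
    """
    fv = np.asarray(fv, dtype=float)
    if fv.shape != (N_FEATURES,):
        raise ValueError(f"feature vector must have length {N_FEATURES}")
    z = (fv - decoder.mean) / decoder.scale
    raw = float(decoder.weights @ z + decoder.bias)
    score = raw / float(np.linalg.norm(decoder.weights))
    if score > 0:
        side = "left"
    elif score < 0:
        side = "right"
    else:
        side = decoder.last_side
    decoder.last_side = side
    return side, score
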