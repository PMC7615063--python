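"""Offline analysis of recorded sessions.

Mirrors the analysis pipeline applied to the BCI recordings: minimal
preprocessing (1-80 Hz band-pass plus 50 Hz notch, no artifact rejection or
baseline correction), epoching around tagging onsets or ball collisions, a
Hanning-tapered time-frequency decomposition with a frequency-dependent
20-cycle window, the spectral SNR measure (power at the tag over the mean
power 2 Hz to either side), Wolpaw's information transfer rate, a trailing
1-s sliding-window power trace downsampled to 100 Hz, a cluster-based
permutation test over timepoints, and the eye-position confound checks
(gaze containment fractions and 40-bin eye-position/power histograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .decode import _psd_bins
from .synthmeg import Recording

# ---------------------------------------------------------------------------
# preprocessing and epoching
# ---------------------------------------------------------------------------


def preprocess(rec: Recording, band=(1.0, 80.0), notch_hz: float = 50.0) -> Recording:
    """Zero-phase 4th-order band-pass plus a narrow 50 Hz notch on MEG channels.

    The notch is a 2 Hz-wide linear-phase FIR band-stop, chosen over a biquad
    notch because its passband is flat at the 56/60 Hz tags (a two-pass IIR
    notch skirt would still shave several percent off 56 Hz).  Gaze and
    trigger channels pass through untouched.  The recording is kept otherwise
    raw: no baseline correction, no artifact rejection.
    """
    if rec.srate < 2.5 * band[1]:
        raise ValueError(f"srate {rec.srate} too low for band edge {band[1]} Hz")
    sos = signal.butter(4, band, btype="bandpass", fs=rec.srate, output="sos")
    b_notch = signal.firwin(
        2001, (notch_hz - 1.0, notch_hz + 1.0), fs=rec.srate
    )
    data = rec.data.copy()
    meg_idx = [i for i, k in enumerate(rec.channel_kinds) if k == "meg"]
    filtered = signal.sosfiltfilt(sos, data[meg_idx], axis=1)
    filtered = signal.filtfilt(b_notch, [1.0], filtered, axis=1)
    data[meg_idx] = filtered
    return Recording(
        data=data,
        srate=rec.srate,
        channel_names=list(rec.channel_names),
        channel_kinds=list(rec.channel_kinds),
        events=list(rec.events),
    )


@dataclass
class Epochs:
    """Trials x channels x samples around an event, with condition labels."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to the event
    labels: list
    srate: float
    n_dropped: int = 0

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis must match sample count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


#: default epoch windows (seconds relative to the event)
TRAINING_WINDOW = (-1.0, 3.0)  # around tagging onset: 1 s pre + 2 s tag + 1 s post
GAME_WINDOW = (-3.0, 1.0)  # around ball collision


def epoch(
    rec: Recording,
    event_codes,
    window,
    label_map=None,
    channel_kind: str = "meg",
) -> Epochs:
    """Cut fixed windows around events with the given codes.

    ``label_map`` maps event codes to condition labels (e.g. 11 -> "left").
    Trials whose window exceeds the recording bounds are dropped and counted
    in ``n_dropped``.
    """
    if np.isscalar(event_codes):
        event_codes = [event_codes]
    idx = [i for i, k in enumerate(rec.channel_kinds) if k == channel_kind]
    lo = int(round(window[0] * rec.srate))
    hi = int(round(window[1] * rec.srate))
    n_samp = hi - lo
    trials, labels, dropped = [], [], 0
    for s, code in rec.events:
        if code not in event_codes:
            continue
        a, b = s + lo, s + lo + n_samp
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[idx, a:b])
        labels.append(label_map.get(code) if label_map else code)
    data = (
        np.stack(trials) if trials else np.empty((0, len(idx), n_samp))
    )
    times = (np.arange(n_samp) + lo) / rec.srate
    return Epochs(data=data, times=times, labels=labels, srate=rec.srate, n_dropped=dropped)


# ---------------------------------------------------------------------------
# time-frequency decomposition
# ---------------------------------------------------------------------------


@dataclass
class TFR:
    """Trial-averaged power: channels x frequencies x times.

    Time points whose 20-cycle window would run past the epoch edge are NaN
    (marked unavailable, never zero-filled); ``available`` flags them.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    available: np.ndarray = field(default=None)
    taper: str = "hann"

    def to_csv(self, path, channel_names=None) -> None:
        ch = channel_names or [f"ch{i}" for i in range(self.power.shape[0])]
        rows = []
        for ci, cname in enumerate(ch):
            for fi, f in enumerate(self.freqs):
                for ti, t in enumerate(self.times):
                    rows.append(
                        {"channel": cname, "frequency": f, "time": t,
                         "power": self.power[ci, fi, ti]}
                    )
        pd.DataFrame(rows).to_csv(path, index=False)


def tfr_hanning(
    epochs: Epochs,
    fmin: float = 40.0,
    fmax: float = 70.0,
    fstep: float = 1.0,
    cycles: float = 20.0,
    step: float = 0.025,
) -> TFR:
    """Hanning-tapered sliding-window power, 20 cycles per frequency, 25 ms steps.

    For frequency f the window spans ``cycles / f`` seconds centred on each
    output time point; power is normalized so a unit-amplitude sinusoid at f
    yields ~1, then averaged over trials.
    """
    srate = epochs.srate
    freqs = np.arange(fmin, fmax + fstep / 2, fstep)
    longest = int(np.ceil(cycles / fmin * srate))
    if epochs.data.shape[2] < longest:
        raise ValueError("epochs shorter than the longest (lowest-frequency) window")
    t0, t1 = epochs.times[0], epochs.times[-1]
    times = np.arange(np.ceil(t0 / step) * step, t1 + 1e-9, step)
    n_tr, n_ch, n_samp = epochs.data.shape
    power = np.full((n_ch, freqs.size, times.size), np.nan)
    available = np.zeros((freqs.size, times.size), dtype=bool)
    for fi, f in enumerate(freqs):
        wlen = int(round(cycles / f * srate))
        taper = np.hanning(wlen)
        carrier = np.exp(-2j * np.pi * f * np.arange(wlen) / srate)
        kern = taper * carrier
        norm = taper.sum() / 2.0
        half = wlen // 2
        for ti, t in enumerate(times):
            center = int(round((t - t0) * srate))
            a, b = center - half, center - half + wlen
            if a < 0 or b > n_samp:
                continue
            seg = epochs.data[:, :, a:b]
            coeff = seg @ kern
            power[:, fi, ti] = np.mean(np.abs(coeff / norm) ** 2, axis=0)
            available[fi, ti] = True
    return TFR(power=power, freqs=freqs, times=times, available=available)


# ---------------------------------------------------------------------------
# SNR and information transfer rate
# ---------------------------------------------------------------------------


def snr(freqs, power, f1: float, neighbour_hz: float = 2.0) -> float:
    """Spectral SNR: p(f1) / (0.5 * [p(f1 - 2) + p(f1 + 2)]).

    ``freqs`` and ``power`` describe a power spectrum sampled at least at the
    three required frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)

    def at(f):
        i = np.flatnonzero(np.isclose(freqs, f))
        if i.size == 0:
            raise ValueError(f"spectrum not defined at {f} Hz")
        return power[i[0]]

    denom = 0.5 * (at(f1 - neighbour_hz) + at(f1 + neighbour_hz))
    if denom == 0:
        raise ZeroDivisionError("zero power in the neighbour bins")
    return float(at(f1) / denom)


def itr(
    n_targets: int,
    accuracy: float,
    n_trials: int,
    minutes: float,
    printed_formula: bool = False,
) -> float:
    """Information transfer rate in bits per minute.

    Wolpaw's bits per trial, ``log2 N + P log2 P + (1-P) log2((1-P)/(N-1))``,
    times the trial rate ``S/T``.  ``printed_formula=True`` divides the error
    term by N instead of N-1 (a published variant that goes negative at
    chance for N=2) and is provided for comparison only.
    """
    N, P, S, T = n_targets, accuracy, n_trials, minutes
    if N < 2 or S < 1 or T <= 0:
        raise ValueError("need N >= 2, S >= 1, T > 0")
    if not (1.0 / N) <= P <= 1.0:
        raise ValueError(f"accuracy {P} outside [1/N, 1]")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        denom = N if printed_formula else N - 1
        bits += (1 - P) * np.log2((1 - P) / denom)
    return float(bits * S / T)


# ---------------------------------------------------------------------------
# sliding-window power
# ---------------------------------------------------------------------------


def sliding_power(
    x: np.ndarray,
    freq: float,
    srate: float = 1000.0,
    window_s: float = 1.0,
    out_rate: float = 100.0,
):
    """Trailing 1-s DFT power at ``freq``, stepped every sample, then decimated.

    Each output point is the raw DFT-bin power (same definition as the online
    decoder) of the window *ending* at that sample, mirroring the causal ring
    buffer.  The per-sample trace is downsampled to ``out_rate`` by keeping
    every ``srate/out_rate``-th point.

    Returns ``(times, power)``: times are the window end times in seconds.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(window_s * srate))
    if x.size < n:
        raise ValueError("recording shorter than the analysis window")
    k_float = freq * n / srate
    if abs(k_float - round(k_float)) > 1e-9:
        raise ValueError(f"{freq} Hz is not bin-aligned for a {window_s}-s window")
    k = int(round(k_float))
    h = np.exp(-2j * np.pi * k * np.arange(n) / n)
    coeff = signal.fftconvolve(x, h[::-1], mode="valid")  # window starting at i
    power = np.abs(coeff) ** 2
    t_end = (np.arange(power.size) + n - 1 + 1) / srate  # window end, seconds
    dec = int(round(srate / out_rate))
    return t_end[::dec], power[::dec]


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    start: int
    end: int  # exclusive
    t_sum: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ClusterTestResult:
    t_values: np.ndarray
    clusters: list
    n_permutations: int
    threshold: float

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]

    def to_csv(self, path) -> None:
        rows = []
        for ti, t in enumerate(self.t_values):
            cid, p = -1, np.nan
            for i, c in enumerate(self.clusters):
                if c.start <= ti < c.end:
                    cid, p = i, c.p
            rows.append({"time_index": ti, "t": t, "cluster_id": cid, "p": p})
        pd.DataFrame(rows).to_csv(path, index=False)


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Per-timepoint paired t statistic from per-subject difference traces."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    return m / (sd / np.sqrt(n))


def _find_clusters(t: np.ndarray, thr: float):
    """Maximal runs of consecutive same-sign supra-threshold t values."""
    clusters = []
    sign = np.where(t > thr, 1, np.where(t < -thr, -1, 0))
    i = 0
    while i < t.size:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j < t.size and sign[j] == sign[i]:
            j += 1
        clusters.append((i, j, float(t[i:j].sum())))
        i = j
    return clusters


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Cluster-based permutation test on paired condition traces.

    ``cond_a`` and ``cond_b`` are (subjects x timepoints) from the same
    subjects.  Per timepoint a paired t-test is computed; clusters are maximal
    runs of consecutive same-sign t values exceeding the two-tailed
    ``alpha`` critical value; the null distribution is the maximum cluster
    |t_sum| under random within-subject condition swaps (sign flips of the
    difference), which controls the family-wise error.  A cluster is
    significant when its permutation p (with the +1 correction) is below 0.05.

    With ``exhaustive=True`` all 2**n sign patterns are enumerated instead of
    sampling; feasible for small n and exact by construction.
    """
    A = np.asarray(cond_a, dtype=float)
    B = np.asarray(cond_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("conditions must have identical (subjects x time) shape")
    n_sub = A.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if not exhaustive and n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse permutation p", stacklevel=2)
    diff = A - B
    thr = stats.t.ppf(1 - alpha / 2, df=n_sub - 1)
    t_obs = _paired_t(diff)
    obs_clusters = _find_clusters(t_obs, thr)

    if exhaustive:
        flips = np.array(
            [[1 if (m >> s) & 1 else -1 for s in range(n_sub)] for m in range(2**n_sub)]
        )
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    # vectorized paired t over all sign patterns: the per-subject sum of
    # squares is flip-invariant, so only the mean changes per permutation
    ssq = (diff**2).sum(axis=0)
    M = flips @ diff / n_sub
    var = (ssq - n_sub * M**2) / (n_sub - 1)
    var = np.where(var > 0, var, np.inf)
    T = M / np.sqrt(var / n_sub)
    null_max = np.empty(len(flips))
    for i in range(len(flips)):
        cl = _find_clusters(T[i], thr)
        null_max[i] = max((abs(c[2]) for c in cl), default=0.0)

    clusters = []
    for start, end, t_sum in obs_clusters:
        if exhaustive:
            p = float(np.mean(null_max >= abs(t_sum)))
        else:
            p = float((1 + np.sum(null_max >= abs(t_sum))) / (len(flips) + 1))
        clusters.append(Cluster(start, end, t_sum, p))
    return ClusterTestResult(
        t_values=t_obs,
        clusters=clusters,
        n_permutations=len(flips),
        threshold=float(thr),
    )


# ---------------------------------------------------------------------------
# eye-position analyses
# ---------------------------------------------------------------------------


def gaze_containment(gaze_x: np.ndarray, thresholds=(1.0, 2.0)) -> dict:
    """Fraction of (non-blink) gaze samples within each threshold in degrees."""
    g = np.asarray(gaze_x, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        return {thr: np.nan for thr in thresholds}
    return {float(thr): float(np.mean(np.abs(g) < thr)) for thr in thresholds}


def eye_power_histogram(
    gaze_x: np.ndarray,
    power: np.ndarray,
    n_bins: int = 40,
    deg_range: tuple = (-2.0, 2.0),
):
    """Mean tagging power as a function of binned horizontal eye position.

    ``gaze_x`` and ``power`` must be time-aligned (both at 100 Hz after
    :func:`sliding_power`).  Returns ``(bin_centers, mean_power, counts)``;
    empty bins have NaN mean and count 0.
    """
    g = np.asarray(gaze_x, dtype=float)
    p = np.asarray(power, dtype=float)
    if g.shape != p.shape:
        raise ValueError("gaze and power must be time-aligned (same length)")
    ok = ~np.isnan(g) & ~np.isnan(p)
    g, p = g[ok], p[ok]
    edges = np.linspace(deg_range[0], deg_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(g, edges) - 1
    in_range = (which >= 0) & (which < n_bins)
    mean_power = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = in_range & (which == b)
        counts[b] = sel.sum()
        if counts[b]:
            mean_power[b] = p[sel].mean()
    return centers, mean_power, counts
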