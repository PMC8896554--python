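"""Channel-quality metrics and interictal-discharge (IED) detection.

Channel rejection uses three complementary metrics computed on the
continuous recording: line length (sensitive to broadband/high-frequency
noise), kurtosis (transient artifacts), and a power-spectral-density
dissimilarity against the other channels (drift/line-noise outliers).

IED detection follows a Hilbert-envelope scheme: downsample to 200 Hz,
band-pass 10-60 Hz, square the analytic-signal magnitude, and threshold the
envelope adaptively in overlapping 5-s windows at k0 times (mode + median)
of the window's envelope.  A spatial filter then discards events not
accompanied by events on at least three other channels within 50 ms, since
genuine discharges propagate across contacts while isolated excursions are
usually artifact.  Trials containing a surviving event are rejected.

Notch filtering, demeaning/detrending and common-average referencing are
provided as thin optional hooks (:func:`preprocess_hooks`); they are
standard plumbing, not part of the analyses here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "ChannelMetrics",
    "IEDEvent",
    "channel_metrics",
    "reject_channels",
    "detect_ieds",
    "reject_ied_trials",
    "preprocess_hooks",
]

IED_FS = 200.0  # Hz, detector operating rate
IED_BAND = (10.0, 60.0)  # Hz
IED_WINDOW = 5.0  # s
IED_OVERLAP = 4.0  # s
IED_K0 = 3.65  # threshold scale on (mode + median) of the envelope
IED_COOCCUR_WINDOW = 0.050  # s, spatial-filter co-occurrence window
IED_MIN_OTHER_CHANNELS = 3


@dataclass
class ChannelMetrics:
    line_length: np.ndarray
    kurtosis_z: np.ndarray
    psd_dissim: np.ndarray
    psd_dissim_z: np.ndarray
    undefined: np.ndarray  # constant channels whose kurtosis is undefined


@dataclass
class IEDEvent:
    channel: int
    time: float  # seconds, envelope peak of the excursion
    passed_spatial_filter: bool = False


def channel_metrics(signals: np.ndarray, fs: float) -> ChannelMetrics:
    """Line length, z-scored kurtosis, and z-scored PSD dissimilarity.

    ``signals`` is channels x samples.  Line length is the summed absolute
    first difference of each trace.  The PSD dissimilarity of a channel is
    the mean over all other channels of one minus the Spearman rank
    correlation of their (Welch) power spectra, so it lies in [0, 2].
    Constant channels have undefined kurtosis and are flagged.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch = signals.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    line_length = np.abs(np.diff(signals, axis=1)).sum(axis=1)
    undefined = signals.std(axis=1) < 1e-12
    kurt = np.array(
        [stats.kurtosis(s) if not u else np.nan for s, u in zip(signals, undefined)]
    )
    _, psd = signal.welch(signals, fs=fs, nperseg=min(signals.shape[1], 1024), axis=1)
    rho = stats.spearmanr(psd, axis=1).statistic
    rho = np.atleast_2d(rho)
    dis = np.array(
        [(1.0 - np.delete(rho[c], c)).mean() for c in range(n_ch)]
    )
    return ChannelMetrics(
        line_length=line_length,
        kurtosis_z=_zscore(kurt),
        psd_dissim=dis,
        psd_dissim_z=_zscore(dis),
        undefined=undefined,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if not np.isfinite(s) or s == 0:
        return np.zeros_like(x)
    return (x - m) / s


def reject_channels(m: ChannelMetrics) -> np.ndarray:
    """Boolean rejection flags from the three channel-quality rules.

    A channel is flagged when its line length exceeds three times the mean
    line length, its z-scored kurtosis exceeds 1.5, or its z-scored PSD
    dissimilarity exceeds 1.5; channels with undefined metrics are flagged
    automatically.
    """
    flags = (
        (m.line_length > 3.0 * m.line_length.mean())
        | (np.nan_to_num(m.kurtosis_z, nan=np.inf) > 1.5)
        | (m.psd_dissim_z > 1.5)
        | m.undefined
    )
    return flags


def _envelope_threshold_mask(env: np.ndarray, fs: float, k0: float) -> np.ndarray:
    """Per-sample supra-threshold mask from overlapping adaptive windows.

    In each 5-s window (4-s overlap) the threshold is k0 * (mode + median)
    of the envelope, the mode estimated from a 64-bin histogram (a mode is
    not otherwise defined for continuous data).  Overlapping decisions are
    combined by per-sample OR.
    """
    n = len(env)
    win = int(IED_WINDOW * fs)
    step = int((IED_WINDOW - IED_OVERLAP) * fs)
    mask = np.zeros(n, dtype=bool)
    starts = list(range(0, max(n - win, 0) + 1, step))
    if not starts:
        starts = [0]
    for s in starts:
        seg = env[s : s + win]
        counts, edges = np.histogram(seg, bins=64)
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        thr = k0 * (mode + np.median(seg))
        mask[s : s + win] |= seg > thr
    return mask


def detect_ieds(
    signals: np.ndarray,
    fs: float,
    k0: float = IED_K0,
    spatial_filter: bool = True,
) -> list[IEDEvent]:
    """Hilbert-envelope IED detection with a multichannel spatial filter.

    Returns one event per supra-threshold excursion per channel, stamped at
    the excursion's envelope peak; ``passed_spatial_filter`` marks events
    co-occurring (within 50 ms) with events on at least three other
    channels.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if fs < IED_FS:
        raise ValueError(f"sampling rate below {IED_FS} Hz; cannot downsample")
    n_samples = signals.shape[1]
    if n_samples / fs < IED_WINDOW:
        raise ValueError("recording shorter than one detector window (5 s)")
    if fs != IED_FS:
        # polyphase resampling to the 200 Hz detector rate
        from fractions import Fraction

        frac = Fraction(int(IED_FS), int(fs)).limit_denominator(1000)
        signals = signal.resample_poly(signals, frac.numerator, frac.denominator, axis=1)
    sos = signal.butter(4, IED_BAND, btype="bandpass", fs=IED_FS, output="sos")
    filtered = signal.sosfiltfilt(sos, signals, axis=1)
    env = np.abs(signal.hilbert(filtered, axis=1)) ** 2
    events: list[IEDEvent] = []
    per_channel_times: list[np.ndarray] = []
    for ch in range(env.shape[0]):
        mask = _envelope_threshold_mask(env[ch], IED_FS, k0)
        times = []
        # contiguous supra-threshold runs -> one event each, at the peak
        for a, b in _runs(mask):
            peak = a + int(np.argmax(env[ch, a:b]))
            times.append(peak / IED_FS)
        per_channel_times.append(np.asarray(times))
        events.extend(IEDEvent(channel=ch, time=t) for t in times)
    if spatial_filter:
        for ev in events:
            n_other = sum(
                1
                for ch, times in enumerate(per_channel_times)
                if ch != ev.channel
                and len(times)
                and np.min(np.abs(times - ev.time)) <= IED_COOCCUR_WINDOW
            )
            ev.passed_spatial_filter = n_other >= IED_MIN_OTHER_CHANNELS
    else:
        for ev in events:
            ev.passed_spatial_filter = True
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) bounds of contiguous True runs."""
    padded = np.r_[False, mask, False].astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def reject_ied_trials(
    events: list[IEDEvent], trial_windows: np.ndarray
) -> np.ndarray:
    """Mask trials containing a spatial-filter-passing IED.

    ``trial_windows`` is (n_trials, 2) of [onset, offset] seconds; returns
    True for trials to reject.
    """
    trial_windows = np.atleast_2d(np.asarray(trial_windows, dtype=float))
    mask = np.zeros(len(trial_windows), dtype=bool)
    times = np.array([ev.time for ev in events if ev.passed_spatial_filter])
    if len(times) == 0:
        return mask
    for k, (onset, offset) in enumerate(trial_windows):
        mask[k] = bool(np.any((times >= onset) & (times <= offset)))
    return mask


def preprocess_hooks(
    signals: np.ndarray,
    fs: float,
    notch: bool = False,
    detrend: bool = False,
    common_average: bool = False,
    line_freq: float = 60.0,
) -> np.ndarray:
    """Optional standard preprocessing: notch, detrend, common average.

    Thin wrappers over scipy; disabled by default and not used by any
    analysis in this package.
    """
    out = np.atleast_2d(np.asarray(signals, dtype=float)).copy()
    if notch:
        for harm in (1, 2, 3):
            freq = line_freq * harm
            if freq < fs / 2:
                sos = signal.butter(
                    4, [freq - 0.5, freq + 0.5], btype="bandstop", fs=fs, output="sos"
                )
                out = signal.sosfiltfilt(sos, out, axis=1)
    if detrend:
        out = signal.detrend(out, axis=1)
    if common_average:
        out = out - out.mean(axis=0, keepdims=True)
    return out
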