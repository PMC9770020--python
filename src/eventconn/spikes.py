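"""Interictal spike detection and pairwise spike-coupling rates.

Spikes are sharp broadband transients riding on a strongly 1/f background.
Whitening the power spectrum removes that background tilt so a simple robust
amplitude threshold can pick the transients out; the pairwise coupling rate
for channels i and j is then the summed spike count over the recording
duration, r_ij = (n_i + n_j) / duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft
from scipy.ndimage import median_filter

__all__ = [
    "SpikeTrain",
    "SpikeCouplingMatrix",
    "whiten",
    "detect_spikes",
    "spike_coupling_rate",
    "spike_coupling_matrix",
    "top_rate_channels",
]


@dataclass
class SpikeTrain:
    """Detected spike times (ms) for one channel."""

    label: str
    times_ms: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return self.times_ms.size

    @property
    def rate_per_s(self) -> float:
        return self.count / self.duration_s


def whiten(signal: np.ndarray, fs: float = 1000.0, smooth_hz: float = 4.0) -> np.ndarray:
    """Flatten the amplitude spectrum (robust spectral whitening).

    The amplitude spectrum is divided by its running-median envelope (median
    smoothing over ``smooth_hz``-wide frequency neighbourhoods), keeping the
    phase.  Narrow features — and broadband transients, whose energy is
    spread across frequencies coherently in phase — survive, while the 1/f
    background is equalized.  Output is rescaled to the input's robust scale
    so threshold units remain comparable.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal")
    spec = rfft(x)
    amp = np.abs(spec)
    df = fs / x.size
    k = max(3, int(round(smooth_hz / df)) | 1)
    env = median_filter(amp, size=k, mode="nearest")
    floor = 1e-12 * max(env.max(), 1e-300)
    white = irfft(spec / np.maximum(env, floor), n=x.size)
    # restore a comparable robust amplitude scale
    mad_in = np.median(np.abs(x - np.median(x)))
    mad_out = np.median(np.abs(white - np.median(white)))
    if mad_out > 0 and mad_in > 0:
        white = white * (mad_in / mad_out)
    return white


def detect_spikes(
    whitened: np.ndarray,
    z_threshold: float = 6.0,
    min_isi_ms: float = 50.0,
    fs: float = 1000.0,
    label: str = "",
) -> SpikeTrain:
    """Threshold the whitened trace with a robust z-score and a refractory rule.

    Candidates are local maxima of |z| with |z| >= ``z_threshold``, where
    z = (x - median) / (1.4826 MAD).  Candidates are kept greedily in order
    of descending amplitude subject to a minimum inter-spike interval.
    """
    x = np.asarray(whitened, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    duration_s = x.size / fs
    if mad == 0:
        return SpikeTrain(label=label, times_ms=np.array([]), duration_s=duration_s)
    a = np.abs((x - med) / (1.4826 * mad))
    mid = a[1:-1]
    peaks = np.nonzero((mid >= a[:-2]) & (mid > a[2:]) & (mid >= z_threshold))[0] + 1
    if peaks.size == 0:
        return SpikeTrain(label=label, times_ms=np.array([]), duration_s=duration_s)
    order = peaks[np.argsort(a[peaks])[::-1]]
    min_gap = min_isi_ms * fs / 1000.0
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= min_gap for q in kept):
            kept.append(p)
    times = np.sort(np.asarray(kept)) * (1000.0 / fs)
    return SpikeTrain(label=label, times_ms=times, duration_s=duration_s)


def spike_coupling_rate(
    train_i: SpikeTrain, train_j: SpikeTrain, duration_s: float, per: str = "s"
) -> float:
    """r_ij = (n_i + n_j) / duration, in events per second (or per minute)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    r = (train_i.count + train_j.count) / duration_s
    if per == "s":
        return r
    if per == "min":
        return r * 60.0
    raise ValueError("per must be 's' or 'min'")


@dataclass
class SpikeCouplingMatrix:
    """Symmetric coupling-rate matrix r_ij = (n_i + n_j)/duration."""

    r: np.ndarray
    duration_s: float
    channel_labels: list[str]
    per: str = "s"


def spike_coupling_matrix(
    trains: list[SpikeTrain], duration_s: float, per: str = "s"
) -> SpikeCouplingMatrix:
    counts = np.array([t.count for t in trains], dtype=float)
    r = (counts[:, None] + counts[None, :]) / duration_s
    if per == "min":
        r = r * 60.0
    return SpikeCouplingMatrix(
        r=r, duration_s=duration_s,
        channel_labels=[t.label for t in trains], per=per,
    )


def top_rate_channels(trains: list[SpikeTrain], percent: float = 5.0) -> list[str]:
    """Channels in the top ``percent`` of spike rates, ties included.

    The base count is max(1, round(percent% of Nc)); every channel whose rate
    ties the last included one is also returned.
    """
    if not trains:
        raise ValueError("need at least one channel")
    rates = np.array([t.rate_per_s for t in trains])
    k = max(1, int(round(percent / 100.0 * len(trains))))
    order = np.argsort(rates)[::-1]
    cut = rates[order[k - 1]]
    return [trains[i].label for i in order if rates[i] >= cut]
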