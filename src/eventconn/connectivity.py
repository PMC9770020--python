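"""Band-event connectivity: peri-event lag histograms normalized by Shannon entropy.

The coupling between two channels is measured from the lead/lag times between
band-limited amplitude peaks ("events") on the two channels.  All lags in
[-T, T) are collected into a histogram with 2-ms bins; a sharp histogram
(low entropy) means the channels' events keep a consistent temporal relation,
a flat histogram (entropy near ln N) means they are unrelated.  The
connectivity index is

    h = (Smax - S) / Smax,   Smax = ln N,

so h = 1 for a perfectly locked pair and h = 0 for an unstructured one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandSpec",
    "EventTrain",
    "PeriEventHistogram",
    "ConnectivityStack",
    "ConnectivityMatrix",
    "THETA",
    "LOW_GAMMA",
    "HIGH_GAMMA",
    "DEFAULT_BANDS",
    "band_spec",
    "detect_events",
    "peri_event_histogram",
    "shannon_entropy",
    "connectivity_index",
    "window_connectivity",
    "mean_connectivity",
    "matrix_similarity",
]


@dataclass(frozen=True)
class BandSpec:
    """Analysis band with the derived histogram design parameters.

    The lag half-width is tied to the slowest oscillation in the band,
    T = ceil(1000 / fmin) ms, and the bin width to the 2-ms resolution that a
    1-kHz sampling rate supports.  A histogram is considered statistically
    valid when it holds at least ``min_events_per_bin`` lag observations per
    bin on average, which translates into a minimum total count and, through
    the band's mean event frequency (fmin + fmax)/2, a minimum stretch of
    recording.
    """

    name: str
    fmin: float
    fmax: float
    bin_width_ms: float = 2.0
    window_length_s: float = 60.0
    min_events_per_bin: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.fmin < self.fmax <= 450):
            raise ValueError(f"band edges out of range: ({self.fmin}, {self.fmax})")
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if (2 * self.T_ms) % self.bin_width_ms:
            raise ValueError(
                f"2T = {2 * self.T_ms} ms is not an integer number of "
                f"{self.bin_width_ms} ms bins"
            )

    @property
    def T_ms(self) -> int:
        """Lag half-width: one period of the slowest in-band frequency."""
        return math.ceil(1000.0 / self.fmin)

    @property
    def n_bins(self) -> int:
        return int(round(2 * self.T_ms / self.bin_width_ms))

    @property
    def min_total_count(self) -> int:
        """Minimum lag observations for a statistically valid histogram."""
        return self.min_events_per_bin * self.n_bins

    @property
    def mean_event_freq_hz(self) -> float:
        """Expected event rate: the band's centre frequency."""
        return 0.5 * (self.fmin + self.fmax)

    @property
    def min_duration_s(self) -> float:
        """Recording length needed to collect ``min_total_count`` events."""
        return self.min_total_count / self.mean_event_freq_hz

    @property
    def window_satisfies_validity(self) -> bool:
        """Whether ``window_length_s`` can in principle meet the validity rule."""
        return self.window_length_s >= self.min_duration_s


def band_spec(
    fmin: float,
    fmax: float,
    bin_width_ms: float = 2.0,
    window_length_s: float = 60.0,
    min_events_per_bin: int = 30,
    name: str | None = None,
) -> BandSpec:
    """Construct a :class:`BandSpec`, deriving T, bin count and validity limits."""
    return BandSpec(
        name=name or f"{fmin:g}-{fmax:g}Hz",
        fmin=fmin,
        fmax=fmax,
        bin_width_ms=bin_width_ms,
        window_length_s=window_length_s,
        min_events_per_bin=min_events_per_bin,
    )


#: Default analysis bands.  The 55-65 Hz gap between the gamma bands is kept
#: clear of analysis to avoid coupling driven by 60-Hz mains contamination.
THETA = BandSpec("theta", 4.0, 8.0, window_length_s=300.0)
LOW_GAMMA = BandSpec("low_gamma", 30.0, 55.0, window_length_s=60.0)
HIGH_GAMMA = BandSpec("high_gamma", 65.0, 95.0, window_length_s=30.0)
DEFAULT_BANDS = (THETA, LOW_GAMMA, HIGH_GAMMA)


@dataclass
class EventTrain:
    """Sorted event times (ms) for one channel."""

    label: str
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.ndim != 1:
            raise ValueError("times_ms must be 1-D")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_ms.size


def detect_events(
    signal: np.ndarray, threshold: float = 0.1, fs: float = 1000.0, label: str = ""
) -> EventTrain:
    """Detect local amplitude maxima that exceed both neighbours by ``threshold``.

    A sample is an event iff it is larger than each adjacent sample by at
    least ``threshold`` (in the signal's amplitude units, µV by convention).
    This is the neighbour-exceedance semantics of the classic findpeaks
    ``Threshold`` parameter, not a minimum absolute height.

    Returns times in ms (sample index at 1 kHz).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")
    mid = x[1:-1]
    rise = mid - x[:-2]
    fall = mid - x[2:]
    idx = np.nonzero((rise >= threshold) & (fall >= threshold))[0] + 1
    return EventTrain(label=label, times_ms=idx * (1000.0 / fs))


@dataclass
class PeriEventHistogram:
    """Lag histogram over [-T, T) with half-open bins of equal width."""

    counts: np.ndarray
    bin_edges_ms: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges_ms = np.asarray(self.bin_edges_ms, dtype=float)
        if self.counts.size != self.bin_edges_ms.size - 1:
            raise ValueError("edges must be one longer than counts")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def probabilities(self) -> np.ndarray:
        total = self.total_count
        if total == 0:
            raise ValueError("empty histogram has no probability distribution")
        return self.counts / total


def peri_event_histogram(
    train_x: EventTrain, train_y: EventTrain, band: BandSpec
) -> PeriEventHistogram:
    """Histogram of all pairwise lags (t_y - t_x) falling in [-T, T).

    Every event pair contributes (not only nearest neighbours); bins are
    half-open ``[l, l + w)`` with edges at multiples of the bin width from -T.
    """
    T = float(band.T_ms)
    w = float(band.bin_width_ms)
    n_bins = band.n_bins
    edges = -T + w * np.arange(n_bins + 1)

    tx = train_x.times_ms
    ty = train_y.times_ms
    counts = np.zeros(n_bins, dtype=np.int64)
    if tx.size and ty.size:
        lo = np.searchsorted(ty, tx - T, side="left")
        hi = np.searchsorted(ty, tx + T, side="left")
        per = hi - lo
        keep = per > 0
        if np.any(keep):
            idx = np.concatenate(
                [np.arange(a, b) for a, b in zip(lo[keep], hi[keep])]
            )
            lags = ty[idx] - np.repeat(tx[keep], per[keep])
            bins = np.floor((lags + T) / w).astype(np.int64)
            # lag == T is excluded by the searchsorted bound; guard rounding
            np.clip(bins, 0, n_bins - 1, out=bins)
            counts = np.bincount(bins, minlength=n_bins)
    return PeriEventHistogram(counts=counts, bin_edges_ms=edges)


def shannon_entropy(hist: PeriEventHistogram) -> float:
    """S = -sum p_i ln p_i in nats, with 0 ln 0 := 0.  Requires counts > 0."""
    p = hist.probabilities
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def connectivity_index(S: float, n_bins: int) -> float:
    """Normalize entropy into h = (Smax - S)/Smax with Smax = ln N.

    h = 1 iff all lag mass sits in a single bin (S = 0); h = 0 iff the lag
    distribution is uniform (S = ln N).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    smax = math.log(n_bins)
    if not (-1e-12 <= S <= smax + 1e-9):
        raise ValueError(f"entropy {S} outside [0, ln {n_bins}]")
    h = (smax - S) / smax
    return float(min(1.0, max(0.0, h)))


@dataclass
class ConnectivityStack:
    """Per-window connectivity values with their validity mask.

    ``values[m, i, j]`` is h for channel pair (i, j) in window m (NaN where no
    lag observations exist); ``valid[m, i, j]`` marks pair-windows whose
    histogram met the minimum-count rule.  Every slice is symmetric.
    """

    values: np.ndarray
    valid: np.ndarray
    band: BandSpec
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Across-window mean connectivity; symmetric, NaN diagonal."""

    h: np.ndarray
    band_name: str
    channel_labels: list[str] = field(default_factory=list)
    n_windows_used: np.ndarray | None = None


def window_connectivity(
    data: np.ndarray,
    band: BandSpec,
    fs: float = 1000.0,
    threshold: float = 0.1,
    channel_labels: list[str] | None = None,
) -> ConnectivityStack:
    """Split a band-filtered recording into windows and compute h per pair.

    The recording is cut into M = floor(duration / L) consecutive
    non-overlapping windows (a trailing partial window is discarded).  For
    each window and unordered channel pair, events are detected, the lag
    histogram built and h computed once, then assigned to both (i, j) and
    (j, i).  A pair-window is valid iff the histogram's total count reaches
    ``min_events_per_bin * n_bins``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    duration_s = n_samp / fs
    L = band.window_length_s
    if duration_s < L:
        raise ValueError(
            f"recording is {duration_s:.1f} s but band '{band.name}' needs at "
            f"least one full window of {L:g} s"
        )
    n_windows = int(duration_s // L)
    labels = channel_labels or [f"ch{i}" for i in range(n_ch)]

    trains = [detect_events(data[i], threshold=threshold, fs=fs, label=labels[i])
              for i in range(n_ch)]
    return window_connectivity_from_trains(
        trains, band, n_windows=n_windows, channel_labels=labels
    )


def window_connectivity_from_trains(
    trains: list[EventTrain],
    band: BandSpec,
    n_windows: int,
    channel_labels: list[str] | None = None,
    window_start_ms: float = 0.0,
) -> ConnectivityStack:
    """Windowed pairwise connectivity straight from event trains.

    Events are assigned to windows by their times; only same-window pairs
    contribute to a window's histogram.
    """
    n_ch = len(trains)
    labels = channel_labels or [t.label or f"ch{i}" for i, t in enumerate(trains)]
    L_ms = band.window_length_s * 1000.0
    values = np.full((n_windows, n_ch, n_ch), np.nan)
    valid = np.zeros((n_windows, n_ch, n_ch), dtype=bool)

    for m in range(n_windows):
        t0 = window_start_ms + m * L_ms
        t1 = t0 + L_ms
        win_trains = []
        for tr in trains:
            t = tr.times_ms
            win_trains.append(
                EventTrain(tr.label, t[(t >= t0) & (t < t1)])
            )
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                hist = peri_event_histogram(win_trains[i], win_trains[j], band)
                total = hist.total_count
                if total > 0:
                    h = connectivity_index(shannon_entropy(hist), band.n_bins)
                    values[m, i, j] = values[m, j, i] = h
                if total >= band.min_total_count:
                    valid[m, i, j] = valid[m, j, i] = True
    return ConnectivityStack(values=values, valid=valid, band=band,
                             channel_labels=list(labels))


def mean_connectivity(stack: ConnectivityStack) -> ConnectivityMatrix:
    """Average h over valid windows per pair; pairs with none become NaN."""
    if stack.n_windows < 1:
        raise ValueError("stack has no windows")
    vals = np.where(stack.valid, stack.values, np.nan)
    n_used = stack.valid.sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    mean[n_used == 0] = np.nan
    np.fill_diagonal(mean, np.nan)
    return ConnectivityMatrix(
        h=mean,
        band_name=stack.band.name,
        channel_labels=stack.channel_labels,
        n_windows_used=n_used,
    )


def matrix_similarity(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Percent similarity of two connectivity matrices.

    100 x Pearson correlation of the upper-triangle entries, over pairs where
    both matrices carry a finite value.  Used e.g. to compare connectivity
    from the first and last stretch of a recording.
    """
    if a.h.shape != b.h.shape:
        raise ValueError("matrices have different channel sets")
    if a.channel_labels and b.channel_labels and a.channel_labels != b.channel_labels:
        raise ValueError("matrices have different channel labels")
    iu = np.triu_indices(a.h.shape[0], k=1)
    x, y = a.h[iu], b.h[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 common valid pairs")
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    return float(100.0 * r)
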