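"""Recording I/O and signal conditioning for interictal iEEG.

All analysis runs at 1 kHz: recordings acquired at other rates are brought to
1 kHz with polyphase rational resampling (anti-alias low-pass at 0.9x the
output Nyquist when down-sampling), mains contamination is removed with a
narrow 60-Hz notch, and each analysis band is extracted with a zero-phase
windowed-sinc FIR filter.  Zero phase matters: the connectivity index is
built from millisecond-scale lead/lag relations, so any channel-dependent
group delay would masquerade as coupling structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .connectivity import BandSpec

__all__ = [
    "Recording",
    "SegmentAnnotation",
    "load_channel_metadata",
    "load_recording",
    "resample_to_1khz",
    "notch_60hz",
    "bandpass",
    "select_segments",
]

METADATA_COLUMNS = [
    "label", "x_mm", "y_mm", "z_mm", "region", "soz",
    "hemisphere", "gray_matter", "noise_free",
]


@dataclass
class Recording:
    """Multichannel recording: channels x samples, amplitudes in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("label count does not match channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            start_time=self.start_time,
        )


@dataclass
class SegmentAnnotation:
    """A labelled stretch of recording, e.g. quiet wakefulness.

    ``flags`` may carry selection metadata such as hours since electrode
    implantation or hours to the next seizure; segment selection is driven by
    these annotations, never inferred from the signal.
    """

    onset_ms: float
    duration_ms: float
    state_label: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be non-negative")


def select_segments(
    annotations: list[SegmentAnnotation],
    recording: Recording,
    state_label: str = "quiet_wakefulness",
    min_post_implant_h: float = 24.0,
    min_hours_to_seizure: float = 6.0,
) -> list[SegmentAnnotation]:
    """Metadata-driven segment filter.

    Keeps segments with the requested vigilance state that start more than
    ``min_post_implant_h`` after implantation and end at least
    ``min_hours_to_seizure`` before the next seizure (when the corresponding
    flags are present; absent flags are treated as passing).
    """
    total_ms = recording.duration_s * 1000.0
    out = []
    for a in annotations:
        if a.onset_ms + a.duration_ms > total_ms + 1e-6:
            raise ValueError("segment extends beyond the recording")
        if state_label and a.state_label != state_label:
            continue
        if a.flags.get("post_implant_hours", math.inf) < min_post_implant_h:
            continue
        if a.flags.get("hours_to_next_seizure", math.inf) < min_hours_to_seizure:
            continue
        out.append(a)
    return out


def load_channel_metadata(path: str | Path) -> pd.DataFrame:
    """Read the channel table (TSV: label, MNI coords, region, soz, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype={"label": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if meta["label"].duplicated().any():
        raise ValueError("duplicate channel labels in metadata")
    bad = set(meta["region"]) - {"M", "L", "E"}
    if bad:
        raise ValueError(f"unknown region codes: {sorted(bad)}")
    return meta


def load_recording(
    path: str | Path,
    metadata: pd.DataFrame,
    fs: float | None = None,
    scale_to_uv: float = 1.0,
) -> Recording:
    """Load a recording and keep only analyzable channels.

    Accepts EDF (via mne) or a delimited numeric matrix with one row per
    channel; for matrix files ``fs`` is required and rows are taken in the
    metadata table's order.  Channels flagged ``gray_matter == 0`` or
    ``noise_free == 0`` are dropped; metadata labels absent from the file are
    an error.  ``scale_to_uv`` converts the file's amplitude unit to µV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    keep = metadata[(metadata["gray_matter"].astype(int) == 1)
                    & (metadata["noise_free"].astype(int) == 1)]
    wanted = list(keep["label"])
    if not wanted:
        raise ValueError("no channels pass the gray-matter/noise-free filters")

    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        missing = [lb for lb in metadata["label"] if lb not in raw.ch_names]
        if missing:
            raise ValueError(f"metadata labels not present in EDF: {missing}")
        raw.pick(wanted)
        # mne returns volts for EEG channel types
        data = raw.get_data() * 1e6 * scale_to_uv
        return Recording(data=data, fs=float(raw.info["sfreq"]),
                         channel_labels=wanted)

    if fs is None:
        raise ValueError("fs is required for delimited matrix recordings")
    mat = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    if mat.shape[0] != len(metadata):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but metadata lists "
            f"{len(metadata)} channels"
        )
    rows = metadata.reset_index(drop=True)
    idx = rows.index[rows["label"].isin(wanted)].to_numpy()
    return Recording(data=mat[idx] * scale_to_uv, fs=float(fs),
                     channel_labels=wanted)


def resample_to_1khz(rec: Recording, cutoff_frac: float = 0.9,
                     max_denominator: int = 1000) -> Recording:
    """Rational-ratio resampling to 1 kHz with an anti-aliasing low-pass.

    Uses polyphase filtering; the anti-alias FIR cuts at ``cutoff_frac`` x the
    output Nyquist (down-sampling) or the input Nyquist (up-sampling).  A
    1-kHz recording is returned unchanged.
    """
    if rec.fs == 1000.0:
        return rec
    from fractions import Fraction

    ratio = Fraction(1000.0 / rec.fs).limit_denominator(max_denominator)
    if abs(float(ratio) - 1000.0 / rec.fs) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.fs} is not rationally related to 1000 Hz"
        )
    up, down = ratio.numerator, ratio.denominator
    # windowed-sinc anti-alias filter at cutoff_frac of the tighter Nyquist
    cutoff = cutoff_frac * min(1.0 / up, 1.0 / down)
    numtaps = 2 * 10 * max(up, down) + 1
    fir = sps.firwin(numtaps, cutoff, window=("kaiser", 8.0))
    data = sps.resample_poly(rec.data, up, down, axis=1, window=fir)
    return rec.copy_with(data=data, fs=1000.0)


def notch_60hz(rec: Recording, freq: float = 60.0, bandwidth: float = 4.0) -> Recording:
    """Zero-phase narrow band-stop at the mains frequency (default 60 Hz)."""
    if rec.fs != 1000.0:
        raise ValueError("notch filter expects a 1-kHz recording")
    b, a = sps.iirnotch(freq, Q=freq / bandwidth, fs=rec.fs)
    data = sps.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(data=data)


def _fir_bandpass(band: BandSpec, fs: float) -> np.ndarray:
    trans = max(2.0, 0.2 * band.fmin)
    numtaps = int(math.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length, type-I linear phase
    return sps.firwin(
        numtaps, [band.fmin, band.fmax], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass(rec: Recording, band: BandSpec) -> Recording:
    """Zero-phase FIR band-pass into one analysis band.

    Windowed-sinc (Hamming) design with transition width
    max(2 Hz, 20% of the lower edge), applied forward-backward so the output
    has no group delay between channels.
    """
    if rec.fs != 1000.0:
        raise ValueError("bandpass expects a 1-kHz recording")
    if not (0 < band.fmin < band.fmax < rec.fs / 2):
        raise ValueError("band edges out of range for this sampling rate")
    fir = _fir_bandpass(band, rec.fs)
    padlen = min(len(fir), rec.n_samples - 1)
    data = sps.filtfilt(fir, [1.0], rec.data, axis=1, padlen=padlen)
    return rec.copy_with(data=data)
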