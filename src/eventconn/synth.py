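"""Synthetic multichannel iEEG with known coupling structure.

The generator emulates the statistical structure the analysis assumes:

* per-channel oscillatory event trains in each analysis band, modelled as
  Poisson point processes;
* pairwise coupling through shared *parent* events — each channel of a
  coupled pair copies a parent event with probability rho and adds Gaussian
  timing jitter (sd sigma, independently per channel, so the pairwise lag sd
  is sigma*sqrt(2)) — with independent background events topping each
  channel up to its target rate;
* optionally, copy probabilities tied to electrode geometry through the
  exponential distance rule rho = A exp(-tau d);
* a rendered voltage trace: each event becomes a Hann-windowed sinusoidal
  burst at the band's centre frequency, interictal spikes become biphasic
  sharp transients (~70 ms), and a pink-noise background is added, all in µV.

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import EventTrain
from .preprocess import Recording

__all__ = [
    "Coupling",
    "SynthConfig",
    "GroundTruth",
    "poisson_train",
    "coupled_pair_trains",
    "generate_event_processes",
    "pink_noise",
    "spike_waveform",
    "render_recording",
    "make_patient",
    "make_study",
    "simulate_pair_table",
]

#: centre frequencies used to render band events as bursts
BAND_CENTER_HZ = {"theta": 6.0, "low_gamma": 42.5, "high_gamma": 80.0}

#: discrete-burst event rates per band (events/s).  These are rates of
#: distinct oscillatory bursts, sparse enough that rendered bursts rarely
#: overlap and every ground-truth event maps onto a detectable amplitude peak.
DEFAULT_BAND_RATES = {"theta": 3.0, "low_gamma": 8.0, "high_gamma": 10.0}


@dataclass(frozen=True)
class Coupling:
    """Shared-parent coupling between one channel pair in one band."""

    i: int
    j: int
    band: str
    rho: float
    jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter sd must be non-negative")


@dataclass
class SynthConfig:
    n_channels: int = 8
    duration_s: float = 120.0
    fs: float = 1000.0
    band_rates: dict = field(default_factory=lambda: dict(DEFAULT_BAND_RATES))
    couplings: list = field(default_factory=list)
    noise_sd_uv: float = 5.0
    burst_amp_uv: float = 25.0
    burst_cycles: int = 3
    spike_rate_per_s: float = 0.0
    spike_amp_uv: float = 40.0
    spike_width_ms: float = 70.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    band_trains: dict  # band -> list[EventTrain]
    spike_trains: list  # list of np.ndarray times (ms) per channel
    couplings: list  # list[Coupling]
    decay: tuple | None = None  # (A, tau) when geometry-ruled
    metadata: pd.DataFrame | None = None


def poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times in ms, sorted."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n))


def _dedupe(times: np.ndarray, min_gap_ms: float = 1e-6) -> np.ndarray:
    """Enforce strictly increasing times (drop pathological duplicates)."""
    t = np.sort(times)
    if t.size < 2:
        return t
    keep = np.concatenate([[True], np.diff(t) > min_gap_ms])
    return t[keep]


def coupled_pair_trains(
    rate_hz: float,
    duration_s: float,
    rho: float,
    jitter_sd_ms: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two trains sharing a parent process: a minimal coupled pair.

    Each channel copies each parent event with probability ``rho`` plus
    independent jitter, and receives its own background process of rate
    ``rate_hz * (1 - rho)``, so both channels keep the target rate while the
    expected fraction ``rho`` of events is shared.  ``rho = 1`` with zero
    jitter yields identical trains.
    """
    parent = poisson_train(rate_hz, duration_s, rng)
    out = []
    for _ in range(2):
        copied = parent[rng.random(parent.size) < rho]
        if jitter_sd_ms > 0:
            copied = copied + rng.normal(0.0, jitter_sd_ms, size=copied.size)
        bg = poisson_train(rate_hz * (1.0 - rho), duration_s, rng)
        t = np.concatenate([copied, bg])
        t = t[(t >= 0) & (t < duration_s * 1000.0)]
        out.append(_dedupe(t))
    return out[0], out[1]


def generate_event_processes(cfg: SynthConfig) -> tuple[dict, GroundTruth]:
    """Per-channel event trains for every band, honouring the coupling list.

    For each coupling a parent Poisson process at the band's target rate is
    drawn; both member channels copy parent events with probability rho (plus
    jitter).  Each channel's background rate is the target rate minus the
    rate it inherits from its couplings — a negative background (over-coupled
    channel) is an error.
    """
    rng = np.random.default_rng(cfg.seed)
    dur_ms = cfg.duration_s * 1000.0
    band_trains: dict[str, list[EventTrain]] = {}
    for band, rate in cfg.band_rates.items():
        contributions: list[list[np.ndarray]] = [[] for _ in range(cfg.n_channels)]
        copied_rate = np.zeros(cfg.n_channels)
        for c in (c for c in cfg.couplings if c.band == band):
            parent = poisson_train(rate, cfg.duration_s, rng)
            for ch in (c.i, c.j):
                copied = parent[rng.random(parent.size) < c.rho]
                if c.jitter_sd_ms > 0:
                    copied = copied + rng.normal(0.0, c.jitter_sd_ms, copied.size)
                contributions[ch].append(copied)
                copied_rate[ch] += c.rho * rate
        trains = []
        for ch in range(cfg.n_channels):
            bg_rate = rate - copied_rate[ch]
            if bg_rate < -1e-9:
                raise ValueError(
                    f"channel {ch} is over-coupled in band {band!r}: "
                    f"copied rate {copied_rate[ch]:.2f} exceeds target {rate:.2f}"
                )
            parts = contributions[ch] + [poisson_train(max(bg_rate, 0.0),
                                                       cfg.duration_s, rng)]
            t = np.concatenate(parts) if parts else np.array([])
            t = _dedupe(t[(t >= 0) & (t < dur_ms)])
            trains.append(EventTrain(label=f"ch{ch}", times_ms=t))
        band_trains[band] = trains

    spike_trains = [poisson_train(cfg.spike_rate_per_s, cfg.duration_s, rng)
                    for _ in range(cfg.n_channels)]
    spike_trains = [_dedupe(t, min_gap_ms=2 * cfg.spike_width_ms) for t in spike_trains]
    return band_trains, GroundTruth(
        band_trains=band_trains, spike_trains=spike_trains,
        couplings=list(cfg.couplings),
    )


def pink_noise(n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """1/f-power noise via spectral shaping, scaled to the given sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    return x * (sd / x.std())


def _burst_waveform(center_hz: float, cycles: int, fs: float) -> np.ndarray:
    width_s = cycles / center_hz
    n = max(3, int(round(width_s * fs)) | 1)
    t = (np.arange(n) - n // 2) / fs
    return np.hanning(n) * np.cos(2 * np.pi * center_hz * t)


def spike_waveform(width_ms: float, fs: float,
                   sharp_sigma_ms: float = 3.0) -> np.ndarray:
    """Interictal-spike transient: sharp biphasic peak plus after-going slow wave.

    The sharp component (derivative of a Gaussian, sd ``sharp_sigma_ms``)
    carries the broadband energy that spectral whitening accentuates; the
    slower wave fills out the ~``width_ms`` envelope.  Unit peak amplitude.
    """
    n = max(3, int(round(width_ms * fs / 1000.0)) | 1)
    t = (np.arange(n) - n // 2) * 1000.0 / fs  # ms
    s = sharp_sigma_ms
    sharp = -t / s * np.exp(-(t ** 2) / (2 * s ** 2))
    slow = -0.35 * np.exp(-((t - 0.3 * width_ms) ** 2) / (2 * (0.18 * width_ms) ** 2))
    w = sharp + slow
    return w / np.abs(w).max()


def _add_at(trace: np.ndarray, waveform: np.ndarray, times_ms: np.ndarray,
            fs: float) -> None:
    half = waveform.size // 2
    n = trace.size
    for t in times_ms:
        c = int(round(t * fs / 1000.0))
        lo, hi = c - half, c + half + 1
        wlo = max(0, -lo)
        whi = waveform.size - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if hi > lo:
            trace[lo:hi] += waveform[wlo:whi]


def render_recording(
    band_trains: dict,
    cfg: SynthConfig,
    spike_trains: list | None = None,
    channel_labels: list[str] | None = None,
) -> Recording:
    """Render event trains into a µV voltage matrix.

    Band events become Hann-windowed sinusoidal bursts at the band's centre
    frequency; spikes become biphasic transients; pink noise is added last.
    The noise generator is seeded from the config seed so rendering is
    deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    n = int(round(cfg.duration_s * cfg.fs))
    labels = channel_labels or [f"ch{i}" for i in range(cfg.n_channels)]
    data = np.zeros((cfg.n_channels, n))
    for band, trains in band_trains.items():
        wf = _burst_waveform(BAND_CENTER_HZ[band], cfg.burst_cycles, cfg.fs)
        wf = wf * cfg.burst_amp_uv
        for ch, tr in enumerate(trains):
            _add_at(data[ch], wf, tr.times_ms, cfg.fs)
    if spike_trains is not None:
        swf = spike_waveform(cfg.spike_width_ms, cfg.fs) * cfg.spike_amp_uv
        for ch, times in enumerate(spike_trains):
            _add_at(data[ch], swf, np.asarray(times), cfg.fs)
    if cfg.noise_sd_uv > 0:
        for ch in range(cfg.n_channels):
            data[ch] += pink_noise(n, rng, sd=cfg.noise_sd_uv)
    return Recording(data=data, fs=cfg.fs, channel_labels=labels)


def make_decay_pairs(
    n_pairs: int = 24,
    A: float = 0.9,
    tau: float = 0.09,
    d_min_mm: float = 3.0,
    d_max_mm: float = 40.0,
    rate_hz: float = 2.0,
    duration_s: float = 300.0,
    jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Disjoint coupled pairs whose copy probability follows rho = A exp(-tau d).

    Returns (distances_mm, [(train_i, train_j), ...]).  Sparse burst trains
    (a few events per second over minutes) keep the lag histogram dominated
    by genuinely shared events rather than chance coincidences — the regime
    in which the connectivity index responds near-linearly to the shared
    fraction, so the decay constant survives the h transform.
    """
    ss = np.random.SeedSequence(seed)
    ds = np.linspace(d_min_mm, d_max_mm, n_pairs)
    pairs = []
    for k, (d, child) in enumerate(zip(ds, ss.spawn(n_pairs))):
        rho = float(np.clip(A * np.exp(-tau * d), 0.0, 1.0))
        rng = np.random.default_rng(child)
        pairs.append(coupled_pair_trains(rate_hz, duration_s, rho,
                                         jitter_sd_ms, rng))
    return ds, pairs


# ---------------------------------------------------------------------------
# study-level generation


def _default_metadata(n_channels: int, n_soz: int, rng: np.random.Generator) -> pd.DataFrame:
    """Channel table with SOZ contacts clustered mesially in one hemisphere."""
    regions = (["M"] * max(3, n_channels // 3)
               + ["L"] * max(3, n_channels // 3)
               + ["E"] * n_channels)[:n_channels]
    hemis = ["L" if i < int(0.75 * n_channels) else "R" for i in range(n_channels)]
    # SOZ contacts sit close together; others are spread out
    coords = np.empty((n_channels, 3))
    coords[:n_soz] = rng.normal([-25.0, -20.0, -15.0], 4.0, size=(n_soz, 3))
    coords[n_soz:] = rng.uniform([-60, -60, -30], [60, 20, 40],
                                 size=(n_channels - n_soz, 3))
    return pd.DataFrame({
        "label": [f"ch{i}" for i in range(n_channels)],
        "x_mm": coords[:, 0], "y_mm": coords[:, 1], "z_mm": coords[:, 2],
        "region": regions,
        "soz": [1 if i < n_soz else 0 for i in range(n_channels)],
        "hemisphere": hemis,
        "gray_matter": 1,
        "noise_free": 1,
    })


def make_patient(
    patient_id: str,
    outcome: str,
    seed: int,
    n_channels: int = 8,
    n_soz: int = 3,
    duration_s: float = 120.0,
    rho_focus: float = 0.4,
    rho_background: float = 0.12,
    jitter_sd_ms: float = 2.0,
    spike_rate_soz: float = 0.25,
    spike_rate_nsoz: float = 0.05,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """One synthetic patient: recording, metadata, ground truth.

    Seizure-free (SF) patients carry the elevated coupling ``rho_focus``
    inside the SOZ — the labelled zone is the true focus.  Not-seizure-free
    (NSF) patients carry it in a designated non-SOZ subset instead (the
    focus the labelling missed), so inside- and outside-SOZ coupling look
    alike.  Gamma-band couplings only; theta stays at background.
    """
    rng = np.random.default_rng(seed)
    meta = _default_metadata(n_channels, n_soz, rng)

    soz = list(range(n_soz))
    nsoz = list(range(n_soz, n_channels))
    couplings: list[Coupling] = []
    if outcome == "SF":
        focus, spiky = soz, soz
    elif outcome == "NSF":
        focus, spiky = nsoz[:n_soz], nsoz[:n_soz]
    else:
        raise ValueError("outcome must be 'SF' or 'NSF'")
    import itertools

    for band in ("low_gamma", "high_gamma"):
        n_f = len(focus)
        rho_f = min(rho_focus, 0.95 / max(1, n_f - 1))
        for a, b in itertools.combinations(focus, 2):
            couplings.append(Coupling(a, b, band, rho_f, jitter_sd_ms))
        rest = [c for c in range(n_channels) if c not in focus]
        for a, b in zip(rest[0::2], rest[1::2]):
            couplings.append(Coupling(a, b, band, rho_background, jitter_sd_ms))

    spike_rates = np.full(n_channels, spike_rate_nsoz)
    spike_rates[spiky] = spike_rate_soz

    cfg = SynthConfig(
        n_channels=n_channels, duration_s=duration_s,
        couplings=couplings, seed=seed,
    )
    band_trains, truth = generate_event_processes(cfg)
    # per-channel spike rates replace the scalar default
    rng2 = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
    spikes = [
        _dedupe(poisson_train(r, duration_s, rng2), min_gap_ms=2 * cfg.spike_width_ms)
        for r in spike_rates
    ]
    truth.spike_trains = spikes
    truth.metadata = meta
    rec = render_recording(band_trains, cfg, spike_trains=spikes,
                           channel_labels=list(meta["label"]))
    return rec, meta, truth


def make_study(
    n_patients: int = 4,
    seed: int = 0,
    n_sf: int | None = None,
    **patient_kwargs,
) -> list[dict]:
    """A small synthetic cohort: SF and NSF patients with ground truth."""
    n_sf = n_patients // 2 if n_sf is None else n_sf
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_patients)]
    study = []
    for k in range(n_patients):
        outcome = "SF" if k < n_sf else "NSF"
        pid = f"P{k + 1:02d}"
        rec, meta, truth = make_patient(pid, outcome, seed=child_seeds[k],
                                        **patient_kwargs)
        study.append({
            "patient": pid, "outcome": outcome,
            "recording": rec, "metadata": meta, "truth": truth,
        })
    return study


def simulate_pair_table(
    n_patients: int = 20,
    n_channels: int = 10,
    n_soz: int = 3,
    base_h: float = 0.10,
    effect_inside_sf: float = 0.02,
    beta_distance: float = -0.0008,
    beta_spike: float = 0.01,
    sd_patient: float = 0.02,
    sd_noise: float = 0.04,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Parametric pair-table generator for exercising the statistics stage.

    h = base + patient intercept + effect*(inside & SF)
         + beta_d*distance + beta_s*spike_rate + noise,  clipped to [0, 1].

    Half the patients are SF.  Returns the table and the true parameters.
    """
    import itertools

    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_patients):
        pid = f"P{k + 1:02d}"
        outcome = "SF" if k < n_patients // 2 else "NSF"
        re_p = rng.normal(0.0, sd_patient)
        soz = rng.choice(n_channels, size=n_soz, replace=False)
        regions = rng.choice(["M", "L", "E"], size=n_channels)
        for a, b in itertools.combinations(range(n_channels), 2):
            inside = a in soz and b in soz
            outside = a not in soz and b not in soz
            zone = "inside" if inside else ("outside" if outside else "between")
            d = rng.uniform(5.0, 80.0)
            spike = rng.exponential(0.2)
            h = (base_h + re_p
                 + effect_inside_sf * (inside and outcome == "SF")
                 + beta_distance * d + beta_spike * spike
                 + rng.normal(0.0, sd_noise))
            rp = "-".join(sorted([regions[a], regions[b]],
                                 key={"M": 0, "L": 1, "E": 2}.__getitem__))
            rows.append({
                "patient": pid, "channel_i": f"ch{a}", "channel_j": f"ch{b}",
                "h_theta": np.nan, "h_lg": np.nan,
                "h_hg": float(np.clip(h, 0.0, 1.0)),
                "spike_rate": spike, "distance_mm": d,
                "zone_pair": zone, "region_pair": rp, "outcome": outcome,
            })
    truth = {
        "base_h": base_h, "effect_inside_sf": effect_inside_sf,
        "beta_distance": beta_distance, "beta_spike": beta_spike,
        "sd_patient": sd_patient, "sd_noise": sd_noise,
    }
    return pd.DataFrame(rows), truth
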