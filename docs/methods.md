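# Methods

## The connectivity model

Band-event connectivity treats each channel's band-limited signal as a point
process: the local amplitude maxima of the filtered trace.  A sample is an
event iff it exceeds *both* adjacent samples by at least a threshold
(default 0.1 µV) — the neighbour-exceedance semantics of the classic
findpeaks `Threshold` parameter, not a minimum absolute height.  At 1 kHz a
unit-amplitude 40-Hz cycle changes by only ~0.03 between adjacent samples,
so the default threshold presumes realistic iEEG amplitudes (tens of µV);
the threshold is configurable and scales with the amplitude unit.

For a channel pair (x, y), every ordered event pair with lag
t_y − t_x ∈ [−T, T) contributes one count to a histogram with half-open
2-ms bins whose edges are multiples of the bin width from −T.  The 2-ms bin
reflects the time resolution a 1-kHz rate supports; T = ⌈1000/f_min⌉ ms is
one period of the slowest in-band oscillation (34 ms / 34 bins for
30–55 Hz, 16 ms / 16 bins for 65–95 Hz, 250 ms / 250 bins for 4–8 Hz).
All event pairs contribute, not nearest neighbours only; this is the
standard cross-correlogram construction.  The histogram entropy
S = −Σ p ln p (natural log, 0·ln 0 := 0) is normalized into
h = (ln N − S)/ln N.  h is computed once per unordered pair and assigned to
both matrix cells, so the matrix is symmetric bit-for-bit; computing the two
directions separately could differ at bin boundaries.

### Windowing and validity

Recordings are cut into M = ⌊duration/L⌋ non-overlapping windows (trailing
partial window discarded; L defaults 30/60/300 s for high-gamma/low-gamma/
theta).  A pair-window is *valid* when its histogram holds at least
`min_events_per_bin × N` lag observations (default 30 per bin, i.e. 1020
total for low gamma, reachable in ≈24 s at the band's 42.5-Hz mean event
rate).  Invalid pair-windows are excluded from the across-window mean rather
than zero-filled, and the number of windows used is reported per pair.  For
theta the rule is arithmetically unsatisfiable at the default L (250 bins ×
30 = 7500 events ≈ 1250 s at 6 Hz), so theta validity is configurable and
reported instead of silently enforced; `BandSpec.window_satisfies_validity`
exposes the check.

### Finite-sample behaviour

For independent stationary trains h does not reach 0: the multinomial
sampling noise of a count-limited histogram leaves an entropy deficit of
order (N−1)/(2·total), giving a bias floor h ≈ (N−1)/(2·total·ln N) that
shrinks as counts grow.  The null-calibration tests measure exactly this,
and the circular-shift permutation null is the recommended reference for
deciding whether an observed h exceeds chance.

## Preprocessing

Resampling to 1 kHz uses polyphase rational resampling with a Kaiser-window
FIR cutting at 0.9× the tighter Nyquist; a 1-kHz input is returned
untouched.  The 60-Hz notch is a zero-phase IIR band-stop of 4 Hz width
(Q = 15; centre configurable for 50-Hz mains).  Band-pass filters are
windowed-sinc (Hamming) FIRs with transition width max(2 Hz, 20% of the
lower edge), applied forward–backward.  Zero phase everywhere is essential:
the index is built from millisecond lead/lag structure, and any
channel-dependent group delay would forge or destroy coupling.  Segment
selection (quiet wakefulness, >24 h post implantation, ≥6 h from the next
seizure) is purely metadata-driven; nothing is inferred from the signal.

## Spike detection and coupling

Interictal spikes are broadband transients on a strongly 1/f background.
The detector divides the amplitude spectrum by its running-median envelope
(median smoothing over 4-Hz neighbourhoods), keeping phase — robust spectral
whitening — then thresholds local maxima of the robust z-score
(median/MAD-based, default z ≥ 6) with a greedy amplitude-ranked refractory
rule (default 50 ms).  The defaults are deliberately conservative (<1 false
detection per 10 min of pink noise) because no human review step follows.
The pairwise coupling rate is r_ij = (n_i + n_j)/duration in events/s; a
per-minute option exists because both conventions appear in the literature.
Note r_ij is a sum of marginal rates, hence the exact additivity identity
r_ij + r_kl = r_il + r_kj; it carries no timing information by design.

## Distance decay and statistics

Inter-contact distances are Euclidean in MNI millimetres.  The decay model
s = A·e^(−τd) is fitted by trust-region nonlinear least squares on all pairs
with a finite strength (listwise deletion), unweighted, τ ≥ 0 and
A ∈ [0, 1.5], initialized from a log-domain linear fit on the positive
strengths; the returned fit is never worse than the best constant model
(which lies in the parameter space at τ = 0).

The group model is a linear mixed model fitted by REML with a random
intercept per patient and no random slopes: pairs within a patient share
recording conditions and geometry, which the intercept absorbs, while the
per-pair fixed structure (zone pair × outcome, optionally region pair)
carries the hypotheses, with spike-coupling rate and distance as covariates.
Estimated marginal means are computed on the crossed factor grid with
covariates at their grand means; all pairwise cell differences form the
contrast family, tested with Wald z statistics and Bonferroni-corrected over
that family.  Singular or non-converged fits are flagged on the result
object, never dropped.  The dependent variable is untransformed by default,
with optional log and rank transforms.  Rank-sum tests use the exact null
distribution for tie-free samples up to n = 25, the tie-corrected normal
approximation otherwise; Cohen's d uses the unbiased pooled SD.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics of seizure networks.  Band events are homogeneous Poisson
processes; a coupled pair shares a *parent* process, each channel copying
parent events with probability ρ and independent Gaussian jitter (sd σ per
channel, so the pairwise lag sd is σ√2), topped up with independent
background events so every channel keeps its target rate.  An over-coupled
channel (copied rate exceeding the target) is rejected.  Rendered
recordings place a 3-cycle Hann-windowed burst at the band's centre
frequency at each event (default 25 µV against 5 µV pink noise), biphasic
sharp transients (70 ms envelope, 3-ms sharp core, default 40 µV = 8× the
noise SD) at spike times, and pink noise on top.  Default burst rates
(3/8/10 events/s for theta/low-/high-gamma) are rates of *distinct* bursts,
sparse enough that rendered bursts rarely overlap and each ground-truth
event maps onto one detectable peak.

What the generator does not emulate: continuous oscillations whose every
cycle is an event (filtered background noise supplies a dense unrelated
event stream instead, which realistically dilutes h to the ~10⁻³–10⁻² range
seen in the study pipeline), non-stationarity, sleep/wake structure, volume
conduction, and electrode artefacts.  Passing tests therefore show that the
estimator chain recovers known coupling structure under its own model
assumptions — not that it is robust to everything real recordings contain.

Synthetic cohorts assign elevated gamma coupling inside the labelled SOZ for
seizure-free patients and inside a designated *non*-SOZ subset for
not-seizure-free patients (the focus the labelling missed) — the structure
the group statistics are meant to detect.  Within a focus of k channels the
per-pair copy probability is capped at 0.95/(k−1) so no channel is
over-coupled.  A fixed integer seed determines every draw; identical seeds
give byte-identical recordings, metadata and ground truth.

## Study conditions for the recovery experiments

- **Coupling monotonicity** uses single pairs at 8 events/s over 60 s,
  ρ ∈ {0, 0.25, 0.5, 0.75, 1} at σ = 0 and σ ∈ {0, 2, 5, 10, 20} ms at
  ρ = 0.75, 20 replicate seeds per level.
- **Distance-decay recovery** uses 24 disjoint pairs with
  ρ(d) = 0.9·e^(−0.09d) over 3–40 mm, sparse burst trains (2 events/s,
  300 s).  Sparseness matters: when shared events dominate chance
  coincidences, h responds near-linearly to the shared fraction and the
  decay constant survives the entropy transform.  At denser rates the h(ρ)
  map is convex (chance pairs flood the histogram) and a naive exponential
  fit on h overestimates τ by up to ~2× — a documented limitation of
  fitting the decay on the index rather than on the underlying copy
  probability.
- **Statistics recovery** uses the table-level generator (20 patients, 10
  channels, 3 SOZ, residual sd 0.04, patient sd 0.02, injected +0.02
  inside-SOZ effect in SF only); the type-I check runs 200 null replicates
  at 12 patients × 8 channels.  Table-level simulation keeps these runs in
  seconds while exercising the full model/contrast machinery.
- The signal-level demonstration study is 4 patients × 8 contacts × 120 s,
  with theta windows shortened to 60 s so at least one window fits.

## Known limitations

- The FIR orders and the exact resampling polyphase design are this
  package's choices; other zero-phase designs meeting the same pass/stop
  contracts would give equivalent results.
- h is not a calibrated coupling probability: it depends on event rates,
  window length and bin count, so comparisons are only meaningful within a
  fixed band specification.
- The decay fit on h inherits the index's nonlinearity (see above).
- EDF files are read (via mne) but not written; the generator emits
  delimited matrices + TSV metadata, which the pipeline accepts equally.
- Wald-based contrast p-values are asymptotic in the number of patients;
  with very few patients a parametric bootstrap would be preferable.
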