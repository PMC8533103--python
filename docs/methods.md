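# Methods

## Signal model

A chamber covered by a static rectangular ROI produces a per-frame mean
grey level that oscillates with the cardiac cycle: blood filling and
ejection change the local optical density, so the ROI mean is a
quasi-periodic signal whose trough-to-trough (or peak-to-peak) spacing is
the inter-beat interval. The analysis assumes:

- the animal is immobilized (e.g. in methylcellulose), so a static box
  placed once on the first frame stays over its chamber for the whole clip;
- the frame rate is constant and high enough to resolve the beat (≥ 10
  samples per cycle is comfortable; 200 fps for a 2.5 Hz zebrafish heart
  gives 80);
- the clip is at least 10 frames long; clips longer than 2000 frames (the
  10 s × 200 fps protocol ceiling) are truncated to their first 2000 frames
  with a warning, which bounds memory and keeps interval counts comparable
  across clips.

Beats are anchored on signal minima (troughs). Whether a chamber darkens
or brightens on contraction depends on optics; the conditioning chain is
sign-agnostic (`beat_anchor="peak"` flips the anchor) and every rate and
interval statistic is unchanged by a global sign flip, only the absolute
beat phase moves.

## Conditioning chain

1. **Normalization** to zero mean, unit variance (sample n−1 convention;
   population convention via `normalize_ddof=0`). A flat series is rejected
   as "no cardiac motion detected".
2. **Cubic smoothing spline** with squared-residual budget `s`. Default
   `s = n·σ̂²` with `σ̂ = median(|Δx|)/√2`, the robust noise scale from
   successive differences — the spline absorbs exactly the expected noise
   energy, so a noiseless signal passes through unchanged (`s=0`
   interpolates exactly).
3. **Zero-phase Butterworth bandpass**, 2nd order, applied
   forward–backward so peak times are not shifted by the filter's phase
   response. Presets: zebrafish 0.5–5 Hz, daphnia 2–15 Hz (ultrafast
   hearts need their own scale).
4. **Extremum detection**: local maxima/minima with prominence ≥ 0.3
   signal standard deviations (scale-invariant) and same-type spacing of at
   least one minimal beat period (60/max_bpm; 400 bpm zebrafish, 900
   daphnia). A cleanup pass enforces strict max/min interleaving by
   dropping the lesser of two same-type neighbours.

Smoothing before filtering is the default order; both steps are individually
optional and the order is a deliberate choice, not a constraint — the
bandpass dominates the final waveform shape, the spline mainly stabilizes
prominence estimates on noisy series.

## Endpoints

- **Rate**: `bpm = 60 / mean(interval)`, the mean over the (count − 1)
  consecutive trough-time differences. Exactly equivalent to 60 divided by
  the mean inter-beat interval in seconds.
- **Intervals**: A-A/V-V are consecutive differences of one chamber's beat
  times; A-V pairs each atrium beat with the earliest ventricle beat
  strictly after it (deterministic under jitter; unpaired trailing beats
  are dropped), V-A symmetrically.
- **Poincaré sd1/sd2**: population standard deviations of
  `(I_{n+1} − I_n)/√2` and `(I_{n+1} + I_n)/√2`. For i.i.d. Gaussian
  jitter of sd σ on beat *times*, sd1 → σ√3 (successive interval
  differences are `ε_{k+2} − 2ε_{k+1} + ε_k`, variance 6σ²), which is the
  closed form the recovery tests check.
- **Cross-correlation**: `r(d)` correlates `x_i` with `y_{i+d}`; positive
  lag means y (ventricle) lags x (atrium). Out-of-range points of the
  shifted series are zero after mean-centering; the denominator uses the
  full-series sums of squares, so `|r| ≤ 1` everywhere (Cauchy–Schwarz)
  and swapping the series exactly mirrors the lag axis. Because two
  near-periodic signals only identify their relative delay modulo the beat
  period, the pipeline searches lags within ± half the measured mean beat
  period; the peak lag × frame duration is the conduction-delay estimate.
  The correlation is a coupling diagnostic only — it never feeds the rate.

## Frame clock

Timestamps are `frame_index / fps`, first frame at t = 0. Two
compatibility constants are provided for comparisons against older
workflows: `paper_compat` truncates 1/fps to three decimals (0.005 s at
200 fps, 0.016 s at 60 fps — a truncation, not a round), biasing the rate
by ≈ 0.4% at 60 fps, which is why exact 1/fps is the default. The
slow-motion factor for footage acquired at `f_a` but re-rendered at `f_p`
is `f_a/f_p` truncated to one decimal (200→30 fps gives 6.6); intervals
measured on the playback clock are multiplied by it to recover acquisition
time.

## Synthetic generator

The generator emulates the acquisition geometry: two ellipses (atrium,
ventricle) on a flat background, each carrying a raised-cosine intensity
pulse of configurable width at each of its beat times, i.i.d. Gaussian
pixel noise, clipped to [0, 255] and quantized to 8 bits. Beat times are
an arithmetic grid at `mean_bpm` with optional i.i.d. Gaussian jitter per
beat time; ventricle beats are atrium beats plus a fixed `av_delay_s`.
Defaults are the reference regime: 200 fps, 10 s, 150 bpm, 0.1 s A-V
delay, baseline 100, amplitude 80, pulse width 0.15 s, noise sd 5.
The raised cosine (not a sinusoid) makes the beat *time* a well-defined
point — the pulse extremum — so trough alignment can be checked against
ground truth. Pulses are bright by default; `pulse_sign="dark"` makes
contraction dip the intensity, placing the signal troughs exactly at the
beat times, which is the configuration the beat-time alignment tests use.
Identical spec + seed reproduces frames bit for bit (beat-time draws and
pixel noise use separate seeded streams).

Not emulated: chamber morphology and wall motion, blood-cell texture,
illumination drift, body drift. Recovery tests therefore validate the
signal chain and its statistics, not robustness to motion artifacts in
real recordings.

## Containers

Uncompressed 8-bit RIFF/AVI is read and written natively (bottom-up DIB
rows, grey-ramp palette; 24-bit BGR frames are accepted and converted with
BT.601 luminance weights, the mainstream video-decoder convention). This
round trip is bit-exact, which the round-trip invariants rely on. mp4 and
compressed AVI are routed through imageio and need an ffmpeg backend; when
none is present the decode error says so explicitly.

## Problem sizes and numerical choices

The test and acceptance workloads use small frames (128×96 and below) at
the protocol frame rates: 2000 frames at 200 fps for the reference regime,
2400 frames at 60 fps over 40 s (~100 beats) for regularity recovery, 1800
frames at 300 fps for the ultrafast regime. The 60 fps choice for the
jitter study balances beat count against trough quantization: each
detected trough is quantized to ± half a frame (variance (1/fps)²/12),
which at 30 fps would inflate sd1 by ~40% over the true-beat-time value
but at 60 fps by ~10%, well inside the 30% recovery tolerance. The
regularity analysis composes the stages directly rather than going through
the 2000-frame gate, which would truncate the 2400-frame clip to 83 beats.

Other numerical details: trough spacing constraints round to whole frames
(minimum 1); the spline uses FITPACK's knot placement under the residual
budget; `filtfilt` padding is capped at series length − 1 so short series
remain filterable; `round_half_up` implements floor(x + 0.5), ties toward
+∞, and is used only for the rounded-bpm display column, never inside the
computation.

## Known limitations

- Static ROIs: a drifting animal invalidates the box (no tracking).
- No automatic chamber segmentation; boxes come from config or prompt.
- Variable-frame-rate containers are not supported; fps metadata must be
  present or overridden.
- Cross-correlation delay is reported modulo the beat period (inherent to
  periodic signals).
- The frequency resolution of the FFT cross-check is fps/n; short clips
  give coarse spectral estimates, which is why the interval-based rate is
  the primary endpoint.
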