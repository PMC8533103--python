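"""Signal conditioning and beat detection.

Raw ROI traces are smoothed with a cubic smoothing spline, bandpass
filtered with a zero-phase Butterworth filter to isolate the cardiac band,
and scanned for local maxima and minima.  Beats are anchored on the minima
(troughs); an FFT-based dominant-frequency estimate provides an independent
spectral cross-check of the beat rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.signal import butter, filtfilt, find_peaks

from .errors import BandError

#: Organism presets: cardiac band (Hz) and physiological rate ceiling (bpm).
#: Zebrafish larvae beat at 2-3 Hz; Daphnia reach ultrafast rates near 10 Hz
#: and need a separate scale.
PRESETS = {
    "zebrafish": {"band": (0.5, 5.0), "max_bpm": 400.0},
    "daphnia": {"band": (2.0, 15.0), "max_bpm": 900.0},
}


@dataclass
class ProcessedSignal:
    """Conditioned intensity series plus a full provenance record of how it
    was produced (no silent defaults)."""

    values: np.ndarray
    fps: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PeakSet:
    """Detected signal extrema as 0-based frame indices.

    After cleanup maxima and minima strictly interleave; minima (troughs)
    are the beat markers.
    """

    maxima_indices: np.ndarray
    minima_indices: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.maxima_indices = np.asarray(self.maxima_indices, dtype=int)
        self.minima_indices = np.asarray(self.minima_indices, dtype=int)

    def times(self, which: str, frame_dur: float | None = None) -> np.ndarray:
        idx = self.maxima_indices if which == "max" else self.minima_indices
        dur = frame_dur if frame_dur is not None else 1.0 / self.fps
        return idx * dur


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise scale estimate: median absolute successive difference / sqrt(2).

    Successive differences of a smooth signal are dominated by the additive
    noise, whose difference has variance 2 sigma^2; the median keeps the
    estimate robust to the beat transients.
    """
    values = np.asarray(values, dtype=float)
    diffs = np.abs(np.diff(values))
    return float(np.median(diffs)) / np.sqrt(2.0)


def smooth_spline(
    values: np.ndarray,
    smoothing_factor: float | None = None,
    fps: float | None = None,
) -> ProcessedSignal:
    """Cubic smoothing spline evaluated back at every frame index.

    ``smoothing_factor`` is the total squared-residual budget s of the
    spline fit; 0 interpolates the samples exactly.  The default budget is
    n * sigma^2 with sigma the robust noise estimate, i.e. the spline is
    allowed to absorb exactly the expected noise energy.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError(f"spline smoothing needs >= 4 samples, got {n}")
    if smoothing_factor is None:
        smoothing_factor = n * robust_noise_sd(values) ** 2
    if smoothing_factor < 0:
        raise ValueError("smoothing_factor must be non-negative")
    x = np.arange(n, dtype=float)
    spline = UnivariateSpline(x, values, k=3, s=smoothing_factor)
    return ProcessedSignal(
        values=spline(x),
        fps=fps if fps is not None else float("nan"),
        provenance={"smoothing_factor": float(smoothing_factor)},
    )


def bandpass(
    values: np.ndarray, fps: float, low_hz: float, high_hz: float
) -> ProcessedSignal:
    """Zero-phase 2nd-order Butterworth bandpass.

    Forward-backward filtering cancels the phase response so peak times are
    not shifted; DC is removed and in-band sinusoid amplitudes are preserved
    within a few percent.
    """
    values = np.asarray(values, dtype=float)
    nyquist = fps / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise BandError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist} Hz at {fps} fps"
        )
    b, a = butter(2, [low_hz, high_hz], btype="bandpass", fs=fps)
    padlen = min(3 * (max(len(a), len(b)) - 1) * 10, len(values) - 1)
    filtered = filtfilt(b, a, values, padlen=padlen)
    return ProcessedSignal(
        values=filtered,
        fps=fps,
        provenance={"band_hz": (float(low_hz), float(high_hz)), "filter": "butter2-filtfilt"},
    )


def detect_peaks(
    values: np.ndarray,
    fps: float,
    max_bpm: float = 400.0,
    prominence_frac: float = 0.3,
) -> PeakSet:
    """Locate beat maxima and minima.

    A candidate extremum must rise (fall) by at least ``prominence_frac``
    standard deviations of the signal and be separated from its neighbour of
    the same type by at least one minimal physiological beat period
    (60/max_bpm seconds).  Prominence is sd-relative, so detection is
    invariant to positive amplitude rescaling.  A final cleanup enforces
    strict max/min interleaving by dropping the lesser of two same-type
    neighbours.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError(f"peak detection needs >= 3 samples, got {len(values)}")
    sd = values.std()
    if sd == 0:
        return PeakSet(np.array([], int), np.array([], int), fps)
    distance = max(1, int(round(fps * 60.0 / max_bpm)))
    prominence = prominence_frac * sd
    maxima, _ = find_peaks(values, prominence=prominence, distance=distance)
    minima, _ = find_peaks(-values, prominence=prominence, distance=distance)
    maxima, minima = _enforce_interleaving(values, maxima, minima)
    return PeakSet(maxima, minima, fps)


def _enforce_interleaving(
    values: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the lesser of two same-type neighbours until extrema alternate."""
    events = sorted(
        [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    )
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx, _ = kept[-1]
            if kind == "max":
                keep_new = values[idx] > values[prev_idx]
            else:
                keep_new = values[idx] < values[prev_idx]
            if keep_new:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    new_max = np.array([i for i, k in kept if k == "max"], dtype=int)
    new_min = np.array([i for i, k in kept if k == "min"], dtype=int)
    return new_max, new_min


def dominant_frequency(
    values: np.ndarray,
    fps: float,
    band: tuple[float, float] = (0.5, 5.0),
) -> tuple[float, float]:
    """Frequency (Hz) of the largest discrete-spectrum magnitude within band.

    Returns ``(frequency, resolution)`` where resolution = fps / n is the
    spacing of the discrete spectrum — the irreducible uncertainty of the
    estimate.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    low, high = band
    nyquist = fps / 2.0
    if not (0 <= low < high <= nyquist):
        raise BandError(
            f"band ({low}, {high}) Hz must lie within [0, Nyquist = {nyquist}] Hz"
        )
    spectrum = np.abs(np.fft.rfft(values - values.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    mask = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not mask.any():
        raise BandError(f"band ({low}, {high}) Hz contains no spectral bins at n={n}")
    idx = np.argmax(spectrum[mask])
    return float(freqs[mask][idx]), float(fps / n)
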