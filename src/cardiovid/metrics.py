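"""Cardiac rhythm endpoints.

Beat series (trough times per chamber) are turned into the study endpoints:
beats per minute (60 over the mean inter-beat interval), same-chamber
(A-A, V-V) and cross-chamber (A-V, V-A) interval series, Poincare sd1/sd2
regularity, and the lagged normalized cross-correlation between the two
chamber signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientBeatsError
from .roi import ChamberLabel


@dataclass
class BeatSeries:
    """Beat times of one chamber, in seconds, strictly increasing."""

    label: ChamberLabel
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @classmethod
    def from_minima(
        cls,
        label: ChamberLabel,
        minima_indices: np.ndarray,
        frame_dur: float,
        slowdown: float = 1.0,
    ) -> "BeatSeries":
        """Beat times = trough frame indices x frame duration (x slowdown
        when the clip is slow-motion re-rendered footage)."""
        times = np.asarray(minima_indices, dtype=float) * frame_dur * slowdown
        return cls(label=label, beat_times=times)

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)


@dataclass
class IntervalSeries:
    """A series of positive inter-beat intervals, in seconds.

    kind is AA or VV (same chamber, successive beats) or AV / VA
    (delay from one chamber's beat to the other chamber's next beat).
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("AA", "VV", "AV", "VA"):
            raise ValueError(f"unknown interval kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and not np.all(self.values > 0):
            raise ValueError(f"{self.kind} intervals must all be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")


@dataclass
class PoincareStats:
    """Poincare-plot dispersion of an interval series: sd1 is the spread
    perpendicular to the identity line (short-term, beat-to-beat
    variability), sd2 the spread along it (long-term variability)."""

    sd1: float
    sd2: float


@dataclass
class CrossCorr:
    """Normalized cross-correlation r(d) over integer lags d in [-D, D].

    Positive lag means the second series lags (is delayed relative to) the
    first; out-of-range points of the shifted series are treated as zero
    after mean-centering, so |r| <= 1 at every lag.
    """

    delays: np.ndarray
    r: np.ndarray

    @property
    def peak_lag(self) -> int:
        return int(self.delays[np.argmax(self.r)])

    @property
    def peak_r(self) -> float:
        return float(np.max(self.r))


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 ties going toward +infinity."""
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x}")
    return int(math.floor(x + 0.5))


def compute_bpm(minima_frames: np.ndarray, frame_dur: float) -> float:
    """Beats per minute from trough frame indices.

    bpm = 60 / mean inter-trough interval, the mean taken over the
    (count - 1) consecutive frame differences times the frame duration.
    """
    minima_frames = np.asarray(minima_frames, dtype=float)
    if len(minima_frames) < 2:
        raise InsufficientBeatsError(
            f"need >= 2 beats to compute a rate, got {len(minima_frames)}"
        )
    mean_interval = float(np.mean(np.diff(minima_frames))) * frame_dur
    return 60.0 / mean_interval


def compute_bpm_from_times(beat_times: np.ndarray) -> float:
    """bpm from beat times already in seconds."""
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 2:
        raise InsufficientBeatsError(
            f"need >= 2 beats to compute a rate, got {len(beat_times)}"
        )
    return 60.0 / float(np.mean(np.diff(beat_times)))


def chamber_intervals(beats: BeatSeries) -> IntervalSeries:
    """Same-chamber beat-to-beat intervals (A-A for the atrium, V-V for the
    ventricle): consecutive differences of the beat times."""
    if beats.n_beats < 2:
        raise InsufficientBeatsError(
            f"chamber '{beats.label.value}' has {beats.n_beats} beats; >= 2 required"
        )
    kind = "AA" if beats.label is ChamberLabel.ATRIUM else "VV"
    return IntervalSeries(kind=kind, values=np.diff(beats.beat_times))


def cross_chamber_intervals(
    atrium: BeatSeries, ventricle: BeatSeries
) -> tuple[IntervalSeries, IntervalSeries]:
    """A-V and V-A delays.

    For each atrium beat, A-V is the time to the earliest ventricle beat
    strictly after it (beats with no later partner are dropped); V-A is
    defined symmetrically.
    """
    av = _pair_intervals(atrium.beat_times, ventricle.beat_times, "AV")
    va = _pair_intervals(ventricle.beat_times, atrium.beat_times, "VA")
    return av, va


def _pair_intervals(src: np.ndarray, dst: np.ndarray, kind: str) -> IntervalSeries:
    if len(src) == 0 or len(dst) == 0:
        warnings.warn(f"{kind}: no beat pairs (one chamber has no beats)", stacklevel=3)
        return IntervalSeries(kind=kind, values=np.array([]))
    j = np.searchsorted(dst, src, side="right")
    valid = j < len(dst)
    if not valid.any():
        warnings.warn(f"{kind}: no beat pairs (no overlapping beats)", stacklevel=3)
        return IntervalSeries(kind=kind, values=np.array([]))
    return IntervalSeries(kind=kind, values=dst[j[valid]] - src[valid])


def poincare(intervals: IntervalSeries) -> PoincareStats:
    """Poincare sd1/sd2 of an interval series.

    On the scatter of consecutive interval pairs (I_n, I_{n+1}):
    sd1 = population sd of (I_{n+1} - I_n)/sqrt(2),
    sd2 = population sd of (I_{n+1} + I_n)/sqrt(2).
    """
    vals = intervals.values
    if len(vals) < 3:
        raise InsufficientBeatsError(
            f"Poincare statistics need >= 3 intervals, got {len(vals)}"
        )
    x, y = vals[:-1], vals[1:]
    sd1 = float(np.std((y - x) / np.sqrt(2.0)))
    sd2 = float(np.std((y + x) / np.sqrt(2.0)))
    return PoincareStats(sd1=sd1, sd2=sd2)


def cross_correlation(x: np.ndarray, y: np.ndarray, max_delay: int) -> CrossCorr:
    """Normalized cross-correlation of two equal-length series over lags
    d in [-max_delay, max_delay].

    r(d) correlates x_i with y_{i+d}: a positive peak lag means y lags x by
    that many samples (for atrium x and ventricle y, the peak lag estimates
    the A-V conduction delay in frames).  Points of the shifted series that
    fall outside the record are treated as zero after mean-centering; the
    normalization uses the full-series sums of squares, so every r stays in
    [-1, 1] (Cauchy-Schwarz) and swapping the series negates the lag axis
    exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"series length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 2:
        raise ValueError("cross-correlation needs series of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("cross-correlation undefined for a constant series")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(np.sum(xc**2)) * float(np.sum(yc**2)))
    delays = np.arange(-max_delay, max_delay + 1)
    r = np.empty(len(delays))
    for k, d in enumerate(delays):
        shifted = np.zeros(n)
        if d >= 0:
            m = n - d
            if m > 0:
                shifted[:m] = yc[d:]
        else:
            m = n + d
            if m > 0:
                shifted[-d:] = yc[:m]
        r[k] = float(np.dot(xc, shifted)) / denom
    return CrossCorr(delays=delays, r=r)


def rescale_intervals(intervals: IntervalSeries, factor: float) -> IntervalSeries:
    """Multiply every interval by a slow-motion factor.

    Intervals measured on the playback clock of re-rendered slow-motion
    footage are multiplied by the slowdown factor (e.g. 6.6 for 200 fps
    footage rendered at 30 fps) to recover acquisition time; pass 1/factor
    for the inverse direction.
    """
    if factor <= 0:
        raise ValueError(f"rescale factor must be positive, got {factor}")
    return IntervalSeries(kind=intervals.kind, values=intervals.values * factor)


@dataclass
class CardiacReport:
    """Aggregated per-clip endpoints plus provenance.

    bpm maps chamber name -> rate; interval_stats maps kind -> (mean, sd, n);
    poincare_stats maps chamber name -> PoincareStats of its same-chamber
    intervals; crosscorr_peak_r / crosscorr_peak_lag summarize the
    atrium-ventricle coupling diagnostic.
    """

    bpm: dict[str, float]
    interval_stats: dict[str, tuple[float, float, int]]
    poincare_stats: dict[str, PoincareStats]
    crosscorr_peak_r: float
    crosscorr_peak_lag: int
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chamber, value in sorted(self.bpm.items()):
            rows.append(("bpm", chamber, value, "beats/min"))
            rows.append(("bpm_rounded", chamber, float(round_half_up(value)), "beats/min"))
        for kind, (mean, sd, count) in sorted(self.interval_stats.items()):
            rows.append((f"interval_{kind}_mean", "", mean, "s"))
            rows.append((f"interval_{kind}_sd", "", sd, "s"))
            rows.append((f"interval_{kind}_n", "", float(count), "count"))
        for chamber, stats in sorted(self.poincare_stats.items()):
            rows.append(("poincare_sd1", chamber, stats.sd1, "s"))
            rows.append(("poincare_sd2", chamber, stats.sd2, "s"))
        rows.append(("crosscorr_peak_r", "", self.crosscorr_peak_r, "ratio"))
        rows.append(("crosscorr_peak_lag", "", float(self.crosscorr_peak_lag), "frames"))
        return pd.DataFrame(rows, columns=["metric", "chamber", "value", "units"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CardiacReport":
        df = pd.read_csv(path_or_buf, keep_default_na=False)

        def _num(v) -> float:
            return float(v) if str(v) != "" else float("nan")

        bpm: dict[str, float] = {}
        interval_stats: dict[str, list] = {}
        poincare_raw: dict[str, dict[str, float]] = {}
        peak_r = float("nan")
        peak_lag = 0
        for _, row in df.iterrows():
            metric, chamber, value = row["metric"], str(row["chamber"]), row["value"]
            if metric == "bpm":
                bpm[chamber] = _num(value)
            elif metric.startswith("interval_"):
                _, kind, stat = metric.split("_")
                interval_stats.setdefault(kind, [float("nan")] * 3)
                pos = {"mean": 0, "sd": 1, "n": 2}[stat]
                interval_stats[kind][pos] = _num(value)
            elif metric in ("poincare_sd1", "poincare_sd2"):
                poincare_raw.setdefault(chamber, {})[metric[-3:]] = _num(value)
            elif metric == "crosscorr_peak_r":
                peak_r = _num(value)
            elif metric == "crosscorr_peak_lag":
                peak_lag = int(_num(value))
        return cls(
            bpm=bpm,
            interval_stats={
                k: (v[0], v[1], int(v[2])) for k, v in interval_stats.items()
            },
            poincare_stats={
                c: PoincareStats(sd1=d["sd1"], sd2=d["sd2"])
                for c, d in poincare_raw.items()
            },
            crosscorr_peak_r=peak_r,
            crosscorr_peak_lag=peak_lag,
        )

    def round_trip_equal(self, other: "CardiacReport", tol: float = 1e-12) -> bool:
        a, b = self.to_frame(), other.to_frame()
        if not (a["metric"].equals(b["metric"]) and a["chamber"].equals(b["chamber"])):
            return False
        return bool(np.allclose(a["value"], b["value"], atol=tol, equal_nan=True))


def build_report(
    atrium: BeatSeries,
    ventricle: BeatSeries,
    crosscorr: CrossCorr | None = None,
    slowdown: float = 1.0,
    provenance: dict | None = None,
) -> CardiacReport:
    """Assemble the per-clip endpoint report from the two chamber beat series.

    Raises an insufficient-beats error naming the failing chamber when a
    chamber has too few beats for its statistics.
    """
    bpm: dict[str, float] = {}
    interval_stats: dict[str, tuple[float, float, int]] = {}
    poincare_stats: dict[str, PoincareStats] = {}

    for beats in (atrium, ventricle):
        name = beats.label.value
        try:
            bpm[name] = compute_bpm_from_times(beats.beat_times)
            same = chamber_intervals(beats)
            if slowdown != 1.0:
                same = rescale_intervals(same, slowdown)
            interval_stats[same.kind] = (same.mean, same.sd, len(same.values))
            if len(same.values) >= 3:
                poincare_stats[name] = poincare(same)
        except InsufficientBeatsError as exc:
            raise InsufficientBeatsError(f"chamber '{name}': {exc}") from exc

    av, va = cross_chamber_intervals(atrium, ventricle)
    for series in (av, va):
        if slowdown != 1.0:
            series = rescale_intervals(series, slowdown)
        if len(series.values):
            interval_stats[series.kind] = (series.mean, series.sd, len(series.values))

    return CardiacReport(
        bpm=bpm,
        interval_stats=interval_stats,
        poincare_stats=poincare_stats,
        crosscorr_peak_r=crosscorr.peak_r if crosscorr is not None else float("nan"),
        crosscorr_peak_lag=crosscorr.peak_lag if crosscorr is not None else 0,
        provenance=provenance or {},
    )
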