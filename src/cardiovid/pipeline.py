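"""End-to-end orchestration: load -> gate -> extract -> condition -> beats
-> endpoints -> CSV artifacts.

The stage order is: frame-count gate, two-ROI mean-intensity extraction
(concurrent), normalization, cubic-spline smoothing, zero-phase Butterworth
bandpass, trough/peak detection, then rate, interval, Poincare and
cross-correlation endpoints.  Every applied default is recorded in the
report's provenance so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, processing, roi, video
from .errors import CardioVidError, ConfigError, PipelineError
from .metrics import BeatSeries, CardiacReport
from .processing import PRESETS
from .roi import ChamberLabel
from .video import VideoClip

logger = logging.getLogger("cardiovid")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializes losslessly to YAML.

    The organism preset fills the cardiac band and rate ceiling; explicit
    band/max_bpm values override the preset.
    """

    video: str = ""
    roi_atrium: str = ""                 # "x,y,w,h"
    roi_ventricle: str = ""
    fps_override: float | None = None
    preset: str = "zebrafish"            # zebrafish | daphnia | custom
    band_hz: tuple[float, float] | None = None
    smoothing_factor: float | None = None
    max_bpm: float | None = None
    prominence_frac: float = 0.3
    paper_compat: bool = False
    slowdown: float = 1.0                # >1 when clip is slow-motion re-rendered footage
    beat_anchor: str = "trough"          # trough | peak
    normalize_ddof: int = 1
    parallel: bool = True
    max_crosscorr_delay_s: float = 1.0
    out_dir: str = "cardiovid_out"
    plots: bool = False
    interactive: bool = False

    def resolved_band(self) -> tuple[float, float]:
        if self.band_hz is not None:
            return tuple(self.band_hz)  # type: ignore[return-value]
        if self.preset in PRESETS:
            return PRESETS[self.preset]["band"]
        raise ConfigError(
            f"preset {self.preset!r} has no default band; pass band_hz explicitly"
        )

    def resolved_max_bpm(self) -> float:
        if self.max_bpm is not None:
            return self.max_bpm
        if self.preset in PRESETS:
            return PRESETS[self.preset]["max_bpm"]
        raise ConfigError(
            f"preset {self.preset!r} has no default max_bpm; pass max_bpm explicitly"
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        if data["band_hz"] is not None:
            data["band_hz"] = list(data["band_hz"])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("band_hz") is not None:
            data["band_hz"] = tuple(data["band_hz"])
        return cls(**data)


@dataclass
class PipelineResult:
    report: CardiacReport
    beat_series: dict[str, BeatSeries]
    signals: dict[str, np.ndarray]
    processed: dict[str, np.ndarray]
    peaks: dict[str, processing.PeakSet]
    crosscorr: metrics.CrossCorr
    intervals: dict[str, metrics.IntervalSeries]
    output_files: list[Path] = field(default_factory=list)


def analyze_clip(config: RunConfig, clip: VideoClip) -> PipelineResult:
    """Run the analysis stages on an already-decoded clip."""
    stage = "gate"
    try:
        start, end = roi.gate_frame_count(clip.n_frames)
        window = VideoClip(frames=clip.frames[start:end], fps=clip.fps, source=clip.source)

        stage = "select_rois"
        spec = None
        if config.roi_atrium or config.roi_ventricle:
            spec = {"atrium": config.roi_atrium, "ventricle": config.roi_ventricle}
            for name, entry in spec.items():
                if not entry:
                    raise ConfigError(f"missing ROI for chamber '{name}'")
        boxes = roi.select_rois(window, spec=spec, interactive=config.interactive)

        stage = "extract"
        raw = roi.extract_signals(window, boxes, parallel=config.parallel)
    except CardioVidError as exc:
        raise PipelineError(stage, None, exc) from exc

    band = config.resolved_band()
    max_bpm = config.resolved_max_bpm()
    frame_dur = video.frame_duration(clip.fps, paper_compat=config.paper_compat)
    logger.info(
        "conditioning with band=%s Hz, max_bpm=%s, prominence_frac=%s, "
        "frame_dur=%s s (paper_compat=%s), beat_anchor=%s",
        band, max_bpm, config.prominence_frac, frame_dur,
        config.paper_compat, config.beat_anchor,
    )

    signals: dict[str, np.ndarray] = {}
    processed: dict[str, np.ndarray] = {}
    peaks: dict[str, processing.PeakSet] = {}
    beat_series: dict[str, BeatSeries] = {}
    for label in (ChamberLabel.ATRIUM, ChamberLabel.VENTRICLE):
        name = label.value
        try:
            stage = "normalize"
            signals[name] = raw[label].values
            norm = roi.normalize(raw[label].values, ddof=config.normalize_ddof)
            stage = "smooth"
            smoothed = processing.smooth_spline(
                norm, smoothing_factor=config.smoothing_factor, fps=clip.fps
            )
            stage = "bandpass"
            filtered = processing.bandpass(smoothed.values, clip.fps, *band)
            processed[name] = filtered.values
            stage = "peaks"
            pk = processing.detect_peaks(
                filtered.values, clip.fps, max_bpm=max_bpm,
                prominence_frac=config.prominence_frac,
            )
            peaks[name] = pk
            anchor = pk.minima_indices if config.beat_anchor == "trough" else pk.maxima_indices
            beat_series[name] = BeatSeries.from_minima(
                label, anchor, frame_dur, slowdown=config.slowdown
            )
        except CardioVidError as exc:
            raise PipelineError(stage, name, exc) from exc
        except ValueError as exc:
            raise PipelineError(stage, name, exc) from exc

    stage = "metrics"
    try:
        # The A-V lag of two near-periodic signals is only identifiable
        # modulo the beat period, so search within +/- half a period
        # (capped by max_crosscorr_delay_s).
        half_period_s = config.max_crosscorr_delay_s
        if beat_series["atrium"].n_beats >= 2:
            half_period_s = float(
                np.mean(np.diff(beat_series["atrium"].beat_times))
            ) / (2.0 * config.slowdown)
        max_delay = int(round(min(half_period_s, config.max_crosscorr_delay_s) * clip.fps))
        max_delay = max(1, min(max_delay, window.n_frames - 1))
        crosscorr = metrics.cross_correlation(
            processed["atrium"], processed["ventricle"], max_delay=max_delay
        )
        provenance = {
            "source": clip.source,
            "fps": clip.fps,
            "frame_dur_s": frame_dur,
            "paper_compat": config.paper_compat,
            "band_hz": list(band),
            "max_bpm": max_bpm,
            "prominence_frac": config.prominence_frac,
            "smoothing_factor": config.smoothing_factor,
            "beat_anchor": config.beat_anchor,
            "slowdown": config.slowdown,
            "rois": {
                lb.value: dataclasses.astuple(bx) for lb, bx in boxes.items()
            },
            "analysis_window": [start, end],
        }
        report = metrics.build_report(
            beat_series["atrium"], beat_series["ventricle"],
            crosscorr=crosscorr, provenance=provenance,
        )
        intervals: dict[str, metrics.IntervalSeries] = {}
        for name in ("atrium", "ventricle"):
            intervals_series = metrics.chamber_intervals(beat_series[name])
            intervals[intervals_series.kind] = intervals_series
        av, va = metrics.cross_chamber_intervals(
            beat_series["atrium"], beat_series["ventricle"]
        )
        intervals["AV"], intervals["VA"] = av, va
    except CardioVidError as exc:
        raise PipelineError(stage, None, exc) from exc

    return PipelineResult(
        report=report,
        beat_series=beat_series,
        signals=signals,
        processed=processed,
        peaks=peaks,
        crosscorr=crosscorr,
        intervals=intervals,
    )


def run_pipeline(config: RunConfig, clip: VideoClip | None = None) -> PipelineResult:
    """Full run: decode the video (unless a clip is passed), analyze, and
    write the CSV (and optional plot) artifacts to config.out_dir."""
    if clip is None:
        stage = "load"
        try:
            clip = video.load_video(config.video, fps_override=config.fps_override)
        except CardioVidError as exc:
            raise PipelineError(stage, None, exc) from exc

    result = analyze_clip(config, clip)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.output_files = _write_outputs(result, out_dir, plots=config.plots)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, plots: bool = False) -> list[Path]:
    files: list[Path] = []

    n = len(next(iter(result.signals.values())))
    fps = result.report.provenance.get("fps", float("nan"))
    sig_df = pd.DataFrame({"frame_index": np.arange(n), "time_s": np.arange(n) / fps})
    for name in ("atrium", "ventricle"):
        sig_df[f"raw_{name}"] = result.signals[name]
        sig_df[f"processed_{name}"] = result.processed[name]
    files.append(out_dir / "signals.csv")
    sig_df.to_csv(files[-1], index=False)

    peak_rows = []
    for name, pk in result.peaks.items():
        for idx in pk.maxima_indices:
            peak_rows.append((name, int(idx), idx / fps, True, False))
        for idx in pk.minima_indices:
            peak_rows.append((name, int(idx), idx / fps, False, True))
    peaks_df = pd.DataFrame(
        peak_rows, columns=["chamber", "frame_index", "time_s", "is_max", "is_min"]
    ).sort_values(["chamber", "frame_index"], kind="stable")
    files.append(out_dir / "peaks.csv")
    peaks_df.to_csv(files[-1], index=False)

    int_rows = [
        (kind, i, v)
        for kind, series in sorted(result.intervals.items())
        for i, v in enumerate(series.values)
    ]
    files.append(out_dir / "intervals.csv")
    pd.DataFrame(int_rows, columns=["kind", "index", "value_s"]).to_csv(
        files[-1], index=False
    )

    files.append(out_dir / "crosscorr.csv")
    pd.DataFrame(
        {"delay": result.crosscorr.delays, "r": result.crosscorr.r}
    ).to_csv(files[-1], index=False)

    files.append(out_dir / "report.csv")
    result.report.to_csv(files[-1])

    if plots:
        files.extend(_write_plots(result, out_dir, fps))
    return files


def _write_plots(result: PipelineResult, out_dir: Path, fps: float) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []
    fig, ax = plt.subplots(figsize=(10, 4))
    n = len(result.processed["atrium"])
    t = np.arange(n) / fps
    ax.plot(t, result.processed["atrium"], label="atrium", color="tab:blue", lw=0.8)
    ax.plot(t, result.processed["ventricle"], label="ventricle", color="tab:red", lw=0.8)
    for name, color in (("atrium", "tab:blue"), ("ventricle", "tab:red")):
        mins = result.peaks[name].minima_indices
        ax.plot(mins / fps, result.processed[name][mins], "v", color=color, ms=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("conditioned intensity (a.u.)")
    ax.legend()
    files.append(out_dir / "signals.png")
    fig.savefig(files[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax2, kind in zip(axes, ("AA", "VV")):
        vals = result.intervals[kind].values
        if len(vals) >= 2:
            ax2.plot(vals[:-1], vals[1:], "o", ms=4, alpha=0.7)
            lim = (vals.min() * 0.9, vals.max() * 1.1)
            ax2.plot(lim, lim, "k--", lw=0.8)
            ax2.set_xlim(lim), ax2.set_ylim(lim)
        ax2.set_title(f"{kind} Poincare")
        ax2.set_xlabel("I(n) (s)"), ax2.set_ylabel("I(n+1) (s)")
    fig.tight_layout()
    files.append(out_dir / "poincare.png")
    fig.savefig(files[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return files
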