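"""Raw detections -> regular 20 s approach tracks.

Three stages, each with an auditable keep/drop decision:

1. `extract_approach_windows` finds pass approaches: the first detection
   within 10 m of the pass entrance triggers a window covering the preceding
   60 min, unless any near-pass detection occurred in the previous 2 h
   (refractory rule).  Windows are rejected when over 90% of their detections
   sit within 15 m of the pass ("loitering"), when they span less than
   30 min, or when they hold fewer than 10 detections.
2. `regularize` splits a window at inter-detection gaps above 60 s, discards
   segments with fewer than 10 detections, and predicts positions on the
   exact 20 s grid with a continuous-time correlated random walk smoother
   (or piecewise-linear interpolation).  Points outside the raster extent
   are removed.
3. `post_filters` keeps tracks that show directed movement toward the pass,
   did not start near it, average at least two steps per minute, and fall
   inside the species' migration season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ctcrw import fit_ctcrw, predict_ctcrw
from .errors import ConfigurationError, EstimationError


@dataclass
class ApproachWindow:
    fish_id: str
    approach_index: int
    trigger_time: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp
    detections: pd.DataFrame  # time, x, y


@dataclass
class RegularTrack:
    fish_id: str
    approach_index: int
    segments: list  # list of DataFrames (time, x, y) at exact dt spacing
    method: str
    params: dict = field(default_factory=dict)
    dropped_segments: list = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def n_steps(self) -> int:
        return sum(max(len(s) - 1, 0) for s in self.segments)


def _dist(x, y, pt):
    return np.hypot(np.asarray(x) - pt[0], np.asarray(y) - pt[1])


def extract_approach_windows(detections: pd.DataFrame, pass_xy, config: PipelineConfig,
                             audit: list | None = None):
    """Find retained approach windows per fish; rejections go to `audit`."""
    windows = []
    audit = audit if audit is not None else []
    refractory = pd.Timedelta(hours=config.refractory_h)
    span = pd.Timedelta(minutes=config.window_min)
    for fish_id, df in detections.groupby("fish_id", sort=True):
        df = df.sort_values("time").reset_index(drop=True)
        t = df["time"]
        near = _dist(df["x"], df["y"], pass_xy) <= config.trigger_radius_m
        near_times = t[near].reset_index(drop=True)
        approach_index = 0
        prev_near: pd.Timestamp | None = None
        for i in range(len(near_times)):
            trigger = near_times[i]
            ok = prev_near is None or (trigger - prev_near) > refractory
            prev_near = trigger
            if not ok:
                continue
            win = df[(t >= trigger - span) & (t <= trigger)]
            reason = _window_rejection(win, trigger, pass_xy, config)
            if reason:
                audit.append(dict(fish_id=fish_id, object="window",
                                  time=str(trigger), decision="drop", reason=reason))
                continue
            approach_index += 1
            windows.append(ApproachWindow(
                fish_id=fish_id, approach_index=approach_index,
                trigger_time=trigger, start=win["time"].iloc[0],
                end=trigger, detections=win.reset_index(drop=True),
            ))
            audit.append(dict(fish_id=fish_id, object="window",
                              time=str(trigger), decision="keep", reason=""))
    return windows


def _window_rejection(win, trigger, pass_xy, config: PipelineConfig):
    if len(win) < config.min_detections:
        return "too_few_detections"
    span_min = (trigger - win["time"].iloc[0]).total_seconds() / 60.0
    if span_min < config.min_span_min:
        return "too_short"
    frac_near = float(
        (_dist(win["x"], win["y"], pass_xy) <= config.loiter_radius_m).mean()
    )
    if frac_near > config.loiter_frac:
        return "loitering"
    return None


def split_segments(detections: pd.DataFrame, gap_s: float, min_det: int):
    """Split at inter-detection gaps > gap_s; drop segments with < min_det."""
    df = detections.sort_values("time").reset_index(drop=True)
    df = df.loc[~df["time"].duplicated()].reset_index(drop=True)
    dt = df["time"].diff().dt.total_seconds().to_numpy()
    breaks = np.flatnonzero(dt > gap_s)
    pieces = np.split(np.arange(len(df)), breaks)
    kept, dropped = [], []
    for idx in pieces:
        seg = df.iloc[idx].reset_index(drop=True)
        (kept if len(seg) >= min_det else dropped).append(seg)
    return kept, dropped


def regularize(window: ApproachWindow, config: PipelineConfig,
               extent=None, method: str | None = None,
               audit: list | None = None) -> RegularTrack:
    """Predict the window's detections onto the exact `dt` grid.

    `extent` is an object with an ``in_extent(x, y)`` method (a raster stack);
    grid points outside it are removed.  Grid timestamps are integer
    multiples of dt from each segment's first detection.
    """
    method = method or config.regularization_method
    audit = audit if audit is not None else []
    kept, dropped = split_segments(window.detections, config.gap_s,
                                   config.segment_min_detections)
    for seg in dropped:
        audit.append(dict(fish_id=window.fish_id, object="segment",
                          time=str(seg["time"].iloc[0]), decision="drop",
                          reason="too_few_detections"))
    segments = []
    used_method = method
    for seg in kept:
        t = (seg["time"].astype("int64") / 1e9).to_numpy()
        x = seg["x"].to_numpy(dtype=float)
        y = seg["y"].to_numpy(dtype=float)
        n_grid = int(np.floor((t[-1] - t[0]) / config.dt_s)) + 1
        grid = t[0] + np.arange(n_grid) * config.dt_s
        if method == "ctcrw":
            try:
                fit = fit_ctcrw(t, x, y, measurement_floor=config.measurement_floor_m)
                gx, gy = predict_ctcrw(fit, t, x, y, grid)
            except (EstimationError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"CTCRW fit failed ({exc}); falling back to linear")
                used_method = "ctcrw+linear_fallback"
                gx = np.interp(grid, t, x)
                gy = np.interp(grid, t, y)
        else:
            gx = np.interp(grid, t, x)
            gy = np.interp(grid, t, y)
        out = pd.DataFrame({
            "time": pd.to_datetime((grid * 1e9).astype("int64"), utc=True),
            "x": gx, "y": gy,
        })
        if extent is not None:
            inside = extent.in_extent(out["x"].to_numpy(), out["y"].to_numpy())
            out = out.loc[inside].reset_index(drop=True)
        if len(out) >= 2:
            segments.append(out)
    return RegularTrack(
        fish_id=window.fish_id, approach_index=window.approach_index,
        segments=segments, method=used_method,
        params=dict(dt_s=config.dt_s, gap_s=config.gap_s,
                    min_det=config.segment_min_detections),
    )


def post_filters(track: RegularTrack, pass_xy, species: str,
                 config: PipelineConfig, tag_date=None):
    """Keep/drop decision with a reason code for a regularized track."""
    if species not in config.season_cutoffs:
        raise ConfigurationError(f"unknown species {species!r}: no season cut-off")
    if not track.segments:
        return False, "empty"
    first = track.segments[0].iloc[0]
    last = track.segments[-1].iloc[-1]
    d_start = float(np.hypot(first["x"] - pass_xy[0], first["y"] - pass_xy[1]))
    d_end = float(np.hypot(last["x"] - pass_xy[0], last["y"] - pass_xy[1]))
    if d_start < config.near_pass_start_radius_m:
        return False, "starts_near_pass"
    if d_start < config.min_start_distance_m:
        return False, "starts_near_pass"
    if (d_start - d_end) / d_start < config.directedness_min:
        return False, "not_directed"
    span_min = (last["time"] - first["time"]).total_seconds() / 60.0
    if span_min <= 0 or track.n_steps / span_min < config.min_steps_per_min:
        return False, "sparse"
    date = first["time"].date()
    month_day = config.season_cutoffs[species]
    cutoff = pd.Timestamp(f"{date.year}-{month_day}").date()
    if date > cutoff:
        return False, "out_of_season"
    if tag_date is not None and date < pd.Timestamp(tag_date).date():
        return False, "before_tagging"
    return True, ""
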