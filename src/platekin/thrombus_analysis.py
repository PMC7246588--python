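"""Ex vivo thrombus-growth metrics and PMN crawling velocity.

Thrombi formed on collagen under flow are followed as per-object time
series of segmented area and mean DiOC6 intensity (a proxy for height
above the collagen surface).  A thrombus counts as growing if its
fluorescence rises at least 1.1-fold within any 2-minute window; field
summaries report the area fraction, the fraction of continuously
growing thrombi, the maximal fold change, and the growth velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass
class ThrombusTrack:
    """Area/intensity time series of one tracked object."""

    object_id: str
    times_s: np.ndarray
    area_px: np.ndarray
    mean_intensity: np.ndarray
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if len(self.area_px) != n or len(self.mean_intensity) != n:
            raise ValueError("track series must be aligned and equal length")
        if n and np.any(np.asarray(self.mean_intensity) <= 0):
            raise ValueError("intensities must be positive")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class FOVSummary:
    """Field-of-view thrombus-growth summary."""

    area_fraction_pct: float
    frac_growing: float | None
    max_fold_change: float
    growth_velocity_pct_per_min: float
    n_tracks: int
    n_classifiable: int


# --------------------------------------------------------------------------
# Segmentation and tracking
# --------------------------------------------------------------------------


def segment_and_track(frames: np.ndarray, threshold: float,
                      max_link_px: float = 10.0,
                      frame_interval_s: float = 30.0,
                      min_area_px: int = 4) -> list[ThrombusTrack]:
    """Threshold, label and greedily link objects across frames.

    Per-frame connected components above ``threshold`` are linked to
    the nearest centroid of the previous frame within ``max_link_px``
    (thrombi are sessile, so greedy nearest-centroid linking is
    sufficient).  Unmatched components start new tracks.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (time, y, x) image stack")
    active: dict[int, dict] = {}
    finished: list[dict] = []
    next_id = 0
    for fi in range(frames.shape[0]):
        labels = measure.label(frames[fi] > threshold)
        props = [p for p in measure.regionprops(labels,
                                                intensity_image=frames[fi])
                 if p.area >= min_area_px]
        t = fi * frame_interval_s
        unmatched = set(range(len(props)))
        assignments: list[tuple[float, int, int]] = []
        for tid, tr in active.items():
            cy, cx = tr["centroid"]
            for j, p in enumerate(props):
                d = math.hypot(p.centroid[0] - cy, p.centroid[1] - cx)
                if d <= max_link_px:
                    assignments.append((d, tid, j))
        assignments.sort()
        used_tracks: set[int] = set()
        for d, tid, j in assignments:
            if tid in used_tracks or j not in unmatched:
                continue
            p = props[j]
            tr = active[tid]
            tr["t"].append(t)
            tr["area"].append(float(p.area))
            tr["intensity"].append(float(p.intensity_mean))
            tr["centroid"] = p.centroid
            used_tracks.add(tid)
            unmatched.discard(j)
        stale = [tid for tid in active if tid not in used_tracks]
        for tid in stale:
            finished.append(active.pop(tid))
        for j in unmatched:
            p = props[j]
            active[next_id] = {
                "t": [t], "area": [float(p.area)],
                "intensity": [float(p.intensity_mean)],
                "centroid": p.centroid,
            }
            next_id += 1
    finished.extend(active.values())
    finished.sort(key=lambda tr: tr["t"][0])
    return [
        ThrombusTrack(object_id=f"obj_{i:03d}",
                      times_s=np.asarray(tr["t"]),
                      area_px=np.asarray(tr["area"]),
                      mean_intensity=np.asarray(tr["intensity"]))
        for i, tr in enumerate(finished)
    ]


# --------------------------------------------------------------------------
# Growth metrics
# --------------------------------------------------------------------------


def classify_growing(track: ThrombusTrack, window_s: float = 120.0,
                     fold: float = 1.1) -> bool | None:
    """Growing iff intensity rises >= ``fold`` over some ``window_s`` span.

    The threshold is inclusive ("at least 1.1-fold in 2 min").  Tracks
    shorter than one window return None (undetermined).
    """
    t = np.asarray(track.times_s, dtype=float)
    y = np.asarray(track.mean_intensity, dtype=float)
    if len(t) < 2 or t[-1] - t[0] < window_s:
        return None
    for i in range(len(t)):
        # last sample within [t_i, t_i + window_s]
        j = int(np.searchsorted(t, t[i] + window_s, side="right")) - 1
        if j <= i or t[j] - t[i] < window_s - 1e-9:
            continue
        if y[j] / y[i] >= fold:
            return True
    return False


def growth_metrics(track: ThrombusTrack,
                   window_s: float = 120.0) -> tuple[float, float]:
    """(max fold change, growth velocity in %/min).

    Fold change is the maximal intensity over the initial intensity
    (median of the first three frames, robust to a dim first frame);
    velocity is the largest relative intensity increase per minute over
    any ``window_s`` window, as a percentage of the window start.
    """
    y = np.asarray(track.mean_intensity, dtype=float)
    t = np.asarray(track.times_s, dtype=float)
    if len(y) == 0:
        raise ValueError("empty track")
    initial = float(np.median(y[:3]))
    if initial <= 0:
        raise ValueError("initial intensity must be positive")
    fold = float(np.max(y)) / initial
    velocity = 0.0
    for i in range(len(t)):
        j = int(np.searchsorted(t, t[i] + window_s, side="right")) - 1
        if j <= i:
            continue
        dt_min = (t[j] - t[i]) / 60.0
        if dt_min <= 0:
            continue
        rate = (y[j] / y[i] - 1.0) / dt_min * 100.0
        velocity = max(velocity, rate)
    return fold, velocity


def area_fraction(tracks: list[ThrombusTrack], fov_area: float,
                  times: np.ndarray | None = None) -> pd.Series:
    """Percent of the field covered by segmented thrombi over time."""
    if fov_area <= 0:
        raise ValueError("fov_area must be positive")
    if times is None:
        all_t = np.concatenate([t.times_s for t in tracks]) if tracks else \
            np.array([0.0])
        times = np.unique(all_t)
    total = np.zeros_like(times, dtype=float)
    for tr in tracks:
        idx = np.searchsorted(times, tr.times_s)
        total[idx] += tr.area_px
    return pd.Series(total / fov_area * 100.0, index=times, name="area_pct")


def summarize_fov(tracks: list[ThrombusTrack], fov_area: float,
                  window_s: float = 120.0, fold: float = 1.1) -> FOVSummary:
    """Aggregate the growth metrics over one field of view.

    ``frac_growing`` counts tracks still growing on their final
    2-minute window ("continuously growing after 20 min") among the
    classifiable tracks; ``max_fold_change`` and the growth velocity
    are means over classifiable tracks.
    """
    if not tracks:
        return FOVSummary(0.0, None, 1.0, 0.0, 0, 0)
    area = area_fraction(tracks, fov_area)
    final_area = float(area.iloc[-1])
    growing = 0
    classifiable = 0
    folds, vels = [], []
    for tr in tracks:
        t = np.asarray(tr.times_s, dtype=float)
        if len(t) < 2 or t[-1] - t[0] < window_s:
            continue
        classifiable += 1
        m = t >= t[-1] - window_s
        tail = ThrombusTrack(tr.object_id, t[m],
                             np.asarray(tr.area_px)[m],
                             np.asarray(tr.mean_intensity)[m])
        if classify_growing(tail, window_s=window_s, fold=fold):
            growing += 1
        fc, v = growth_metrics(tr, window_s)
        folds.append(fc)
        vels.append(v)
    frac = growing / classifiable if classifiable else None
    return FOVSummary(
        area_fraction_pct=final_area,
        frac_growing=frac,
        max_fold_change=float(np.mean(folds)) if folds else 1.0,
        growth_velocity_pct_per_min=float(np.mean(vels)) if vels else 0.0,
        n_tracks=len(tracks),
        n_classifiable=classifiable,
    )


# --------------------------------------------------------------------------
# PMN crawling
# --------------------------------------------------------------------------


def pmn_crawl_velocity(tracks: pd.DataFrame, um_per_px: float,
                       epoch_split_s: float = 600.0) -> pd.DataFrame:
    """Mean crawling speed per PMN track in nm/s, with epoch means.

    ``tracks`` columns: track_id, time_s, x_px, y_px.  Speed is the
    mean frame-to-frame displacement over elapsed time.  Tracks with a
    single point are excluded.  Each track is assigned to the early or
    late epoch by its midpoint time.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    rows = []
    for tid, g in tracks.sort_values("time_s").groupby("track_id"):
        if len(g) < 2:
            continue
        t = g["time_s"].to_numpy(dtype=float)
        dx = np.diff(g["x_px"].to_numpy(dtype=float))
        dy = np.diff(g["y_px"].to_numpy(dtype=float))
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"track {tid!r} has nonincreasing times")
        step_nm = np.hypot(dx, dy) * um_per_px * 1000.0
        speed = float(np.sum(step_nm) / np.sum(dt))
        mid = 0.5 * (t[0] + t[-1])
        rows.append({"track_id": tid, "speed_nm_s": speed,
                     "epoch": "early" if mid < epoch_split_s else "late"})
    return pd.DataFrame(rows, columns=["track_id", "speed_nm_s", "epoch"])


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_tracks_csv(path) -> list[ThrombusTrack]:
    """Per-object CSV: object_id, time_s, area_px, mean_intensity[, fov_id]."""
    df = pd.read_csv(path)
    tracks = []
    for oid, g in df.groupby("object_id"):
        g = g.sort_values("time_s")
        tracks.append(ThrombusTrack(
            object_id=str(oid),
            times_s=g["time_s"].to_numpy(dtype=float),
            area_px=g["area_px"].to_numpy(dtype=float),
            mean_intensity=g["mean_intensity"].to_numpy(dtype=float),
            fov_id=str(g["fov_id"].iloc[0]) if "fov_id" in g else "fov",
        ))
    return tracks


def write_tracks_tsv(tracks: list[ThrombusTrack], path) -> None:
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append({"object_id": tr.object_id, "fov_id": tr.fov_id,
                         "time_s": tr.times_s[i], "area_px": tr.area_px[i],
                         "mean_intensity": tr.mean_intensity[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
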