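"""Process continuous flow-cytometry event streams into calibrated traces.

The pipeline turns per-event fluorescence of the ratiometric calcium dye
Fura-Red (calcium-bound form excited at 405 nm, calcium-free at 488 nm),
an Alexa488-fibrinogen channel, and side scatter into:

* a per-second binned trace,
* a calibrated cytosolic calcium series via the Grynkiewicz equation

      [Ca2+] = Kd * (FImax/FImin) * (R - Rmin) / (Rmax - R)

  anchored to the known free-calcium level of the EGTA-buffered Tyrode
  buffer at the end of the run,
* relative fibrinogen binding on the "quiescent = 0, ionomycin = 1"
  scale, and
* the four donor-level features used for cohort clustering: basal and
  maximal calcium, relative fibrinogen binding, and relative SSC-A
  (shape) change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyStreamError,
    IncompleteProtocolError,
    OutOfRegimeError,
    SaturationError,
)
from .protocol import ProtocolSpec

CHANNELS = ("FSC", "SSC_A", "FL405", "FL488", "FL_FIB")

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class EventStream:
    """Time-stamped multichannel cytometry events for one donor run.

    ``events`` columns: time_s, FSC, SSC_A, FL405, FL488, FL_FIB.
    Times are nondecreasing and intensities nonnegative.
    """

    donor_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("time_s",) + tuple(CHANNELS)
                   if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        t = self.events["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) < 0):
            raise ValueError("event times must be nondecreasing")
        if len(t) and any((self.events[c].to_numpy() < 0).any()
                          for c in CHANNELS):
            raise ValueError("channel intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class CalibrationConstants:
    """All symbols of the Grynkiewicz equation plus the EGTA anchor.

    ``kd_furared`` is the Fura-Red affinity for free calcium (nM);
    ``fi_max``/``fi_min`` are the 488 nm channel intensities of the
    calcium-free and calcium-saturated dye; ``r_min``/``r_max`` bound
    the 405/488 ratio.  ``egta_mark_nM`` is the free calcium of the
    2 mM Ca / 10 mM EGTA buffer used as the absolute anchor.
    """

    kd_furared: float = 400.0
    fi_max: float = 1.0
    fi_min: float = 0.5
    r_min: float = 0.1
    r_max: float = 3.0
    egta_total: float = 10.0   # mM
    ca_total: float = 2.0      # mM
    pH: float = 7.35
    kd_egta_app: float = field(default=0.0)   # M, filled in __post_init__
    egta_mark_nM: float = field(default=0.0)  # filled in __post_init__

    def __post_init__(self) -> None:
        if not (self.r_min < self.r_max and self.fi_min < self.fi_max):
            raise ValueError("need r_min < r_max and fi_min < fi_max")
        if min(self.kd_furared, self.fi_min, self.r_min, self.r_max) <= 0:
            raise ValueError("calibration constants must be positive")
        if self.kd_egta_app == 0.0:
            self.kd_egta_app = apparent_kd_egta(self.pH)
        if self.egta_mark_nM == 0.0:
            self.egta_mark_nM = egta_free_calcium(
                self.ca_total, self.egta_total, self.pH)

    @property
    def k_eff(self) -> float:
        """Kd * FImax / FImin — the effective half-point concentration."""
        return self.kd_furared * self.fi_max / self.fi_min


@dataclass
class BinnedTrace:
    """Per-bin channel means over a fixed-width time grid.

    Empty bins are dropped.  ``ca_nM`` is None until calibration;
    ``scale_factor`` records the EGTA-anchor rescaling applied to it.
    """

    donor_id: str
    bin_width_s: float
    bin_centers_s: np.ndarray
    means: pd.DataFrame            # one column per channel
    n_events_per_bin: np.ndarray
    R: np.ndarray                  # FL405 mean / FL488 mean per bin
    ca_nM: np.ndarray | None = None
    fib_rel: np.ndarray | None = None
    scale_factor: float = 1.0
    n_clipped: int = 0             # bins with R < r_min clipped to 0 nM
    n_saturated: int = 0           # bins with R >= r_max (ca undefined)


@dataclass(frozen=True)
class FeatureVector:
    """The four donor-level features used for clustering."""

    ca_basal_nM: float
    ca_max_nM: float
    fib_rel: float
    ssc_change: float

    def __post_init__(self) -> None:
        if not (self.ca_max_nM >= self.ca_basal_nM >= 0):
            raise ValueError("need ca_max >= ca_basal >= 0")
        if self.ssc_change <= -1:
            raise ValueError("ssc_change must exceed -1")

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_basal_nM, self.ca_max_nM,
                         self.fib_rel, self.ssc_change])


@dataclass(frozen=True)
class WindowConfig:
    """Analysis-window spans (seconds).

    baseline = last ``baseline_span_s`` before agonist; response = first
    ``response_span_s`` after agonist; ionomycin plateau = minutes 5-10
    after addition; EGTA window = last ``egta_span_s`` of the run.
    """

    baseline_span_s: float = 30.0
    response_span_s: float = 300.0
    iono_plateau_start_s: float = 300.0
    iono_plateau_end_s: float = 600.0
    egta_span_s: float = 30.0
    #: moving-average span for max-statistics (ca_max, SSC step, fib
    #: max).  The maximum of raw 1-s bins is upward-biased by event
    #: noise; a short average over a span well below the response
    #: timescale (rise ~30 s, decay ~120 s) suppresses the bias
    #: without flattening the peak.
    smooth_span_s: float = 15.0


# --------------------------------------------------------------------------
# EGTA equilibrium
# --------------------------------------------------------------------------

#: Ca-EGTA binding constants at 37 C and physiological ionic strength.
#: Published EGTA constant sets disagree substantially (apparent Kd at
#: pH 7.0 spans roughly 0.1-1 uM between sets); these values belong to
#: the high-Kd school and reproduce the ~50 nM free-calcium mark of
#: 2 mM Ca / 10 mM EGTA Tyrode at pH 7.35 used to anchor the assay.
LOG_K_CAEGTA = 10.00   # log10 of the absolute Ca-EGTA4- association (1/M)
PKA1_EGTA = 9.40       # HEGTA3-  <-> EGTA4- + H+
PKA2_EGTA = 8.58       # H2EGTA2- <-> HEGTA3- + H+


def apparent_kd_egta(pH: float, log_k: float = LOG_K_CAEGTA,
                     pka1: float = PKA1_EGTA,
                     pka2: float = PKA2_EGTA) -> float:
    """pH-corrected apparent Ca-EGTA dissociation constant in molar.

    Protonation competes with calcium for the EGTA4- species, so the
    apparent Kd is the absolute Kd inflated by
    ``alpha = 1 + [H]/Ka1 + [H]^2/(Ka1*Ka2)``.
    """
    if not 6.0 <= pH <= 9.0:
        raise OutOfRegimeError(f"pH {pH} outside supported range [6, 9]")
    h = 10.0 ** (-pH)
    alpha = 1.0 + h * 10.0 ** pka1 + h * h * 10.0 ** (pka1 + pka2)
    return alpha / 10.0 ** log_k


def egta_free_calcium(ca_total_mM: float, egta_total_mM: float,
                      pH: float = 7.35, *,
                      log_k: float = LOG_K_CAEGTA,
                      pka1: float = PKA1_EGTA,
                      pka2: float = PKA2_EGTA) -> float:
    """Free calcium (nM) of a Ca/EGTA mixture with excess chelator.

    Solves the 1:1 mass-balance quadratic

        x^2 + (E - C + Kd') x - Kd' C = 0

    for free calcium ``x`` with totals ``C`` (calcium) and ``E`` (EGTA)
    and the pH-corrected apparent dissociation constant ``Kd'``.
    """
    if egta_total_mM <= 0:
        if ca_total_mM <= 0:
            return 0.0
        return ca_total_mM * 1e6  # no chelation: free = total, mM -> nM
    if ca_total_mM >= egta_total_mM:
        raise OutOfRegimeError(
            "anchoring requires excess EGTA (ca_total < egta_total)")
    kd = apparent_kd_egta(pH, log_k, pka1, pka2)
    c = ca_total_mM * 1e-3
    e = egta_total_mM * 1e-3
    b = e - c + kd
    # positive root of x^2 + b x - kd c = 0, written stably
    x = 2.0 * kd * c / (b + np.sqrt(b * b + 4.0 * kd * c))
    return float(x * 1e9)


# --------------------------------------------------------------------------
# Binning and calibration
# --------------------------------------------------------------------------


def bin_events(stream: EventStream, bin_width_s: float = 1.0) -> BinnedTrace:
    """Average each channel over consecutive equal time bins.

    Bins with no events are dropped from the trace (low event rates
    leave gaps; interpolation would invent data).
    """
    if len(stream) == 0:
        raise EmptyStreamError(f"stream {stream.donor_id!r} has no events")
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    t = stream.events["time_s"].to_numpy()
    idx = np.floor(t / bin_width_s).astype(np.int64)
    grouped = stream.events.groupby(idx, sort=True)
    means = grouped[list(CHANNELS)].mean()
    counts = grouped.size().to_numpy()
    centers = (means.index.to_numpy() + 0.5) * bin_width_s
    fl488 = means["FL488"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fl488 > 0, means["FL405"].to_numpy() / fl488, np.nan)
    return BinnedTrace(
        donor_id=stream.donor_id,
        bin_width_s=bin_width_s,
        bin_centers_s=centers,
        means=means.reset_index(drop=True),
        n_events_per_bin=counts,
        R=ratio,
    )


def grynkiewicz_calcium(R, c: CalibrationConstants):
    """Convert a bound/free Fura-Red ratio into free calcium (nM).

    Ratios below ``r_min`` (noisy baseline undershoot) are clipped to
    0 nM with a warning; ratios at or above ``r_max`` raise
    :class:`SaturationError` because calcium is undefined there.
    Scalar in, scalar out; array in, array out.
    """
    r = np.asarray(R, dtype=float)
    if np.any(~np.isfinite(r)):
        raise ValueError("R must be finite")
    if np.any(r >= c.r_max):
        raise SaturationError("R >= r_max: indicator saturated")
    ca = c.k_eff * (r - c.r_min) / (c.r_max - r)
    n_clip = int(np.sum(r < c.r_min))
    if n_clip:
        warnings.warn(f"{n_clip} ratio value(s) below r_min clipped to 0 nM",
                      stacklevel=2)
        ca = np.where(r < c.r_min, 0.0, ca)
    return float(ca) if np.isscalar(R) else ca


def _window_mask(trace: BinnedTrace, t0: float, t1: float) -> np.ndarray:
    return (trace.bin_centers_s >= t0) & (trace.bin_centers_s < t1)


def _smooth(values: np.ndarray, bin_width_s: float,
            span_s: float) -> np.ndarray:
    """Centered moving average, NaN-tolerant, edges padded by shrinkage."""
    w = max(int(round(span_s / bin_width_s)), 1)
    if w <= 1:
        return values
    return (pd.Series(values)
            .rolling(w, center=True, min_periods=1)
            .mean().to_numpy())


def _window_median(trace: BinnedTrace, column: str, t0: float,
                   t1: float, what: str) -> float:
    m = _window_mask(trace, t0, t1)
    if not m.any():
        raise IncompleteProtocolError(f"no bins in the {what} window "
                                      f"[{t0:.0f}, {t1:.0f}) s")
    if column == "R":
        return float(np.nanmedian(trace.R[m]))
    return float(np.nanmedian(trace.means[column].to_numpy()[m]))


def extract_calibration(trace: BinnedTrace, protocol: ProtocolSpec,
                        windows: WindowConfig = WindowConfig(),
                        kd_furared: float = 400.0,
                        egta_total_mM: float = 10.0,
                        ca_total_mM: float = 2.0,
                        pH: float = 7.35) -> CalibrationConstants:
    """Estimate the Grynkiewicz constants from a run's own epochs.

    * ``fi_min`` and ``r_max``: medians over the ionomycin plateau
      (indicator saturated).
    * ``fi_max``: median 488-channel level over the pre-agonist
      baseline, corrected for the small calcium-bound dye fraction at
      basal calcium (solved self-consistently).
    * ``r_min``: from the post-EGTA epoch, where EGTA minimises the
      calcium-bound dye, using the known buffered free-calcium mark:
      with the EGTA-window ratio R_e and mark m,
      ``r_min = R_e - m (r_max - R_e) / K_eff``.

    Because the mark is built into ``r_min``, the calibrated trace is
    already on the EGTA-anchored absolute scale.
    """
    t_ag = protocol.agonist_time_s
    t_io = protocol.ionomycin_time_s
    base0 = t_ag - windows.baseline_span_s
    fi_max_raw = _window_median(trace, "FL488", base0, t_ag, "baseline")
    r_base = _window_median(trace, "R", base0, t_ag, "baseline")
    io0 = t_io + windows.iono_plateau_start_s
    io1 = min(t_io + windows.iono_plateau_end_s, protocol.egta_time_s)
    fi_min = _window_median(trace, "FL488", io0, io1, "ionomycin plateau")
    r_max = _window_median(trace, "R", io0, io1, "ionomycin plateau")
    eg0 = protocol.run_end_s - windows.egta_span_s
    r_egta = _window_median(trace, "R", eg0, protocol.run_end_s, "EGTA")
    # The EGTA mark (~50 nM) can sit above a quiescent baseline of
    # 8-15 nM, so R_egta may exceed R_baseline; both must lie well
    # below the ionomycin-saturated ratio.
    if not (r_base < r_max and r_egta < r_max):
        raise IncompleteProtocolError(
            "baseline/EGTA ratios not below the ionomycin R_max; "
            "protocol annotation likely wrong")

    mark = egta_free_calcium(ca_total_mM, egta_total_mM, pH)
    # Baseline 488 signal sits slightly below the true calcium-free
    # level because a small dye fraction is calcium-bound at basal
    # calcium.  Solve fi_max and basal calcium self-consistently.
    fi_max = fi_max_raw
    for _ in range(8):
        k_eff = kd_furared * fi_max / fi_min
        r_min = r_egta - mark * (r_max - r_egta) / k_eff
        ca_base = k_eff * (r_base - r_min) / (r_max - r_base)
        ca_base = max(ca_base, 0.0)
        bound = ca_base / (ca_base + kd_furared)
        new = (fi_max_raw - fi_min * bound) / (1.0 - bound)
        if abs(new - fi_max) < 1e-9 * fi_max:
            fi_max = new
            break
        fi_max = new
    k_eff = kd_furared * fi_max / fi_min
    r_min = r_egta - mark * (r_max - r_egta) / k_eff
    return CalibrationConstants(
        kd_furared=kd_furared, fi_max=fi_max, fi_min=fi_min,
        r_min=r_min, r_max=r_max, egta_total=egta_total_mM,
        ca_total=ca_total_mM, pH=pH,
    )


def normalize_calcium(trace: BinnedTrace, c: CalibrationConstants,
                      protocol: ProtocolSpec,
                      windows: WindowConfig = WindowConfig()) -> BinnedTrace:
    """Calibrate the calcium series and anchor it to the EGTA mark.

    The whole series is rescaled by ``egta_mark / measured post-EGTA
    calcium`` so that multiplicative calibration errors (wrong Kd,
    mis-estimated FImax) cancel.  Idempotent: a second application
    finds the factor already equal to one.
    """
    if trace.ca_nM is None:
        r = trace.R
        sat = r >= c.r_max
        clip = r < c.r_min
        with np.errstate(divide="ignore", invalid="ignore"):
            ca = c.k_eff * (r - c.r_min) / (c.r_max - r)
        ca = np.where(sat, np.nan, np.where(clip, 0.0, ca))
        trace = replace(trace, ca_nM=ca, n_clipped=int(clip.sum()),
                        n_saturated=int(sat.sum()))
    m = _window_mask(trace, protocol.run_end_s - windows.egta_span_s,
                     protocol.run_end_s)
    if not m.any():
        raise IncompleteProtocolError("no bins in the EGTA window")
    measured = float(np.nanmedian(trace.ca_nM[m]))
    if not measured > 0:
        raise IncompleteProtocolError(
            "post-EGTA calcium is not positive; cannot anchor")
    factor = c.egta_mark_nM / measured
    return replace(trace, ca_nM=trace.ca_nM * factor,
                   scale_factor=trace.scale_factor * factor)


def fibrinogen_relative(trace: BinnedTrace, protocol: ProtocolSpec,
                        windows: WindowConfig = WindowConfig(),
                        slope_warn_frac: float = 0.05) -> np.ndarray:
    """Rescale the fibrinogen channel to quiescent = 0, ionomycin = 1.

    Zero is the median over the pre-agonist baseline, one the median
    over the ionomycin plateau (minutes 5-10 after addition).  A
    non-stationary plateau (|linear drift| over the window above
    ``slope_warn_frac`` of the dynamic range) warns but still computes.
    """
    t_ag = protocol.agonist_time_s
    f = trace.means["FL_FIB"].to_numpy()
    f0 = _window_median(trace, "FL_FIB", t_ag - windows.baseline_span_s,
                        t_ag, "baseline")
    io0 = protocol.ionomycin_time_s + windows.iono_plateau_start_s
    io1 = min(protocol.ionomycin_time_s + windows.iono_plateau_end_s,
              protocol.egta_time_s)
    f1 = _window_median(trace, "FL_FIB", io0, io1, "ionomycin plateau")
    if f1 <= f0:
        raise IncompleteProtocolError(
            "ionomycin plateau not above baseline in FL_FIB")
    m = _window_mask(trace, io0, io1)
    tt = trace.bin_centers_s[m]
    if len(tt) >= 3:
        slope = np.polyfit(tt, f[m], 1)[0]
        if abs(slope) * (io1 - io0) > slope_warn_frac * (f1 - f0):
            warnings.warn("ionomycin plateau fails the stationarity check",
                          stacklevel=2)
    return (f - f0) / (f1 - f0)


def ssc_shape_change(trace: BinnedTrace, protocol: ProtocolSpec,
                     windows: WindowConfig = WindowConfig()) -> float:
    """Relative SSC-A change on activation: (post-agonist max - baseline)/baseline."""
    t_ag = protocol.agonist_time_s
    base = _window_mask(trace, t_ag - windows.baseline_span_s, t_ag)
    resp = _window_mask(trace, t_ag,
                        min(t_ag + windows.response_span_s,
                            protocol.ionomycin_time_s))
    if not base.any() or not resp.any():
        raise IncompleteProtocolError("baseline or response window empty")
    ssc = _smooth(trace.means["SSC_A"].to_numpy(), trace.bin_width_s,
                  windows.smooth_span_s)
    b = float(np.mean(ssc[base]))
    if b <= 0:
        raise ValueError("baseline SSC-A mean must be positive")
    return float(np.max(ssc[resp]) - b) / b


def process_stream(stream: EventStream, protocol: ProtocolSpec,
                   bin_width_s: float = 1.0,
                   windows: WindowConfig = WindowConfig(),
                   kd_furared: float = 400.0,
                   ) -> tuple[BinnedTrace, CalibrationConstants]:
    """Bin, self-calibrate, anchor, and attach derived series."""
    trace = bin_events(stream, bin_width_s)
    consts = extract_calibration(trace, protocol, windows,
                                 kd_furared=kd_furared)
    trace = normalize_calcium(trace, consts, protocol, windows)
    trace = replace(trace,
                    fib_rel=fibrinogen_relative(trace, protocol, windows))
    return trace, consts


def extract_features(stream: EventStream, protocol: ProtocolSpec,
                     bin_width_s: float = 1.0,
                     windows: WindowConfig = WindowConfig(),
                     kd_furared: float = 400.0) -> FeatureVector:
    """Donor-level feature vector from one raw event stream.

    ``ca_basal`` is the mean calibrated calcium over the baseline
    window; ``ca_max`` the maximum within 5 min after the agonist;
    ``fib_rel`` the maximum relative fibrinogen binding in the first
    5 min of activation; ``ssc_change`` the relative SSC-A step.
    """
    trace, _ = process_stream(stream, protocol, bin_width_s, windows,
                              kd_furared)
    t_ag = protocol.agonist_time_s
    base = _window_mask(trace, t_ag - windows.baseline_span_s, t_ag)
    resp = _window_mask(trace, t_ag,
                        min(t_ag + windows.response_span_s,
                            protocol.ionomycin_time_s))
    # Mask the ionomycin epoch before smoothing so the saturation rise
    # cannot bleed into the response-window maximum.
    pre_iono = trace.bin_centers_s < protocol.ionomycin_time_s
    ca_m = np.where(pre_iono, trace.ca_nM, np.nan)
    fib_m = np.where(pre_iono, trace.fib_rel, np.nan)
    ca_s = _smooth(ca_m, trace.bin_width_s, windows.smooth_span_s)
    fib_s = _smooth(fib_m, trace.bin_width_s, windows.smooth_span_s)
    ca_basal = float(np.nanmean(trace.ca_nM[base]))
    ca_max = float(np.nanmax(ca_s[resp]))
    fib = float(np.nanmax(fib_s[resp]))
    ssc = ssc_shape_change(trace, protocol, windows)
    return FeatureVector(
        ca_basal_nM=max(ca_basal, 0.0),
        ca_max_nM=max(ca_max, ca_basal, 0.0),
        fib_rel=fib,
        ssc_change=ssc,
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_events_csv(path: str | Path, donor_id: str | None = None) -> EventStream:
    """Read the CSV event dialect (columns time_s, FSC, SSC_A, FL405, FL488, FL_FIB)."""
    path = Path(path)
    df = pd.read_csv(path)
    return EventStream(donor_id=donor_id or path.stem, events=df)


def write_events_csv(stream: EventStream, path: str | Path) -> None:
    stream.events.to_csv(path, index=False)


def write_trace_tsv(trace: BinnedTrace, path: str | Path) -> None:
    """Per-donor binned trace as TSV (time, channel means, R, calcium, fib_rel)."""
    out = trace.means.copy()
    out.insert(0, "time_s", trace.bin_centers_s)
    out["n_events"] = trace.n_events_per_bin
    out["R"] = trace.R
    if trace.ca_nM is not None:
        out["ca_nM"] = trace.ca_nM
    if trace.fib_rel is not None:
        out["fib_rel"] = trace.fib_rel
    out.to_csv(path, sep="\t", index=False)
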