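"""Seeded synthetic donor cohorts with the published group statistics.

Emulates the continuous-cytometry assay well enough to exercise every
downstream stage: per-event Fura-Red channels are obtained by inverting
the Grynkiewicz relation from a programmed calcium time course, the
fibrinogen channel follows a programmed relative-binding curve scaled
by a donor-specific mean fluorescence, and SSC-A steps up on activation.
Group feature distributions default to the published cohort statistics
(healthy, Glanzmann thrombasthenia, and the ITP high-/low-fibrinogen-
binding subgroups plus unassigned outliers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyStreamError, InvalidSpecError
from .protocol import ProtocolSpec
from .trace_processing import (
    CalibrationConstants,
    EventStream,
    FeatureVector,
)
from .thrombus_analysis import ThrombusTrack

GROUPS = ("healthy", "GT", "ITP_HFB", "ITP_LFB", "ITP_NC")

#: Cytosolic calcium reached under 1 uM ionomycin (nM): the membrane
#: becomes calcium-permeable and the cytosol approaches the buffer.
CA_IONOMYCIN_NM = 2.0e6

#: Agonist-specific transient kinetics (rise and decay constants, s).
#: Only response envelopes are published, so kinetics are fixed at
#: plausible values: fast biphasic transient for ADP/TRAP, a slower
#: sustained rise for CRP.
AGONIST_KINETICS = {
    "ADP": (10.0, 120.0),
    "TRAP": (10.0, 150.0),
    "CRP": (60.0, math.inf),
}


@dataclass(frozen=True)
class GroupSpec:
    """Feature distribution of one donor group; (mean, sd) tuples."""

    group_name: str
    n_donors: int
    ca_basal: tuple[float, float]    # nM
    ca_max: tuple[float, float]      # nM
    fib_rel: tuple[float, float]     # fraction of ionomycin level
    ssc_change: tuple[float, float]  # fractional step on activation
    ssc_mean: tuple[float, float]    # a.u.
    event_rate: float = 500.0        # events/s
    noise_cv: float = 0.25           # per-event multiplicative CV

    def __post_init__(self) -> None:
        if self.group_name not in GROUPS:
            raise InvalidSpecError(f"unknown group {self.group_name!r}")
        if self.n_donors < 0 or self.event_rate < 0 or self.noise_cv < 0:
            raise InvalidSpecError("counts and rates must be nonnegative")
        for name in ("ca_basal", "ca_max", "fib_rel", "ssc_mean"):
            m, s = getattr(self, name)
            if m <= 0 or s < 0:
                raise InvalidSpecError(f"{name}: mean must be > 0, sd >= 0")
        if self.ca_max[0] < self.ca_basal[0]:
            raise InvalidSpecError("group mean ca_max must be >= ca_basal")


@dataclass(frozen=True)
class ThrombusSimSpec:
    """Programmed statistics for a synthetic thrombus field of view."""

    n_thrombi: int = 30
    frac_growing: float = 0.74
    fold_change: tuple[float, float] = (2.7, 0.3)
    area_fraction_final: float = 0.15
    noise_cv: float = 0.05
    frame_interval_s: float = 30.0
    duration_s: float = 1200.0
    fov_area_px: float = 512.0 * 512.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_growing <= 1.0:
            raise InvalidSpecError("frac_growing must lie in [0, 1]")
        if self.fold_change[0] < 1.0:
            raise InvalidSpecError("mean fold change must be >= 1")
        if self.n_thrombi < 0:
            raise InvalidSpecError("n_thrombi must be nonnegative")


@dataclass(frozen=True)
class DonorRecord:
    """Ground truth for one synthetic donor."""

    donor_id: str
    group: str
    features: FeatureVector          # programmed values
    fib_mfi: float                   # donor fibrinogen m.f.i. at saturation
    dye_scale: float                 # donor Fura-Red loading factor
    ssc_mean: float
    event_rate: float
    noise_cv: float


def make_default_group_specs() -> dict[str, GroupSpec]:
    """The five donor groups with the published means and SDs.

    Healthy basal calcium 8.0 +/- 4.7 nM and maximal ~91 +/- 22 nM;
    ITP basal 15 +/- 5 nM with the HFB subgroup reaching 155 +/- 27 nM
    and binding 21% +/- 5% of the ionomycin fibrinogen level versus
    101 +/- 31 nM and 8.2% +/- 4.8% for LFB; GT binds 3.4% +/- 0.9%.
    Shape change is 30-32% for healthy/HFB and 20-25% for GT/LFB.
    """
    return {
        "healthy": GroupSpec("healthy", 14, (8.0, 4.7), (91.0, 22.0),
                             (0.16, 0.04), (0.31, 0.04), (7000.0, 1000.0)),
        "GT": GroupSpec("GT", 8, (8.0, 4.7), (81.0, 23.0),
                        (0.034, 0.009), (0.225, 0.04), (7300.0, 900.0)),
        "ITP_HFB": GroupSpec("ITP_HFB", 12, (15.0, 5.0), (155.0, 27.0),
                             (0.21, 0.05), (0.31, 0.04), (8300.0, 2100.0)),
        "ITP_LFB": GroupSpec("ITP_LFB", 21, (15.0, 5.0), (101.0, 31.0),
                             (0.082, 0.048), (0.225, 0.04),
                             (8200.0, 1500.0)),
        # Unassigned donors fall in low-density regions between/around
        # the two ITP subgroups; handled by uniform outlier draws.
        "ITP_NC": GroupSpec("ITP_NC", 3, (15.0, 8.0), (120.0, 50.0),
                            (0.15, 0.10), (0.27, 0.08), (8000.0, 2000.0)),
    }


def default_generator_constants() -> CalibrationConstants:
    """Instrument-like Fura-Red constants used to synthesise channels."""
    return CalibrationConstants(kd_furared=400.0, fi_max=2000.0,
                                fi_min=600.0, r_min=0.20, r_max=3.0)


# --------------------------------------------------------------------------
# Calcium target curve
# --------------------------------------------------------------------------


def synthesize_calcium_target(ca_basal: float, ca_max: float,
                              protocol: ProtocolSpec,
                              constants: CalibrationConstants | None = None,
                              ca_iono_nM: float = CA_IONOMYCIN_NM):
    """Ground-truth cytosolic calcium curve (nM) for the generator.

    Flat at ``ca_basal`` before the agonist; a transient peaking at
    ``ca_max`` after it; a rise toward the ionomycin-saturated level;
    and relaxation to the EGTA-buffered free calcium at the end.
    Returns a vectorised callable time -> nM.
    """
    if ca_max < ca_basal:
        raise InvalidSpecError("ca_max must be >= ca_basal")
    constants = constants or default_generator_constants()
    mark = constants.egta_mark_nM
    tau_r, tau_d = AGONIST_KINETICS.get(protocol.agonist, (10.0, 120.0))

    if protocol.agonist == "none" or ca_max == ca_basal:
        def transient(dt):
            return np.zeros_like(dt)
    else:
        if math.isinf(tau_d):
            def shape(dt):
                return 1.0 - np.exp(-dt / tau_r)
            peak_t = protocol.ionomycin_time_s - protocol.agonist_time_s
        else:
            peak_t = tau_r * math.log1p(tau_d / tau_r)

            def shape(dt):
                return (1.0 - np.exp(-dt / tau_r)) * np.exp(-dt / tau_d)
        norm = float(shape(np.asarray(peak_t)))

        def transient(dt):
            return (ca_max - ca_basal) * shape(dt) / norm

    t_ag, t_io, t_eg = (protocol.agonist_time_s,
                        protocol.ionomycin_time_s, protocol.egta_time_s)
    tau_io, tau_eg = 20.0, 1.0  # EGTA chelation is effectively instant

    def ca_pre_iono(t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, float(ca_basal))
        m = t >= t_ag
        out[m] = ca_basal + transient(t[m] - t_ag)
        return out

    ca_at_io = float(ca_pre_iono(np.asarray([t_io]))[0])

    def ca_iono_phase(t):
        dt = np.asarray(t, dtype=float) - t_io
        return ca_at_io + (ca_iono_nM - ca_at_io) * (1.0 - np.exp(-dt / tau_io))

    ca_at_eg = float(ca_iono_phase(np.asarray([t_eg]))[0])

    def target(t):
        t = np.asarray(t, dtype=float)
        out = ca_pre_iono(t)
        m = t >= t_io
        out[m] = ca_iono_phase(t[m])
        m = t >= t_eg
        out[m] = mark + (ca_at_eg - mark) * np.exp(-(t[m] - t_eg) / tau_eg)
        return out

    return target


def _fib_curve(fib_rel: float, protocol: ProtocolSpec):
    """Relative fibrinogen-binding curve: 0 at rest, 1 at ionomycin plateau."""
    t_ag, t_io = protocol.agonist_time_s, protocol.ionomycin_time_s
    tau_ag, tau_io = 45.0, 60.0
    level = 0.0 if protocol.agonist == "none" else fib_rel
    at_io = level * (1.0 - math.exp(-(t_io - t_ag) / tau_ag))

    def curve(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        m = (t >= t_ag) & (t < t_io)
        out[m] = level * (1.0 - np.exp(-(t[m] - t_ag) / tau_ag))
        m = t >= t_io
        out[m] = at_io + (1.0 - at_io) * (1.0 - np.exp(-(t[m] - t_io) / tau_io))
        return out

    return curve


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int):
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=n)


# --------------------------------------------------------------------------
# Event-stream synthesis
# --------------------------------------------------------------------------


def _stream_for_donor(donor: DonorRecord, protocol: ProtocolSpec,
                      constants: CalibrationConstants,
                      rng: np.random.Generator) -> EventStream:
    if donor.event_rate <= 0:
        raise EmptyStreamError("event_rate must be positive to emit events")
    f = donor.features
    n = rng.poisson(donor.event_rate * protocol.run_end_s)
    if n == 0:
        raise EmptyStreamError("Poisson draw produced no events")
    t = np.sort(rng.uniform(0.0, protocol.run_end_s, size=n))

    ca = synthesize_calcium_target(f.ca_basal_nM, f.ca_max_nM, protocol,
                                   constants)(t)
    k_eff = constants.k_eff
    c = ca / k_eff
    ratio = (constants.r_min + constants.r_max * c) / (1.0 + c)
    # Two-state dye fluorescence on the 488 nm (calcium-free) channel.
    bound = ca / (ca + constants.kd_furared)
    fl488 = (constants.fi_max * (1.0 - bound)
             + constants.fi_min * bound) * donor.dye_scale
    fl405 = ratio * fl488

    fib = _fib_curve(f.fib_rel, protocol)(t)
    fl_fib = 25.0 + donor.fib_mfi * fib

    dt_ag = t - protocol.agonist_time_s
    step = np.where(dt_ag >= 0, 1.0 - np.exp(-np.maximum(dt_ag, 0) / 30.0), 0.0)
    ssc = donor.ssc_mean * (1.0 + f.ssc_change * step)
    fsc = np.full(n, 500.0)

    cv = donor.noise_cv
    events = pd.DataFrame({
        "time_s": t,
        "FSC": fsc * _lognormal_factors(rng, cv, n),
        "SSC_A": ssc * _lognormal_factors(rng, cv, n),
        "FL405": fl405 * _lognormal_factors(rng, cv, n),
        "FL488": fl488 * _lognormal_factors(rng, cv, n),
        "FL_FIB": fl_fib * _lognormal_factors(rng, cv, n),
    })
    return EventStream(donor_id=donor.donor_id, events=events)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = 0.0, hi: float = math.inf) -> float:
    """Resample until the draw falls inside [lo, hi]."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InvalidSpecError(
        f"cannot draw N({mean}, {sd}) within [{lo}, {hi}]")


def _draw_donor(group: GroupSpec, rng: np.random.Generator,
                donor_id: str,
                nc_bounds: dict[str, tuple[float, float]] | None = None,
                ) -> DonorRecord:
    if group.group_name == "ITP_NC" and nc_bounds is not None:
        # Outliers live in low-density regions: uniform draws over the
        # union of subgroup ranges, rejected while within 2 SD of both
        # subgroup centres on every coordinate.
        keys = ("ca_basal", "ca_max", "fib_rel", "ssc_change")
        centers = nc_bounds["centers"]
        for _ in range(1000):
            vals = {k: float(rng.uniform(*nc_bounds[k])) for k in keys}
            x = np.array([vals[k] for k in keys])
            dist = min(
                float(np.max(np.abs((x - m) / np.maximum(s, 1e-12))))
                for m, s in centers)
            if dist >= 2.0:
                break
        if vals["ca_max"] < vals["ca_basal"]:
            vals["ca_max"] = vals["ca_basal"]
    else:
        vals = {
            "ca_basal": _truncated_normal(rng, *group.ca_basal),
            "ca_max": _truncated_normal(rng, *group.ca_max),
            "fib_rel": _truncated_normal(rng, *group.fib_rel, hi=1.5),
            "ssc_change": _truncated_normal(rng, *group.ssc_change),
        }
        while vals["ca_max"] < vals["ca_basal"]:
            vals["ca_max"] = _truncated_normal(rng, *group.ca_max)
    features = FeatureVector(vals["ca_basal"], vals["ca_max"],
                             vals["fib_rel"], vals["ssc_change"])
    # Donor-to-donor fibrinogen fluorescence varies widely (450 +/- 250
    # m.f.i. at saturation); dye loading varies too but cancels in R.
    mfi = _truncated_normal(rng, 450.0, 250.0, lo=50.0)
    dye = _truncated_normal(rng, 1.0, 0.3, lo=0.2)
    ssc_mean = _truncated_normal(rng, *group.ssc_mean, lo=100.0)
    return DonorRecord(donor_id=donor_id, group=group.group_name,
                       features=features, fib_mfi=mfi, dye_scale=dye,
                       ssc_mean=ssc_mean, event_rate=group.event_rate,
                       noise_cv=group.noise_cv)


def _nc_bounds(specs: dict[str, GroupSpec]) -> dict:
    """Uniform outlier ranges: union of HFB/LFB ranges +/- 2 SD, >= 0."""
    keys = ("ca_basal", "ca_max", "fib_rel", "ssc_change")
    out: dict = {}
    anchors = [g for g in ("ITP_HFB", "ITP_LFB") if g in specs] or ["ITP_NC"]
    for key in keys:
        los, his = [], []
        for g in anchors:
            m, s = getattr(specs[g], key)
            los.append(m - 2 * s)
            his.append(m + 2 * s)
        out[key] = (max(min(los), 0.0), max(his))
    out["centers"] = [
        (np.array([getattr(specs[g], k)[0] for k in keys]),
         np.array([getattr(specs[g], k)[1] for k in keys]))
        for g in anchors
    ]
    return out


def make_donor_stream(features: FeatureVector, protocol: ProtocolSpec,
                      constants: CalibrationConstants | None = None,
                      seed: int = 0, event_rate: float = 500.0,
                      noise_cv: float = 0.25, fib_mfi: float = 450.0,
                      dye_scale: float = 1.0, ssc_mean: float = 7000.0,
                      donor_id: str = "donor") -> EventStream:
    """Event stream for one donor with explicitly programmed features."""
    constants = constants or default_generator_constants()
    donor = DonorRecord(donor_id=donor_id, group="healthy",
                        features=features, fib_mfi=fib_mfi,
                        dye_scale=dye_scale, ssc_mean=ssc_mean,
                        event_rate=event_rate, noise_cv=noise_cv)
    rng = np.random.default_rng(seed)
    return _stream_for_donor(donor, protocol, constants, rng)


def generate_event_stream(group: GroupSpec, protocol: ProtocolSpec,
                          constants: CalibrationConstants | None = None,
                          seed: int = 0) -> EventStream:
    """One synthetic donor run drawn from a group specification."""
    constants = constants or default_generator_constants()
    rng = np.random.default_rng(seed)
    donor = _draw_donor(group, rng, f"{group.group_name}_{seed}")
    return _stream_for_donor(donor, protocol, constants, rng)


def draw_cohort_records(specs: dict[str, GroupSpec],
                        seed: int = 0) -> list[DonorRecord]:
    """Donor ground-truth records for a cohort, without event streams.

    This is the fast path for clustering studies: the programmed
    feature vectors are exactly what noiseless processing would
    recover from the corresponding streams.
    """
    if not specs:
        raise InvalidSpecError("specs must be nonempty")
    rng = np.random.default_rng(seed)
    bounds = _nc_bounds(specs) if "ITP_NC" in specs else None
    records = []
    for name in sorted(specs):
        group = specs[name]
        for i in range(group.n_donors):
            records.append(_draw_donor(group, rng, f"{name}_{i:02d}",
                                       nc_bounds=bounds))
    return records


def generate_cohort(specs: dict[str, GroupSpec], protocol: ProtocolSpec,
                    seed: int = 0,
                    constants: CalibrationConstants | None = None,
                    ) -> list[tuple[DonorRecord, EventStream]]:
    """One event stream per donor, plus the ground truth that made it."""
    constants = constants or default_generator_constants()
    records = draw_cohort_records(specs, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return [(rec, _stream_for_donor(rec, protocol, constants, rng))
            for rec in records]


def cohort_manifest(records: list[DonorRecord]) -> pd.DataFrame:
    """Cohort manifest table (donor_id, true group, programmed features)."""
    return pd.DataFrame([{
        "donor_id": r.donor_id,
        "true_group": r.group,
        "ca_basal_nM": r.features.ca_basal_nM,
        "ca_max_nM": r.features.ca_max_nM,
        "fib_rel": r.features.fib_rel,
        "ssc_change": r.features.ssc_change,
    } for r in records])


# --------------------------------------------------------------------------
# Thrombus dataset
# --------------------------------------------------------------------------


def generate_thrombus_dataset(spec: ThrombusSimSpec,
                              seed: int = 0) -> list[ThrombusTrack]:
    """Synthetic per-object thrombus time series for one field of view.

    Growing tracks follow accelerating DiOC6-intensity growth to a
    drawn fold change (platelet recruitment speeds up as a thrombus
    matures, so the steepest rise sits in the final windows — this
    matches the published growth velocities, which far exceed what a
    uniform exponential with the same total fold change would give);
    non-growing tracks fluctuate about their initial intensity with
    the programmed CV.  Areas are scaled so the final total area
    matches ``area_fraction_final`` of the field.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_thrombi
    if n == 0:
        return []
    times = np.arange(0.0, spec.duration_s + 0.5 * spec.frame_interval_s,
                      spec.frame_interval_s)
    n_grow = int(round(spec.frac_growing * n))
    grow_flags = np.array([True] * n_grow + [False] * (n - n_grow))

    weights = rng.uniform(0.5, 1.5, size=n)
    final_total = spec.area_fraction_final * spec.fov_area_px
    final_areas = final_total * weights / weights.sum()

    # growth exponent ramp: s(0) = 0, s(T) = 1, steepest at the end,
    # so a growing thrombus is still growing in its final 2-min window
    k_accel = 4.0
    s = np.expm1(k_accel * times / spec.duration_s) / math.expm1(k_accel)

    tracks = []
    for i in range(n):
        base_intensity = rng.uniform(80.0, 120.0)
        if grow_flags[i]:
            fold = max(_truncated_normal(rng, *spec.fold_change, lo=1.35), 1.35)
            growth = fold ** s
        else:
            fold = 1.0
            growth = np.ones_like(times)
        noise = _lognormal_factors(rng, spec.noise_cv, len(times))
        intensity = base_intensity * growth * noise
        area_final = final_areas[i]
        area0 = area_final / (fold if grow_flags[i] else 1.0)
        area = area0 * growth * _lognormal_factors(rng, spec.noise_cv,
                                                   len(times))
        tracks.append(ThrombusTrack(
            object_id=f"thr_{i:03d}",
            times_s=times.copy(),
            area_px=area,
            mean_intensity=intensity,
            fov_id="fov_0",
        ))
    return tracks
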