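"""ODE model of platelet calcium signaling and integrin activation.

The model follows calcium exchange between the cytosol, the dense
tubular system (DTS, the platelet calcium store) and a mitochondrial
pool, driven by receptor signaling:

* G-protein coupled receptors (ADP: P2Y1/P2Y12; thrombin/TRAP:
  PAR1/PAR4) and the collagen receptor GPVI activate phospholipase C,
  producing IP3 and DAG.
* IP3 opens the IP3 receptor on the DTS (IP3-gated, with biphasic
  calcium dependence), releasing stored calcium; SERCA refills the
  store and PMCA extrudes calcium; linear leaks and a store-operated
  entry (SOCE) term on the plasma membrane set the resting state; a
  uniporter/NCLX pair with a threshold-gated permeability transition
  pore couples the mitochondrion.
* Calcium activates CalDAGGEFI, loading the small GTPase Rap1 with
  GTP; PI3K (Gbeta-gamma from P2Y12, tyrosine-kinase from GPVI) makes
  PIP3, which inhibits the Rap1 GAP RASA3; Gα_i from P2Y12 lowers
  cAMP and thereby relieves PKA inhibition of CalDAGGEFI.  Rap1-GTP
  switches integrin αIIbβ3 to its active conformation, which binds
  fibrinogen ("inside-out" activation).

Four phenotype variants reproduce the donor subgroups: N (baseline,
resting cytosolic calcium 10 nM), LFB (increased DTS membrane
conductivity, rest tuned to 15 nM), LFB* (LFB with 75% of normal
Rap1), and HFB (constant quiescent PLC activity, rest tuned to 15 nM).
Variant levers are calibrated by deterministic 1-D root-finding, never
by hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .exceptions import ConvergenceError, InvalidSpecError

VARIANTS = ("N", "LFB", "LFB_star", "HFB")

STATE_NAMES = (
    "ca_cyt",        # nM
    "ca_dts",        # uM
    "ca_mit",        # uM
    "ip3",           # uM
    "dag",           # uM
    "pip3",          # fraction of membrane sites
    "rasa3_active",  # fraction
    "rap1_gtp",      # fraction of total Rap1
    "integrin_active",  # fraction of surface integrin
    "fib_bound",     # fraction of saturable fibrinogen sites
    "camp",          # uM
    "r_p2y1", "z_p2y1",
    "r_p2y12", "z_p2y12",
    "r_par1", "z_par1",
    "r_par4", "z_par4",
    "r_gpvi", "z_gpvi",
)

_RECEPTORS = ("p2y1", "p2y12", "par1", "par4", "gpvi")
_AGONIST_TARGETS = {
    "ADP": ("p2y1", "p2y12"),
    "TRAP": ("par1", "par4"),
    "CRP": ("gpvi",),
}


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants; units noted per field.  Time in seconds."""

    # compartment volume ratios (cytosol : store / mitochondrion)
    vol_cyt_over_dts: float = 10.0
    vol_cyt_over_mit: float = 50.0

    # IP3 receptor (release flux = (v_ip3r * P_open + leak) * gradient)
    v_ip3r: float = 0.01          # 1/s
    k_ip3: float = 0.40           # uM, IP3 gate
    n_ip3: float = 4.0            # cooperative IP3 gating (4 subunits)
    k_ip3r_act: float = 150.0     # nM, activating Ca gate (Hill 2)
    k_ip3r_inh: float = 110.0     # nM, inhibitory Ca gate (Hill 4)

    # SERCA / DTS leak
    v_serca: float = 200.0        # nM/s
    k_serca: float = 150.0        # nM (Hill 2)
    g_dts_leak: float = 1.77e-6   # 1/s
    dts_leak_scale: float = 1.0   # LFB lever

    # plasma membrane
    v_pm_leak: float = 0.095      # nM/s, solved so N rests at 10 nM
    pm_leak_scale: float = 1.0
    v_pmca: float = 50.0          # nM/s
    k_pmca: float = 100.0         # nM (Hill 2)
    v_soce: float = 2.0           # nM/s, store-operated entry
    k_soce: float = 458.6         # uM of DTS calcium at half activity
    n_soce: float = 16.0          # STIM1 oligomerisation makes it steep

    # mitochondrion
    v_uni: float = 50.0           # nM/s
    k_uni: float = 2000.0         # nM (Hill 2)
    v_nclx: float = 1.0           # nM/s
    k_nclx: float = 10.0          # uM
    v_mptp: float = 5.0           # nM/s
    mptp_threshold: float = 5.0   # uM mitochondrial Ca
    mptp_width: float = 0.5       # uM

    # receptors: EC50 (uM), activation and desensitisation rates (1/s)
    ec50: dict = field(default_factory=lambda: {
        "p2y1": 1.0, "p2y12": 1.0, "par1": 5.0, "par4": 50.0, "gpvi": 1.0})
    k_act: float = 0.15
    k_des: dict = field(default_factory=lambda: {
        "p2y1": 0.02, "p2y12": 0.003, "par1": 0.035, "par4": 0.01,
        "gpvi": 0.005})
    k_resens: float = 0.002

    # PLC arms (uM IP3 / s at full receptor activity)
    v_plc_gq: dict = field(default_factory=lambda: {
        "p2y1": 0.0544, "par1": 0.046, "par4": 0.0163})
    v_plc_gpvi: float = 0.068
    # calcium-activated PLC (delta-type): irrelevant during ~100 nM
    # agonist transients, dominant under ionomycin calcium overload,
    # where it supplies the DAG for full CalDAGGEFI/integrin engagement
    v_plc_ca: float = 0.20        # uM/s at saturating calcium
    k_plc_ca: float = 2000.0      # nM (Hill 2)
    basal_plc: float = 0.0        # HFB lever (uM IP3 / s)
    k_ip3_deg: float = 0.15       # 1/s
    k_dag_deg: float = 0.10       # 1/s

    # PI3K -> PIP3 -> RASA3
    w_pi3k_gi: float = 1.0        # P2Y12 (Gbeta-gamma) weight
    w_pi3k_gpvi: float = 1.0      # Syk/Src weight
    k_pip3_on: float = 0.05       # 1/s
    k_pip3_off: float = 0.01      # 1/s
    k_rasa3_pip3: float = 0.30    # PIP3 level halving RASA3 (Hill 2)
    k_rasa3_relax: float = 0.05   # 1/s

    # cAMP / PKA
    v_ac: float = 0.02            # uM/s
    k_pde: float = 0.02           # 1/s
    g_gi: float = 2.5             # Gα_i inhibition gain on AC
    k_pka: float = 2.0            # uM cAMP halving CalDAGGEFI (Hill 2)

    # CalDAGGEFI -> Rap1 cycle: a calcium/DAG coincidence detector,
    # so quiescent calcium differences alone do not load Rap1
    k_cdg_ca: float = 300.0       # nM
    n_cdg: float = 4.0            # steep calcium dependence (EF hands)
    k_cdg_dag: float = 0.20       # uM DAG at half activity
    k_rap_on: float = 12.0        # 1/s at full CalDAGGEFI activity
    k_rap_gap: float = 0.2        # 1/s at full RASA3 activity
    k_rap_gap0: float = 0.05      # 1/s basal hydrolysis
    rap1_total_scale: float = 1.0  # LFB* lever

    # integrin and fibrinogen
    k_int_on: float = 0.3         # 1/s at full Rap1-GTP
    k_int_off: float = 0.1        # 1/s
    k_fib_on: float = 0.015       # 1/s at full integrin activity
    k_fib_off: float = 5.0e-5     # 1/s, bound fibrinogen is stable

    # ionomycin surrogate (membrane permeabilisation)
    v_iono: float = 5.0e-3        # 1/s toward external calcium
    ec50_iono: float = 0.3        # uM
    ca_external: float = 2.0e6    # nM (2 mM Tyrode)

    variant: str = "N"


@dataclass
class ModelState:
    """Named view of the state vector."""

    values: np.ndarray

    def __getattr__(self, name):
        try:
            return float(self.values[STATE_NAMES.index(name)])
        except ValueError as exc:
            raise AttributeError(name) from exc

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class StimulusProtocol:
    """Sequence of agonist additions: (time_s, agonist, dose in uM)."""

    additions: tuple = ()

    def __post_init__(self) -> None:
        times = [a[0] for a in self.additions]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise InvalidSpecError("addition times must be increasing")
        for _, agonist, dose in self.additions:
            if agonist not in (*_AGONIST_TARGETS, "ionomycin"):
                raise InvalidSpecError(f"unknown agonist {agonist!r}")
            if dose < 0:
                raise InvalidSpecError("doses must be nonnegative")

    def doses_at(self, t: float) -> dict[str, float]:
        doses: dict[str, float] = {}
        for t0, agonist, dose in self.additions:
            if t >= t0:
                doses[agonist] = doses.get(agonist, 0.0) + dose
        return doses


@dataclass
class SimulationResult:
    """Trajectories on a fixed output grid plus derived series."""

    times: np.ndarray
    trajectories: pd.DataFrame      # state + algebraic columns
    fib_rel: np.ndarray             # fibrinogen binding, ionomycin = 1
    resting_state: ModelState
    fib_reference: float

    def peak(self, column: str, t0: float = 0.0,
             t1: float = math.inf) -> float:
        m = (self.times >= t0) & (self.times <= t1)
        return float(self.trajectories.loc[m, column].max())


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------


def _hill2(x, k):
    x2 = x * x
    return x2 / (x2 + k * k)


def _algebraic(y: np.ndarray, p: ModelParameters,
               doses: dict[str, float]) -> dict[str, float]:
    idx = {n: i for i, n in enumerate(STATE_NAMES)}
    r = {rec: y[idx[f"r_{rec}"]] for rec in _RECEPTORS}
    ca_for_plc = max(y[idx["ca_cyt"]], 0.0)
    plc = (p.basal_plc
           + sum(v * r[rec] for rec, v in p.v_plc_gq.items())
           + p.v_plc_gpvi * r["gpvi"]
           + p.v_plc_ca * _hill2(ca_for_plc, p.k_plc_ca))
    pi3k = min(p.w_pi3k_gi * r["p2y12"] + p.w_pi3k_gpvi * r["gpvi"], 1.0)
    camp = y[idx["camp"]]
    ca = max(y[idx["ca_cyt"]], 0.0)
    dag = max(y[idx["dag"]], 0.0)
    ca_gate = ca ** p.n_cdg / (ca ** p.n_cdg + p.k_cdg_ca ** p.n_cdg)
    cdg = (ca_gate * dag / (dag + p.k_cdg_dag)
           * (p.k_pka ** 2 / (p.k_pka ** 2 + camp ** 2)))
    return {"plc_active": plc, "pi3k_active": pi3k, "cdg_active": cdg}


def rhs(t: float, y: np.ndarray, p: ModelParameters,
        protocol: StimulusProtocol) -> np.ndarray:
    """Time derivative of the full state vector."""
    idx = {n: i for i, n in enumerate(STATE_NAMES)}
    ca = max(y[idx["ca_cyt"]], 0.0)       # nM
    ca_dts = max(y[idx["ca_dts"]], 0.0)   # uM
    ca_mit = max(y[idx["ca_mit"]], 0.0)   # uM
    ip3 = max(y[idx["ip3"]], 0.0)
    dag = max(y[idx["dag"]], 0.0)
    pip3 = y[idx["pip3"]]
    rasa3 = y[idx["rasa3_active"]]
    rap1 = y[idx["rap1_gtp"]]
    integ = y[idx["integrin_active"]]
    fib = y[idx["fib_bound"]]
    camp = max(y[idx["camp"]], 0.0)

    doses = protocol.doses_at(t)
    alg = _algebraic(y, p, doses)

    dy = np.zeros_like(y)

    # receptor pools: naive -> active -> desensitised (slow recovery)
    for rec in _RECEPTORS:
        dose = sum(d for ag, d in doses.items()
                   if rec in _AGONIST_TARGETS.get(ag, ()))
        occ = dose / (dose + p.ec50[rec]) if dose > 0 else 0.0
        r = y[idx[f"r_{rec}"]]
        z = y[idx[f"z_{rec}"]]
        naive = max(1.0 - r - z, 0.0)
        dy[idx[f"r_{rec}"]] = p.k_act * occ * naive - p.k_des[rec] * r
        dy[idx[f"z_{rec}"]] = p.k_des[rec] * r - p.k_resens * z

    # phosphoinositide and cAMP signaling
    plc = alg["plc_active"]
    dy[idx["ip3"]] = plc - p.k_ip3_deg * ip3
    dy[idx["dag"]] = plc - p.k_dag_deg * dag
    pi3k = alg["pi3k_active"]
    dy[idx["pip3"]] = p.k_pip3_on * pi3k * (1.0 - pip3) - p.k_pip3_off * pip3
    rasa3_target = p.k_rasa3_pip3 ** 2 / (p.k_rasa3_pip3 ** 2 + pip3 ** 2)
    dy[idx["rasa3_active"]] = p.k_rasa3_relax * (rasa3_target - rasa3)
    gi = y[idx["r_p2y12"]]
    dy[idx["camp"]] = p.v_ac / (1.0 + p.g_gi * gi) - p.k_pde * camp

    # calcium fluxes, all in nM/s referred to the cytosol
    grad_dts = ca_dts * 1.0e3 - ca
    ip3_gate = ip3 ** p.n_ip3 / (ip3 ** p.n_ip3 + p.k_ip3 ** p.n_ip3)
    p_open = (ip3_gate * _hill2(ca, p.k_ip3r_act)
              * p.k_ip3r_inh ** 4 / (p.k_ip3r_inh ** 4 + ca ** 4))
    j_rel = (p.v_ip3r * p_open
             + p.g_dts_leak * p.dts_leak_scale) * grad_dts
    j_serca = p.v_serca * _hill2(ca, p.k_serca)
    soce = p.v_soce / (1.0 + (ca_dts / p.k_soce) ** p.n_soce)
    iono = doses.get("ionomycin", 0.0)
    iono_frac = iono / (iono + p.ec50_iono) if iono > 0 else 0.0
    j_iono = p.v_iono * iono_frac * (p.ca_external - ca)
    j_in = p.v_pm_leak * p.pm_leak_scale + soce + j_iono
    j_pmca = p.v_pmca * _hill2(ca, p.k_pmca)
    j_uni = p.v_uni * _hill2(ca, p.k_uni)
    j_nclx = p.v_nclx * ca_mit / (ca_mit + p.k_nclx)
    mptp_open = 1.0 / (1.0 + math.exp(-(ca_mit - p.mptp_threshold)
                                      / p.mptp_width))
    j_mptp = p.v_mptp * mptp_open

    dy[idx["ca_cyt"]] = (j_rel - j_serca + j_in - j_pmca
                         - j_uni + j_nclx + j_mptp)
    dy[idx["ca_dts"]] = -(j_rel - j_serca) * p.vol_cyt_over_dts * 1.0e-3
    # ionomycin also permeabilises the store membrane
    if iono_frac > 0.0:
        j_iono_dts = p.v_iono * iono_frac * grad_dts
        dy[idx["ca_cyt"]] += j_iono_dts
        dy[idx["ca_dts"]] -= j_iono_dts * p.vol_cyt_over_dts * 1.0e-3
    dy[idx["ca_mit"]] = ((j_uni - j_nclx - j_mptp)
                         * p.vol_cyt_over_mit * 1.0e-3)

    # Rap1 cycle (rap1 + rap1_gdp = 1 by construction)
    cdg = alg["cdg_active"]
    dy[idx["rap1_gtp"]] = (p.k_rap_on * cdg * (1.0 - rap1)
                           - (p.k_rap_gap * rasa3 + p.k_rap_gap0) * rap1)

    # integrin activation and fibrinogen binding
    rap_eff = rap1 * p.rap1_total_scale
    dy[idx["integrin_active"]] = (p.k_int_on * rap_eff * (1.0 - integ)
                                  - p.k_int_off * integ)
    dy[idx["fib_bound"]] = (p.k_fib_on * integ * (1.0 - fib)
                            - p.k_fib_off * fib)
    return dy


# --------------------------------------------------------------------------
# Steady state and simulation
# --------------------------------------------------------------------------

_NO_STIMULUS = StimulusProtocol()


def _initial_guess(p: ModelParameters) -> np.ndarray:
    y = np.zeros(len(STATE_NAMES))
    idx = {n: i for i, n in enumerate(STATE_NAMES)}
    y[idx["ca_cyt"]] = 10.0
    y[idx["ca_dts"]] = 500.0
    y[idx["ca_mit"]] = 0.1
    y[idx["rasa3_active"]] = 1.0
    y[idx["camp"]] = p.v_ac / p.k_pde
    return y


def _integrate(p: ModelParameters, protocol: StimulusProtocol,
               y0: np.ndarray, t0: float, t1: float,
               t_eval: np.ndarray | None = None, rtol: float = 1e-8):
    atol = np.full(len(STATE_NAMES), 1e-10)
    atol[STATE_NAMES.index("ca_cyt")] = 1e-6
    sol = solve_ivp(rhs, (t0, t1), y0, args=(p, protocol),
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
                    max_step=50.0)
    if not sol.success:
        raise ConvergenceError(f"integrator failed: {sol.message}")
    return sol


def find_resting_state(p: ModelParameters,
                       max_time_s: float = 1.0e4) -> ModelState:
    """Integrate without stimulus to steady state and polish it.

    Convergence requires a relative state change below 1e-8 over
    100 s of model time; the integrated point is then polished with a
    damped Newton solve of ``rhs = 0`` for machine-precision rest.
    """
    y = _initial_guess(p)
    t = 0.0
    chunk = 1000.0
    delta = math.inf
    while t < max_time_s:
        sol = _integrate(p, _NO_STIMULUS, y, 0.0, chunk, rtol=1e-10)
        y = sol.y[:, -1]
        t += chunk
        # Newton polish of rhs = 0 accelerates the slowest modes
        # (store filling and the fibrinogen off-rate relax over 1e3-1e5 s).
        for method in ("hybr", "lm"):
            polished = root(lambda v: rhs(0.0, v, p, _NO_STIMULUS), y,
                            method=method, tol=1e-13)
            if polished.success and np.all(polished.x[:11] > -1e-12):
                resid = np.max(np.abs(rhs(0.0, polished.x, p,
                                          _NO_STIMULUS)))
                if resid < 1e-9:
                    y = polished.x
                    break
        scale = np.maximum(np.abs(y), 1e-6)
        probe = _integrate(p, _NO_STIMULUS, y, 0.0, 100.0, rtol=1e-10)
        delta = np.max(np.abs(probe.y[:, -1] - y) / scale)
        if delta < 1e-8:
            return ModelState(values=y)
    raise ConvergenceError(
        f"no steady state within {max_time_s:.0f} s of model time "
        f"(last relative change {delta:.2e})")


def _trajectory_frame(sol_t, sol_y, p, protocol) -> pd.DataFrame:
    df = pd.DataFrame(sol_y.T, columns=STATE_NAMES)
    alg = [_algebraic(sol_y[:, i], p, protocol.doses_at(sol_t[i]))
           for i in range(len(sol_t))]
    for key in ("plc_active", "pi3k_active", "cdg_active"):
        df[key] = [a[key] for a in alg]
    return df


_DICT_FIELDS = ("ec50", "k_des", "v_plc_gq")


@lru_cache(maxsize=32)
def _fib_reference_cached(params_key: tuple) -> float:
    kwargs = {k: (dict(v) if k in _DICT_FIELDS else v)
              for k, v in params_key}
    return _fib_reference(ModelParameters(**kwargs))


def _params_key(p: ModelParameters) -> tuple:
    items = []
    for f in p.__dataclass_fields__:
        v = getattr(p, f)
        items.append((f, tuple(sorted(v.items())) if isinstance(v, dict)
                      else v))
    return tuple(items)


def _fib_reference(p: ModelParameters) -> float:
    """Saturating fibrinogen binding under the ionomycin surrogate.

    Mirrors the experimental convention: 10 min of 1 uM ionomycin
    defines relative binding = 1.
    """
    rest = find_resting_state(p)
    protocol = StimulusProtocol(additions=((0.0, "ionomycin", 1.0),))
    sol = _integrate(p, protocol, rest.as_array(), 0.0, 600.0)
    fib = sol.y[STATE_NAMES.index("fib_bound"), -1]
    return float(fib)


def fib_reference(p: ModelParameters) -> float:
    key = _params_key(p)
    try:
        return _fib_reference_cached(key)
    except TypeError:  # unhashable custom dicts: compute directly
        return _fib_reference(p)


def simulate_protocol(p: ModelParameters, protocol: StimulusProtocol,
                      duration_s: float, dt_out: float = 1.0,
                      rest: ModelState | None = None) -> SimulationResult:
    """Integrate across addition discontinuities from the resting state.

    The integrator is restarted at every addition time so the stiff
    solver never steps across a discontinuous stimulus.
    """
    rest = rest or find_resting_state(p)
    y = rest.as_array().copy()
    edges = ([0.0]
             + [t for t, _, _ in protocol.additions if 0 < t < duration_s]
             + [duration_s])
    times, states = [], []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        grid = np.arange(math.ceil(t0 / dt_out) * dt_out,
                         t1 + 0.5 * dt_out, dt_out)
        grid = grid[(grid >= t0) & (grid <= t1)]
        # evaluate stimulus strictly inside the segment
        seg = _integrate(p, protocol, y, t0, t1, t_eval=grid)
        times.append(seg.t)
        states.append(seg.y)
        y = seg.y[:, -1]
    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    t_all, y_all = t_all[keep], y_all[:, keep]
    df = _trajectory_frame(t_all, y_all, p, protocol)
    ref = fib_reference(p)
    fib0 = rest.fib_bound
    fib_rel = (df["fib_bound"].to_numpy() - fib0) / max(ref - fib0, 1e-12)
    df["fib_rel"] = fib_rel
    return SimulationResult(times=t_all, trajectories=df, fib_rel=fib_rel,
                            resting_state=rest, fib_reference=ref)


# --------------------------------------------------------------------------
# Variants
# --------------------------------------------------------------------------

_REST_TARGETS = {"N": 10.0, "LFB": 15.0, "LFB_star": 15.0, "HFB": 15.0}


def _resting_ca(p: ModelParameters) -> float:
    return find_resting_state(p).ca_cyt


def _tune_lever(base: ModelParameters, lever: str, lo: float, hi: float,
                target_nM: float) -> ModelParameters:
    """Solve the 1-D lever so the no-stimulus rest hits ``target_nM``.

    The bracket is grown geometrically from ``lo``; an endpoint where
    the model no longer settles (e.g. basal PLC so high the system
    oscillates) terminates the expansion.
    """
    def f(x):
        return _resting_ca(replace(base, **{lever: x})) - target_nM

    f_lo = f(lo)
    if f_lo > 0:
        raise ConvergenceError(
            f"{lever}={lo} already rests above {target_nM} nM")
    x = lo
    f_hi = f_lo
    hi_ok = None
    while x < hi:
        x = min(max(x * 4.0, lo + 0.01 * (hi - lo)), hi)
        try:
            f_hi = f(x)
        except ConvergenceError:
            break
        if f_hi > 0:
            hi_ok = x
            break
        lo, f_lo = x, f_hi
    if hi_ok is None:
        raise ConvergenceError(
            f"could not bracket {lever} for rest = {target_nM} nM")
    value = brentq(f, lo, hi_ok, xtol=1e-8, rtol=1e-12, maxiter=100)
    return replace(base, **{lever: value})


@lru_cache(maxsize=8)
def default_parameters(variant: str = "N") -> ModelParameters:
    """Calibrated parameters for a phenotype variant.

    N's plasma-membrane leak is solved so the quiescent steady state
    sits at 10 nM cytosolic calcium.  LFB multiplies the DTS leak
    conductance and HFB adds constant quiescent PLC activity, each
    root-found so rest moves to 15 nM; LFB* is LFB with Rap1 reduced
    to 75% of normal.
    """
    if variant not in VARIANTS:
        raise InvalidSpecError(f"unknown variant {variant!r}; "
                               f"expected one of {VARIANTS}")
    base = _tune_lever(ModelParameters(variant="N"), "v_pm_leak",
                       1e-4, 5.0, _REST_TARGETS["N"])
    if variant == "N":
        return base
    if variant in ("LFB", "LFB_star"):
        tuned = _tune_lever(replace(base, variant=variant),
                            "dts_leak_scale", 1.0, 60.0,
                            _REST_TARGETS[variant])
        if variant == "LFB_star":
            tuned = replace(tuned, rap1_total_scale=0.75)
        return tuned
    return _tune_lever(replace(base, variant="HFB"), "basal_plc",
                       0.0, 1.0, _REST_TARGETS["HFB"])


# --------------------------------------------------------------------------
# Experiments
# --------------------------------------------------------------------------


def adp_response(p: ModelParameters, dose_uM: float = 2.0,
                 t_add: float = 50.0, duration_s: float = 650.0,
                 rest: ModelState | None = None) -> SimulationResult:
    protocol = StimulusProtocol(additions=((t_add, "ADP", dose_uM),))
    return simulate_protocol(p, protocol, duration_s, rest=rest)


def predict_synergy(p: ModelParameters, dose_adp: float = 2.0,
                    dose_trap: float = 10.0, gap_s: float = 300.0,
                    ) -> dict[str, float]:
    """ADP-then-TRAP stimulation of the N model.

    Returns the fold change of the fibrinogen-binding plateau after
    TRAP relative to the pre-TRAP level, together with the calcium
    peaks of both phases.
    """
    t_adp, t_trap = 50.0, 50.0 + gap_s
    protocol = StimulusProtocol(additions=(
        (t_adp, "ADP", dose_adp), (t_trap, "TRAP", dose_trap)))
    res = simulate_protocol(p, protocol, t_trap + 550.0)
    m_pre = (res.times >= t_trap - 5.0) & (res.times <= t_trap)
    pre = float(np.mean(res.fib_rel[m_pre]))
    post = float(res.fib_rel[-1])
    if pre <= 1e-6:
        raise ConvergenceError("pre-TRAP fibrinogen level is ~0; "
                               "fold change undefined")
    peak_adp = res.peak("ca_cyt", t_adp, t_trap)
    peak_trap = res.peak("ca_cyt", t_trap, res.times[-1])
    return {
        "fib_pre_trap": pre,
        "fib_post_trap": post,
        "fold_change": post / pre,
        "ca_peak_adp": peak_adp,
        "ca_peak_trap": peak_trap,
        "fib_vs_adp_endpoint": post / max(
            float(adp_response(p, dose_adp,
                               duration_s=t_trap + 550.0).fib_rel[-1]),
            1e-12),
    }


def pm_conductivity_experiment(p: ModelParameters,
                               pm_leak_scale: float | None = None,
                               target_rest_nM: float = 15.0,
                               ) -> dict[str, float]:
    """Raise plasma-membrane calcium conductivity and compare with N.

    If no scale is given, it is root-found so the quiescent state sits
    at ``target_rest_nM``.  Returns resting and ADP-stimulated summary
    numbers for the scaled model next to the baseline.
    """
    if pm_leak_scale is None:
        scaled = _tune_lever(p, "pm_leak_scale", 1.0, 60.0, target_rest_nM)
    else:
        if pm_leak_scale < 1.0:
            raise InvalidSpecError("pm_leak_scale must be >= 1")
        scaled = replace(p, pm_leak_scale=pm_leak_scale)
    out = {"pm_leak_scale": scaled.pm_leak_scale}
    for tag, params in (("base", p), ("scaled", scaled)):
        rest = find_resting_state(params)
        res = adp_response(params, rest=rest)
        out[f"rest_ca_{tag}"] = rest.ca_cyt
        out[f"peak_ca_{tag}"] = res.peak("ca_cyt", 50.0)
        out[f"fib_rel_{tag}"] = float(res.fib_rel[-1])
    return out
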