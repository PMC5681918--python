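"""Stimulation and clamp protocols.

* regular pacing (see :func:`atriakur.cell.run_paced`)
* irregular pacing: uniform random cycle lengths, 20 s, from the 3-Hz
  steady state
* S1-S2 effective refractory period: premature S2 (5 ms, 2x diastolic
  threshold) scanned from 700 ms downward in 2-ms decrements; ERP is the
  longest failing interval under the capture criteria (dV/dt_max >= 5 V/s
  and amplitude >= 50% of the preceding S1 AP amplitude)
* IC50 down-ramp voltage clamp: 200-ms linear ramp +30 -> -60 mV repeated
  at the pacing rate, holding at the resting potential in between; the
  Markov subsystem is propagated with matrix exponentials over
  piecewise-constant voltage steps until beat-to-beat peak I_Kur changes by
  < 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import cell
from .biomarkers import apd
from .cell import CellSim, Trace, equilibrated_state
from .markov import (DRUG_FREE, N_STATES, NO_DRUG, DrugSpec, KurScheme,
                     _fill_generator, steady_occupancy)
from .params import ModelParameters

V_HOLD = -80.0       # mV, clamp holding potential (resting potential)
RAMP_MS = 200.0      # down-ramp duration
RAMP_V0, RAMP_V1 = 30.0, -60.0
ERP_SCAN_START = 700.0   # ms
ERP_SCAN_MIN = 50.0      # "refractoriness" lower bound
CAPTURE_DVDT = 5.0       # V/s
CAPTURE_AMP_FRAC = 0.5


class ProtocolError(RuntimeError):
    pass


@dataclass
class PacingProtocol:
    """Description of a stimulation protocol (configuration container)."""

    kind: str = "regular"            # regular|irregular|s1s2|voltage_ramp
    rate_hz: float = 1.0
    n_beats: int | None = None       # default: fixed equilibration counts
    stim_amplitude: float | None = None   # A/F; None -> parameter file value
    stim_duration: float = 5.0       # ms
    seed: int | None = None          # irregular only
    duration_s: float = 20.0         # irregular only
    cl_min: float = 285.7            # ms, irregular
    cl_max: float = 400.0
    s2_start: float = ERP_SCAN_START
    s2_decrement: float = 2.0

    def __post_init__(self):
        if self.kind not in ("regular", "irregular", "s1s2", "voltage_ramp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.s2_decrement <= 0:
            raise ValueError("S1-S2 decrement must be positive")
        if not 0 < self.cl_min <= self.cl_max:
            raise ValueError("need 0 < cl_min <= cl_max")

    @property
    def beats(self) -> int:
        return self.n_beats if self.n_beats is not None \
            else cell.default_beats(self.rate_hz)


# ---------------------------------------------------------------------------
# irregular pacing
# ---------------------------------------------------------------------------
def irregular_cl_sequence(seed: int, total_duration_s: float = 20.0,
                          cl_min: float = 285.7,
                          cl_max: float = 400.0) -> np.ndarray:
    """Independent uniform cycle-length draws on [cl_min, cl_max] ms,
    truncated once the cumulative time exceeds ``total_duration_s``."""
    if not 0 < cl_min <= cl_max:
        raise ValueError("need 0 < cl_min <= cl_max")
    if total_duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    total = total_duration_s * 1000.0
    # upper bound on count, then truncate at cumulative duration
    n_max = int(total / cl_min) + 2
    draws = rng.uniform(cl_min, cl_max, size=n_max)
    csum = np.cumsum(draws)
    n = int(np.searchsorted(csum, total)) + 1
    return draws[:min(n, n_max)]


@dataclass
class IrregularResult:
    cl_sequence: np.ndarray
    apd90: np.ndarray        # per-beat
    trace: Trace

    @property
    def mean_apd90(self) -> float:
        return float(np.nanmean(self.apd90))


def run_irregular(params: ModelParameters, drug: DrugSpec = NO_DRUG,
                  seed: int = 0, total_duration_s: float = 20.0,
                  cl_min: float = 285.7, cl_max: float = 400.0,
                  base_rate_hz: float = 3.0,
                  equilibration_beats: int | None = None,
                  y0: np.ndarray | None = None,
                  rtol: float = 1e-6) -> IrregularResult:
    """20-s irregular pacing from the fixed-rate steady state.

    The first random cycle length follows the last regular beat.
    """
    cls = irregular_cl_sequence(seed, total_duration_s, cl_min, cl_max)
    if y0 is None:
        n_eq = equilibration_beats if equilibration_beats is not None \
            else cell.default_beats(base_rate_hz)
        y0 = equilibrated_state(params, drug, base_rate_hz, n_eq, rtol=rtol)
    sim = CellSim(params, drug, y0=y0, rtol=rtol)
    t_parts, y_parts, bounds, stim_times = [], [], [], []
    t_acc = 0.0
    apds = []
    for k, cl in enumerate(cls):
        bounds.append(sum(len(tp) for tp in t_parts))
        stim_times.append(t_acc)
        t, y = sim.stim_beat(cl, record=True)
        if t_parts:
            t, y = t[1:], y[1:]
        t_parts.append(t + t_acc)
        y_parts.append(y)
        t_acc += cl
        sim.check(k)
    t = np.concatenate(t_parts)
    y = np.concatenate(y_parts, axis=0)
    g_kur = params["g_kur"]
    ek = (1.0 / cell.FORT) * np.log(cell.KO / y[:, 33])
    trace = Trace(t=t, v=y[:, 0], cai=y[:, cell.IDX_CAI],
                  i_kur=g_kur * y[:, cell.IDX_MK_O] * (y[:, 0] - ek),
                  occupancies=y[:, cell.MK0:cell.MK0 + N_STATES],
                  beat_bounds=np.asarray(bounds),
                  stim_times=np.asarray(stim_times),
                  final_state=sim.y.copy())
    # per-beat APD90
    for k in range(len(cls)):
        i0 = trace.beat_bounds[k]
        i1 = trace.beat_bounds[k + 1] if k + 1 < len(cls) else len(t)
        sub = Trace(t=t[i0:i1], v=trace.v[i0:i1], cai=trace.cai[i0:i1],
                    i_kur=trace.i_kur[i0:i1],
                    occupancies=trace.occupancies[i0:i1],
                    beat_bounds=np.array([0]),
                    stim_times=np.array([trace.stim_times[k]]))
        apds.append(apd(sub, 0.9))
    return IrregularResult(cl_sequence=cls, apd90=np.asarray(apds),
                           trace=trace)


# ---------------------------------------------------------------------------
# diastolic threshold and ERP
# ---------------------------------------------------------------------------
def _test_stimulus(sim0: CellSim, amplitude: float, ref_amp: float,
                   observe_ms: float = 300.0) -> tuple[bool, float, float]:
    """Apply a 5-ms stimulus to a copy of ``sim0``; return (elicited,
    dvdt_max, amplitude_ratio) under the capture criteria."""
    sim = sim0.copy()
    v_pre = sim.y[0]
    t1, y1 = sim.step_record(sim.params.stim_duration, istim=amplitude)
    t2, y2 = sim.step_record(observe_ms)
    # the passive artifact dV/dt = I_stim is subtracted inside the pulse so
    # the upstroke criterion sees only the membrane-driven (regenerative)
    # depolarization rate, wherever the upstroke occurs
    dvdt_stim = float(np.gradient(y1[:, 0], t1).max()) - amplitude
    dvdt_post = float(np.gradient(y2[:, 0], t2).max())
    dvdt = max(dvdt_stim, dvdt_post)
    amp = float(max(y1[:, 0].max(), y2[:, 0].max()) - v_pre)
    ratio = amp / ref_amp if ref_amp > 0 else 0.0
    elicited = (dvdt >= CAPTURE_DVDT) and (ratio >= CAPTURE_AMP_FRAC)
    return elicited, dvdt, ratio


def _reference_amplitude(params: ModelParameters, y_eq: np.ndarray,
                         drug: DrugSpec, cl: float,
                         rtol: float = 1e-6) -> tuple[float, np.ndarray]:
    """Amplitude of one steady S1 beat and the state at next S1 onset."""
    sim = CellSim(params, drug, y0=y_eq, rtol=rtol)
    v_pre = sim.y[0]
    t, y = sim.stim_beat(cl, record=True, dt=0.5)
    return float(y[:, 0].max() - v_pre), sim.y.copy()


def diastolic_threshold(params: ModelParameters, drug: DrugSpec = NO_DRUG,
                        rate_hz: float = 1.0,
                        y_eq: np.ndarray | None = None,
                        equilibration_beats: int | None = None,
                        max_amplitude: float = 60.0,
                        rtol: float = 1e-6) -> float:
    """Minimal 5-ms stimulus amplitude (A/F) eliciting an AP in late
    diastole, by bisection to 1% relative precision."""
    cl = 1000.0 / rate_hz
    if y_eq is None:
        n_eq = equilibration_beats if equilibration_beats is not None \
            else cell.default_beats(rate_hz)
        y_eq = equilibrated_state(params, drug, rate_hz, n_eq, rtol=rtol)
    ref_amp, y_onset = _reference_amplitude(params, y_eq, drug, cl, rtol)
    sim0 = CellSim(params, drug, y0=y_onset, rtol=rtol)
    lo, hi = 0.0, max_amplitude
    ok, _, _ = _test_stimulus(sim0, hi, ref_amp)
    if not ok:
        raise ProtocolError(
            f"no capture at maximal tested amplitude {hi} A/F")
    while hi - lo > 0.01 * hi:
        mid = 0.5 * (lo + hi)
        ok, _, _ = _test_stimulus(sim0, mid, ref_amp)
        if ok:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class ERPResult:
    erp: float                       # ms; NaN when flagged below bound
    below_bound: bool
    scan_log: list = field(default_factory=list)
    # scan_log rows: (interval, dvdt_max, amplitude_ratio, elicited)

    def log_frame(self):
        import pandas as pd
        return pd.DataFrame(self.scan_log, columns=[
            "interval_ms", "dvdt_max", "amplitude_ratio", "elicited"])


def measure_erp(params: ModelParameters, drug: DrugSpec = NO_DRUG,
                rate_hz: float = 1.0,
                y_eq: np.ndarray | None = None,
                equilibration_beats: int | None = None,
                decrement: float = 2.0,
                start: float = ERP_SCAN_START,
                coarse_first: bool = True,
                s2_amplitude: float | None = None,
                rtol: float = 1e-6) -> ERPResult:
    """Effective refractory period by the S1-S2 protocol.

    S2 = 5 ms at 2x the diastolic threshold (measured unless
    ``s2_amplitude`` is given); the scan runs from ``start`` downward by
    ``decrement`` ms; the ERP is the longest failing interval.  With
    ``coarse_first`` a 16x-decrement bracketing pass precedes the fine scan
    (identical result under monotone capture).
    """
    cl = 1000.0 / rate_hz
    if y_eq is None:
        n_eq = equilibration_beats if equilibration_beats is not None \
            else cell.default_beats(rate_hz)
        y_eq = equilibrated_state(params, drug, rate_hz, n_eq, rtol=rtol)
    ref_amp, _ = _reference_amplitude(params, y_eq, drug, cl, rtol)
    if s2_amplitude is None:
        thr = diastolic_threshold(params, drug, rate_hz, y_eq=y_eq,
                                  rtol=rtol)
        s2_amplitude = 2.0 * thr

    # one shared pre-S2 trajectory: last S1 beat then quiescence to `start`;
    # snapshot the state at every candidate S2 onset on the scan grid
    n_grid = int(math.floor((start - ERP_SCAN_MIN) / decrement)) + 1
    intervals = start - decrement * np.arange(n_grid)
    sim = CellSim(params, drug, y0=y_eq, rtol=rtol)
    sim.step(params.stim_duration, istim=params.stim_amplitude)
    tgrid = np.sort(intervals - params.stim_duration)
    tgrid = np.concatenate([[0.0], tgrid])
    out = cell.odeint(cell._rhs, sim.y, tgrid, args=(sim.p, 0.0),
                      rtol=rtol, atol=cell._ATOL, mxstep=200000)
    snapshots = {}
    for tv, row in zip(tgrid[1:], out[1:]):
        snapshots[round(tv + params.stim_duration, 6)] = row

    log = []
    cache = {}

    def trial(interval: float) -> bool:
        key = round(interval, 6)
        if key in cache:
            return cache[key]
        sim_i = CellSim(params, drug, y0=snapshots[key], rtol=rtol)
        ok, dvdt, ratio = _test_stimulus(sim_i, s2_amplitude, ref_amp,
                                         observe_ms=400.0)
        log.append((interval, dvdt, ratio, ok))
        cache[key] = ok
        return ok

    i = 0
    if coarse_first:
        stride = 16
        while i + stride < n_grid and trial(intervals[i]):
            i += stride
        i = max(i - stride + 1, 1) if i > 0 else 0
        # ensure the bracket start captures; walk back if needed
        while i > 0 and not trial(intervals[i - 1]):
            i -= 1
    while i < n_grid:
        if not trial(intervals[i]):
            return ERPResult(erp=float(intervals[i]), below_bound=False,
                             scan_log=log)
        i += 1
    return ERPResult(erp=math.nan, below_bound=True, scan_log=log)


# ---------------------------------------------------------------------------
# IC50 down-ramp voltage clamp
# ---------------------------------------------------------------------------
def _clamp_propagators(scheme: KurScheme, concentration: float,
                       rate_hz: float, dt_ramp: float = 0.5):
    """Per-step propagators over one clamp cycle.

    Returns (ramp_mats, hold_mat, v_ramp): matrix exponentials over
    piecewise-constant 0.5-ms voltage steps of the ramp, one exponential
    for the holding interval, and the ramp voltages.
    """
    cl = 1000.0 / rate_hz
    if cl <= RAMP_MS:
        raise ProtocolError("cycle shorter than the 200-ms ramp")
    n = int(round(RAMP_MS / dt_ramp))
    t_mid = (np.arange(n) + 0.5) * dt_ramp
    v_ramp = RAMP_V0 + (RAMP_V1 - RAMP_V0) * t_mid / RAMP_MS
    b = scheme.binding_vector(concentration)
    mats = []
    for v in v_ramp:
        q = np.zeros((N_STATES, N_STATES))
        _fill_generator(q, float(v), *b)
        mats.append(expm(q * dt_ramp))
    q = np.zeros((N_STATES, N_STATES))
    _fill_generator(q, V_HOLD, *b)
    hold = expm(q * (cl - RAMP_MS))
    return mats, hold, v_ramp


def downramp_peak_ikur(scheme: KurScheme, concentration: float,
                       rate_hz: float = 1.0, g_kur: float = 0.045,
                       max_cycles: int = 2000,
                       tol: float = 1e-3,
                       return_details: bool = False):
    """Equilibrated peak I_Kur (A/F) during the 200-ms down-ramp clamp.

    The clamp holds at the resting potential and ramps +30 -> -60 mV once
    per pacing cycle; cycles repeat until the beat-to-beat peak changes by
    less than ``tol`` (0.1%).
    """
    ramp_mats, hold_mat, v_ramp = _clamp_propagators(
        scheme, concentration, rate_hz)
    ek = (1.0 / cell.FORT) * math.log(cell.KO / 120.0)
    drive = v_ramp - ek
    p = np.zeros(N_STATES)
    p[:6] = steady_occupancy(DRUG_FREE, V_HOLD)
    prev_peak = None
    history = []
    dt_ramp = RAMP_MS / len(ramp_mats)
    for cycle in range(max_cycles):
        peak = 0.0
        t_peak = 0.0
        for step, (m, dv) in enumerate(zip(ramp_mats, drive)):
            p = m @ p
            cur = p[4] * dv
            if cur > peak:
                peak = cur
                t_peak = (step + 1) * dt_ramp
        p = hold_mat @ p
        history.append(peak)
        if prev_peak is not None and abs(peak - prev_peak) <= tol * max(
                prev_peak, 1e-300):
            if return_details:
                return g_kur * peak, t_peak, cycle + 1
            return g_kur * peak
        prev_peak = peak
    raise ProtocolError(
        f"block did not equilibrate within {max_cycles} cycles; "
        f"last peaks: {history[-5:]}")
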