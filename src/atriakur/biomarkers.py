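"""Biomarker extraction from simulated traces.

Conventions: AP onset is the time of maximum upstroke velocity after the
stimulus; AP amplitude is peak E_m minus the pre-stimulus diastolic E_m;
APD_x is the time from onset until E_m first falls below
peak - x * amplitude (linear interpolation between samples).  Ca2+
biomarkers are reported in nM: diastolic [Ca2+]i at stimulus onset, CaT
amplitude = beat peak - diastolic, t50 = time from CaT peak to the first
crossing of peak - amplitude/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .cell import Trace

#: minimum AP amplitude (mV) for biomarkers to be defined
MIN_AP_AMPLITUDE = 10.0


@dataclass
class BiomarkerSet:
    apd40: float = math.nan          # ms
    apd90: float = math.nan          # ms
    erp: float = math.nan            # ms (optional, protocol-derived)
    cat_amp: float = math.nan        # nM
    diastolic_ca: float = math.nan   # nM
    cat_t50: float = math.nan        # ms
    dvdt_max: float = math.nan       # V/s

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.apd90) or math.isnan(self.cat_amp))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _interp_crossing(t: np.ndarray, x: np.ndarray, level: float,
                     start: int) -> float:
    """First downward crossing of ``level`` at/after index ``start``."""
    below = x[start:] < level
    if not below.any():
        return math.nan
    k = start + int(np.argmax(below))
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    x0, x1 = x[k - 1], x[k]
    if x1 == x0:
        return float(t1)
    return float(t0 + (x0 - level) / (x0 - x1) * (t1 - t0))


def _final_beat(trace: Trace) -> tuple[slice, float]:
    """Index slice of the final beat and its stimulus-onset time."""
    if len(trace.beat_bounds) == 0:
        return slice(0, len(trace.t)), float(trace.t[0])
    i0 = int(trace.beat_bounds[-1])
    return slice(i0, len(trace.t)), float(trace.stim_times[-1])


def max_upstroke(trace: Trace, beat: slice | None = None) -> float:
    """Maximum upstroke velocity dV/dt_max of the (final) beat, V/s."""
    sl, _ = _final_beat(trace) if beat is None else (beat, None)
    t, v = trace.t[sl], trace.v[sl]
    dvdt = np.gradient(v, t)
    return float(dvdt.max())  # mV/ms == V/s


def apd(trace: Trace, repolarization_fraction: float = 0.9) -> float:
    """Action potential duration at the given repolarization fraction, ms.

    Returns NaN (undefined-biomarker flag) when no AP was elicited
    (amplitude < 10 mV).
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization_fraction must be in (0, 1)")
    sl, t_stim = _final_beat(trace)
    t, v = trace.t[sl], trace.v[sl]
    if len(t) < 3:
        raise ValueError("trace must contain at least one full beat")
    v_dia = v[0]                      # pre-stimulus diastolic E_m
    dvdt = np.gradient(v, t)
    i_on = int(np.argmax(dvdt))
    t_on = t[i_on]
    i_peak = i_on + int(np.argmax(v[i_on:]))
    amp = v[i_peak] - v_dia
    if amp < MIN_AP_AMPLITUDE:
        return math.nan
    level = v[i_peak] - repolarization_fraction * amp
    t_cross = _interp_crossing(t, v, level, i_peak)
    if math.isnan(t_cross):
        return math.nan
    return t_cross - t_on


def cat_metrics(trace: Trace) -> tuple[float, float, float]:
    """(CaT amplitude nM, diastolic [Ca2+]i nM, t50 decay ms) of the final
    beat.  Flat signal: amplitude 0 and t50 NaN."""
    sl, _ = _final_beat(trace)
    t = trace.t[sl]
    ca = trace.cai[sl] * 1e6  # nM
    dia = float(ca[0])        # at stimulus onset
    i_peak = int(np.argmax(ca))
    amp = float(ca[i_peak] - dia)
    if amp <= 1e-9:
        return 0.0, dia, math.nan
    level = ca[i_peak] - 0.5 * amp
    t_half = _interp_crossing(t, ca, level, i_peak)
    t50 = t_half - t[i_peak] if not math.isnan(t_half) else math.nan
    return amp, dia, t50


def biomarkers(trace: Trace, erp: float = math.nan) -> BiomarkerSet:
    """Full biomarker set from the final beat of a trace."""
    amp, dia, t50 = cat_metrics(trace)
    return BiomarkerSet(
        apd40=apd(trace, 0.4),
        apd90=apd(trace, 0.9),
        erp=erp,
        cat_amp=amp,
        diastolic_ca=dia,
        cat_t50=t50,
        dvdt_max=max_upstroke(trace),
    )
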