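"""Six-state Markov model of the Kv1.5 channel (I_Kur) with drug binding.

Drug-free topology::

    C1 <-> C2 <-> C3 <-> C4 <-> O <-> I

Four closed states, one conducting open state O and one inactivated state I.
The activation chain uses per-gate rates (4a,b), (3a,2b), (2a,3b), (a,4b) of a
single two-state gate, so the chain's stationary open probability and dominant
relaxation time equal those of the published Hodgkin-Huxley activation gate of
the same current; O<->I carries the HH inactivation-gate rates directly.

Drug-bound extensions (pure state occlusion; no drug-free rate is altered):

* ``open``: one extra state Od, O <-> Od with rates k_on*[D] / k_off.
* ``open_inactivated``: Od and Id; optionally "bridged", i.e. Od <-> Id
  transitions carrying the drug-free O <-> I voltage-dependent rates.
* ``closed``: C1d..C4d, each Ci <-> Cid with identical k_on*[D] / k_off;
  transitions among drug-bound closed states mirror the drug-free ones.

Units: k_on in uM^-1 s^-1 and k_off in s^-1, so that Kd [uM] = k_off/k_on and
k_on = k_off (numerically) means Kd = 1 uM.  All internal kinetics are ms^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

STATE_NAMES: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "O", "I",
    "Od", "Id", "C1d", "C2d", "C3d", "C4d",
)
N_STATES = len(STATE_NAMES)
IDX_O = STATE_NAMES.index("O")
IDX_I = STATE_NAMES.index("I")

SCHEME_KINDS = ("drug_free", "open", "open_inactivated", "closed")


class SchemeError(ValueError):
    """Invalid drug-binding scheme or concentration."""


@njit(cache=False)
def gate_rates(v):
    """Voltage-dependent gate rates (ms^-1), from the published HH gates.

    Returns (alpha, beta, k_oi, k_io): per-gate activation forward/backward
    rates and the O->I / I->O inactivation rates.
    """
    xss = 1.0 / (1.0 + math.exp(-(v + 6.0) / 8.6))
    taux = 9.0 / (1.0 + math.exp((v + 5.0) / 12.0)) + 0.5
    yss = 1.0 / (1.0 + math.exp((v + 7.5) / 10.0))
    tauy = 590.0 / (1.0 + math.exp((v + 60.0) / 10.0)) + 3050.0
    u = xss ** 0.25          # per-gate steady state; chain P_O = xss
    alpha = u / taux
    beta = (1.0 - u) / taux
    # O<->I kinetics 10x the HH gate (slow inactivation tau of a few
    # hundred ms at plateau potentials); steady-state availability unchanged
    k_oi = 10.0 * (1.0 - yss) / tauy
    k_io = 10.0 * yss / tauy
    return alpha, beta, k_oi, k_io


@dataclass(frozen=True)
class KurScheme:
    """Drug-binding scheme: targeted conformations and binding rates."""

    kind: str = "drug_free"
    bridged: bool = False
    kon_o: float = 0.0   # uM^-1 s^-1
    koff_o: float = 0.0  # s^-1
    kon_i: float = 0.0
    koff_i: float = 0.0
    kon_c: float = 0.0
    koff_c: float = 0.0

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise SchemeError(f"unknown scheme kind {self.kind!r}")
        for r in (self.kon_o, self.koff_o, self.kon_i, self.koff_i,
                  self.kon_c, self.koff_c):
            if r < 0 or not math.isfinite(r):
                raise SchemeError("binding rates must be finite and >= 0")
        if self.kind == "drug_free" and any(
                r != 0.0 for r in (self.kon_o, self.koff_o, self.kon_i,
                                   self.koff_i, self.kon_c, self.koff_c)):
            raise SchemeError("drug_free scheme has no binding rates")
        if self.bridged and self.kind != "open_inactivated":
            raise SchemeError("bridged applies to open_inactivated only")

    # -- constructors -------------------------------------------------
    @classmethod
    def open_blocker(cls, kon: float, koff: float) -> "KurScheme":
        return cls(kind="open", kon_o=kon, koff_o=koff)

    @classmethod
    def open_inactivated_blocker(cls, kon_o: float, koff_o: float,
                                 kon_i: float | None = None,
                                 koff_i: float | None = None,
                                 bridged: bool = False) -> "KurScheme":
        kon_i = kon_o if kon_i is None else kon_i
        koff_i = koff_o if koff_i is None else koff_i
        return cls(kind="open_inactivated", bridged=bridged,
                   kon_o=kon_o, koff_o=koff_o, kon_i=kon_i, koff_i=koff_i)

    @classmethod
    def closed_blocker(cls, kon: float, koff: float) -> "KurScheme":
        return cls(kind="closed", kon_c=kon, koff_c=koff)

    # -- derived quantities (never stored) ----------------------------
    @property
    def kd_o(self) -> float:
        return self.koff_o / self.kon_o if self.kon_o > 0 else math.inf

    @property
    def kd_i(self) -> float:
        return self.koff_i / self.kon_i if self.kon_i > 0 else math.inf

    @property
    def kd_c(self) -> float:
        return self.koff_c / self.kon_c if self.kon_c > 0 else math.inf

    @property
    def k_o_over_k_i(self) -> float:
        """Affinity-constant ratio K_O/K_I = (kon_o/koff_o)/(kon_i/koff_i)."""
        return self.kd_i / self.kd_o

    @property
    def active_states(self) -> tuple[int, ...]:
        idx = list(range(6))
        if self.kind == "open":
            idx += [6]
        elif self.kind == "open_inactivated":
            idx += [6, 7]
        elif self.kind == "closed":
            idx += [8, 9, 10, 11]
        return tuple(idx)

    def binding_vector(self, concentration: float) -> np.ndarray:
        """Internal ms^-1 binding parameters for the cell-model RHS:
        [bon_o, boff_o, bon_i, boff_i, bon_c, boff_c, bridged]."""
        if concentration < 0:
            raise SchemeError("concentration must be >= 0")
        c = concentration * 1e-3  # uM^-1 s^-1 * uM -> ms^-1
        return np.array([
            self.kon_o * c, self.koff_o * 1e-3,
            self.kon_i * c, self.koff_i * 1e-3,
            self.kon_c * c, self.koff_c * 1e-3,
            1.0 if self.bridged else 0.0,
        ])


DRUG_FREE = KurScheme()


@dataclass(frozen=True)
class DrugSpec:
    """A scheme applied at a constant bath concentration (uM)."""

    scheme: KurScheme = DRUG_FREE
    concentration: float = 0.0

    def __post_init__(self):
        if self.concentration < 0 or not math.isfinite(self.concentration):
            raise SchemeError("concentration must be finite and >= 0")


NO_DRUG = DrugSpec()


@njit(cache=False)
def _fill_generator(q, v, bon_o, boff_o, bon_i, boff_i, bon_c, boff_c,
                    bridged):
    """Fill the 12x12 generator (column convention: dp/dt = Q @ p)."""
    alpha, beta, k_oi, k_io = gate_rates(v)
    # (from, to, rate) over the drug-free chain C1..C4,O plus O<->I
    fwd = (4.0 * alpha, 3.0 * alpha, 2.0 * alpha, alpha)
    bwd = (beta, 2.0 * beta, 3.0 * beta, 4.0 * beta)

    def add(i, j, rate):
        # transition i -> j
        q[j, i] += rate
        q[i, i] -= rate

    for k in range(4):
        add(k, k + 1, fwd[k])
        add(k + 1, k, bwd[k])
    add(4, 5, k_oi)
    add(5, 4, k_io)
    # open-state binding
    if bon_o > 0.0 or boff_o > 0.0:
        add(4, 6, bon_o)
        add(6, 4, boff_o)
    # inactivated-state binding
    if bon_i > 0.0 or boff_i > 0.0:
        add(5, 7, bon_i)
        add(7, 5, boff_i)
    if bridged > 0.0:
        add(6, 7, k_oi)
        add(7, 6, k_io)
    # closed-state binding: each Ci <-> Cid, mirrored closed-closed chain
    if bon_c > 0.0 or boff_c > 0.0:
        for k in range(4):
            add(k, 8 + k, bon_c)
            add(8 + k, k, boff_c)
        for k in range(3):
            add(8 + k, 9 + k, fwd[k])
            add(9 + k, 8 + k, bwd[k])


def transition_matrix(scheme: KurScheme, v: float,
                      concentration: float = 0.0) -> np.ndarray:
    """Generator matrix over the scheme's state set at voltage ``v`` (mV).

    Column convention: dp/dt = Q @ p, so every column sums to zero.
    """
    if concentration < 0:
        raise SchemeError("concentration must be >= 0")
    if not math.isfinite(v):
        raise SchemeError("voltage must be finite")
    q = np.zeros((N_STATES, N_STATES))
    b = scheme.binding_vector(concentration)
    _fill_generator(q, float(v), *b)
    idx = np.array(scheme.active_states)
    return q[np.ix_(idx, idx)]


def steady_occupancy(scheme: KurScheme, v: float,
                     concentration: float = 0.0) -> np.ndarray:
    """Stationary distribution over the scheme's active states.

    Solves Q p = 0, sum(p) = 1.  If the chain is reducible at the given
    inputs (e.g. a drug scheme at zero concentration), the distribution is
    returned on the reachable drug-free component with a warning, zero mass
    elsewhere.
    """
    q = transition_matrix(scheme, v, concentration)
    n = q.shape[0]
    if scheme.kind != "drug_free" and concentration == 0.0:
        warnings.warn("reducible chain at zero concentration; returning "
                      "distribution on the drug-free component",
                      RuntimeWarning, stacklevel=2)
        free = steady_occupancy(DRUG_FREE, v)
        p = np.zeros(n)
        p[:6] = free
        return p
    a = np.vstack([q, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def ikur_current(occupancy_o: float, v: float, g_kur: float,
                 ko: float = 5.4, ki: float = 120.0) -> float:
    """Ohmic open-state conduction: I = G_Kur * P_O * (V - E_K), A/F.

    E_K from the Nernst relation at 310 K with the given K+ concentrations
    (mM).
    """
    if not 0.0 <= occupancy_o <= 1.0:
        raise ValueError("open-state occupancy must be in [0, 1]")
    rtof = 8314.0 * 310.0 / 96485.0  # RT/F in mV at 310 K
    e_k = rtof * math.log(ko / ki)
    return g_kur * occupancy_o * (v - e_k)
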