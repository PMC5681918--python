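import numpy as np
import pytest

from atriakur import DrugSpec, KurScheme, build_parameters
from atriakur.cell import (MK0, N_MARKOV, CellSim, SimulationError,
                           derivatives, initial_state, run_paced)
from atriakur.biomarkers import apd
from atriakur.markov import NO_DRUG


def test_occupancy_derivatives_sum_to_zero(nsr_params):
    y = initial_state()
    dy = derivatives(y, nsr_params, stimulus_current=0.0)
    assert abs(dy[MK0:MK0 + N_MARKOV].sum()) < 1e-15


def test_ikur_linear_in_conductance(nsr_params):
    """Doubling the G_Kur scale factor doubles the I_Kur term exactly:
    the V' difference between scaled runs is the extra I_Kur."""
    from atriakur.params import N_PARAMS, PARAM_NAMES
    y = initial_state(v0=0.0)
    y[MK0 + 4] = 0.3  # force open occupancy
    y[MK0:MK0 + 4] = [0.4, 0.1, 0.1, 0.1]
    y[MK0 + 5] = 0.0
    sf = np.ones(N_PARAMS)
    i = PARAM_NAMES.index("g_kur")
    sf[i] = 2.0
    p2 = build_parameters("nSR", sf)
    dv1 = derivatives(y, nsr_params)[0]
    dv2 = derivatives(y, p2)[0]
    ek = 8314.0 * 310.0 / 96485.0 * np.log(5.4 / 120.0)
    ikur1 = nsr_params["g_kur"] * 0.3 * (0.0 - ek)
    assert dv2 - dv1 == pytest.approx(-ikur1, rel=1e-9)


def test_nonfinite_state_raises(nsr_params):
    y = initial_state()
    y[0] = np.nan
    with pytest.raises(SimulationError):
        derivatives(y, nsr_params)


def test_relaxation_to_rest(nsr_params):
    """60 s stimulus-free integration reaches quiescence: |dV/dt| small."""
    sim = CellSim(nsr_params)
    sim.step(60_000.0, istim=0.0)
    dy = derivatives(sim.y, nsr_params)
    assert abs(dy[0]) < 1e-3  # mV/ms


def test_occupancy_conservation_through_pacing(caf_params):
    tr = run_paced(caf_params, rate_hz=1.0, n_beats=3, record_beats=3)
    s = tr.occupancies.sum(axis=1)
    assert np.max(np.abs(s - 1.0)) < 1e-6
    assert np.all(np.diff(tr.t) > 0)


def test_zero_dose_drug_trace_matches_drug_free(caf_params, eq_state_fast):
    y0 = eq_state_fast("cAF", 1.0)
    drug = DrugSpec(KurScheme.open_blocker(3.0, 3.0), concentration=0.0)
    tr_free = run_paced(caf_params, NO_DRUG, rate_hz=1.0, n_beats=2, y0=y0)
    tr_drug = run_paced(caf_params, drug, rate_hz=1.0, n_beats=2, y0=y0)
    assert np.max(np.abs(tr_free.v - tr_drug.v)) < 1e-3
    assert np.max(np.abs(tr_free.i_kur - tr_drug.i_kur)) < 1e-5


def test_rate_and_phenotype_apd_ordering(eq_state_fast):
    """APD90(3 Hz) < APD90(1 Hz) for both phenotypes; cAF < nSR at both
    rates, drug-free."""
    apds = {}
    for phen in ("nSR", "cAF"):
        p = build_parameters(phen)
        for rate in (1.0, 3.0):
            tr = run_paced(p, rate_hz=rate, n_beats=2,
                           y0=eq_state_fast(phen, rate))
            apds[(phen, rate)] = apd(tr, 0.9)
    assert apds[("nSR", 3.0)] < apds[("nSR", 1.0)]
    assert apds[("cAF", 3.0)] < apds[("cAF", 1.0)]
    assert apds[("cAF", 1.0)] < apds[("nSR", 1.0)]
    assert apds[("cAF", 3.0)] < apds[("nSR", 3.0)]


def test_solver_tolerance_convergence(nsr_params, eq_state_fast):
    """Halving the relative tolerance changes APD90 by < 0.5 ms."""
    y0 = eq_state_fast("nSR", 1.0)
    a = apd(run_paced(nsr_params, rate_hz=1.0, n_beats=2, y0=y0,
                      rtol=1e-6), 0.9)
    b = apd(run_paced(nsr_params, rate_hz=1.0, n_beats=2, y0=y0,
                      rtol=5e-7), 0.9)
    assert abs(a - b) < 0.5
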