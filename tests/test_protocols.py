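import numpy as np
import pytest

from atriakur import KurScheme, build_parameters
from atriakur.protocols import (ERP_SCAN_START, PacingProtocol,
                                diastolic_threshold, downramp_peak_ikur,
                                irregular_cl_sequence, measure_erp)


# ---------------------------------------------------------------------------
# irregular cycle-length sequence
# ---------------------------------------------------------------------------
def test_irregular_draws_within_bounds():
    cls = irregular_cl_sequence(seed=1, total_duration_s=20.0)
    assert np.all(cls >= 285.7) and np.all(cls <= 400.0)
    assert cls.sum() >= 20_000.0
    assert cls[:-1].sum() < 20_000.0  # truncated at the duration


def test_irregular_degenerate_range_is_regular_pacing():
    cls = irregular_cl_sequence(seed=5, total_duration_s=2.0,
                                cl_min=333.3, cl_max=333.3)
    assert np.allclose(cls, 333.3)


def test_irregular_reproducible_and_seed_sensitive():
    a = irregular_cl_sequence(seed=7, total_duration_s=5.0)
    b = irregular_cl_sequence(seed=7, total_duration_s=5.0)
    c = irregular_cl_sequence(seed=8, total_duration_s=5.0)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_irregular_analytic_uniform_mean():
    """1e6 draws on [285.7, 400]: sample mean = 342.85 +- 0.1 ms."""
    cls = irregular_cl_sequence(seed=11, total_duration_s=342_850.0)
    assert len(cls) >= 990_000
    assert cls.mean() == pytest.approx((285.7 + 400.0) / 2, abs=0.1)


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError):
        irregular_cl_sequence(seed=0, cl_min=400.0, cl_max=285.7)
    with pytest.raises(ValueError):
        irregular_cl_sequence(seed=0, total_duration_s=-1.0)


def test_protocol_validation():
    with pytest.raises(ValueError):
        PacingProtocol(kind="spiral")
    with pytest.raises(ValueError):
        PacingProtocol(s2_decrement=0.0)
    assert PacingProtocol(rate_hz=3.0).beats == 900
    assert PacingProtocol(rate_hz=1.0).beats == 300


# ---------------------------------------------------------------------------
# diastolic threshold and ERP
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def caf_eq_3hz(eq_state_fast):
    return eq_state_fast("cAF", 3.0)


def test_threshold_bisection_matches_dense_scan(caf_params, caf_eq_3hz):
    """Bisection threshold within 1% of a dense linear amplitude scan."""
    from atriakur.protocols import _reference_amplitude, _test_stimulus
    from atriakur.cell import CellSim
    thr = diastolic_threshold(caf_params, rate_hz=3.0, y_eq=caf_eq_3hz)
    ref_amp, y_onset = _reference_amplitude(
        caf_params, caf_eq_3hz, __import__("atriakur").NO_DRUG,
        1000.0 / 3.0)
    sim0 = CellSim(caf_params, y0=y_onset)
    grid = np.linspace(0.5 * thr, 1.5 * thr, 41)
    elicited = np.array(
        [_test_stimulus(sim0, a, ref_amp)[0] for a in grid])
    dense_thr = grid[np.argmax(elicited)]
    assert thr == pytest.approx(dense_thr, rel=0.04)
    # zero amplitude never captures; 2x threshold always does
    assert not _test_stimulus(sim0, 0.0, ref_amp)[0]
    assert _test_stimulus(sim0, 2.0 * thr, ref_amp)[0]


def test_erp_on_scan_grid_and_fine_scan_agreement(caf_params, caf_eq_3hz):
    """ERP lies on the 700 - 2k grid; a 1-ms fine scan agrees within 2 ms;
    the coarse-first bracketing pass changes nothing."""
    res2 = measure_erp(caf_params, rate_hz=3.0, y_eq=caf_eq_3hz,
                       decrement=2.0)
    assert not res2.below_bound
    assert (ERP_SCAN_START - res2.erp) % 2.0 == pytest.approx(0.0, abs=1e-9)
    res1 = measure_erp(caf_params, rate_hz=3.0, y_eq=caf_eq_3hz,
                       decrement=1.0)
    assert abs(res2.erp - res1.erp) <= 2.0
    res2f = measure_erp(caf_params, rate_hz=3.0, y_eq=caf_eq_3hz,
                        decrement=2.0, coarse_first=False)
    assert res2f.erp == res2.erp
    # scan log records the required columns
    log = res2.log_frame()
    assert set(log.columns) == {"interval_ms", "dvdt_max",
                                "amplitude_ratio", "elicited"}


def test_erp_phenotype_ordering_at_3hz(eq_state_fast):
    erp = {}
    for phen in ("nSR", "cAF"):
        p = build_parameters(phen)
        erp[phen] = measure_erp(p, rate_hz=3.0,
                                y_eq=eq_state_fast(phen, 3.0)).erp
    assert erp["cAF"] < erp["nSR"]


# ---------------------------------------------------------------------------
# down-ramp clamp
# ---------------------------------------------------------------------------
def test_downramp_zero_concentration_equals_drug_free():
    scheme = KurScheme.open_blocker(3.0, 3.0)
    free = downramp_peak_ikur(scheme, 0.0, rate_hz=1.0)
    ref = downramp_peak_ikur(
        KurScheme(), 0.0, rate_hz=1.0)
    assert free == pytest.approx(ref, rel=1e-9)


def test_downramp_zero_conductance_zero_peak():
    assert downramp_peak_ikur(KurScheme(), 0.0, rate_hz=1.0,
                              g_kur=0.0) == 0.0


def test_downramp_peak_time_within_ramp_window():
    peak, t_peak, cycles = downramp_peak_ikur(
        KurScheme.open_blocker(10.0, 10.0), 5.0, rate_hz=1.0,
        return_details=True)
    assert 0.0 < t_peak <= 200.0
    assert peak > 0.0
    assert cycles >= 2


def test_run_irregular_short(caf_params, eq_state_fast):
    """Irregular pacing carries the drawn CL sequence through the
    simulation and yields one APD per beat."""
    from atriakur.protocols import run_irregular
    res = run_irregular(caf_params, seed=3, total_duration_s=1.5,
                        y0=eq_state_fast("cAF", 3.0))
    assert len(res.apd90) == len(res.cl_sequence)
    assert np.all((res.cl_sequence >= 285.7) & (res.cl_sequence <= 400.0))
    assert np.isfinite(res.mean_apd90)
    # beat boundaries follow the cumulative cycle lengths
    assert np.allclose(np.diff(res.trace.stim_times),
                       res.cl_sequence[:-1])
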