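import numpy as np
import pytest
from scipy.integrate import solve_ivp

from atriakur.markov import (DRUG_FREE, KurScheme, SchemeError,
                             ikur_current, steady_occupancy,
                             transition_matrix)

SCHEMES = [
    DRUG_FREE,
    KurScheme.open_blocker(3.0, 3.0),
    KurScheme.open_inactivated_blocker(10.0, 1.0),
    KurScheme.open_inactivated_blocker(10.0, 1.0, bridged=True),
    KurScheme.closed_blocker(1.0, 0.3),
]


@pytest.mark.parametrize("scheme", SCHEMES)
@pytest.mark.parametrize("v", [-90.0, -30.0, 0.0, 30.0, 60.0])
def test_generator_columns_sum_to_zero(scheme, v):
    q = transition_matrix(scheme, v, concentration=1.0)
    assert np.allclose(q.sum(axis=0), 0.0, atol=1e-14)
    # off-diagonal rates are non-negative
    off = q - np.diag(np.diag(q))
    assert np.all(off >= 0)


def test_zero_concentration_restricts_to_drug_free_dynamics():
    v = 10.0
    q_free = transition_matrix(DRUG_FREE, v)
    for scheme in SCHEMES[1:]:
        q = transition_matrix(scheme, v, concentration=0.0)
        assert np.allclose(q[:6, :6], q_free)
        # no flux from drug-free into bound states
        assert np.all(q[6:, :6] == 0)


@pytest.mark.parametrize("scheme,conc", [
    (DRUG_FREE, 0.0),
    (KurScheme.open_blocker(3.0, 3.0), 2.0),
    (KurScheme.open_inactivated_blocker(1.0, 0.3, bridged=True), 5.0),
    (KurScheme.closed_blocker(0.3, 1.0), 0.5),
])
def test_stationary_distribution_matches_long_integration(scheme, conc):
    """Null-space stationary state vs. a 10-s fixed-voltage ODE run."""
    v = 30.0
    q = transition_matrix(scheme, v, conc)
    n = q.shape[0]
    p0 = np.zeros(n)
    p0[0] = 1.0
    sol = solve_ivp(lambda t, p: q @ p, (0.0, 100_000.0), p0,
                    method="BDF", rtol=1e-10, atol=1e-12)
    p_ode = sol.y[:, -1]
    p_ss = steady_occupancy(scheme, v, conc)
    assert np.max(np.abs(p_ode - p_ss)) < 1e-6


def test_steady_occupancy_sums_to_one():
    for scheme in SCHEMES:
        conc = 0.0 if scheme.kind == "drug_free" else 1.0
        p = steady_occupancy(scheme, -20.0, conc)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


def test_closed_mass_dominates_at_rest():
    p = steady_occupancy(DRUG_FREE, -80.0)
    assert p[:4].sum() > 0.99


def test_saturating_open_blocker_occupies_bound_state():
    """At [D] >> Kd and depolarized V, the drug-bound mass approaches the
    open(+downstream) share of the drug-free chain."""
    scheme = KurScheme.open_blocker(10.0, 10.0)  # Kd = 1 uM
    p = steady_occupancy(scheme, 30.0, concentration=1e4)
    free = steady_occupancy(DRUG_FREE, 30.0)
    assert p[6] > 0.9 * (free[4] + free[5])
    assert p[4] < 0.01 * free[4]


def test_kon_equals_koff_means_kd_one_micromolar():
    s = KurScheme.open_blocker(3.0, 3.0)
    assert s.kd_o == pytest.approx(1.0)
    s2 = KurScheme.open_inactivated_blocker(0.01, 0.01)
    assert s2.kd_o == s2.kd_i == pytest.approx(1.0)


def test_affinity_ratio_derivation():
    s = KurScheme.open_inactivated_blocker(10.0, 1.0, 0.1, 1.0)
    # K_O/K_I = (kon_o/koff_o) / (kon_i/koff_i) = 10 / 0.1
    assert s.k_o_over_k_i == pytest.approx(100.0)


def test_bridged_reuses_drug_free_oi_rates():
    v = -15.0
    qf = transition_matrix(DRUG_FREE, v)
    qb = transition_matrix(
        KurScheme.open_inactivated_blocker(1.0, 1.0, bridged=True), v, 1.0)
    # Od (idx 6) <-> Id (idx 7) carries the O (4) <-> I (5) rates
    assert qb[7, 6] == pytest.approx(qf[5, 4])
    assert qb[6, 7] == pytest.approx(qf[4, 5])


def test_ikur_current_trivial_properties():
    assert ikur_current(0.0, 30.0, 0.045) == 0.0
    ek = 8314.0 * 310.0 / 96485.0 * np.log(5.4 / 120.0)
    assert ikur_current(0.5, ek, 0.045) == pytest.approx(0.0, abs=1e-12)
    one = ikur_current(0.3, 10.0, 0.045)
    assert ikur_current(0.3, 10.0, 0.090) == pytest.approx(2 * one)


def test_invalid_schemes_rejected():
    with pytest.raises(SchemeError):
        KurScheme(kind="open", kon_o=-1.0)
    with pytest.raises(SchemeError):
        KurScheme(kind="drug_free", kon_o=1.0)
    with pytest.raises(SchemeError):
        KurScheme(kind="open", bridged=True)
    with pytest.raises(SchemeError):
        transition_matrix(DRUG_FREE, 0.0, concentration=-1.0)
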