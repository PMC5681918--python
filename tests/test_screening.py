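import math

import numpy as np
import pandas as pd
import pytest

from atriakur.screening import (IC50Cache, ScreeningError,
                                SweepOptions, _scenarios, heatmap_matrix,
                                ic50_bin, kinetic_grid, selectivity_metrics,
                                sweep)


def test_kinetic_grid_exact():
    grid = kinetic_grid()
    assert grid.tolist() == [0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100]
    assert len(grid) == 9
    ratios = grid[1:] / grid[:-1]
    # half-log structure: alternating x3 and x10/3
    assert np.allclose(ratios[::2], 3.0, rtol=1e-12)
    assert np.allclose(ratios[1::2], 10.0 / 3.0, rtol=1e-12)
    assert grid[0] == 0.01 and grid[-1] == 100.0


def test_scenario_grids_cardinality():
    assert len(_scenarios("open", "diagonal")) == 9
    assert len(_scenarios("open_inactivated", "full")) == 81
    assert len(_scenarios("open_inactivated", "state_affinity")) == 81
    assert len({id(s) for s in _scenarios("closed", "full")}) == 81
    with pytest.raises(ScreeningError):
        _scenarios("open", "state_affinity")
    with pytest.raises(ScreeningError):
        _scenarios("banana", "full")


def test_state_affinity_grid_varies_conformations_independently():
    scen = _scenarios("open_inactivated", "state_affinity")
    quads = {(s.kon_o, s.koff_o, s.kon_i, s.koff_i) for s in scen}
    assert len(quads) == 81
    ratios = {round(math.log10(s.k_o_over_k_i), 6) for s in scen}
    assert len(ratios) > 5  # K_O/K_I is derived, spans many values


def _fake_table():
    """Synthetic sweep table exercising the flag logic without simulation."""
    rows = []

    def add(sid, phen, rate, apd90, erp, cat, kind="open"):
        rows.append(dict(scenario_id=sid, phenotype=phen, rate_hz=rate,
                         kind=kind if sid.startswith("k") else "reference",
                         apd90=apd90, apd40=apd90 / 3, erp=erp,
                         cat_amp=cat, diastolic_ca=150.0, cat_t50=100.0,
                         dvdt_max=150.0, ic50_um=1.0, conc_um=1.0,
                         failed=False, note="", bridged=False,
                         kon_o=3.0, koff_o=3.0, kon_i=np.nan,
                         koff_i=np.nan, kon_c=np.nan, koff_c=np.nan,
                         kd_o=1.0, kd_i=np.nan, k_o_over_k_i=np.nan))

    for rate, apd_free, erp_free, cat_free in ((1.0, 230.0, 240.0, 100.0),
                                               (3.0, 180.0, 200.0, 110.0)):
        add("drug_free", "cAF", rate, apd_free, erp_free, cat_free)
        add("gkur_50", "cAF", rate, apd_free + 10, erp_free + 10,
            cat_free + 5)
        add("gkur_0", "cAF", rate, apd_free + 30, erp_free + 30,
            cat_free + 15)
        add("nsr_drug_free", "cAF", rate, 300.0 if rate == 1.0 else 230.0,
            310.0 if rate == 1.0 else 250.0, 250.0)
    # k_good: ERP(3Hz) above nSR ref, APD(1Hz) below nSR ref, CaT up
    add("k_good", "cAF", 1.0, 260.0, 270.0, 115.0)
    add("k_good", "cAF", 3.0, 215.0, 260.0, 120.0)
    # k_toxic: APD(1Hz) above the nSR reference
    add("k_toxic", "cAF", 1.0, 320.0, 330.0, 115.0)
    add("k_toxic", "cAF", 3.0, 220.0, 270.0, 120.0)
    # k_weak: no efficacy, no inotropy
    add("k_weak", "cAF", 1.0, 231.0, 241.0, 99.0)
    add("k_weak", "cAF", 3.0, 181.0, 201.0, 109.0)
    return pd.DataFrame(rows)


def test_selectivity_flags_on_synthetic_table():
    out = selectivity_metrics(_fake_table())
    row = out[(out.scenario_id == "k_good") & (out.rate_hz == 1.0)].iloc[0]
    assert row.efficacy and row.safety and row.inotropy
    assert row.best_performing
    toxic = out[out.scenario_id == "k_toxic"].iloc[0]
    assert not toxic.safety and not toxic.best_performing
    weak = out[out.scenario_id == "k_weak"].iloc[0]
    assert not weak.efficacy and not weak.inotropy
    free = out[(out.scenario_id == "drug_free") & (out.rate_hz == 1.0)]
    assert free.iloc[0].delta_apd90 == 0.0
    assert not free.iloc[0].best_performing


def test_selectivity_requires_references():
    bad = _fake_table()
    bad = bad[bad.scenario_id != "nsr_drug_free"]
    with pytest.raises(ScreeningError):
        selectivity_metrics(bad)


def test_ic50_bins():
    assert ic50_bin(0.01) == "<0.1 uM"
    assert ic50_bin(1.0) == "0.1-10 uM"
    assert ic50_bin(100.0) == "10 uM-1 mM"
    assert ic50_bin(1e4) == ">1 mM"


@pytest.fixture(scope="module")
def tiny_sweep():
    """3-scenario diagonal sweep at heavily reduced equilibration."""
    opts = SweepOptions(beats={1.0: 20}, warm_start=True)
    cache = IC50Cache()
    table = sweep("open", "diagonal", phenotypes=("cAF",), rates=(1.0,),
                  options=opts, ic50_cache=cache)
    return table, cache


def test_sweep_table_structure(tiny_sweep):
    table, cache = tiny_sweep
    # 9 scenarios + 4 reference rows for the single condition
    assert len(table) == 13
    for sid in ("drug_free", "gkur_50", "gkur_0", "nsr_drug_free"):
        assert (table.scenario_id == sid).sum() == 1
    assert not table.failed.any()
    scen = table[table.kind != "reference"]
    assert scen.ic50_um.notna().all()
    assert (scen.conc_um == scen.ic50_um).all()
    # every scenario ran at its own IC50 and the cache kept them
    assert len(cache.to_frame()) == 9


def test_sweep_heatmap_matrix(tiny_sweep):
    table, _ = tiny_sweep
    m = heatmap_matrix(table, "apd90", "cAF", 1.0)
    assert m.shape == (9, 9) or m.shape[0] * m.shape[1] >= 9


def test_100pct_block_reference_matches_recomputation(tiny_sweep):
    """The gkur_0 reference row reproduces an independent recomputation."""
    from atriakur import build_parameters, run_paced, biomarkers
    table, _ = tiny_sweep
    ref = table[table.scenario_id == "gkur_0"].iloc[0]
    p = build_parameters("cAF")
    y0 = run_paced(p, rate_hz=1.0, n_beats=20).final_state
    tr = run_paced(p.with_gkur_scale(0.0), rate_hz=1.0, n_beats=20, y0=y0)
    b = biomarkers(tr)
    assert ref.apd90 == pytest.approx(b.apd90, abs=0.5)
    assert ref.cat_amp == pytest.approx(b.cat_amp, abs=0.5)
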