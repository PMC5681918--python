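"""Kinetic-sweep engine and AF-selectivity metrics.

Enumerates theoretical drugs over grids of binding/unbinding rates, runs
each at its own IC50 concentration, and tabulates biomarkers per
(phenotype, rate) together with the four reference conditions: drug-free,
constant 50% and 100% G_Kur reduction, and nSR drug-free.

AF-selectivity flags (on cAF rows): *efficacy* = ERP at 3 Hz above the nSR
drug-free reference; *safety* = APD90 at 1 Hz below the nSR drug-free
reference; *inotropy* = CaT amplitude at 1 Hz above drug-free cAF;
*best-performing* = all three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cell
from .biomarkers import biomarkers
from .cell import run_paced
from .markov import DrugSpec, KurScheme, NO_DRUG
from .params import ModelParameters, build_parameters
from .potency import find_ic50
from .protocols import measure_erp

HALF_LOG_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
AFFINITY_GRID = (0.01, 3.0, 100.0)

REFERENCE_IDS = ("drug_free", "gkur_50", "gkur_0", "nsr_drug_free")

#: IC50 display bins of the state-affinity analysis (uM), optional
IC50_BIN_EDGES = (0.1, 10.0, 1000.0)


def kinetic_grid() -> np.ndarray:
    """The nine half-logarithmic binding rates, s^-1."""
    return np.array(HALF_LOG_GRID)


class ScreeningError(RuntimeError):
    pass


@dataclass
class SweepOptions:
    """Simulation-budget and protocol options for a sweep.

    ``beats`` overrides the fixed equilibration counts (300 at 1 Hz / 900
    at 3 Hz); ``warm_start`` starts each drug scenario from the cached
    drug-free steady state of the same condition, which shortens the
    required drug-equilibration window in scaled-down runs.
    """

    beats: dict[float, int] | None = None
    warm_start: bool = True
    include_erp: bool = False
    erp_decrement: float = 2.0
    erp_equilibration_beats: dict[float, int] | None = None
    rtol: float = 1e-6
    record_dt: float = 0.1
    #: None = rate-matched IC50 (default); a number fixes the IC50 pacing
    #: rate regardless of the AP simulation rate
    ic50_rate: float | None = None

    def n_beats(self, rate_hz: float) -> int:
        if self.beats and rate_hz in self.beats:
            return self.beats[rate_hz]
        return cell.default_beats(rate_hz)


def _scenarios(scheme_family: str, grid_spec: str) -> list[KurScheme]:
    bridged = scheme_family == "open_inactivated_bridged"
    family = ("open_inactivated" if bridged else scheme_family)
    if family not in ("open", "open_inactivated", "closed"):
        raise ScreeningError(f"unknown scheme family {scheme_family!r}")

    def make(kon_o, koff_o, kon_i=None, koff_i=None):
        if family == "open":
            return KurScheme.open_blocker(kon_o, koff_o)
        if family == "closed":
            return KurScheme.closed_blocker(kon_o, koff_o)
        return KurScheme.open_inactivated_blocker(
            kon_o, koff_o, kon_i, koff_i, bridged=bridged)

    grid = kinetic_grid()
    if grid_spec == "diagonal":
        return [make(k, k) for k in grid]
    if grid_spec == "full":
        return [make(kon, koff) for kon in grid for koff in grid]
    if grid_spec == "state_affinity":
        if family != "open_inactivated":
            raise ScreeningError(
                "state_affinity grid applies to open_inactivated blockers")
        g = AFFINITY_GRID
        return [make(a, b, c, d)
                for a in g for b in g for c in g for d in g]
    raise ScreeningError(f"unknown grid_spec {grid_spec!r}")


def _scenario_id(s: KurScheme) -> str:
    if s.kind == "closed":
        return f"closed:kon={s.kon_c:g},koff={s.koff_c:g}"
    tag = "OI" if s.kind == "open_inactivated" else "O"
    if s.bridged:
        tag += "b"
    sid = f"{tag}:kon_o={s.kon_o:g},koff_o={s.koff_o:g}"
    if s.kind == "open_inactivated":
        sid += f",kon_i={s.kon_i:g},koff_i={s.koff_i:g}"
    return sid


class IC50Cache:
    """In-memory IC50 cache keyed by (scheme, rate), CSV round-trippable."""

    def __init__(self):
        self._data: dict[tuple, float] = {}

    @staticmethod
    def _key(scheme: KurScheme, rate_hz: float) -> tuple:
        return (scheme.kind, scheme.bridged, scheme.kon_o, scheme.koff_o,
                scheme.kon_i, scheme.koff_i, scheme.kon_c, scheme.koff_c,
                round(rate_hz, 9))

    def get(self, scheme: KurScheme, rate_hz: float) -> float:
        key = self._key(scheme, rate_hz)
        if key not in self._data:
            self._data[key] = find_ic50(scheme, rate_hz).ic50
        return self._data[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(kind=k[0], bridged=k[1], kon_o=k[2], koff_o=k[3],
                     kon_i=k[4], koff_i=k[5], kon_c=k[6], koff_c=k[7],
                     rate_hz=k[8], ic50_um=v)
                for k, v in self._data.items()]
        return pd.DataFrame(rows)


def _row(scenario_id, scheme: KurScheme | None, phenotype, rate_hz,
         ic50, conc, bset, failed=False, note=""):
    d = dict(scenario_id=scenario_id, phenotype=phenotype, rate_hz=rate_hz,
             ic50_um=ic50, conc_um=conc, failed=failed, note=note)
    if scheme is not None:
        d.update(kind=scheme.kind, bridged=scheme.bridged,
                 kon_o=scheme.kon_o, koff_o=scheme.koff_o,
                 kon_i=scheme.kon_i, koff_i=scheme.koff_i,
                 kon_c=scheme.kon_c, koff_c=scheme.koff_c,
                 kd_o=scheme.kd_o, kd_i=scheme.kd_i,
                 k_o_over_k_i=scheme.k_o_over_k_i)
    else:
        d.update(kind="reference", bridged=False,
                 kon_o=np.nan, koff_o=np.nan, kon_i=np.nan, koff_i=np.nan,
                 kon_c=np.nan, koff_c=np.nan, kd_o=np.nan, kd_i=np.nan,
                 k_o_over_k_i=np.nan)
    d.update(bset.as_dict() if bset is not None else
             {k: np.nan for k in ("apd40", "apd90", "erp", "cat_amp",
                                  "diastolic_ca", "cat_t50", "dvdt_max")})
    return d


def _condition_biomarkers(params: ModelParameters, drug: DrugSpec,
                          rate_hz: float, opts: SweepOptions,
                          y0=None):
    n = opts.n_beats(rate_hz)
    trace = run_paced(params, drug, rate_hz=rate_hz, n_beats=n,
                      record_beats=1, dt=opts.record_dt, rtol=opts.rtol,
                      y0=y0)
    erp = math.nan
    if opts.include_erp:
        erp_res = measure_erp(
            params, drug, rate_hz, y_eq=trace.final_state,
            decrement=opts.erp_decrement, rtol=opts.rtol)
        erp = erp_res.erp
    return biomarkers(trace, erp=erp), trace.final_state


def sweep(scheme_family: str = "open_inactivated",
          grid_spec: str = "diagonal",
          phenotypes: tuple[str, ...] = ("cAF",),
          rates: tuple[float, ...] = (1.0, 3.0),
          options: SweepOptions | None = None,
          ic50_cache: IC50Cache | None = None) -> pd.DataFrame:
    """Run a kinetic sweep; returns a long-format table with one row per
    (scenario, phenotype, rate) plus the four reference rows per
    (phenotype, rate) condition.

    Every scenario is simulated at its own IC50 computed at the matched
    pacing rate.  Per-scenario failures are recorded as flagged rows.
    """
    opts = options or SweepOptions()
    cache = ic50_cache or IC50Cache()
    scen = _scenarios(scheme_family, grid_spec)
    rows = []
    base_states: dict[tuple, np.ndarray] = {}
    for phenotype in phenotypes:
        params = build_parameters(phenotype)
        nsr = build_parameters("nSR")
        for rate in rates:
            # reference rows
            bset_free, y_free = _condition_biomarkers(
                params, NO_DRUG, rate, opts)
            base_states[(phenotype, rate)] = y_free
            rows.append(_row("drug_free", None, phenotype, rate,
                             np.nan, 0.0, bset_free))
            for sid, fac in (("gkur_50", 0.5), ("gkur_0", 0.0)):
                b, _ = _condition_biomarkers(
                    params.with_gkur_scale(fac), NO_DRUG, rate, opts,
                    y0=y_free if opts.warm_start else None)
                rows.append(_row(sid, None, phenotype, rate,
                                 np.nan, 0.0, b))
            bset_nsr, _ = _condition_biomarkers(nsr, NO_DRUG, rate, opts)
            rows.append(_row("nsr_drug_free", None, phenotype, rate,
                             np.nan, 0.0, bset_nsr))
            # drug scenarios
            for s in scen:
                sid = _scenario_id(s)
                try:
                    ic50 = cache.get(s, opts.ic50_rate or rate)
                    drug = DrugSpec(scheme=s, concentration=ic50)
                    b, _ = _condition_biomarkers(
                        params, drug, rate, opts,
                        y0=y_free if opts.warm_start else None)
                    rows.append(_row(sid, s, phenotype, rate, ic50, ic50, b))
                except Exception as exc:  # flagged row, not an abort
                    rows.append(_row(sid, s, phenotype, rate,
                                     np.nan, np.nan, None,
                                     failed=True, note=str(exc)))
    df = pd.DataFrame(rows)
    df.attrs["scheme_family"] = scheme_family
    df.attrs["grid_spec"] = grid_spec
    return df


def selectivity_metrics(table: pd.DataFrame,
                        use_erp: bool = True) -> pd.DataFrame:
    """Annotate a sweep table with deltas vs. drug-free and the
    AF-selectivity flags.

    Requires cAF rows at 1 and 3 Hz and the nSR drug-free reference rows.
    With ``use_erp=False`` (e.g. a sweep run without ERP measurement) the
    efficacy flag uses APD90 at 3 Hz as the refractoriness surrogate, since
    ERP changes mirror APD changes under this protocol family.
    """
    df = table.copy()
    need = df[(df.phenotype == "cAF")]
    if need.empty or not {1.0, 3.0} <= set(need.rate_hz):
        raise ScreeningError("table lacks cAF biomarkers at 1 and 3 Hz")

    def ref(sid, phenotype, rate, col):
        sel = df[(df.scenario_id == sid) & (df.phenotype == phenotype)
                 & (df.rate_hz == rate)]
        if len(sel) != 1:
            raise ScreeningError(
                f"missing reference row {sid} ({phenotype}, {rate} Hz)")
        return float(sel.iloc[0][col])

    for rate in sorted(set(df.rate_hz)):
        for phenotype in sorted(set(df.phenotype)):
            m = (df.rate_hz == rate) & (df.phenotype == phenotype)
            if not m.any():
                continue
            apd_free = ref("drug_free", phenotype, rate, "apd90")
            cat_free = ref("drug_free", phenotype, rate, "cat_amp")
            erp_free = ref("drug_free", phenotype, rate, "erp")
            df.loc[m, "delta_apd90"] = df.loc[m, "apd90"] - apd_free
            df.loc[m, "delta_erp"] = df.loc[m, "erp"] - erp_free
            df.loc[m, "pct_cat_amp"] = (
                100.0 * (df.loc[m, "cat_amp"] - cat_free) / cat_free)

    eff_col = "erp" if use_erp else "apd90"
    erp_ref_3 = ref("nsr_drug_free", "cAF", 3.0, eff_col)
    apd_ref_1 = ref("nsr_drug_free", "cAF", 1.0, "apd90")
    cat_free_1 = ref("drug_free", "cAF", 1.0, "cat_amp")
    if use_erp and math.isnan(erp_ref_3):
        raise ScreeningError(
            "ERP references absent; run the sweep with include_erp or use "
            "use_erp=False")

    caf1 = df[(df.phenotype == "cAF") & (df.rate_hz == 1.0)]
    caf3 = df[(df.phenotype == "cAF") & (df.rate_hz == 3.0)]
    eff = {r.scenario_id: r[eff_col] > erp_ref_3
           for _, r in caf3.iterrows()}
    safe = {r.scenario_id: r.apd90 < apd_ref_1 for _, r in caf1.iterrows()}
    ino = {r.scenario_id: r.cat_amp > cat_free_1
           for _, r in caf1.iterrows()}
    df["efficacy"] = df.scenario_id.map(eff)
    df["safety"] = df.scenario_id.map(safe)
    df["inotropy"] = df.scenario_id.map(ino)
    df["best_performing"] = (df.efficacy.fillna(False)
                             & df.safety.fillna(False)
                             & df.inotropy.fillna(False))
    df.loc[df.scenario_id.isin(REFERENCE_IDS), "best_performing"] = False
    return df


def ic50_bin(ic50_um: float) -> str:
    """Optional display binning of IC50 values (uM cutoffs 0.1, 10, 1000)."""
    if ic50_um < IC50_BIN_EDGES[0]:
        return "<0.1 uM"
    if ic50_um < IC50_BIN_EDGES[1]:
        return "0.1-10 uM"
    if ic50_um < IC50_BIN_EDGES[2]:
        return "10 uM-1 mM"
    return ">1 mM"


def heatmap_matrix(table: pd.DataFrame, value: str, phenotype: str = "cAF",
                   rate_hz: float = 1.0) -> pd.DataFrame:
    """Wide-format (k_on x k_off) matrix of a biomarker for a full-grid
    sweep, for heatmap rendering."""
    sub = table[(table.phenotype == phenotype) & (table.rate_hz == rate_hz)
                & (table.kind != "reference")]
    kon = sub.kon_o.where(sub.kind != "closed", sub.kon_c)
    koff = sub.koff_o.where(sub.kind != "closed", sub.koff_c)
    out = pd.DataFrame({"kon": kon, "koff": koff, value: sub[value]})
    return out.pivot_table(index="kon", columns="koff", values=value)
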