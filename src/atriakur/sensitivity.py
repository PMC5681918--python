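"""Population-of-models parameter sensitivity analysis.

A population of model variants is generated by multiplying each of the 18
maximal conductances/transport rates by an independent log-normal factor
(SD of the natural-log factor = 0.1).  Biomarkers are computed per variant;
partial-least-squares regression (NIPALS, full component count) of z-scored
log outputs on z-scored log scale factors is repeated for random subsets
(30 subsets of 300 of the 900 variants by default), and the mean and SD of
the standardized coefficients across subsets are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from . import cell
from .biomarkers import biomarkers
from .cell import run_paced
from .markov import NO_DRUG
from .params import PARAM_NAMES, build_parameters
from .protocols import measure_erp

DEFAULT_OUTPUTS = ("apd40", "apd90", "cat_amp", "diastolic_ca", "cat_t50")


class SensitivityError(RuntimeError):
    pass


@dataclass
class SensitivitySpec:
    n_variants: int = 900
    sigma: float = 0.1                      # SD of ln(scale factor)
    parameters: tuple[str, ...] = PARAM_NAMES
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS
    n_subsets: int = 30
    subset_size: int = 300
    phenotypes: tuple[str, ...] = ("nSR", "cAF")
    rates: tuple[float, ...] = (1.0, 3.0)
    seed: int = 0
    include_erp: bool = False
    erp_subsample: int | None = None        # fast mode: ERP on a subsample
    beats: dict[float, int] | None = None   # equilibration override
    rtol: float = 1e-6

    def __post_init__(self):
        if self.sigma < 0:
            raise SensitivityError("sigma must be >= 0")
        if self.subset_size > self.n_variants:
            raise SensitivityError("subset_size must be <= n_variants")

    def n_beats(self, rate_hz: float) -> int:
        if self.beats and rate_hz in self.beats:
            return self.beats[rate_hz]
        return cell.default_beats(rate_hz)


@dataclass
class RegressionResult:
    """Mean and SD of standardized PLS coefficients across subsets."""

    phenotype: str
    rate_hz: float
    outputs: tuple[str, ...]
    parameters: tuple[str, ...]
    mean: np.ndarray          # (n_outputs, n_parameters)
    sd: np.ndarray
    n_excluded: int = 0

    def coefficient(self, output: str, parameter: str) -> float:
        return float(self.mean[self.outputs.index(output),
                               self.parameters.index(parameter)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, out in enumerate(self.outputs):
            for k, par in enumerate(self.parameters):
                rows.append(dict(phenotype=self.phenotype,
                                 rate_hz=self.rate_hz, output=out,
                                 parameter=par, coef_mean=self.mean[i, k],
                                 coef_sd=self.sd[i, k]))
        return pd.DataFrame(rows)


def sample_population(spec: SensitivitySpec,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """(n_variants x n_parameters) matrix of multiplicative scale factors,
    exp(z) with z ~ Normal(0, sigma^2), independent per entry."""
    rng = rng or np.random.default_rng(spec.seed)
    z = rng.normal(0.0, spec.sigma,
                   size=(spec.n_variants, len(spec.parameters)))
    return np.exp(z)


def pls_coefficients(x: np.ndarray, y: np.ndarray,
                     n_components: int | None = None) -> np.ndarray:
    """Standardized regression coefficients (n_outputs x n_params) by
    NIPALS partial least squares on z-scored X and Y."""
    n_components = n_components or x.shape[1]
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    ys = (y - y.mean(0)) / y.std(0, ddof=1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(xs, ys)
    return np.asarray(pls.coef_)  # (n_targets, n_features)


def regress(scale_factors: np.ndarray, outputs: np.ndarray,
            spec: SensitivitySpec, phenotype: str = "",
            rate_hz: float = float("nan"),
            rng: np.random.Generator | None = None) -> RegressionResult:
    """Subset-resampled PLS regression of log outputs on log scale factors.

    Rows with any undefined (NaN) output are excluded (and counted); a
    warning-level note is attached when more than 10% are excluded.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    x = np.log(np.asarray(scale_factors, dtype=float))
    y = np.log(np.asarray(outputs, dtype=float))
    ok = np.all(np.isfinite(y), axis=1)
    n_excluded = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.shape[0] < spec.subset_size:
        raise SensitivityError(
            f"only {x.shape[0]} defined variants, need >= "
            f"{spec.subset_size}")
    if np.any(x.std(0) == 0):
        raise SensitivityError("degenerate parameter column (zero variance)")
    if n_excluded > 0.1 * len(ok):
        import warnings
        warnings.warn(f"{n_excluded} of {len(ok)} variants excluded "
                      "(undefined biomarkers)", RuntimeWarning)
    coefs = []
    for _ in range(spec.n_subsets):
        idx = rng.choice(x.shape[0], size=spec.subset_size, replace=False)
        coefs.append(pls_coefficients(x[idx], y[idx],
                                      n_components=x.shape[1]))
    coefs = np.asarray(coefs)
    return RegressionResult(
        phenotype=phenotype, rate_hz=rate_hz,
        outputs=tuple(spec.outputs), parameters=tuple(spec.parameters),
        mean=coefs.mean(0), sd=coefs.std(0, ddof=1),
        n_excluded=n_excluded)


def population_biomarkers(spec: SensitivitySpec, phenotype: str,
                          rate_hz: float,
                          scale_factors: np.ndarray,
                          y0: np.ndarray | None = None) -> pd.DataFrame:
    """Biomarkers for every variant of a population at one condition.

    With ``y0`` (e.g. the baseline steady state) each variant is paced from
    that shared state for the spec's beat count; otherwise from the default
    initial conditions.
    """
    n_beats = spec.n_beats(rate_hz)
    rows = []
    erp_idx: set[int] = set()
    if spec.include_erp:
        n_erp = spec.erp_subsample or spec.n_variants
        erp_idx = set(range(min(n_erp, scale_factors.shape[0])))
    for i, sf in enumerate(scale_factors):
        params = build_parameters(phenotype, sf)
        try:
            trace = run_paced(params, NO_DRUG, rate_hz=rate_hz,
                              n_beats=n_beats, rtol=spec.rtol, y0=y0)
            erp = math.nan
            if i in erp_idx:
                from .protocols import ProtocolError
                try:
                    erp = measure_erp(params, NO_DRUG, rate_hz,
                                      y_eq=trace.final_state,
                                      rtol=spec.rtol).erp
                except ProtocolError:
                    pass  # inexcitable variant: ERP undefined, excluded
            b = biomarkers(trace, erp=erp)
            row = b.as_dict()
            row["failed"] = False
        except cell.SimulationError:
            row = {k: math.nan for k in
                   ("apd40", "apd90", "erp", "cat_amp", "diastolic_ca",
                    "cat_t50", "dvdt_max")}
            row["failed"] = True
        row["variant"] = i
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def run_sensitivity(spec: SensitivitySpec,
                    warm_start: bool = True) -> list[RegressionResult]:
    """Full pipeline: sample population, simulate biomarkers, regress.

    Repolarization-failure variants (undefined biomarkers) are excluded
    from regression and counted in ``n_excluded``.
    """
    rng = np.random.default_rng(spec.seed)
    sf = sample_population(spec, rng)
    results = []
    for phenotype in spec.phenotypes:
        base = build_parameters(phenotype)
        for rate in spec.rates:
            y0 = None
            if warm_start:
                # the shared baseline is always fully equilibrated; the
                # per-variant beat budget (spec.beats) then only needs to
                # re-settle the perturbed parameters
                y0 = cell.equilibrated_state(
                    base, NO_DRUG, rate, cell.default_beats(rate),
                    rtol=spec.rtol)
            table = population_biomarkers(spec, phenotype, rate, sf, y0=y0)
            y = table[list(spec.outputs)].to_numpy()
            res = regress(sf, y, spec, phenotype=phenotype, rate_hz=rate,
                          rng=np.random.default_rng(spec.seed + 1))
            results.append(res)
            if spec.include_erp and "erp" not in spec.outputs:
                # ERP is regressed separately: it may be measured on a
                # documented subsample only (fast mode)
                has_erp = table["erp"].notna().to_numpy()
                n_sub = int(has_erp.sum())
                if n_sub >= len(spec.parameters) + 2:
                    erp_spec = SensitivitySpec(**{
                        **spec.__dict__, "outputs": ("erp",),
                        "n_variants": n_sub,
                        "subset_size": min(spec.subset_size, n_sub)})
                    res_erp = regress(
                        sf[has_erp], table.loc[has_erp, ["erp"]].to_numpy(),
                        erp_spec, phenotype=phenotype, rate_hz=rate,
                        rng=np.random.default_rng(spec.seed + 2))
                    results.append(res_erp)
    return results
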