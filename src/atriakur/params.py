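"""Model parameters: baseline constants, cAF remodeling, scale factors.

The scalable parameters are the 18 maximal conductances / transport rates
used in the population-of-models sensitivity analysis.  The chronic-AF (cAF)
phenotype applies the documented remodeling multipliers to the normal sinus
rhythm (nSR) baseline *before* any user scale factors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Names and order of the scalable parameters (the sensitivity-analysis set).
PARAM_NAMES: tuple[str, ...] = (
    "g_na", "g_nab", "g_to", "g_kr", "g_ks", "g_k1", "g_kp", "g_kur",
    "g_clca", "g_clb", "p_ca", "g_cab", "ibar_nak", "ibar_ncx",
    "ibar_pmca", "vmax_serca", "ks_ryr", "k_sr_leak",
)

N_PARAMS = len(PARAM_NAMES)

PHENOTYPES = ("nSR", "cAF")


class ParameterError(ValueError):
    """Invalid phenotype or scale factors."""


def _load_parameter_file() -> dict:
    ref = importlib.resources.files("atriakur.data") / "baseline_parameters.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_PFILE = _load_parameter_file()

PARAMETER_FILE_VERSION: int = int(_PFILE["version"])
DEFAULT_STIM_AMPLITUDE: float = float(_PFILE["stimulus"]["amplitude"])  # A/F
DEFAULT_STIM_DURATION: float = float(_PFILE["stimulus"]["duration"])    # ms


@dataclass(frozen=True)
class ModelParameters:
    """Fully resolved parameter set for one phenotype.

    ``values`` holds the 18 scalable parameters (order :data:`PARAM_NAMES`)
    with phenotype multipliers and user scale factors already applied.
    ``ryr_ko_ca`` (uM^-2 ms^-1) is the RyR opening-rate Ca2+ sensitivity,
    remodeled in cAF but not part of the scalable set.
    """

    phenotype: str
    values: np.ndarray
    ryr_ko_ca: float
    scale_factors: np.ndarray = field(
        default_factory=lambda: np.ones(N_PARAMS))
    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE
    stim_duration: float = DEFAULT_STIM_DURATION

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ParameterError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}")
        if self.values.shape != (N_PARAMS,) or np.any(self.values <= 0):
            raise ParameterError("parameter vector must be positive, length 18")

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    @property
    def g_kur(self) -> float:
        return self["g_kur"]

    def with_gkur_scale(self, factor: float) -> "ModelParameters":
        """Constant conductance scaling of G_Kur (e.g. 0.5 or 0 for the
        50% / 100%-reduction reference scenarios)."""
        if factor < 0:
            raise ParameterError("G_Kur scale factor must be >= 0")
        v = self.values.copy()
        i = PARAM_NAMES.index("g_kur")
        if factor == 0.0:
            # exact full block; keep vector positive for validation by using
            # a conductance that is numerically zero in the current
            v[i] = 1e-300
        else:
            v[i] *= factor
        return replace(self, values=v)


def baseline_values() -> np.ndarray:
    base = _PFILE["baseline"]
    return np.array([float(base[k]) for k in PARAM_NAMES])


def caf_multipliers() -> dict[str, float]:
    return {k: float(v) for k, v in _PFILE["caf_multipliers"].items()}


def build_parameters(phenotype: str = "nSR",
                     scale_factors=None) -> ModelParameters:
    """Build a resolved parameter set.

    cAF remodeling multipliers are applied before the user ``scale_factors``
    (length-18 positive vector, one per entry of :data:`PARAM_NAMES`).
    """
    if phenotype not in PHENOTYPES:
        raise ParameterError(
            f"phenotype must be one of {PHENOTYPES}, got {phenotype!r}")
    if scale_factors is None:
        scale_factors = np.ones(N_PARAMS)
    scale_factors = np.asarray(scale_factors, dtype=float)
    if scale_factors.shape != (N_PARAMS,):
        raise ParameterError(
            f"scale_factors must have length {N_PARAMS}, "
            f"got shape {scale_factors.shape}")
    if np.any(scale_factors <= 0) or not np.all(np.isfinite(scale_factors)):
        raise ParameterError("scale_factors must be positive and finite")

    values = baseline_values()
    ko_ca = 10.0  # uM^-2 ms^-1
    if phenotype == "cAF":
        mult = caf_multipliers()
        for name, m in mult.items():
            if name == "ryr_ko_ca":
                ko_ca *= m
            else:
                values[PARAM_NAMES.index(name)] *= m
    values = values * scale_factors
    return ModelParameters(phenotype=phenotype, values=values,
                           ryr_ko_ca=ko_ca,
                           scale_factors=scale_factors.copy())
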