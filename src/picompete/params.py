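"""Parameter containers for the two-genus, two-nutrient competition model.

Units are fixed package-wide: time in days, nutrient concentrations in
nmol N L^-1 (nM), cell abundances in cells L^-1, cell quotas in
nmol N cell^-1, supply fluxes in nmol N L^-1 d^-1.

The model tracks *Prochlorococcus* and *Synechococcus* competing for
nitrate (NO3-) and ammonium (NH4+).  Each genus is described by
Michaelis-Menten uptake kinetics per nutrient (maximum specific uptake
rate Vmax, half-saturation constant K), a specific mortality rate m and
a cellular nitrogen quota QN that converts cell counts to nitrogen
biomass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import yaml

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "GenusParams",
    "CommunityConfig",
    "InitialConditions",
    "default_pro",
    "default_syn",
    "default_config",
    "default_initial",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class GenusParams:
    """Uptake and growth traits of one genus.

    Parameters
    ----------
    vmax_no3, vmax_nh4 : float
        Maximum specific uptake rate for NO3- / NH4+, d^-1.
    k_no3, k_nh4 : float
        Half-saturation constants, nmol L^-1.
    mortality : float
        Specific mortality rate m, d^-1.
    q_n : float
        Cellular nitrogen quota QN, nmol cell^-1.
    """

    vmax_no3: float
    vmax_nh4: float
    k_no3: float
    k_nh4: float
    mortality: float
    q_n: float

    def __post_init__(self) -> None:
        for name in ("vmax_no3", "vmax_nh4", "mortality"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("k_no3", "k_nh4", "q_n"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.viable:
            warnings.warn(
                "mortality >= vmax_no3 + vmax_nh4: this genus can never achieve "
                "positive net growth and will always decline",
                stacklevel=2,
            )

    @property
    def viable(self) -> bool:
        """Whether positive net growth is achievable at saturating nutrients."""
        return self.mortality < self.vmax_no3 + self.vmax_nh4

    def replace(self, **kwargs) -> "GenusParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CommunityConfig:
    """Full parameterization of the two-genus community.

    ``s_no3`` and ``s_nh4`` are the constant external supply fluxes of
    each nutrient, nmol L^-1 d^-1.  Their ratio (the resource ratio
    SNO3/SNH4) is the environmental axis along which dominance shifts.
    """

    pro: GenusParams
    syn: GenusParams
    s_no3: float
    s_nh4: float

    def __post_init__(self) -> None:
        if self.s_no3 < 0 or self.s_nh4 < 0:
            raise ParameterError("supply fluxes s_no3, s_nh4 must be >= 0")

    def genus(self, which: str) -> GenusParams:
        if which not in ("pro", "syn"):
            raise ParameterError(f"genus must be 'pro' or 'syn', got {which!r}")
        return self.pro if which == "pro" else self.syn

    @property
    def s_ratio(self) -> float:
        """Resource supply ratio SNO3/SNH4."""
        return self.s_no3 / self.s_nh4

    def replace(self, **kwargs) -> "CommunityConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitialConditions:
    """Initial state for simulations: ambient cells and nutrients."""

    x_pro: float = 2.5e7
    x_syn: float = 4.0e6
    no3: float = 5.0
    nh4: float = 5.0

    def __post_init__(self) -> None:
        if min(self.x_pro, self.x_syn, self.no3, self.nh4) < 0:
            raise ParameterError("initial conditions must be >= 0")


# ---------------------------------------------------------------------------
# Reference parameterization
#
# Default trait values for the two genera.  They encode the trait structure
# inferred from nanomolar N-addition incubations in the subtropical NW
# Pacific: Prochlorococcus holds the lower half-saturation constant for
# ammonium, Synechococcus the lower one for nitrate (and the larger
# VmaxNO3), both genera have VmaxNH4 > VmaxNO3, and Synechococcus'
# preferred nutrient flips from nitrate to ammonium at 39 nM.  Supply
# defaults use the baseline nitrate:ammonium resource ratio of 1:3.
# ---------------------------------------------------------------------------

def default_pro() -> GenusParams:
    """Reference *Prochlorococcus* traits (ammonium specialist)."""
    return GenusParams(
        vmax_no3=0.1, vmax_nh4=1.2, k_no3=45.0, k_nh4=8.0,
        mortality=0.12, q_n=5.0e-7,
    )


def default_syn() -> GenusParams:
    """Reference *Synechococcus* traits (nitrate specialist below 39 nM)."""
    return GenusParams(
        vmax_no3=0.6, vmax_nh4=1.0, k_no3=15.0, k_nh4=51.0,
        mortality=0.12, q_n=1.5e-6,
    )


def default_config(s_no3: float = 2.5, s_nh4: float = 7.5) -> CommunityConfig:
    """Reference community at the baseline 1:3 NO3-:NH4+ supply ratio."""
    return CommunityConfig(pro=default_pro(), syn=default_syn(),
                           s_no3=s_no3, s_nh4=s_nh4)


def default_initial() -> InitialConditions:
    return InitialConditions()


# ---------------------------------------------------------------------------
# Config file I/O.  Keys mirror the conventional symbol names
# (VmaxNO3Pro, KNH4Syn, mPro, QNPro, SNO3, SNH4, ...), so published
# parameter tables can be pasted in verbatim.
# ---------------------------------------------------------------------------

_PARAM_KEYS = {
    "pro": {"vmax_no3": "VmaxNO3Pro", "vmax_nh4": "VmaxNH4Pro",
            "k_no3": "KNO3Pro", "k_nh4": "KNH4Pro",
            "mortality": "mPro", "q_n": "QNPro"},
    "syn": {"vmax_no3": "VmaxNO3Syn", "vmax_nh4": "VmaxNH4Syn",
            "k_no3": "KNO3Syn", "k_nh4": "KNH4Syn",
            "mortality": "mSyn", "q_n": "QNSyn"},
}
_INIT_KEYS = {"x_pro": "XPro", "x_syn": "XSyn", "no3": "NO3", "nh4": "NH4"}


def _genus_from_mapping(mapping: dict, which: str) -> GenusParams:
    kwargs = {}
    for attr, key in _PARAM_KEYS[which].items():
        if key not in mapping:
            raise ConfigurationError(f"missing required parameter {key!r}")
        kwargs[attr] = float(mapping[key])
    return GenusParams(**kwargs)


def config_from_mapping(mapping: dict) -> tuple[CommunityConfig, InitialConditions]:
    """Build (CommunityConfig, InitialConditions) from a parsed config dict."""
    params = mapping.get("parameters")
    if params is None:
        raise ConfigurationError("config must contain a 'parameters' section")
    pro = _genus_from_mapping(params, "pro")
    syn = _genus_from_mapping(params, "syn")
    for key in ("SNO3", "SNH4"):
        if key not in params:
            raise ConfigurationError(f"missing required parameter {key!r}")
    cfg = CommunityConfig(pro=pro, syn=syn,
                          s_no3=float(params["SNO3"]), s_nh4=float(params["SNH4"]))
    init_map = mapping.get("initial", {})
    init_kwargs = {attr: float(init_map[key])
                   for attr, key in _INIT_KEYS.items() if key in init_map}
    return cfg, InitialConditions(**init_kwargs)


def config_to_mapping(cfg: CommunityConfig,
                      init: InitialConditions | None = None) -> dict:
    params = {}
    for which in ("pro", "syn"):
        g = cfg.genus(which)
        for attr, key in _PARAM_KEYS[which].items():
            params[key] = float(getattr(g, attr))
    params["SNO3"] = float(cfg.s_no3)
    params["SNH4"] = float(cfg.s_nh4)
    out = {"units": {"rates": "d-1", "concentrations": "nmol L-1",
                     "abundances": "cells L-1", "quotas": "nmol cell-1",
                     "supply": "nmol L-1 d-1"},
           "parameters": params}
    if init is not None:
        out["initial"] = {key: float(getattr(init, attr))
                          for attr, key in _INIT_KEYS.items()}
    return out


def load_config(path) -> tuple[CommunityConfig, InitialConditions]:
    """Read a YAML config file into (CommunityConfig, InitialConditions)."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return config_from_mapping(mapping)


def dump_config(cfg: CommunityConfig, init: InitialConditions | None, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_mapping(cfg, init), fh, sort_keys=False)
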