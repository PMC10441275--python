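"""Michaelis-Menten uptake kinetics and derived trait quantities.

The specific uptake rate of nutrient j by genus i is

    V_j^i([j]) = Vmax_j^i [j] / ([j] + K_j^i)        (d^-1)

Specific growth is the sum of the two uptake terms minus mortality.
Two derived trait summaries matter for competition at low nutrients:
the affinity A = Vmax/K (initial slope of the uptake curve, the
relevant competitive measure when nutrients are depleted) and the
preference crossover, the concentration at which a genus takes up both
nutrients at the same specific rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, StateError
from .params import GenusParams

__all__ = ["uptake_rate", "growth_rate", "TraitSummary", "trait_summary"]


def uptake_rate(vmax: float, k: float, conc) -> float:
    """Specific Michaelis-Menten uptake rate, d^-1.

    Parameters
    ----------
    vmax : float
        Maximum specific uptake rate, d^-1 (>= 0).
    k : float
        Half-saturation constant, nmol L^-1 (> 0).
    conc : float or ndarray
        Nutrient concentration, nmol L^-1 (>= 0).  ``inf`` is accepted
        and yields the saturating rate ``vmax``.
    """
    if vmax < 0:
        raise ParameterError(f"vmax must be >= 0, got {vmax}")
    if k <= 0:
        raise ParameterError(f"k must be > 0, got {k}")
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise StateError(f"concentration must be >= 0, got {conc}")
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(conc_arr), vmax, vmax * conc_arr / (conc_arr + k))
    return float(out) if np.isscalar(conc) or conc_arr.ndim == 0 else out


def growth_rate(g: GenusParams, no3: float, nh4: float) -> float:
    """Specific net growth rate (uptake sum minus mortality), d^-1."""
    return (uptake_rate(g.vmax_no3, g.k_no3, no3)
            + uptake_rate(g.vmax_nh4, g.k_nh4, nh4)
            - g.mortality)


@dataclass(frozen=True)
class TraitSummary:
    """Affinities (L nmol^-1 d^-1 scale: d^-1 per nmol L^-1) and preference
    crossover concentration (nmol L^-1; ``None`` when one nutrient is
    preferred at every concentration)."""

    affinity_no3: float
    affinity_nh4: float
    crossover_conc: float | None


def trait_summary(g: GenusParams) -> TraitSummary:
    """Affinity per nutrient and the preference-crossover concentration.

    The crossover is the positive root of
    ``vmax_nh4 c/(c+k_nh4) = vmax_no3 c/(c+k_no3)``:

        c* = (vmax_no3 k_nh4 - vmax_nh4 k_no3) / (vmax_nh4 - vmax_no3)

    Reported as absent (``None``) when the two Vmax are equal (one
    nutrient then dominates at all concentrations) or when c* <= 0.
    """
    a3 = g.vmax_no3 / g.k_no3
    a4 = g.vmax_nh4 / g.k_nh4
    dv = g.vmax_nh4 - g.vmax_no3
    if dv == 0:
        crossover = None
    else:
        c = (g.vmax_no3 * g.k_nh4 - g.vmax_nh4 * g.k_no3) / dv
        crossover = c if c > 0 else None
    return TraitSummary(affinity_no3=a3, affinity_nh4=a4, crossover_conc=crossover)
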