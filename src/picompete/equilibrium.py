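"""Steady-state analysis: equilibria, coexistence zones and trait sweeps.

Setting the growth equations to zero defines each genus' zero-net-growth
isocline (ZNGI) in ([NO3-], [NH4+]) space; a coexistence equilibrium is
an intersection of the two ZNGIs at which the 2x2 nutrient-balance
system

    S_j = sum_i V_j^i([j]*) n_i ,   n_i = QN_i X_i

has strictly positive biomass solutions.  For Michaelis-Menten uptake
the ZNGIs invert in closed form, so the intersection reduces to a
bracketed one-dimensional root-find, and single-resident equilibria are
fully closed-form (at a resident steady state the two specific uptake
rates must split the mortality in proportion to the supply fluxes).

Zones follow the four-domain classification of half-saturation-ratio
space: coexistence with Prochlorococcus drawing most of its N from
NH4+ and Synechococcus from NO3- (domain iv), the mirrored
specialization (domain i), and exclusion of one genus (domains ii and
iii, labelled ``syn_only`` / ``pro_only``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import ModelState, _rhs_array
from .exceptions import DegenerateSystemError, ParameterError
from .kinetics import growth_rate, uptake_rate
from .params import CommunityConfig, GenusParams

__all__ = [
    "EquilibriumSolution", "ZoneMap", "ResourceSweep",
    "solve_coexistence", "solve_single", "classify_zone",
    "sweep_k_ratios", "sweep_resource_ratio",
]

ZONES = ("coexist_iv", "coexist_i", "pro_only", "syn_only", "none")


@dataclass(frozen=True)
class EquilibriumSolution:
    """A candidate community steady state.

    ``no3_star``/``nh4_star`` may be ``inf`` for a single-resident state in
    which the unconsumed nutrient has no sink (the model has no abiotic
    loss term); such components are excluded from residual checks and the
    absent genus sees them as saturating in invasion tests.
    """

    no3_star: float
    nh4_star: float
    n_pro: float
    n_syn: float
    zone: str
    valid: bool
    stable: bool | None = None
    bistable: bool = False
    invasion_rate: float | None = None  # absent genus' growth at the state

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ParameterError(f"unknown zone label {self.zone!r}")

    @property
    def biomass_ratio(self) -> float:
        """N_Pro / N_Syn; NaN unless both biomasses are positive."""
        if self.n_pro > 0 and self.n_syn > 0:
            return self.n_pro / self.n_syn
        return float("nan")

    def to_state(self, cfg: CommunityConfig) -> ModelState:
        return ModelState(x_pro=self.n_pro / cfg.pro.q_n,
                          x_syn=self.n_syn / cfg.syn.q_n,
                          no3=self.no3_star, nh4=self.nh4_star)


def _invert_mm(u: float, vmax: float, k: float) -> float:
    """Concentration at which MM uptake equals ``u`` (requires 0 <= u < vmax)."""
    if u <= 0:
        return 0.0
    return u * k / (vmax - u)


def _zngi_no3(g: GenusParams, nh4: float) -> float:
    """[NO3-] on the genus' ZNGI at a given [NH4+].

    Returns NaN when no finite nonnegative solution exists (the NH4+
    level either already sustains growth at zero NO3-, in which case the
    value 0 marks the boundary, or cannot be compensated by NO3-).
    """
    r = g.mortality - uptake_rate(g.vmax_nh4, g.k_nh4, nh4)
    if r < 0:
        return np.nan  # growing even at [NO3-] = 0; isocline not defined here
    if r >= g.vmax_no3:
        return np.inf  # NO3- cannot close the deficit
    return _invert_mm(r, g.vmax_no3, g.k_no3)


def _same_traits(a: GenusParams, b: GenusParams) -> bool:
    return (a.vmax_no3 == b.vmax_no3 and a.vmax_nh4 == b.vmax_nh4
            and a.k_no3 == b.k_no3 and a.k_nh4 == b.k_nh4
            and a.mortality == b.mortality)


def _uptake_matrix(cfg: CommunityConfig, c3: float, c4: float) -> np.ndarray:
    """Per-biomass uptake matrix: rows = nutrients (NO3, NH4), cols = genera."""
    p, s = cfg.pro, cfg.syn
    return np.array([
        [uptake_rate(p.vmax_no3, p.k_no3, c3), uptake_rate(s.vmax_no3, s.k_no3, c3)],
        [uptake_rate(p.vmax_nh4, p.k_nh4, c4), uptake_rate(s.vmax_nh4, s.k_nh4, c4)],
    ])


def _interior_roots(cfg: CommunityConfig, n_scan: int = 400) -> list[tuple[float, float]]:
    """All intersections of the two ZNGIs at finite positive concentrations."""
    p, s = cfg.pro, cfg.syn

    # A genus with no NO3- uptake has a horizontal ZNGI ([NH4+] = const),
    # which the [NH4+]-parametrized scan below cannot represent.
    if p.vmax_no3 == 0 or s.vmax_no3 == 0:
        if p.vmax_no3 == 0 and s.vmax_no3 == 0:
            return []  # both limited by NH4+ alone: single-resource exclusion
        flat, other = (p, s) if p.vmax_no3 == 0 else (s, p)
        if flat.vmax_nh4 <= flat.mortality:
            return []
        c4 = _invert_mm(flat.mortality, flat.vmax_nh4, flat.k_nh4)
        c3 = _zngi_no3(other, c4)
        if np.isfinite(c3) and c3 >= 0:
            return [(float(c3), float(c4))]
        return []

    # [NH4+] interval on which both ZNGIs are finite:
    # need 0 <= m - u4(c4) < vmax_no3 for each genus.
    lo, hi = 0.0, np.inf
    for g in (p, s):
        if g.mortality > g.vmax_no3:
            # NH4+ must contribute at least m - vmax_no3
            need = g.mortality - g.vmax_no3
            if need >= g.vmax_nh4:
                return []  # genus cannot reach zero net growth at all
            lo = max(lo, _invert_mm(need, g.vmax_nh4, g.k_nh4))
        if g.vmax_nh4 > g.mortality:
            hi = min(hi, _invert_mm(g.mortality, g.vmax_nh4, g.k_nh4))
    if not np.isfinite(hi):
        hi = 1e6  # pragmatic cap, far above any realistic concentration
    if hi <= lo:
        return []

    def h(c4: float) -> float:
        return _zngi_no3(p, c4) - _zngi_no3(s, c4)

    eps = 1e-12 * max(1.0, hi - lo)
    grid = np.linspace(lo + eps, hi - eps, n_scan)
    vals = np.array([h(c) for c in grid])
    roots: list[tuple[float, float]] = []
    finite = np.isfinite(vals)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            c4 = grid[i]
        elif a * b < 0:
            c4 = brentq(h, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
        else:
            continue
        c3 = _zngi_no3(p, c4)
        if np.isfinite(c3) and c3 >= 0:
            if not any(np.isclose(c4, r[1], rtol=1e-6, atol=1e-12) for r in roots):
                roots.append((float(c3), float(c4)))
    return roots


def solve_coexistence(cfg: CommunityConfig) -> EquilibriumSolution:
    """Solve for a two-genus coexistence equilibrium.

    Finds ([NO3-]*, [NH4+]*) with zero net growth for both genera, then
    solves the 2x2 linear nutrient-balance system for the biomasses.
    ``valid`` iff a finite positive-concentration intersection exists with
    both biomasses strictly positive.

    Raises
    ------
    DegenerateSystemError
        If the two genera have identical traits (rank-1 system).
    """
    if _same_traits(cfg.pro, cfg.syn):
        raise DegenerateSystemError(
            "identical genera: the steady-state system is rank deficient")
    candidates = []
    for c3, c4 in _interior_roots(cfg):
        A = _uptake_matrix(cfg, c3, c4)
        det = np.linalg.det(A)
        if abs(det) < 1e-14 * max(np.abs(A).max() ** 2, 1e-30):
            raise DegenerateSystemError(
                "singular nutrient-balance system at ZNGI intersection")
        n = np.linalg.solve(A, np.array([cfg.s_no3, cfg.s_nh4]))
        candidates.append((c3, c4, n))
    for c3, c4, n in candidates:
        if n[0] > 0 and n[1] > 0:
            return EquilibriumSolution(
                no3_star=c3, nh4_star=c4, n_pro=float(n[0]), n_syn=float(n[1]),
                zone=_coexistence_zone(cfg, c3, c4), valid=True)
    if candidates:  # intersection exists but supply lies outside the cone
        c3, c4, n = candidates[0]
        return EquilibriumSolution(
            no3_star=c3, nh4_star=c4, n_pro=float(n[0]), n_syn=float(n[1]),
            zone="none", valid=False)
    return EquilibriumSolution(no3_star=np.nan, nh4_star=np.nan,
                               n_pro=0.0, n_syn=0.0, zone="none", valid=False)


def _coexistence_zone(cfg: CommunityConfig, c3: float, c4: float) -> str:
    """Domain iv vs i from equilibrium uptake fractions: iv when Pro draws
    the majority of its N from NH4+ and Syn from NO3-, i for the mirrored
    specialization."""
    A = _uptake_matrix(cfg, c3, c4)
    pro_nh4_frac = A[1, 0] / (A[0, 0] + A[1, 0])
    syn_no3_frac = A[0, 1] / (A[0, 1] + A[1, 1])
    if pro_nh4_frac >= 0.5 and syn_no3_frac >= 0.5:
        return "coexist_iv"
    if pro_nh4_frac < 0.5 and syn_no3_frac < 0.5:
        return "coexist_i"
    # mixed pattern: assign by the dominant joint specialization
    return "coexist_iv" if pro_nh4_frac + syn_no3_frac >= 1.0 else "coexist_i"


def solve_single(cfg: CommunityConfig, which: str) -> EquilibriumSolution:
    """Equilibrium with a single resident genus.

    At a resident steady state the two specific uptake rates must sum to
    the mortality (zero net growth) and split it in proportion to the
    supply fluxes (nutrient balances), giving closed forms

        u_j = m S_j / (S_NO3 + S_NH4),  [j]* = u_j K_j / (Vmax_j - u_j),
        n   = (S_NO3 + S_NH4) / m .

    If the required u_j exceeds Vmax_j the resident cannot consume
    nutrient j fast enough; that nutrient then has no sink and its
    concentration is reported as ``inf`` (its balance is dropped).  The
    absent genus' invasion growth rate is evaluated at the resulting
    concentrations, with ``inf`` treated as saturating.
    """
    res = cfg.genus(which)
    other = cfg.genus("syn" if which == "pro" else "pro")
    s_tot = cfg.s_no3 + cfg.s_nh4
    infeasible = EquilibriumSolution(
        no3_star=np.nan, nh4_star=np.nan, n_pro=0.0, n_syn=0.0,
        zone="none", valid=False)
    if s_tot <= 0 or res.mortality <= 0:
        return infeasible

    u3 = res.mortality * cfg.s_no3 / s_tot
    u4 = res.mortality * cfg.s_nh4 / s_tot
    c3 = c4 = None
    n = s_tot / res.mortality
    if u3 < res.vmax_no3 and u4 < res.vmax_nh4:
        c3 = _invert_mm(u3, res.vmax_no3, res.k_no3)
        c4 = _invert_mm(u4, res.vmax_nh4, res.k_nh4)
    elif u3 >= res.vmax_no3 and u4 < res.vmax_nh4:
        # NO3- accumulates without bound; resident saturates on it.
        u4_eff = res.mortality - res.vmax_no3
        if u4_eff <= 0 or u4_eff >= res.vmax_nh4 or u4_eff > 0 and cfg.s_nh4 <= 0:
            return infeasible
        c3, c4 = np.inf, _invert_mm(u4_eff, res.vmax_nh4, res.k_nh4)
        n = cfg.s_nh4 / u4_eff
    elif u4 >= res.vmax_nh4 and u3 < res.vmax_no3:
        u3_eff = res.mortality - res.vmax_nh4
        if u3_eff <= 0 or u3_eff >= res.vmax_no3 or u3_eff > 0 and cfg.s_no3 <= 0:
            return infeasible
        c4, c3 = np.inf, _invert_mm(u3_eff, res.vmax_no3, res.k_no3)
        n = cfg.s_no3 / u3_eff
    else:
        return infeasible
    if n <= 0:
        return infeasible

    inv = growth_rate(other, c3, c4)
    zone = f"{which}_only"
    n_pro, n_syn = (n, 0.0) if which == "pro" else (0.0, n)
    # valid = feasible resident state AND uninvadable by the absent genus
    return EquilibriumSolution(
        no3_star=float(c3), nh4_star=float(c4), n_pro=n_pro, n_syn=n_syn,
        zone=zone if inv < 0 else "none", valid=inv < 0,
        invasion_rate=float(inv))


def _interior_stable(cfg: CommunityConfig, eq: EquilibriumSolution) -> bool:
    """Local asymptotic stability of the interior equilibrium (numerical
    Jacobian of the 4-D system; eigenvalue real parts <= small tolerance)."""
    y0 = eq.to_state(cfg).to_array()
    n = len(y0)
    jac = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(y0[j]), 1e-6)
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] = max(ym[j] - h, 0.0)
        jac[:, j] = (_rhs_array(yp, cfg) - _rhs_array(ym, cfg)) / (yp[j] - ym[j])
    eigs = np.linalg.eigvals(jac)
    scale = max(np.abs(eigs).max(), 1e-12)
    return bool(np.max(eigs.real) < 1e-7 * scale)


def classify_zone(cfg: CommunityConfig) -> EquilibriumSolution:
    """Classify the community outcome into the four-domain scheme.

    Tries the interior (coexistence) equilibrium first; it must be
    locally stable to count.  Otherwise falls back to uninvadable
    single-resident states.  If more than one uninvadable state exists
    simultaneously the result carries ``bistable=True`` (reported, not
    resolved).
    """
    coexist = solve_coexistence(cfg)
    if coexist.valid:
        stable = _interior_stable(cfg, coexist)
        coexist = EquilibriumSolution(
            **{**coexist.__dict__, "stable": stable})
        if stable:
            return coexist

    singles = [solve_single(cfg, "pro"), solve_single(cfg, "syn")]
    winners = [s for s in singles if s.valid]
    if coexist.valid and not coexist.stable and len(winners) >= 1:
        # unstable interior: outcome is founder controlled if both
        # boundary states resist invasion
        if len(winners) == 2:
            return EquilibriumSolution(
                **{**winners[0].__dict__, "bistable": True})
        return winners[0]
    if len(winners) == 2:
        return EquilibriumSolution(**{**winners[0].__dict__, "bistable": True})
    if len(winners) == 1:
        return winners[0]
    if coexist.valid:  # interior stable already returned; unstable, no winner
        return EquilibriumSolution(**{**coexist.__dict__, "zone": "none",
                                      "valid": False})
    return EquilibriumSolution(no3_star=np.nan, nh4_star=np.nan, n_pro=0.0,
                               n_syn=0.0, zone="none", valid=False)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneMap:
    """Zone classification over a grid of half-saturation ratios.

    Axes are KNO3Pro/KNO3Syn and KNH4Pro/KNH4Syn; ``zones`` and
    ``biomass_ratio`` are indexed [i_no3, i_nh4].  ``biomass_ratio`` is
    NaN outside coexistence.
    """

    ratio_no3_axis: np.ndarray
    ratio_nh4_axis: np.ndarray
    zones: np.ndarray
    biomass_ratio: np.ndarray

    def __post_init__(self) -> None:
        for ax in (self.ratio_no3_axis, self.ratio_nh4_axis):
            if np.any(np.diff(ax) <= 0) or np.any(ax <= 0):
                raise ParameterError("ratio axes must be positive and strictly increasing")
        shape = (len(self.ratio_no3_axis), len(self.ratio_nh4_axis))
        if self.zones.shape != shape or self.biomass_ratio.shape != shape:
            raise ParameterError("matrix shapes must match axes")

    def to_dataframe(self) -> pd.DataFrame:
        r3, r4 = np.meshgrid(self.ratio_no3_axis, self.ratio_nh4_axis, indexing="ij")
        return pd.DataFrame({
            "ratio_no3": r3.ravel(), "ratio_nh4": r4.ravel(),
            "zone": self.zones.ravel(), "biomass_ratio": self.biomass_ratio.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def coexistence_mask(self) -> np.ndarray:
        return np.isin(self.zones, ("coexist_iv", "coexist_i"))


@dataclass(frozen=True)
class ResourceSweep:
    """Equilibrium biomass ratio N_Pro/N_Syn along the supply ratio axis."""

    s_ratio_axis: np.ndarray
    biomass_ratio: np.ndarray
    zones: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s_ratio_axis) <= 0) or np.any(self.s_ratio_axis <= 0):
            raise ParameterError("s_ratio axis must be positive and strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"s_ratio_no3_nh4": self.s_ratio_axis,
                             "biomass_ratio": self.biomass_ratio,
                             "zone": self.zones})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _with_pro_k(base: CommunityConfig, r3: float, r4: float) -> CommunityConfig:
    pro = base.pro.replace(k_no3=r3 * base.syn.k_no3, k_nh4=r4 * base.syn.k_nh4)
    return base.replace(pro=pro)


def sweep_k_ratios(base: CommunityConfig,
                   ratio_no3_grid=None, ratio_nh4_grid=None) -> ZoneMap:
    """Classify zones over a grid of Pro:Syn half-saturation ratios.

    Syn K values stay fixed at ``base``; Pro K values are set to
    ratio x Syn value at every node.  Default grid: 30x30, log-spaced
    over [1e-2, 1e2] on both axes.  Per-node failures are recorded as
    zone ``none``.
    """
    if ratio_no3_grid is None:
        ratio_no3_grid = np.logspace(-2, 2, 30)
    if ratio_nh4_grid is None:
        ratio_nh4_grid = np.logspace(-2, 2, 30)
    r3s = np.asarray(ratio_no3_grid, dtype=float)
    r4s = np.asarray(ratio_nh4_grid, dtype=float)
    zones = np.full((len(r3s), len(r4s)), "none", dtype=object)
    ratio = np.full((len(r3s), len(r4s)), np.nan)
    for i, r3 in enumerate(r3s):
        for j, r4 in enumerate(r4s):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    eq = classify_zone(_with_pro_k(base, r3, r4))
            except DegenerateSystemError:
                continue
            zones[i, j] = eq.zone
            if eq.zone.startswith("coexist"):
                ratio[i, j] = eq.biomass_ratio
    return ZoneMap(ratio_no3_axis=r3s, ratio_nh4_axis=r4s,
                   zones=zones, biomass_ratio=ratio)


def sweep_resource_ratio(cfg: CommunityConfig, s_ratio_grid=None) -> ResourceSweep:
    """Equilibrium N_Pro/N_Syn as the supply ratio SNO3/SNH4 varies.

    The ammonium supply is held at its baseline value and the nitrate
    supply set to ratio x SNH4 (scenarios phrased as increasing or
    doubling the NO3- resource).  The biomass ratio is NaN outside the
    coexistence window; within it the NO3- specialist's share rises
    monotonically with the supply ratio (so N_Pro/N_Syn is nonincreasing
    in domain iv and nondecreasing in the mirrored domain i).
    """
    if s_ratio_grid is None:
        s_ratio_grid = np.logspace(-2, 1.5, 60)
    ratios = np.asarray(s_ratio_grid, dtype=float)
    if np.any(ratios <= 0):
        raise ParameterError("supply ratios must be positive")
    biomass = np.full(len(ratios), np.nan)
    zones = np.full(len(ratios), "none", dtype=object)
    for i, r in enumerate(ratios):
        try:
            eq = classify_zone(cfg.replace(s_no3=r * cfg.s_nh4))
        except DegenerateSystemError:
            continue
        zones[i] = eq.zone
        if eq.zone.startswith("coexist"):
            biomass[i] = eq.biomass_ratio
    return ResourceSweep(s_ratio_axis=ratios, biomass_ratio=biomass, zones=zones)
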