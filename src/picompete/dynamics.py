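"""Time-domain dynamics: model state, right-hand side and integration.

State variables are (X_Pro, X_Syn, [NO3-], [NH4+]) in
(cells L^-1, cells L^-1, nmol L^-1, nmol L^-1).  The governing balances
are

    dX_i/dt  = (V_NO3^i + V_NH4^i - m_i) X_i
    d[j]/dt  = - sum_i V_j^i QN_i X_i + S_j

with Michaelis-Menten specific uptake V_j^i (see :mod:`.kinetics`).
Total nitrogen N_tot = [NO3-] + [NH4+] + QN_Pro X_Pro + QN_Syn X_Syn
obeys dN_tot/dt = S_NO3 + S_NH4 - m_Pro QN_Pro X_Pro - m_Syn QN_Syn X_Syn,
so with zero supply and zero mortality the total N budget is conserved
exactly; the integrator must preserve it to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, ParameterError, StateError
from .params import CommunityConfig

__all__ = ["ModelState", "Trajectory", "rhs", "integrate", "total_nitrogen"]

# Default solver tolerances: relative 1e-8 throughout; absolute floors of
# 1e-3 cells L^-1 for abundances and 1e-6 nmol L^-1 for concentrations.
RTOL = 1e-8
ATOL = np.array([1e-3, 1e-3, 1e-6, 1e-6])

_COLUMNS = ["time_d", "x_pro_cells_per_L", "x_syn_cells_per_L", "no3_nM", "nh4_nM"]


@dataclass(frozen=True)
class ModelState:
    """Instantaneous system state."""

    x_pro: float
    x_syn: float
    no3: float
    nh4: float

    def __post_init__(self) -> None:
        if min(self.x_pro, self.x_syn, self.no3, self.nh4) < 0:
            raise StateError(f"state components must be >= 0: {self}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x_pro, self.x_syn, self.no3, self.nh4], dtype=float)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)  # clip solver jitter
        return cls(*y)


def _rhs_array(y: np.ndarray, cfg: CommunityConfig) -> np.ndarray:
    """RHS on a raw state vector; negative components are clipped to zero
    before evaluation (amendments can drive nutrients to numerical zero and
    the Michaelis-Menten form is well behaved at 0)."""
    xp, xs, c3, c4 = np.maximum(y, 0.0)
    p, s = cfg.pro, cfg.syn
    u3p = p.vmax_no3 * c3 / (c3 + p.k_no3)
    u4p = p.vmax_nh4 * c4 / (c4 + p.k_nh4)
    u3s = s.vmax_no3 * c3 / (c3 + s.k_no3)
    u4s = s.vmax_nh4 * c4 / (c4 + s.k_nh4)
    return np.array([
        (u3p + u4p - p.mortality) * xp,
        (u3s + u4s - s.mortality) * xs,
        -u3p * p.q_n * xp - u3s * s.q_n * xs + cfg.s_no3,
        -u4p * p.q_n * xp - u4s * s.q_n * xs + cfg.s_nh4,
    ])


def rhs(state: ModelState, cfg: CommunityConfig) -> np.ndarray:
    """Time derivative (dX_Pro/dt, dX_Syn/dt, d[NO3-]/dt, d[NH4+]/dt)."""
    return _rhs_array(state.to_array(), cfg)


def total_nitrogen(state: ModelState, cfg: CommunityConfig) -> float:
    """Total nitrogen inventory, nmol L^-1."""
    return (state.no3 + state.nh4
            + cfg.pro.q_n * state.x_pro + cfg.syn.q_n * state.x_syn)


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved solution on a regular output grid.

    ``times`` is strictly increasing (days); ``values`` has shape
    (len(times), 4) with columns (x_pro, x_syn, no3, nh4).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise StateError("trajectory times must be strictly increasing")
        if self.values.shape != (len(self.times), 4):
            raise StateError("trajectory values must be (n_times, 4)")

    @property
    def states(self) -> list[ModelState]:
        return [ModelState.from_array(row) for row in self.values]

    def state_at(self, t: float) -> ModelState:
        """State at an output grid time (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise StateError(f"time {t} not on the output grid")
        return ModelState.from_array(self.values[idx[0]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.times, self.values]), columns=_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise StateError(f"trajectory table missing columns {missing}")
        return cls(times=df["time_d"].to_numpy(dtype=float),
                   values=df[_COLUMNS[1:]].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path))


def integrate(cfg: CommunityConfig, init: ModelState, t_end: float,
              dt_out: float = 0.25, rtol: float = RTOL,
              atol=None) -> Trajectory:
    """Integrate the community ODEs on [0, t_end] with output every dt_out.

    Uses a stiff-capable variable-step method (LSODA).  Raises
    :class:`IntegrationError` carrying the last valid state if the solver
    fails.
    """
    if t_end <= 0:
        raise ParameterError(f"t_end must be > 0, got {t_end}")
    if dt_out <= 0:
        raise ParameterError(f"dt_out must be > 0, got {dt_out}")
    if atol is None:
        atol = ATOL
    n_out = int(round(t_end / dt_out))
    t_eval = np.linspace(0.0, n_out * dt_out, n_out + 1)
    if t_eval[-1] < t_end - 1e-12:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(lambda t, y: _rhs_array(y, cfg), (0.0, t_end),
                    init.to_array(), method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        last = (ModelState.from_array(sol.y[:, -1])
                if sol.t.size else init)
        raise IntegrationError(f"integration failed: {sol.message}",
                               last_time=last_t, last_state=last)
    values = np.maximum(sol.y.T, 0.0)
    return Trajectory(times=sol.t, values=values)
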