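"""Deterministic and stochastic simulation of SSNM models.

The deterministic path integrates the mass-action ODEs with a stiff-capable
variable-step method (LSODA) and derives the *fusion level*: the fraction of
the readout moiety (the v-SNARE) that has ended up in fused species.  Because
every binding step is reversible while fusion is irreversible, the true
t → ∞ fusion level is 1 for any positive basal fusion rate; the biologically
meaningful dose-dependent quantity is the fusion level at the *plateau* on
the assay time scale, detected as the first time the fusion rate drops below
a small threshold (or the integration horizon ``t_max``).

The stochastic path is an exact Gillespie direct-method sampler used as an
independent oracle for the ODE compilation: at large system size Ω the mean
of many runs must reproduce the deterministic trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    NetworkModel,
    RateSet,
    _rate_vectors,
    build_mass_action_rhs,
    stoichiometric_matrices,
)

__all__ = [
    "Trajectory",
    "DoseResponse",
    "ReadoutSettings",
    "simulate_ode",
    "simulate_stochastic",
    "fusion_level",
    "fusion_rate",
    "plateau_readout",
    "PlateauResult",
    "dose_response",
]


@dataclass
class ReadoutSettings:
    """Numerical configuration for plateau detection and integration.

    ``t_max`` bounds the integration horizon (s); ``epsilon`` is the fusion
    rate (s⁻¹, on the normalized 0-1 fusion scale) below which the curve is
    declared to have plateaued; ``n_points`` sets the dense reporting grid.
    """

    t_max: float = 5000.0
    epsilon: float = 1e-6
    rtol: float = 1e-6
    atol: float = 1e-9
    n_points: int = 500


@dataclass
class Trajectory:
    """Time-stamped concentration matrix (time × species, μM)."""

    times: np.ndarray
    concentrations: np.ndarray
    model: NetworkModel
    rates: RateSet

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.model.species_names())
        df.insert(0, "time_s", self.times)
        return df

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D sequence")


@dataclass
class DoseResponse:
    """Plateau fusion level as a function of the scanned initial concentration."""

    species: str
    doses: np.ndarray
    fusion: np.ndarray
    readout_times: np.ndarray
    plateau_met: np.ndarray
    model_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_uM": self.doses,
                "fusion_level": self.fusion,
                "readout_time_s": self.readout_times,
                "plateau_met": self.plateau_met.astype(int),
            }
        )


def simulate_ode(
    model: NetworkModel,
    rates: RateSet,
    t_end: float,
    y0: Optional[Dict[str, float]] = None,
    settings: Optional[ReadoutSettings] = None,
) -> Trajectory:
    """Integrate the mass-action ODEs to ``t_end`` on a dense reporting grid.

    ``y0`` overrides individual initial concentrations (μM) by species name;
    unspecified species keep the model defaults.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    settings = settings or ReadoutSettings()
    rhs = build_mass_action_rhs(model, rates)
    y_init = model.initial_vector()
    if y0:
        idx = model.species_index()
        for name, val in y0.items():
            y_init[idx[name]] = float(val)
    t_eval = np.linspace(0.0, t_end, settings.n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y_init,
        method="LSODA",
        t_eval=t_eval[1:],
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t={sol.t[-1] if sol.t.size else 0.0:.4g}s "
            f"(state {sol.y[:, -1] if sol.y.size else y_init}): {sol.message}"
        )
    times = np.concatenate([[0.0], sol.t])
    conc = np.vstack([y_init, sol.y.T])
    return Trajectory(times=times, concentrations=conc, model=model, rates=rates)


def _readout_weights(model: NetworkModel) -> tuple[np.ndarray, np.ndarray]:
    """(total-moiety weights, fused-only weights) for the readout protein."""
    w_all = np.array([s.moiety_count(model.readout_moiety) for s in model.species], float)
    w_fused = np.array(
        [s.moiety_count(model.readout_moiety) if s.role == "fused" else 0 for s in model.species],
        float,
    )
    return w_all, w_fused


def fusion_level(trajectory: Trajectory, model: Optional[NetworkModel] = None) -> np.ndarray:
    """Fraction of the readout moiety residing in fused species, per time point."""
    model = model or trajectory.model
    w_all, w_fused = _readout_weights(model)
    total = trajectory.concentrations @ w_all
    if np.any(total <= 0):
        raise ValueError("total readout moiety is zero; fusion level undefined")
    return (trajectory.concentrations @ w_fused) / total


def fusion_rate(model: NetworkModel, rates: RateSet, y: np.ndarray) -> float:
    """d(fusion level)/dt at state ``y``, from the exact mass-action fluxes."""
    w_all, w_fused = _readout_weights(model)
    y = np.asarray(y, dtype=float)
    total = float(y @ w_all)
    if total <= 0:
        raise ValueError("total readout moiety is zero; fusion rate undefined")
    rhs = build_mass_action_rhs(model, rates)
    return float(rhs(0.0, y) @ w_fused) / total


@dataclass
class PlateauResult:
    fusion: float
    time: float
    met: bool


def plateau_readout(
    model: NetworkModel,
    rates: RateSet,
    y0: Optional[Dict[str, float]] = None,
    settings: Optional[ReadoutSettings] = None,
) -> PlateauResult:
    """Fusion level once d(fusion)/dt < epsilon, or at ``t_max``.

    The rate is evaluated exactly from the mass-action fluxes on the
    reporting grid.  Because the fusion rate is zero at t = 0 (no SNAREpin
    exists yet) the criterion additionally requires the rate to be
    non-increasing, so the initial rise is never mistaken for a plateau.
    """
    settings = settings or ReadoutSettings()
    traj = simulate_ode(model, rates, settings.t_max, y0=y0, settings=settings)
    lvl = fusion_level(traj)
    w_all, w_fused = _readout_weights(model)
    total = traj.concentrations[0] @ w_all
    rhs = build_mass_action_rhs(model, rates)
    rate = np.array([rhs(0.0, y) @ w_fused for y in traj.concentrations]) / total
    for i in range(1, len(rate)):
        if rate[i] < settings.epsilon and rate[i] <= rate[i - 1]:
            return PlateauResult(fusion=float(lvl[i]), time=float(traj.times[i]), met=True)
    return PlateauResult(fusion=float(lvl[-1]), time=float(traj.times[-1]), met=False)


def dose_response(
    model: NetworkModel,
    rates: RateSet,
    scan_species: str,
    values: Sequence[float],
    settings: Optional[ReadoutSettings] = None,
) -> DoseResponse:
    """Plateau fusion level for each initial concentration of ``scan_species``.

    Runs are independent (all other initials at model defaults), so results
    are order-invariant.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 scan values")
    if np.any(np.diff(values) <= 0):
        raise ValueError("scan values must be strictly increasing")
    if scan_species not in model.species_index():
        raise KeyError(f"unknown species {scan_species!r}")
    fusion = np.empty_like(values)
    times = np.empty_like(values)
    met = np.zeros(values.shape, dtype=bool)
    for i, v in enumerate(values):
        res = plateau_readout(model, rates, y0={scan_species: float(v)}, settings=settings)
        fusion[i], times[i], met[i] = res.fusion, res.time, res.met
    return DoseResponse(
        species=scan_species,
        doses=values,
        fusion=fusion,
        readout_times=times,
        plateau_met=met,
        model_name=model.name,
    )


# --- stochastic oracle ------------------------------------------------------

_GILLESPIE_CACHE: dict = {}


def _gillespie_kernel():
    """Compile (once) the jitted direct-method inner loop."""
    if "kernel" in _GILLESPIE_CACHE:
        return _GILLESPIE_CACHE["kernel"]
    import numba

    @numba.njit(cache=False)
    def kernel(Rm, Net, c, x0, t_grid, seed):  # pragma: no cover - jitted
        np.random.seed(seed)
        n_rx, n_sp = Rm.shape
        x = x0.copy()
        n_t = t_grid.shape[0]
        out = np.zeros((n_t, n_sp), dtype=np.int64)
        t = 0.0
        gi = 0
        a = np.zeros(n_rx)
        while gi < n_t:
            a0 = 0.0
            for j in range(n_rx):
                aj = c[j]
                for s in range(n_sp):
                    for m in range(Rm[j, s]):
                        aj *= x[s] - m
                if aj < 0.0:
                    aj = 0.0
                a[j] = aj
                a0 += aj
            if a0 <= 0.0:
                while gi < n_t:
                    for s in range(n_sp):
                        out[gi, s] = x[s]
                    gi += 1
                break
            tau = -np.log(np.random.random()) / a0
            t_new = t + tau
            while gi < n_t and t_grid[gi] < t_new:
                for s in range(n_sp):
                    out[gi, s] = x[s]
                gi += 1
            t = t_new
            r = np.random.random() * a0
            cum = 0.0
            pick = n_rx - 1
            for j in range(n_rx):
                cum += a[j]
                if r <= cum:
                    pick = j
                    break
            for s in range(n_sp):
                x[s] += Net[pick, s]
        return out

    _GILLESPIE_CACHE["kernel"] = kernel
    return kernel


def _factorial(n: int) -> int:
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


def simulate_stochastic(
    model: NetworkModel,
    rates: RateSet,
    t_end: float,
    omega: float,
    seed: int,
    y0: Optional[Dict[str, float]] = None,
    n_points: int = 100,
) -> Trajectory:
    """Exact Gillespie direct-method simulation at system size Ω.

    Ω converts concentrations to copy numbers (molecules per μM); stochastic
    rate constants are ``k·Ω^(1−order)/∏ s_i!`` so propensities match the
    deterministic mass-action fluxes in the large-Ω limit.  Reversible
    reactions are unrolled into two irreversible channels.  Reported
    concentrations are copy numbers divided by Ω.
    """
    if omega < 1:
        raise ValueError("omega must be ≥ 1 molecule per μM")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    R, P, _ = stoichiometric_matrices(model)
    kf, kr = _rate_vectors(model, rates)
    Rm_rows, net_rows, cs = [], [], []
    for j in range(len(model.reactions)):
        if kf[j] > 0:
            order = int(R[j].sum())
            fact = 1.0
            for s in R[j]:
                fact *= _factorial(int(s))
            Rm_rows.append(R[j])
            net_rows.append(P[j] - R[j])
            cs.append(kf[j] * omega ** (1 - order) / fact)
        if kr[j] > 0:
            order = int(P[j].sum())
            fact = 1.0
            for s in P[j]:
                fact *= _factorial(int(s))
            Rm_rows.append(P[j])
            net_rows.append(R[j] - P[j])
            cs.append(kr[j] * omega ** (1 - order) / fact)
    Rm = np.asarray(Rm_rows, dtype=np.int64)
    Net = np.asarray(net_rows, dtype=np.int64)
    c = np.asarray(cs, dtype=np.float64)
    y_init = model.initial_vector()
    if y0:
        idx = model.species_index()
        for name, val in y0.items():
            y_init[idx[name]] = float(val)
    x0 = np.rint(y_init * omega).astype(np.int64)
    t_grid = np.linspace(0.0, t_end, n_points + 1)[1:]
    kernel = _gillespie_kernel()
    counts = kernel(Rm, Net, c, x0, t_grid, int(seed) & 0x7FFFFFFF)
    times = np.concatenate([[0.0], t_grid])
    conc = np.vstack([x0, counts]).astype(float) / omega
    return Trajectory(times=times, concentrations=conc, model=model, rates=rates)
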