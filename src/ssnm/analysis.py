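"""Dose-response classification, optimum location, robustness and scenarios.

"Bifurcation" in the SSNM literature means a *biphasic* steady-state fusion
dose-response with an interior maximum — SM stimulates fusion below the
optimum and inhibits it above — as opposed to the hyperbolic (monotone
saturating) yeast response.  This module names the landmark the *optimum SM
dose*; ``bifurcation_point`` is kept as an alias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import NetworkModel, RateSet
from .simulate import DoseResponse, PlateauResult, ReadoutSettings, dose_response, plateau_readout

__all__ = [
    "ResponseClassification",
    "RobustnessReport",
    "OverexpressionResult",
    "classify_response",
    "find_optimum_sm",
    "bifurcation_point",
    "lhs_sample",
    "robustness_analysis",
    "overexpression_outcome",
    "compare_motifs",
]

SHAPES = ("monotonic_increasing", "monotonic_decreasing", "biphasic", "flat")

#: default tolerance on fusion-level differences (dimensionless)
DEFAULT_SHAPE_TOL = 1e-3


@dataclass(frozen=True)
class ResponseClassification:
    shape: str
    argmax_dose: float
    max_fusion: float
    tolerance: float


def classify_response(dr: DoseResponse, tolerance: float = DEFAULT_SHAPE_TOL) -> ResponseClassification:
    """Label a dose-response as monotone, biphasic, or flat.

    monotonic_increasing: no successive drop beyond ``tolerance`` and a net
    rise above it; monotonic_decreasing symmetric; biphasic: rises by more
    than ``tolerance`` before its maximum and falls by more than it after;
    flat: total variation below ``tolerance``.  Ties at the maximum break to
    the smallest dose.
    """
    f = np.asarray(dr.fusion, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 scan points to classify a response shape")
    d = np.diff(f)
    i_max = int(np.argmax(f))  # argmax returns the first (smallest-dose) maximum
    rise = f[i_max] - f[0]
    fall = f[i_max] - f[-1]
    if np.all(d >= -tolerance) and f[-1] - f[0] > tolerance:
        shape = "monotonic_increasing"
    elif np.all(d <= tolerance) and f[0] - f[-1] > tolerance:
        shape = "monotonic_decreasing"
    elif rise > tolerance and fall > tolerance:
        shape = "biphasic"
    else:
        shape = "flat"
    return ResponseClassification(
        shape=shape,
        argmax_dose=float(dr.doses[i_max]),
        max_fusion=float(f[i_max]),
        tolerance=tolerance,
    )


def _plateau_fusion(model, rates, sm_name, dose, settings) -> float:
    return plateau_readout(model, rates, y0={sm_name: float(dose)}, settings=settings).fusion


def find_optimum_sm(
    model: NetworkModel,
    rates: RateSet,
    lo: float,
    hi: float,
    resolution: float = 0.05,
    scan_species: Optional[str] = None,
    settings: Optional[ReadoutSettings] = None,
) -> float:
    """SM dose maximizing plateau fusion, to within ± ``resolution``.

    Dense grid scan at ``resolution`` followed by golden-section refinement
    of the bracketing interval; a maximum on the scan boundary is returned
    as-is (the response is monotone there).
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if scan_species is None:
        from .motifs import sm_species

        scan_species = sm_species(model)
    grid = np.arange(lo, hi + resolution / 2, resolution)
    vals = np.array([_plateau_fusion(model, rates, scan_species, d, settings) for d in grid])
    i = int(np.argmax(vals))
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    a, b = grid[i - 1], grid[i + 1]
    invphi = (np.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc = _plateau_fusion(model, rates, scan_species, c, settings)
    fd = _plateau_fusion(model, rates, scan_species, d, settings)
    while b - a > resolution / 4:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _plateau_fusion(model, rates, scan_species, c, settings)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _plateau_fusion(model, rates, scan_species, d, settings)
    return float((a + b) / 2)


#: the field's name for the interior optimum of a biphasic response
bifurcation_point = find_optimum_sm


def lhs_sample(nominal: RateSet, n: int, variance_fraction: float, seed: int) -> List[RateSet]:
    """Latin hypercube sample of rate sets around ``nominal``.

    Each rate constant (every kf and kr) is an independent dimension sampled
    uniformly on ``[(1−v)·k, (1+v)·k]`` with exactly one draw per equal-width
    stratum; reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if not 0 <= variance_fraction < 1:
        raise ValueError("variance_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = sorted(nominal)
    dims = [(lab, side) for lab in labels for side in (0, 1)]
    # one column of stratified uniforms per dimension
    u = (rng.permuted(np.tile(np.arange(n), (len(dims), 1)), axis=1).T + rng.random((n, len(dims)))) / n
    out: List[RateSet] = []
    for i in range(n):
        rs: Dict[str, list] = {lab: [0.0, 0.0] for lab in labels}
        for j, (lab, side) in enumerate(dims):
            k = nominal[lab][side]
            lo, hi = (1 - variance_fraction) * k, (1 + variance_fraction) * k
            rs[lab][side] = lo + (hi - lo) * u[i, j]
        out.append({lab: (v[0], v[1]) for lab, v in rs.items()})
    return out


@dataclass
class RobustnessReport:
    """Shape preservation of the dose-response under LHS-perturbed rates."""

    n: int
    variance_fraction: float
    seed: int
    nominal_shape: str
    shapes: List[Optional[str]]  # None where the integrator failed
    preservation_fraction: float
    failures: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": np.arange(self.n),
                "shape": [s if s is not None else "FAILED" for s in self.shapes],
                "preserved": [int(s == self.nominal_shape) for s in self.shapes],
            }
        )


def robustness_analysis(
    model: NetworkModel,
    nominal: RateSet,
    n: int,
    variance_fraction: float,
    seed: int,
    scan_values: Optional[Sequence[float]] = None,
    scan_species: Optional[str] = None,
    settings: Optional[ReadoutSettings] = None,
    tolerance: float = DEFAULT_SHAPE_TOL,
) -> RobustnessReport:
    """Classify the dose-response under each of ``n`` LHS rate samples.

    The preservation fraction is the share of samples whose shape label
    matches the nominal one; integrator failures are recorded per sample and
    count as not preserved.
    """
    if scan_species is None:
        from .motifs import sm_species

        scan_species = sm_species(model)
    if scan_values is None:
        scan_values = np.round(np.arange(0.0, 6.0001, 0.5), 6)
    nominal_dr = dose_response(model, nominal, scan_species, scan_values, settings=settings)
    nominal_shape = classify_response(nominal_dr, tolerance).shape
    shapes: List[Optional[str]] = []
    failures = 0
    for rs in lhs_sample(nominal, n, variance_fraction, seed):
        try:
            dr = dose_response(model, rs, scan_species, scan_values, settings=settings)
            shapes.append(classify_response(dr, tolerance).shape)
        except Exception:
            shapes.append(None)
            failures += 1
    preserved = sum(1 for s in shapes if s == nominal_shape)
    return RobustnessReport(
        n=n,
        variance_fraction=variance_fraction,
        seed=seed,
        nominal_shape=nominal_shape,
        shapes=shapes,
        preservation_fraction=preserved / n,
        failures=failures,
    )


@dataclass(frozen=True)
class OverexpressionResult:
    outcome: str  # increased | decreased | unchanged
    baseline_sm: float
    overexpressed_sm: float
    baseline_fusion: float
    overexpressed_fusion: float


def overexpression_outcome(
    model: NetworkModel,
    rates: RateSet,
    baseline_sm: float,
    fold_increase: float,
    scan_species: Optional[str] = None,
    settings: Optional[ReadoutSettings] = None,
    tolerance: float = DEFAULT_SHAPE_TOL,
) -> OverexpressionResult:
    """Effect of raising the SM dose ``fold_increase``-fold on plateau fusion.

    This is the model's account of the conflicting SM-overexpression
    literature: on a biphasic response the same fold increase can raise or
    lower fusion depending on where the final dose lands relative to the
    optimum.
    """
    if baseline_sm < 0:
        raise ValueError("baseline_sm must be ≥ 0")
    if fold_increase < 1:
        raise ValueError("fold_increase must be ≥ 1")
    if scan_species is None:
        from .motifs import sm_species

        scan_species = sm_species(model)
    f0 = _plateau_fusion(model, rates, scan_species, baseline_sm, settings)
    f1 = _plateau_fusion(model, rates, scan_species, baseline_sm * fold_increase, settings)
    if f1 - f0 > tolerance:
        outcome = "increased"
    elif f0 - f1 > tolerance:
        outcome = "decreased"
    else:
        outcome = "unchanged"
    return OverexpressionResult(
        outcome=outcome,
        baseline_sm=baseline_sm,
        overexpressed_sm=baseline_sm * fold_increase,
        baseline_fusion=f0,
        overexpressed_fusion=f1,
    )


def compare_motifs(
    motifs: Sequence[Tuple[NetworkModel, RateSet]],
    scan_values: Optional[Sequence[float]] = None,
    settings: Optional[ReadoutSettings] = None,
    tolerance: float = DEFAULT_SHAPE_TOL,
) -> Tuple[pd.DataFrame, Dict[str, ResponseClassification]]:
    """Aligned dose-response tables and shape labels on a common scan grid."""
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs to compare")
    if scan_values is None:
        scan_values = np.round(np.arange(0.0, 6.0001, 0.25), 6)
    from .motifs import sm_species

    table = pd.DataFrame({"dose_uM": np.asarray(list(scan_values), dtype=float)})
    labels: Dict[str, ResponseClassification] = {}
    for model, rates in motifs:
        dr = dose_response(model, rates, sm_species(model), scan_values, settings=settings)
        table[model.name] = dr.fusion
        labels[model.name] = classify_response(dr, tolerance)
    return table, labels
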