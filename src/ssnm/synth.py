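"""Synthetic lipid-mixing assay traces and the fluorescence→rounds transform.

In the physical assay, v-SNARE liposomes carry a self-quenched fluorophore
pair; fusion with unlabeled t-SNARE liposomes dilutes the dyes and the
dequenched signal (ex/em 465/530 nm) tracks lipid mixing.  The generator
here drives a normalized trace with the simulated fusion level and adds
Gaussian noise, so every downstream analysis stage can be exercised without
real fluorimeter data.  The emulation is deliberately minimal: no
photobleaching, inner-filter effects, or calibration drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .network import NetworkModel, RateSet
from .simulate import ReadoutSettings, dose_response, fusion_level, simulate_ode

__all__ = [
    "AssayTrace",
    "generate_assay_trace",
    "fluorescence_to_rounds",
    "RecoveryFixture",
    "make_recovery_fixture",
]

_F_CEIL = 1.0 - 1e-6  # keep the rounds transform finite


@dataclass
class AssayTrace:
    """A normalized, noisy dequenching trace with full generation provenance."""

    times: np.ndarray
    fluorescence: np.ndarray
    noise_sd: float
    seed: int
    model_name: str
    sm_dose: float


def generate_assay_trace(
    model: NetworkModel,
    rates: RateSet,
    sm_dose: float,
    duration: float = 2000.0,
    sample_interval: float = 10.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    scan_species: Optional[str] = None,
    settings: Optional[ReadoutSettings] = None,
) -> AssayTrace:
    """Simulate fusion at ``sm_dose`` and emit a noisy normalized trace.

    f(t) = clamp(fusion_level(t) + N(0, noise_sd²), [0, 1−1e−6]);
    deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    if scan_species is None:
        from .motifs import sm_species

        scan_species = sm_species(model)
    settings = settings or ReadoutSettings()
    n = int(round(duration / sample_interval))
    times = np.linspace(0.0, duration, n + 1)
    traj = simulate_ode(
        model,
        rates,
        duration,
        y0={scan_species: float(sm_dose)},
        settings=ReadoutSettings(
            t_max=duration,
            epsilon=settings.epsilon,
            rtol=settings.rtol,
            atol=settings.atol,
            n_points=max(settings.n_points, n + 1),
        ),
    )
    clean = np.interp(times, traj.times, fusion_level(traj))
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
    return AssayTrace(
        times=times,
        fluorescence=np.clip(noisy, 0.0, _F_CEIL),
        noise_sd=noise_sd,
        seed=seed,
        model_name=model.name,
        sm_dose=float(sm_dose),
    )


def fluorescence_to_rounds(f: Union[float, np.ndarray, AssayTrace]) -> Union[float, np.ndarray]:
    """Transform normalized fluorescence to rounds of fusion: −ln(1 − f).

    Under the Poisson picture of the assay, a liposome that has undergone r
    rounds of fusion dilutes its dyes geometrically, so the observed
    normalized signal saturates as 1 − e^(−r); inverting gives the rounds.
    Strictly increasing and convex on [0, 1); f = 0 maps to 0 rounds.
    """
    if isinstance(f, AssayTrace):
        f = f.fluorescence
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("fluorescence must satisfy 0 ≤ f < 1")
    rounds = -np.log1p(-arr)
    return float(rounds) if np.isscalar(f) or arr.ndim == 0 else rounds


@dataclass
class RecoveryFixture:
    """End-to-end regression bundle: perturbed rates + noisy dose-response."""

    model: NetworkModel
    rates: RateSet
    doses: np.ndarray
    clean_fusion: np.ndarray
    noisy_fusion: np.ndarray
    clean_shape: str
    noisy_shape: str
    seed: int


def make_recovery_fixture(
    motif: str,
    seed: int,
    noise_sd: float = 0.01,
    settings: Optional[ReadoutSettings] = None,
) -> RecoveryFixture:
    """Draw one LHS rate sample, scan the dose-response, and add noise.

    The classification of the noisy table must match the clean one — the
    classifier's tolerance absorbs readout noise at this level.
    """
    from .analysis import classify_response, lhs_sample
    from .motifs import default_rates, get_motif, sm_species

    model = get_motif(motif)
    nominal = default_rates(model.name)
    rates = lhs_sample(nominal, 1, 0.30, seed)[0]
    doses = np.round(np.arange(0.0, 6.0001, 0.5), 6)
    dr = dose_response(model, rates, sm_species(model), doses, settings=settings)
    rng = np.random.default_rng(seed + 1)
    noisy = np.clip(dr.fusion + rng.normal(0.0, noise_sd, size=dr.fusion.shape), 0.0, _F_CEIL)
    noisy_dr = type(dr)(
        species=dr.species,
        doses=dr.doses,
        fusion=noisy,
        readout_times=dr.readout_times,
        plateau_met=dr.plateau_met,
        model_name=dr.model_name,
    )
    # noise sd 0.01 sits above the default 1e-3 shape tolerance; classify with
    # a tolerance that dominates the noise, as the fixture contract requires
    tol = max(3 * noise_sd, 1e-3)
    clean_shape = classify_response(dr, tol).shape
    noisy_shape = classify_response(noisy_dr, tol).shape
    return RecoveryFixture(
        model=model,
        rates=rates,
        doses=dr.doses,
        clean_fusion=dr.fusion,
        noisy_fusion=noisy,
        clean_shape=clean_shape,
        noisy_shape=noisy_shape,
        seed=seed,
    )
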