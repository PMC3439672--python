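"""ODE/stochastic simulation, fusion readout, plateau and dose scans."""

import numpy as np
import pytest

from conftest import BINDING_EQ_C

from ssnm.motifs import default_rates, neuronal_ssnm, sm_species, yeast_ssnm
from ssnm.network import conservation_laws
from ssnm.simulate import (
    ReadoutSettings,
    dose_response,
    fusion_level,
    plateau_readout,
    simulate_ode,
    simulate_stochastic,
)


class TestSimulateOde:
    def test_sm_free_subspace_is_invariant(self):
        """With ySM(0)=0 every SM-containing species stays exactly zero."""
        m = yeast_ssnm()
        traj = simulate_ode(m, default_rates("yeast"), 1000.0)
        idx = m.species_index()
        for name in ("ySM", "yPinSM", "yFusedSM"):
            assert np.all(np.abs(traj.concentrations[:, idx[name]]) < 1e-12)

    def test_binding_equilibrium_matches_quadratic_root(self, binding_model):
        model, rates = binding_model
        traj = simulate_ode(model, rates, 100.0)
        assert traj.concentrations[-1, 2] == pytest.approx(BINDING_EQ_C, rel=1e-4)

    def test_conservation_and_nonnegativity(self, catalog_motif):
        model, rates = catalog_motif
        sm = sm_species(model)
        traj = simulate_ode(model, rates, 2000.0, y0={sm: 3.0})
        assert np.all(traj.concentrations >= -1e-9)
        idx = model.species_index()
        for law in conservation_laws(model):
            c = np.zeros(len(model.species))
            for n, v in law.coefficients.items():
                c[idx[n]] = v
            tot = traj.concentrations @ c
            ref = tot[0]
            if ref > 0:
                assert np.all(np.abs(tot - ref) <= 1e-6 * ref)

    def test_rejects_nonpositive_horizon(self, binding_model):
        model, rates = binding_model
        with pytest.raises(ValueError):
            simulate_ode(model, rates, 0.0)


class TestFusionLevel:
    def test_zero_at_start_and_bounded(self, catalog_motif):
        model, rates = catalog_motif
        traj = simulate_ode(model, rates, 1000.0, y0={sm_species(model): 2.0})
        lvl = fusion_level(traj)
        assert lvl[0] == 0.0
        assert np.all((lvl >= 0) & (lvl <= 1 + 1e-6))

    def test_monotone_nondecreasing(self, catalog_motif):
        """Fusion is irreversible, so the fused fraction can only grow."""
        model, rates = catalog_motif
        traj = simulate_ode(model, rates, 2000.0, y0={sm_species(model): 4.0})
        assert np.all(np.diff(fusion_level(traj)) >= -1e-9)

    def test_total_conversion_normalizes_to_one(self):
        """Mass placed entirely in a fused species reads out as fusion = 1."""
        m = yeast_ssnm()
        y0 = {s.name: 0.0 for s in m.species}
        y0["yFused"] = 4.5
        traj = simulate_ode(m, default_rates("yeast"), 10.0, y0=y0)
        assert fusion_level(traj)[-1] == pytest.approx(1.0)


class TestPlateauReadout:
    def test_no_fusion_reactions_plateaus_at_zero(self):
        m = yeast_ssnm()
        rates = default_rates("yeast")
        rates["R4"] = (0.0, 0.0)
        rates["R5"] = (0.0, 0.0)
        # zero-rate reactions are invalid as *model structure* but legal as a
        # what-if rate configuration for the readout
        res = plateau_readout(m, rates, y0={"ySM": 3.0})
        assert res.fusion == pytest.approx(0.0, abs=1e-12)
        assert res.met

    def test_sm_raises_plateau_fusion(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        with_sm = plateau_readout(m, r, y0={"ySM": 4.5}).fusion
        without = plateau_readout(m, r, y0={"ySM": 0.0}).fusion
        assert with_sm > without

    def test_self_consistent_at_doubled_horizon(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        res = plateau_readout(m, r, y0={"ySM": 4.5})
        assert res.met
        traj = simulate_ode(m, r, 2 * res.time, y0={"ySM": 4.5})
        assert abs(fusion_level(traj)[-1] - res.fusion) < 1e-3

    def test_tolerance_robustness(self):
        m = neuronal_ssnm()
        r = default_rates("neuronal")
        loose = plateau_readout(m, r, y0={"nSM": 3.0}).fusion
        tight = plateau_readout(
            m, r, y0={"nSM": 3.0}, settings=ReadoutSettings(rtol=5e-7, atol=5e-10)
        ).fusion
        assert abs(loose - tight) < 1e-4


class TestDoseResponse:
    def test_yeast_fusion_increases_with_sm(self):
        m = yeast_ssnm()
        dr = dose_response(m, default_rates("yeast"), "ySM", [0.0, 1.5, 3.0, 4.5, 6.0])
        assert np.all(np.diff(dr.fusion) > 0)

    def test_scan_is_pure_and_order_invariant(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        a = dose_response(m, r, "ySM", [0.0, 2.0, 4.0])
        b = dose_response(m, r, "ySM", [0.0, 2.0, 4.0])
        assert np.array_equal(a.fusion, b.fusion)

    def test_input_validation(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        with pytest.raises(ValueError):
            dose_response(m, r, "ySM", [0.0, 1.0])
        with pytest.raises(ValueError):
            dose_response(m, r, "ySM", [0.0, 2.0, 1.0])
        with pytest.raises(KeyError):
            dose_response(m, r, "zzz", [0.0, 1.0, 2.0])


class TestStochastic:
    def test_seed_determinism(self, binding_model):
        model, rates = binding_model
        a = simulate_stochastic(model, rates, 5.0, 1000, seed=7)
        b = simulate_stochastic(model, rates, 5.0, 1000, seed=7)
        assert np.array_equal(a.concentrations, b.concentrations)
        c = simulate_stochastic(model, rates, 5.0, 1000, seed=8)
        assert not np.array_equal(a.concentrations, c.concentrations)

    def test_zero_molecules_stay_zero(self, binding_model):
        model, rates = binding_model
        traj = simulate_stochastic(
            model, rates, 5.0, 1000, seed=1, y0={"A": 0.0, "B": 0.0, "C": 0.0}
        )
        assert np.all(traj.concentrations == 0)

    def test_mean_tracks_ode(self, binding_model):
        """Law of large numbers: Gillespie means reproduce the ODE solution."""
        model, rates = binding_model
        t_end = 10.0
        runs = np.array(
            [
                simulate_stochastic(model, rates, t_end, 2000, seed=100 + s, n_points=5).concentrations[-1, 2]
                for s in range(60)
            ]
        )
        ode = simulate_ode(model, rates, t_end).concentrations[-1, 2]
        se = runs.std(ddof=1) / np.sqrt(len(runs))
        assert abs(runs.mean() - ode) <= 3 * se + 1e-4
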