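"""Shape classification, optimum location, LHS and scenario analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssnm.analysis import (
    classify_response,
    compare_motifs,
    find_optimum_sm,
    lhs_sample,
    overexpression_outcome,
    robustness_analysis,
)
from ssnm.motifs import default_rates, neuronal_ssnm, yeast_ssnm
from ssnm.simulate import DoseResponse, ReadoutSettings


def _dr(fusion):
    fusion = np.asarray(fusion, dtype=float)
    doses = np.arange(len(fusion), dtype=float)
    return DoseResponse(
        species="SM",
        doses=doses,
        fusion=fusion,
        readout_times=np.full_like(doses, 100.0),
        plateau_met=np.ones(len(doses), bool),
    )


class TestClassifyResponse:
    def test_monotone_increasing(self):
        assert classify_response(_dr([0.1, 0.2, 0.4, 0.6, 0.7])).shape == "monotonic_increasing"

    def test_monotone_decreasing(self):
        assert classify_response(_dr([0.7, 0.6, 0.4, 0.2, 0.1])).shape == "monotonic_decreasing"

    def test_biphasic(self):
        cls = classify_response(_dr([0.1, 0.4, 0.8, 0.5, 0.2]))
        assert cls.shape == "biphasic"
        assert cls.argmax_dose == 2.0
        assert cls.max_fusion == 0.8

    def test_flat_constant(self):
        assert classify_response(_dr([0.5, 0.5, 0.5, 0.5, 0.5])).shape == "flat"

    def test_flat_below_tolerance(self):
        assert classify_response(_dr([0.5, 0.5004, 0.5002, 0.5003, 0.5001])).shape == "flat"

    def test_tie_breaks_to_smallest_dose(self):
        cls = classify_response(_dr([0.1, 0.8, 0.8, 0.8, 0.1]))
        assert cls.argmax_dose == 1.0

    def test_requires_five_points(self):
        with pytest.raises(ValueError):
            classify_response(_dr([0.1, 0.2, 0.3]))

    def test_noise_within_tolerance_does_not_flip_monotone(self):
        f = [0.1, 0.3, 0.2995, 0.5, 0.7]  # 5e-4 dip absorbed by the 1e-3 tolerance
        assert classify_response(_dr(f)).shape == "monotonic_increasing"


class TestFindOptimum:
    def test_refinement_matches_dense_grid(self):
        """Golden-section agrees with a 10× finer grid argmax on the peak."""
        m = neuronal_ssnm()
        r = default_rates("neuronal")
        coarse = ReadoutSettings(n_points=300)
        opt = find_optimum_sm(m, r, 4.1, 4.9, resolution=0.1, settings=coarse)
        from ssnm.simulate import dose_response

        fine = np.round(np.arange(4.1, 4.9001, 0.01), 6)
        dr = dose_response(m, r, "nSM", fine, settings=coarse)
        dense_argmax = fine[int(np.argmax(dr.fusion))]
        assert abs(opt - dense_argmax) <= 0.1

    def test_monotone_model_optimum_on_boundary(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        opt = find_optimum_sm(m, r, 0.0, 6.0, resolution=1.0, settings=ReadoutSettings(n_points=200))
        assert opt == 6.0

    def test_input_validation(self):
        m = yeast_ssnm()
        r = default_rates("yeast")
        with pytest.raises(ValueError):
            find_optimum_sm(m, r, 5.0, 1.0)
        with pytest.raises(ValueError):
            find_optimum_sm(m, r, 0.0, 6.0, resolution=-1)


NOMINAL = default_rates("neuronal")


class TestLhsSample:
    def test_zero_variance_returns_nominal(self):
        for rs in lhs_sample(NOMINAL, 5, 0.0, seed=3):
            assert rs == NOMINAL

    def test_bounds_at_thirty_percent(self):
        for rs in lhs_sample(NOMINAL, 40, 0.30, seed=3):
            for lab, (kf, kr) in rs.items():
                nf, nr = NOMINAL[lab]
                assert 0.7 * nf <= kf <= 1.3 * nf
                assert 0.7 * nr <= kr <= 1.3 * nr

    def test_exactly_one_sample_per_stratum(self):
        n, v = 16, 0.30
        samples = lhs_sample(NOMINAL, n, v, seed=9)
        for lab, (nf, nr) in NOMINAL.items():
            for side, k in ((0, nf), (1, nr)):
                if k == 0:
                    continue
                vals = np.array([s[lab][side] for s in samples])
                lo, hi = (1 - v) * k, (1 + v) * k
                bins = np.floor((vals - lo) / (hi - lo) * n).astype(int)
                bins = np.clip(bins, 0, n - 1)
                assert sorted(bins) == list(range(n))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n=st.integers(1, 12), v=st.floats(0.0, 0.5), seed=st.integers(0, 2**20))
    def test_seeded_reproducibility_and_bounds(self, n, v, seed):
        a = lhs_sample(NOMINAL, n, v, seed)
        b = lhs_sample(NOMINAL, n, v, seed)
        assert a == b
        for rs in a:
            for lab, (kf, kr) in rs.items():
                nf, nr = NOMINAL[lab]
                assert (1 - v) * nf - 1e-12 <= kf <= (1 + v) * nf + 1e-12
                assert (1 - v) * nr - 1e-12 <= kr <= (1 + v) * nr + 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lhs_sample(NOMINAL, 0, 0.3, 1)
        with pytest.raises(ValueError):
            lhs_sample(NOMINAL, 5, 1.0, 1)


FAST = ReadoutSettings(t_max=5000.0, n_points=250)
COARSE_GRID = np.round(np.arange(0.0, 6.0001, 1.0), 6)


class TestRobustness:
    def test_zero_variance_preserves_everything(self):
        m = neuronal_ssnm()
        rep = robustness_analysis(
            m, NOMINAL, n=3, variance_fraction=0.0, seed=1, scan_values=COARSE_GRID, settings=FAST
        )
        assert rep.preservation_fraction == 1.0
        assert rep.nominal_shape == "biphasic"

    def test_sample_bookkeeping_and_reproducibility(self):
        m = neuronal_ssnm()
        kw = dict(n=4, variance_fraction=0.30, seed=11, scan_values=COARSE_GRID, settings=FAST)
        rep1 = robustness_analysis(m, NOMINAL, **kw)
        rep2 = robustness_analysis(m, NOMINAL, **kw)
        assert rep1.n == len(rep1.shapes) == 4
        assert rep1.shapes == rep2.shapes
        assert rep1.preservation_fraction == rep2.preservation_fraction
        assert 0.0 <= rep1.preservation_fraction <= 1.0


class TestOverexpression:
    def test_fold_one_is_unchanged(self):
        m = neuronal_ssnm()
        res = overexpression_outcome(m, NOMINAL, baseline_sm=2.0, fold_increase=1.0, settings=FAST)
        assert res.outcome == "unchanged"
        assert res.baseline_fusion == res.overexpressed_fusion

    def test_input_validation(self):
        m = neuronal_ssnm()
        with pytest.raises(ValueError):
            overexpression_outcome(m, NOMINAL, baseline_sm=-1.0, fold_increase=2.0)
        with pytest.raises(ValueError):
            overexpression_outcome(m, NOMINAL, baseline_sm=1.0, fold_increase=0.5)


class TestCompareMotifs:
    def test_single_motif_rejected(self):
        with pytest.raises(ValueError):
            compare_motifs([(yeast_ssnm(), default_rates("yeast"))])

    def test_common_grid_and_labels(self):
        pairs = [
            (yeast_ssnm(), default_rates("yeast")),
            (neuronal_ssnm(), default_rates("neuronal")),
        ]
        table, labels = compare_motifs(pairs, scan_values=COARSE_GRID, settings=FAST)
        assert list(table.columns) == ["dose_uM", "yeast", "neuronal"]
        assert len(table) == len(COARSE_GRID)
        assert labels["yeast"].shape == "monotonic_increasing"
        assert labels["neuronal"].shape == "biphasic"
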