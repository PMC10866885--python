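"""Expression binning, activation-model selection and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rtkquant import (
    ActivationModelSelector,
    CellPopConfig,
    bin_population,
    fit_activation,
    fraction_phosphorylated,
    measure_population,
    normalized_phospho,
    simulate_cell_population,
    ttest_unpaired,
)
from rtkquant.exceptions import InsufficientDataError, ValidationError

from conftest import make_cells


class TestBinPopulation:
    def test_cells_in_same_bin_are_averaged(self):
        cells = make_cells([100.0, 2400.0], [10.0, 30.0])
        binned = bin_population(cells, bin_width=2500.0, min_cells=1)
        assert binned.n_bins == 1
        assert binned.table.loc[0, "expr_mean"] == 1250.0
        assert binned.table.loc[0, "phospho_mean"] == 20.0

    def test_half_open_boundary_splits_bins(self):
        cells = make_cells([100.0, 2600.0], [1.0, 1.0])
        assert bin_population(cells, 2500.0, min_cells=1).n_bins == 2

    def test_single_cell_single_bin(self):
        cells = make_cells([1000.0], [5.0])
        binned = bin_population(cells, 2500.0, min_cells=1)
        assert binned.table.loc[0, "expr_mean"] == 1000.0
        assert binned.table.loc[0, "n_cells"] == 1

    def test_sparse_bins_dropped_and_reported(self):
        cells = make_cells([100, 200, 300, 9000], [1, 1, 1, 1])
        binned = bin_population(cells, 2500.0, min_cells=3)
        assert binned.n_bins == 1
        assert len(binned.dropped) == 1

    def test_all_bins_sparse_raises(self):
        cells = make_cells([100.0, 9000.0], [1.0, 1.0])
        with pytest.raises(InsufficientDataError):
            bin_population(cells, 2500.0, min_cells=3)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e5), min_size=1, max_size=60),
        st.floats(min_value=10.0, max_value=2e4),
    )
    def test_retained_plus_dropped_partition_cells(self, exprs, width):
        cells = make_cells(exprs, [1.0] * len(exprs))
        try:
            binned = bin_population(cells, width, min_cells=2)
        except InsufficientDataError:
            return
        total = binned.table["n_cells"].sum() + (
            binned.dropped["n_cells"].sum() if len(binned.dropped) else 0
        )
        assert total == len(cells)


class TestActivationFit:
    def _binned(self, x, y):
        cells = make_cells(x, y)
        return bin_population(cells, bin_width=2500.0, min_cells=1)

    def test_noiseless_linear_selects_linear(self):
        x = np.arange(1, 9) * 2500.0 + 100
        sel = fit_activation(self._binned(x, 2.0 * x))
        assert sel.model_ == "linear"
        assert sel.slope_ == pytest.approx(2.0, abs=1e-9)
        assert sel.curvature_ == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_quadratic_selects_quadratic(self):
        x = np.arange(1, 9) * 2500.0 + 100
        sel = fit_activation(self._binned(x, 0.001 * x**2))
        assert sel.model_ == "quadratic"
        assert sel.curvature_ == pytest.approx(0.001, rel=1e-6)

    def test_negative_curvature_never_selects_quadratic(self):
        x = np.arange(1, 9) * 2500.0
        sel = fit_activation(self._binned(x, 1e4 * np.sqrt(x)))
        assert sel.curvature_ < 0
        assert sel.model_ == "linear"

    def test_too_few_bins_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_activation(self._binned([100.0, 2600.0, 5100.0], [1.0, 2.0, 3.0]))

    def test_sklearn_params_roundtrip(self):
        sel = ActivationModelSelector(alpha=0.01)
        assert sel.get_params() == {"alpha": 0.01, "weighting": "cv"}
        sel.set_params(alpha=0.1)
        assert sel.alpha == 0.1

    def test_predict_follows_selected_model(self):
        x = np.arange(1, 9) * 2500.0
        sel = ActivationModelSelector().fit(x, 3.0 * x + 7.0)
        np.testing.assert_allclose(sel.predict(x), 3.0 * x + 7.0, rtol=1e-9)


def test_model_selection_accuracy_on_synthetic_populations():
    """Ligand-dependent (linear) and ligand-independent (supra-linear)
    populations are distinguished in >= 90% of seeds at default noise."""
    hits = {"linear": 0, "quadratic_threshold": 0}
    want = {"linear": "linear", "quadratic_threshold": "quadratic"}
    for law in hits:
        for seed in range(10):
            res = simulate_cell_population(CellPopConfig(law=(law, None), seed=seed))
            cells = measure_population(
                res.expression, res.phospho, res.rois, res.background, res.background
            )
            sel = fit_activation(bin_population(cells))
            hits[law] += sel.model_ == want[law]
    assert hits["linear"] >= 9
    assert hits["quadratic_threshold"] >= 9


class TestNormalizedPhospho:
    def test_single_cell_ratio(self):
        out = normalized_phospho(make_cells([100.0], [50.0]), bin_width=10000.0)
        assert out.loc[0, "ratio_mean"] == 0.5

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_to_common_channel_scaling(self, scale):
        # scaling both channels regroups the expression bins but leaves
        # every per-bin mean ratio at the common per-cell value
        expr = np.array([500.0, 1500.0, 22000.0, 35000.0])
        phospho = 0.4 * expr
        scaled = normalized_phospho(make_cells(scale * expr, scale * phospho))
        np.testing.assert_allclose(scaled["ratio_mean"].to_numpy(), 0.4, rtol=1e-9)

    def test_nonpositive_expression_excluded_with_warning(self):
        cells = make_cells([-5.0, 100.0], [1.0, 50.0])
        with pytest.warns(UserWarning, match="excluding"):
            out = normalized_phospho(cells)
        assert len(out) == 1 and out.loc[0, "ratio_mean"] == 0.5

    def test_constant_fraction_recovered_within_two_sd(self, rng):
        f = 0.35
        expr = rng.lognormal(9.2, 0.8, size=200)
        phospho = f * expr * rng.lognormal(0.0, 0.1, size=200)
        out = normalized_phospho(make_cells(expr, phospho))
        for _, row in out.iterrows():
            sd = row["ratio_sd"] if np.isfinite(row["ratio_sd"]) else 0.1 * f
            assert abs(row["ratio_mean"] - f) <= 2.0 * max(sd, 0.05 * f)


class TestFractionPhosphorylated:
    def _fit(self, slope):
        x = np.arange(1, 9) * 2500.0
        return ActivationModelSelector().fit(x, slope * x)

    def test_equal_slopes_give_unity(self):
        fit = self._fit(0.3)
        assert fraction_phosphorylated(fit, fit) == pytest.approx(1.0)

    def test_slope_ratio(self):
        assert fraction_phosphorylated(self._fit(0.4), self._fit(0.2)) == pytest.approx(2.0)

    def test_nonpositive_wt_slope_rejected(self):
        with pytest.raises(ValidationError):
            fraction_phosphorylated(self._fit(0.4), self._fit(-0.1))

    def test_generator_fraction_ratio_recovered(self):
        def slope_for(f, seed):
            res = simulate_cell_population(
                CellPopConfig(law=("linear", {"f": f}), seed=seed)
            )
            cells = measure_population(
                res.expression, res.phospho, res.rois, res.background, res.background
            )
            return fit_activation(bin_population(cells))

        ratios = [
            fraction_phosphorylated(slope_for(0.45, s), slope_for(0.30, s))
            for s in range(4)
        ]
        assert np.mean(ratios) == pytest.approx(1.5, rel=0.15)


class TestTtest:
    def test_identical_groups(self):
        t, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        # oracle: pooled-variance formula computed by hand for {1,2,3} vs {2,3,4}
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        t, p = ttest_unpaired(a, b)
        assert t == pytest.approx(t_hand) == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(p_hand) == pytest.approx(0.2879, abs=1e-4)

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(3.0, 1.0, 30)
        _, p = ttest_unpaired(a, b)
        assert p < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            ttest_unpaired([1.0], [1.0, 2.0])
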