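"""Regression fitting, grids, model selection and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from topoqspr import (
    DEGREE,
    NEIGHBORHOOD,
    correlation_grid,
    fit_model,
    fit_stats,
    load_model,
    predict,
    save_model,
)


class TestFitModel:
    def test_exact_linear_recovery(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = fit_model(x, 2 + 3 * x, "linear")
        assert m.coef == pytest.approx((2.0, 3.0), abs=1e-10)
        assert m.stats.r == pytest.approx(1.0)

    def test_exact_quadratic_recovery(self):
        x = np.linspace(1, 5, 8)
        m = fit_model(x, 1 - 2 * x + 0.5 * x**2, "quadratic")
        assert m.coef == pytest.approx((1.0, -2.0, 0.5), abs=1e-9)

    def test_exact_logarithmic_recovery(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        m = fit_model(x, 7 + 2.5 * np.log(x), "logarithmic")
        assert m.coef == pytest.approx((7.0, 2.5), abs=1e-10)

    def test_mw_quadratic_coefficients_match_reported_model(self, index_tables, properties):
        m = fit_model(index_tables[DEGREE]["ReZ1"], properties["MW"], "quadratic")
        assert m.coef == pytest.approx((-14.051, 14.995, -0.0147), abs=5e-3)

    def test_hac_linear_is_the_identity(self, index_tables, properties):
        m = fit_model(index_tables[DEGREE]["ReZ1"], properties["HAC"], "linear")
        assert m.coef == pytest.approx((0.0, 1.0), abs=1e-9)
        assert m.stats.r2 == 1.0

    @pytest.mark.parametrize(
        "x, y, family, message",
        [
            ([1, 1, 1, 1], [1, 2, 3, 4], "linear", "constant"),
            ([0, 1, 2, 3], [1, 2, 3, 4], "logarithmic", "positive"),
            ([1, 2, 3], [1, 2, 3], "linear", "at least 4"),
            ([1, 2, 3, 4], [1, 2, 3, 4], "cubic", "family"),
        ],
    )
    def test_invalid_inputs(self, x, y, family, message):
        with pytest.raises(ValueError, match=message):
            fit_model(x, y, family)


class TestFitStats:
    def test_mw_quadratic_statistics(self, index_tables, properties):
        x = index_tables[DEGREE]["ReZ1"].to_numpy()
        y = properties["MW"].to_numpy()
        s = fit_model(x, y, "quadratic").stats
        assert s.r2 == pytest.approx(0.963, abs=2e-3)
        assert s.adj_r2 == pytest.approx(0.9589, abs=2e-3)
        assert s.f == pytest.approx(234.0981, abs=1.0)
        assert s.se == pytest.approx(15.6895, abs=0.05)

    def test_exact_fit_flags_f_undefined_and_zero_se(self, index_tables, properties):
        s = fit_model(index_tables[DEGREE]["ReZ1"], properties["HAC"], "linear").stats
        assert s.r2 == 1.0
        assert s.f is None
        assert s.se == 0.0

    def test_orthogonal_toy_data_gives_zero_r2(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # even function, no linear part
        s = fit_model(x, y, "linear").stats
        assert s.r2 == pytest.approx(0.0, abs=1e-12)

    def test_fit_stats_recomputes_on_given_data(self, index_tables, properties):
        x = index_tables[DEGREE]["ABC"].to_numpy()
        y = properties["BP"].to_numpy()
        m = fit_model(x, y, "quadratic")
        s = fit_stats(m, x, y)
        assert s.r2 == pytest.approx(m.stats.r2)
        assert s.se == pytest.approx(m.stats.se)

    def test_too_few_residual_dof_rejected(self):
        m = fit_model([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 5.0], "quadratic")
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_stats(m, [1.0, 2.0, 3.0], [1.0, 3.0, 2.0])


class TestCorrelationGrid:
    def test_linear_degree_spot_values(self, grids):
        grid = grids[("linear", DEGREE)]
        assert grid.loc["ABC", "MW"] == pytest.approx(0.9725, abs=1e-3)
        assert grid.loc["ReZ1", "HAC"] == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_degree_spot_value(self, grids):
        assert grids[("quadratic", DEGREE)].loc["ABC", "BP"] == pytest.approx(0.97239, abs=1e-3)

    def test_linear_entries_equal_absolute_pearson(self, index_tables, properties):
        grid = correlation_grid(index_tables[DEGREE], properties, "linear")
        for ind in ("ABC", "mM2"):
            for prop in ("MW", "MV"):
                pearson = np.corrcoef(index_tables[DEGREE][ind], properties[prop])[0, 1]
                assert grid.loc[ind, prop] == pytest.approx(abs(pearson), rel=1e-9)

    def test_quadratic_dominates_linear_entrywise(self, grids):
        lin = grids[("linear", DEGREE)].to_numpy()
        quad = grids[("quadratic", DEGREE)].to_numpy()
        assert (quad >= lin - 1e-12).all()

    def test_mismatched_graph_sets_rejected(self, index_tables, properties):
        with pytest.raises(ValueError, match="graph sets"):
            correlation_grid(index_tables[DEGREE].iloc[:-1], properties, "linear")

    def test_all_six_grids_match_reported_values(self, grids):
        """Reproduction sweep: every recomputed grid cell agrees with the
        reported correlation to within 0.001."""
        from topoqspr import data

        for (family, flavor), grid in grids.items():
            ref = data.load_reference_correlations(family, flavor)
            ref.index = grid.index
            diff = (grid - ref).abs().to_numpy()
            assert diff.max() <= 1e-3, (family, flavor, diff.max())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 100),
    shift=st.floats(-50, 50),
    seed=st.integers(0, 100),
)
def test_r_invariant_under_affine_rescaling(scale, shift, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 10, size=12)
    y = 3 * x + rng.normal(0, 1, size=12)
    base = fit_model(x, y, "linear").stats.r
    assert fit_model(x, scale * y + shift, "linear").stats.r == pytest.approx(base, rel=1e-7)
    assert fit_model(scale * x + abs(shift) + 0.1, y, "linear").stats.r == pytest.approx(
        base, rel=1e-7
    )


class TestModelSelection:
    def test_hac_selects_exact_linear_rez1(self, selected_models):
        m = selected_models["HAC"]
        assert (m.family, m.descriptor, m.flavor) == ("linear", "ReZ1", DEGREE)
        assert m.stats.r2 == 1.0

    def test_bp_selects_quadratic_abc_degree(self, selected_models):
        m = selected_models["BP"]
        assert (m.family, m.descriptor, m.flavor) == ("quadratic", "ABC", DEGREE)

    def test_mv_selects_quadratic_modified_zagreb(self, selected_models):
        m = selected_models["MV"]
        assert (m.family, m.descriptor, m.flavor) == ("quadratic", "mM2", DEGREE)

    def test_all_nine_properties_covered(self, selected_models, properties):
        assert set(selected_models) == set(properties.columns)

    def test_reported_winning_descriptors(self, selected_models):
        # the nine selected models use only four degree-based descriptors
        winners = {p: m.descriptor for p, m in selected_models.items()}
        assert winners == {
            "MW": "ReZ1", "HAC": "ReZ1", "CO": "SO", "BP": "ABC", "EV": "ReZ1",
            "FP": "ReZ1", "MR": "ReZ1", "PO": "ReZ1", "MV": "mM2",
        }
        assert all(m.flavor == DEGREE for m in selected_models.values())


class TestPredict:
    def test_mw_prediction_for_trazodone(self, selected_models):
        assert round(predict(selected_models["MW"], 26.0), 1) == pytest.approx(365.9, abs=0.1)

    def test_hac_prediction_is_identity(self, selected_models):
        assert predict(selected_models["HAC"], 10.0) == pytest.approx(10.0, abs=1e-9)

    def test_bp_prediction_for_tranylcypromine(self, selected_models, index_tables):
        x = index_tables[DEGREE].loc["G12", "ABC"]
        assert round(predict(selected_models["BP"], x), 1) == pytest.approx(248.2, abs=0.1)

    def test_vectorized_prediction(self, selected_models):
        out = predict(selected_models["HAC"], np.array([10.0, 26.0]))
        assert out == pytest.approx([10.0, 26.0])


def test_model_serialization_roundtrip(selected_models):
    for m in selected_models.values():
        again = load_model(save_model(m))
        assert again.family == m.family
        assert again.coef == pytest.approx(m.coef)
        assert again.stats.r2 == pytest.approx(m.stats.r2)
        assert (again.stats.f is None) == (m.stats.f is None)
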