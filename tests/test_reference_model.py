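"""Reference regression: prediction, limits, fitting, indexation, serialization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thvnorm import (
    FitError,
    ReferenceModel,
    classify_thv,
    expected_thv,
    fit_reference_model,
    index_thv,
    load_model,
    paper_model,
    prediction_limits,
    reindex_bsa_to_height,
    save_model,
    standard_thv,
)

heights = st.floats(min_value=1.4, max_value=2.1)
ds = st.floats(min_value=-0.6, max_value=0.4)


def test_paper_model_pins_published_constants(model):
    assert (model.coef_height, model.coef_d, model.intercept, model.half_width) == (
        456.0,
        -221.0,
        -335.0,
        142.0,
    )
    # upper-limit intercept: -335 + 142 = -193
    assert model.intercept + model.half_width == -193.0
    assert model.n_fit == 353


@pytest.mark.parametrize(
    "d, rounded",
    [(-0.2, 498), (-0.34, 529), (0.2, 410)],
)
def test_expected_thv_known_values(model, d, rounded):
    assert round(expected_thv(model, 1.73, d)) == rounded


def test_expected_thv_unrounded_standard_case(model):
    assert expected_thv(model, 1.73, 0.0) == pytest.approx(453.88)


def test_standard_thv_is_expected_at_d_zero(model):
    assert standard_thv(model, 2.00) == pytest.approx(577.00)
    for h in (1.5, 1.73, 1.95):
        assert standard_thv(model, h) == expected_thv(model, h, 0.0)


def test_prediction_limits_symmetry_and_known_interval(model):
    lower, upper = prediction_limits(model, expected_thv(model, 1.73, -0.34))
    assert (round(lower), round(upper)) == (387, 671)
    assert upper - lower == pytest.approx(2 * model.half_width)


@given(h=heights, d=ds)
def test_upper_limit_matches_closed_form(model, h, d):
    """expected + half-width equals the 456h - 221d - 193 closed form."""
    _, upper = prediction_limits(model, expected_thv(model, h, d))
    assert upper == pytest.approx(456 * h - 221 * d - 193, abs=1e-9)


@given(h=heights, w1=st.floats(min_value=40, max_value=150), dw=st.floats(min_value=1, max_value=50))
def test_expected_thv_increases_with_weight(model, h, w1, dw):
    """At fixed height, heavier build (smaller d) means larger expected THV."""
    from thvnorm import h_minus_bsa

    e1 = expected_thv(model, h, h_minus_bsa(h, w1))
    e2 = expected_thv(model, h, h_minus_bsa(h, w1 + dw))
    assert e2 > e1


@pytest.mark.parametrize(
    "measured, upper, label",
    [
        (600.0, 671.02, "within_expected"),
        (672.0, 671.02, "abnormal"),
        (671.02, 671.02, "within_expected"),  # boundary belongs to within
    ],
)
def test_classify_thv(measured, upper, label):
    assert classify_thv(measured, upper) == label


def _normal_equations(height, d, thv):
    """Independent least-squares oracle via the normal equations."""
    X = np.column_stack([np.ones_like(height), height, d])
    beta = np.linalg.solve(X.T @ X, X.T @ thv)
    return beta  # (intercept, coef_height, coef_d)


def test_fit_recovers_exact_plane():
    rng = np.random.default_rng(0)
    h = rng.uniform(1.5, 2.0, size=20)
    d = rng.uniform(-0.4, 0.2, size=20)
    thv = 456 * h - 221 * d - 335
    m = fit_reference_model(np.column_stack([h, d, thv]))
    assert m.coef_height == pytest.approx(456, abs=1e-8)
    assert m.coef_d == pytest.approx(-221, abs=1e-8)
    assert m.intercept == pytest.approx(-335, abs=1e-8)
    assert m.residual_sd == pytest.approx(0, abs=1e-6)


def test_fit_matches_normal_equations_oracle():
    """OLS path agrees with an independent normal-equations solve."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = rng.integers(10, 31)
        h = rng.uniform(1.4, 2.1, size=n)
        d = rng.uniform(-0.6, 0.4, size=n)
        thv = 456 * h - 221 * d - 335 + rng.normal(0, 70, size=n)
        m = fit_reference_model(np.column_stack([h, d, thv]))
        b0, b1, b2 = _normal_equations(h, d, thv)
        assert m.intercept == pytest.approx(b0, rel=1e-8)
        assert m.coef_height == pytest.approx(b1, rel=1e-8)
        assert m.coef_d == pytest.approx(b2, rel=1e-8)


def test_fit_half_width_is_z_times_residual_sd():
    rng = np.random.default_rng(5)
    h = rng.uniform(1.5, 2.0, size=200)
    d = rng.uniform(-0.4, 0.2, size=200)
    thv = 456 * h - 221 * d - 335 + rng.normal(0, 70, size=200)
    m = fit_reference_model(np.column_stack([h, d, thv]), coverage=0.95)
    assert m.half_width == pytest.approx(1.959963984540054 * m.residual_sd)
    assert m.n_fit == 200
    assert 0 < m.r_multiple < 1
    assert m.f_stat > 0


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda h, d: (np.full_like(h, 1.7), d), "height"),
        (lambda h, d: (h, np.zeros_like(d)), "d"),
    ],
)
def test_fit_degenerate_design_errors(mutate, message):
    rng = np.random.default_rng(1)
    h = rng.uniform(1.5, 2.0, size=20)
    d = rng.uniform(-0.4, 0.2, size=20)
    h, d = mutate(h, d)
    thv = 456 * h - 221 * d - 335
    with pytest.raises(FitError, match=message):
        fit_reference_model(np.column_stack([h, d, thv]))


def test_fit_requires_minimum_sample():
    with pytest.raises(FitError, match="10"):
        fit_reference_model([(1.6, 0.0, 400.0)] * 5)


def test_index_thv_known_values():
    per_h, per_bsa, corr = index_thv(500, 1.73, 1.73)
    assert corr == 0.0
    _, _, corr2 = index_thv(500, 1.73, 1.93)
    assert corr2 == pytest.approx(29.95, abs=0.005)


@given(
    thv=st.floats(min_value=200, max_value=900),
    h=heights,
    bsa=st.floats(min_value=1.3, max_value=2.6),
)
def test_index_correction_sign(thv, h, bsa):
    """Correction sign equals sign(BSA - height)."""
    _, _, corr = index_thv(thv, h, bsa)
    assert np.sign(corr) == np.sign(bsa - h)


@pytest.mark.parametrize(
    "value, h, bsa, expected",
    [(100, 2.0, 2.0, 100.0), (100, 1.6, 2.0, 125.0), (252, 1.81, 1.955, 272.2)],
)
def test_reindex_bsa_to_height(value, h, bsa, expected):
    assert reindex_bsa_to_height(value, h, bsa) == pytest.approx(expected, abs=0.05)


def test_model_json_round_trip_is_bit_exact(tmp_path, model):
    fitted = ReferenceModel(
        coef_height=455.9000000123,
        coef_d=-220.87654321,
        intercept=-334.1234567890123,
        half_width=141.99999999,
        n_fit=353,
        r_multiple=0.5612345,
        f_stat=80.199999,
        residual_sd=72.44897959,
    )
    for m in (model, fitted):
        path = tmp_path / "model.json"
        save_model(m, path)
        assert load_model(path) == m
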