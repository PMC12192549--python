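"""Synthetic cohort generator: determinism, structure, parameter recovery."""

import numpy as np
import pytest

from thvnorm import (
    CohortConfig,
    assess_cohort,
    default_config,
    derive_anthropometry,
    fit_reference_model,
    generate_cohort,
    generate_worked_examples,
    paper_model,
    risk_classify,
)

from conftest import zero_shift_config


@pytest.fixture(scope="module")
def cohort_20k():
    return generate_cohort(default_config(n=20_000, seed=20))


def test_default_config_values():
    cfg = default_config()
    assert cfg.sex_proportion_female == pytest.approx(1503 / 2305)
    assert cfg.bmi_class_probs == (0.25, 0.40, 0.35)
    assert cfg.residual_sd == 72.4
    assert cfg.risk_shift["M"]["overweight"]["high"] == 98.2
    assert cfg.risk_shift["F"]["obese"]["low"] == -32.9


def test_config_validation():
    cfg = default_config()
    with pytest.raises(ValueError):
        CohortConfig(**{**cfg.model_dump(), "bmi_class_probs": (0.5, 0.4, 0.3)})
    with pytest.raises(ValueError):
        CohortConfig(**{**cfg.model_dump(), "residual_sd": -1.0})
    bad = cfg.model_dump()
    bad["bmi_by_cell"]["F"]["normal"]["mean"] = 40.0  # outside class bounds
    with pytest.raises(ValueError):
        CohortConfig(**bad)


def test_empty_cohort():
    assert generate_cohort(default_config(n=0, seed=1)) == []


def test_determinism():
    cfg = default_config(n=500, seed=99)
    assert generate_cohort(cfg) == generate_cohort(cfg)


def test_different_seeds_differ():
    a = generate_cohort(default_config(n=100, seed=1))
    b = generate_cohort(default_config(n=100, seed=2))
    assert a != b


def test_cell_proportions_converge(cohort_20k):
    """Empirical sex/BMI-class proportions sit within 3 binomial SE."""
    n = len(cohort_20k)
    cfg = default_config()
    p_f = cfg.sex_proportion_female
    f_frac = sum(r.sex.value == "F" for r in cohort_20k) / n
    assert abs(f_frac - p_f) < 3 * np.sqrt(p_f * (1 - p_f) / n)
    classes = [derive_anthropometry(r.height, r.weight).bmi_class.value for r in cohort_20k]
    for name, p in zip(("normal", "overweight", "obese"), cfg.bmi_class_probs):
        frac = classes.count(name) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_weight_is_bmi_times_height_squared(cohort_20k):
    for r in cohort_20k[:100]:
        a = derive_anthropometry(r.height, r.weight)
        assert a.bmi_class.value in ("normal", "overweight", "obese")


def test_reference_fraction_matches_config(cohort_20k):
    """Kept reference fraction tracks P(normal BMI) * P(low risk | cell)."""
    cfg = default_config()
    p_ref = cfg.bmi_class_probs[0] * (
        cfg.sex_proportion_female * (1 - cfg.p_high_risk["F"]["normal"])
        + (1 - cfg.sex_proportion_female) * (1 - cfg.p_high_risk["M"]["normal"])
    )
    frac = sum(risk_classify(r).is_reference for r in cohort_20k) / len(cohort_20k)
    assert abs(frac - p_ref) < 0.03


def test_risk_rule_round_trip():
    """Risk labels drawn by the generator survive re-classification."""
    all_low = zero_shift_config(
        2000, 8, p_high_risk={s: {c: 0.0 for c in ("normal", "overweight", "obese")} for s in "FM"}
    )
    for r in generate_cohort(all_low):
        assert risk_classify(r).risk_class == "low"
    all_high = zero_shift_config(
        2000, 8, p_high_risk={s: {c: 1.0 for c in ("normal", "overweight", "obese")} for s in "FM"}
    )
    for r in generate_cohort(all_high):
        assert risk_classify(r).risk_class == "high"


def test_h_minus_bsa_decreases_across_bmi_classes(cohort_20k):
    """Mean h-BSA falls monotonically normal -> overweight -> obese per sex."""
    by_cell = {}
    for r in cohort_20k:
        a = derive_anthropometry(r.height, r.weight)
        by_cell.setdefault((r.sex.value, a.bmi_class.value), []).append(a.d)
    for sex in ("F", "M"):
        means = [np.mean(by_cell[(sex, c)]) for c in ("normal", "overweight", "obese")]
        assert means[0] > means[1] > means[2]


def test_residual_sd_recovery():
    """Regression on a zero-shift cohort recovers the configured noise SD."""
    cfg = zero_shift_config(10_000, 17)
    recs = generate_cohort(cfg)
    triples = [
        (r.height, derive_anthropometry(r.height, r.weight).d, r.thv_measured)
        for r in recs
    ]
    m = fit_reference_model(triples)
    assert m.residual_sd == pytest.approx(72.4, rel=0.05)


def test_risk_shift_is_recovered_in_cell_means():
    """Measured-minus-expected in a shifted cell centers on the configured
    shift (3 SE tolerance)."""
    cfg = default_config(n=20_000, seed=31)
    recs = generate_cohort(cfg)
    model = paper_model()
    assessments = assess_cohort(recs, model)
    diffs = []
    for r, a in zip(recs, assessments):
        anthro = derive_anthropometry(r.height, r.weight)
        if (
            r.sex.value == "M"
            and anthro.bmi_class.value == "overweight"
            and risk_classify(r).risk_class == "high"
        ):
            diffs.append(r.thv_measured - a.thv_expected)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - 98.2) < 3 * se


def test_thv_floor():
    cfg = zero_shift_config(2000, 55, residual_sd=300.0)
    recs = generate_cohort(cfg)
    assert min(r.thv_measured for r in recs) >= 150.0


def test_worked_examples_fixture():
    recs = generate_worked_examples()
    assert len(recs) == 4
    assert [r.id for r in recs] == ["A", "B", "C", "D"]
    assert all(r.height == 1.73 for r in recs)
    assert recs[0].weight == 62.3
    assert recs[2].weight == 77.5
    assert generate_worked_examples() == recs  # no randomness
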