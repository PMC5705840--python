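"""Forward-model unit and property tests.

The oracle for composite predictions is an independent straight-line
re-implementation of the model equations in arbitrary precision (mpmath),
kept deliberately separate from the vectorized numpy code under test.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from mpmath import mp, mpf

from mitohet import FixedConstants, ModelParameters, PARAM_NAMES, predict_all
from mitohet.model import (
    OBSERVABLE_FEATURES,
    cell_volume,
    etc_mrna,
    etc_protein,
    glycolysis_mrna,
    growth_rate,
    max_respiratory_capacity,
    mrna_degradation_rate,
    normalized_predictions,
    oxphos_fraction,
    wildtype_copy_number,
)

mp.dps = 40

BASE = dict(
    beta=1.0, k_mRNA=4.0, k_m=20.0, h0=0.42, delta_p=1.0, c1=1.0,
    m2=2.0, h_star=0.4, k_o=5.0, k_g=1.0, k_gr=1.0, k_p=1.0,
)


def make_params(**overrides) -> ModelParameters:
    return ModelParameters(**{**BASE, **overrides})


def mp_predict(h, p: ModelParameters, N=1):
    """Independent arbitrary-precision evaluation of the whole model."""
    h, N = mpf(repr(h)), mpf(N)
    n_plus = N * (1 - h)
    delta_m = mpf(repr(p.k_mRNA)) / (1 + mp.exp(mpf(repr(p.k_m)) * (h - mpf(repr(p.h0)))))
    m_etc = mpf(repr(p.beta)) / (delta_m + 1) * n_plus
    p_plus = n_plus * m_etc / mpf(repr(p.delta_p))
    if h <= mpf(repr(p.h_star)):
        m_gly = mpf(repr(p.c1))
    else:
        m_gly = mpf(repr(p.m2)) * h + (mpf(repr(p.c1)) - mpf(repr(p.m2)) * mpf(repr(p.h_star)))
    volume = mpf(repr(p.k_o)) * p_plus + mpf(repr(p.k_g)) * m_gly
    return {
        "N_plus": n_plus,
        "delta_m": delta_m,
        "M_ETC": m_etc,
        "P_plus": p_plus,
        "M_gly": m_gly,
        "V": volume,
        "G": mpf(repr(p.k_gr)) / volume,
        "R_max": mpf(repr(p.k_p)) * p_plus,
    }


# --------------------------------------------------------------------------
# individual relations


@pytest.mark.parametrize(
    "h, N, expected",
    [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.3, 1.0, 0.7), (0.5, 2.0, 1.0)],
)
def test_wildtype_copy_number_is_linear_decay(h, N, expected):
    assert wildtype_copy_number(h, N) == pytest.approx(expected, abs=1e-15)


def test_wildtype_copy_number_rejects_out_of_range():
    with pytest.raises(ValueError):
        wildtype_copy_number(1.2)
    with pytest.raises(ValueError):
        wildtype_copy_number(-0.1)
    with pytest.raises(ValueError):
        wildtype_copy_number(0.5, N=0.0)


def test_degradation_sigmoid_midpoint_and_flat_cases():
    p = make_params(k_mRNA=1.0, k_m=20.0, h0=0.4)
    assert mrna_degradation_rate(0.4, p) == pytest.approx(0.5)
    flat = make_params(k_mRNA=3.0, k_m=0.0, h0=0.4)
    for h in (0.0, 0.3, 1.0):
        assert mrna_degradation_rate(h, flat) == pytest.approx(1.5)


def test_degradation_sigmoid_matches_arbitrary_precision_oracle():
    p = make_params(k_mRNA=1.0, k_m=20.0, h0=0.4)
    # 1/(1 + e^10), frozen from a 40-digit evaluation
    assert mrna_degradation_rate(0.9, p) == pytest.approx(
        4.53978687024343945047762327634894550937e-5, rel=1e-14
    )


def test_degradation_sigmoid_extreme_steepness_hits_exact_asymptotes():
    p = make_params(k_mRNA=2.5, k_m=1e8, h0=0.5)
    assert mrna_degradation_rate(1.0, p) == 0.0
    assert mrna_degradation_rate(0.0, p) == 2.5


def test_etc_mrna_composition_and_boundary():
    p = make_params(beta=1.5, k_mRNA=2.0, k_m=10.0, h0=0.4)
    assert etc_mrna(1.0, p) == 0.0
    # frozen composition of the copy-number and degradation relations
    assert etc_mrna(0.5, p) == pytest.approx(0.487683443209335845548826741305, rel=1e-14)


def test_etc_protein_quadratic_structure():
    p = make_params(beta=1.5, k_mRNA=2.0, k_m=10.0, h0=0.4, delta_p=1.0)
    assert etc_protein(1.0, p) == 0.0
    assert etc_protein(0.5, p) == pytest.approx(0.243841721604667922774413370653, rel=1e-14)
    # doubling protein degradation halves protein
    p2 = make_params(beta=1.5, k_mRNA=2.0, k_m=10.0, h0=0.4, delta_p=2.0)
    assert etc_protein(0.5, p2) == pytest.approx(etc_protein(0.5, p) / 2)


@pytest.mark.parametrize(
    "h, expected",
    [(0.0, 1.0), (0.4, 1.0), (0.4 + 1e-12, 1.0), (0.9, 2.0 * 0.9 + 0.2)],
)
def test_glycolysis_spline_branches_and_continuity(h, expected):
    p = make_params(c1=1.0, m2=2.0, h_star=0.4)
    assert glycolysis_mrna(h, p) == pytest.approx(expected, abs=1e-10)


def test_supply_demand_arithmetic():
    p = make_params(k_o=0.7, k_g=0.4)
    assert cell_volume(0.6, 1.2, p) == pytest.approx(0.9)
    assert cell_volume(0.0, 0.0, p) == 0.0
    with pytest.raises(ValueError):
        cell_volume(-0.1, 1.0, p)


def test_growth_rate_reciprocal_law():
    p = make_params(k_gr=0.35)
    assert growth_rate(0.8, p) == pytest.approx(0.4375)
    with pytest.raises(ValueError):
        growth_rate(0.0, p)


def test_max_respiratory_capacity_is_linear():
    p = make_params(k_p=1.4)
    assert max_respiratory_capacity(0.5, p) == pytest.approx(0.7)
    assert max_respiratory_capacity(0.0, p) == 0.0


def test_oxphos_fraction_limits_and_symmetry():
    p = make_params(k_o=2.0, k_g=2.0)
    assert oxphos_fraction(0.0, 1.0, p) == 0.0
    assert oxphos_fraction(1.0, 0.0, p) == 1.0
    assert oxphos_fraction(0.7, 0.7, p) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        oxphos_fraction(0.0, 0.0, p)


# --------------------------------------------------------------------------
# parameter container


def test_exactly_twelve_adjustable_parameters():
    assert len(dataclasses.fields(ModelParameters)) == 12
    assert len(PARAM_NAMES) == 12


def test_c2_is_derived_by_continuity():
    p = make_params(c1=1.0, m2=2.0, h_star=0.4)
    assert p.c2 == pytest.approx(1.0 - 2.0 * 0.4)


@pytest.mark.parametrize(
    "bad",
    [dict(beta=0.0), dict(k_gr=-1.0), dict(h_star=0.95), dict(h_star=0.0), dict(h0=1.5)],
)
def test_parameter_invariants_enforced(bad):
    with pytest.raises(ValueError):
        make_params(**bad)


def test_parameters_round_trip_json_yaml(tmp_path):
    p = make_params()
    for name in ("p.json", "p.yaml"):
        p.save(tmp_path / name)
        assert ModelParameters.load(tmp_path / name) == p
    assert ModelParameters.from_array(p.to_array()) == p


# --------------------------------------------------------------------------
# predict_all: structure and oracle equivalence


def test_predict_all_exposes_seven_observables_plus_derived():
    pred = predict_all([0.0, 0.5], make_params())
    for f in OBSERVABLE_FEATURES:
        assert f in pred.columns
    assert len(OBSERVABLE_FEATURES) == 7
    assert {"delta_m", "density", "oxphos_fraction"} <= set(pred.columns)


def test_predict_all_boundary_rows():
    pred = predict_all([0.0, 1.0], make_params())
    assert pred.loc[0.0, "N_plus"] == 1.0
    for f in ("N_plus", "M_ETC", "P_plus", "R_max"):
        assert pred.loc[1.0, f] == 0.0


def _random_params(rng):
    return ModelParameters(
        beta=rng.uniform(0.1, 5),
        k_mRNA=rng.uniform(0.1, 10),
        k_m=rng.uniform(0.5, 50),
        h0=rng.uniform(0, 1),
        delta_p=rng.uniform(0.1, 5),
        c1=rng.uniform(0.2, 3),
        m2=rng.uniform(0.1, 5),
        h_star=rng.uniform(0.05, 0.85),
        k_o=rng.uniform(0.1, 10),
        k_g=rng.uniform(0.1, 10),
        k_gr=rng.uniform(0.1, 5),
        k_p=rng.uniform(0.1, 5),
    )


def test_predict_all_matches_independent_oracle_on_random_draws(rng):
    h_grid = np.linspace(0.0, 1.0, 11)
    for _ in range(100):
        p = _random_params(rng)
        pred = predict_all(h_grid, p)
        for h in h_grid:
            oracle = mp_predict(float(h), p)
            for feature, expected in oracle.items():
                got = pred.loc[h, feature]
                expected = float(expected)
                if expected == 0.0:
                    assert got == 0.0
                else:
                    assert abs(got - expected) / abs(expected) < 1e-12


def test_normalized_predictions_are_unit_at_reference(rng):
    p = _random_params(rng)
    norm = normalized_predictions([0.0, 0.3, 0.9], p)
    assert np.allclose(norm.loc[0.0], 1.0)


# --------------------------------------------------------------------------
# invariants as properties

param_strategy = st.builds(
    ModelParameters,
    beta=st.floats(0.1, 5),
    k_mRNA=st.floats(0.1, 10),
    k_m=st.floats(0.1, 80),
    h0=st.floats(0, 1),
    delta_p=st.floats(0.1, 5),
    c1=st.floats(0.2, 3),
    m2=st.floats(0.1, 5),
    h_star=st.floats(0.05, 0.85),
    k_o=st.floats(0.1, 10),
    k_g=st.floats(0.1, 10),
    k_gr=st.floats(0.1, 5),
    k_p=st.floats(0.1, 5),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(params=param_strategy, h=st.floats(0, 1))
def test_conservation_identities_hold_everywhere(params, h):
    row = predict_all([h], params).iloc[0]
    assert row["V"] - (params.k_o * row["P_plus"] + params.k_g * row["M_gly"]) == 0.0
    assert row["G"] * row["V"] == pytest.approx(params.k_gr, rel=1e-12)
    assert row["R_max"] == params.k_p * row["P_plus"]
    assert 0.0 <= row["oxphos_fraction"] <= 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(params=param_strategy, eps=st.floats(1e-9, 0.05))
def test_glycolysis_continuity_at_changepoint(params, eps):
    lo = glycolysis_mrna(params.h_star - eps, params)
    hi = glycolysis_mrna(min(params.h_star + eps, 1.0), params)
    assert abs(hi - lo) <= params.m2 * 2 * eps + 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(params=param_strategy)
def test_degradation_and_copy_number_strictly_decreasing(params):
    h = np.linspace(0, 1, 21)
    dm = mrna_degradation_rate(h, params)
    assert np.all(np.diff(dm) < 0)  # k_m > 0 in the strategy
    assert np.all(np.diff(wildtype_copy_number(h)) < 0)


def test_predict_matrix_fast_path_agrees_with_reference(rng):
    from mitohet.inference import _predict_matrix

    h = np.array([0.1, 0.35, 0.6, 0.9])
    for _ in range(20):
        p = _random_params(rng)
        fast = _predict_matrix(np.array(p.to_array()), h, OBSERVABLE_FEATURES)
        ref = normalized_predictions(h, p).to_numpy()
        assert np.allclose(fast, ref, rtol=1e-13)
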