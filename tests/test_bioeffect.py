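"""LQ survival models, Monte Carlo fates, SF curves and TCP."""

import numpy as np
import pytest

from celldose.bioeffect import (
    LQParameterTable,
    SimpleLQ,
    alpha_from_d0,
    evaluate_survival,
    monte_carlo_fates,
    sf_curve,
    survival_complex,
    survival_simple,
    tcp,
)
from celldose.decay import ICode
from celldose.dosimetry import DoseBreakdown
from celldose.scoeff import Region


def test_alpha_from_d0_reciprocal():
    assert alpha_from_d0(1.8) == pytest.approx(1.0 / 1.8)
    assert round(alpha_from_d0(1.8), 2) == 0.56
    with pytest.raises(ValueError):
        alpha_from_d0(0.0)


def test_zero_dose_survives_with_certainty():
    params = SimpleLQ(1.0, 0.5, 0.7, 0.1)
    assert survival_simple(0.0, 0.0, params) == 1.0


def test_d0_dose_reduces_survival_to_one_over_e():
    params = SimpleLQ(alpha_self=1.0 / 1.8)
    assert survival_simple(1.8, 0.0, params) == pytest.approx(np.exp(-1.0))


def test_quadratic_cross_term_strictly_lowers_survival():
    lin = SimpleLQ(alpha_self=0.0, alpha_cross=0.3)
    quad = SimpleLQ(alpha_self=0.0, alpha_cross=0.3, beta_cross=0.05)
    d = 2.0
    assert survival_simple(0.0, d, quad) < survival_simple(0.0, d, lin)
    assert survival_simple(0.0, d, lin) == pytest.approx(np.exp(-0.3 * d))


def _breakdown_single(n, d_self, d_cross, icode=ICode.ALPHA, source=Region.CELL_SURFACE):
    b = DoseBreakdown(n_cells=n)
    b.add((Region.NUCLEUS, icode, source, "self"), np.full(n, d_self))
    b.add((Region.NUCLEUS, icode, source, "cross"), np.full(n, d_cross))
    return b


def test_complex_model_reduces_to_simple_for_one_component():
    """Single radiation type, single source region, matched parameters:
    the complex product equals the simple two-exponential model."""
    b = _breakdown_single(5, 1.2, 0.8)
    table = LQParameterTable.uniform(0.4, 0.03)
    p_complex = survival_complex(b, table, Region.NUCLEUS)
    p_simple = survival_simple(1.2, 0.8, SimpleLQ(0.4, 0.03, 0.4, 0.03))
    assert np.allclose(p_complex, p_simple)


def test_complex_model_all_zero_doses_survive():
    b = _breakdown_single(3, 0.0, 0.0)
    table = LQParameterTable.uniform(0.4, 0.03)
    assert np.allclose(survival_complex(b, table, Region.NUCLEUS), 1.0)


def test_complex_model_missing_parameter_is_hard_error():
    b = _breakdown_single(3, 1.0, 0.0, icode=ICode.AUGER)
    table = LQParameterTable()
    table.set(ICode.ALPHA, "CS", "self", "N", 0.5, 0.0)
    with pytest.raises(KeyError, match="auger"):
        survival_complex(b, table, Region.NUCLEUS)


def test_zero_parameters_for_inert_radiations_change_nothing():
    """With alpha-only response, zeroing the electron/beta parameters gives
    the same survival as any other value of those parameters times zero
    dose — and with nonzero electron dose but zero parameters, only the
    alpha components matter."""
    b = _breakdown_single(4, 2.0, 1.0, icode=ICode.ALPHA)
    b.add((Region.NUCLEUS, ICode.BETA_MINUS, Region.CELL_SURFACE, "self"), np.full(4, 5.0))
    zeros = LQParameterTable.uniform(0.0, 0.0)
    for kind in ("self", "cross"):
        for tgt in ("C", "N", "Cy"):
            for src in ("C", "N", "Cy", "CS"):
                zeros.set(ICode.ALPHA, src, kind, tgt, 0.56, 0.0)
    alpha_only = _breakdown_single(4, 2.0, 1.0, icode=ICode.ALPHA)
    expected = survival_complex(alpha_only, zeros, Region.NUCLEUS)
    assert np.allclose(survival_complex(b, zeros, Region.NUCLEUS), expected)


def test_default_lq_table_warns_on_use():
    b = _breakdown_single(2, 1.0, 0.0)
    with pytest.warns(UserWarning, match="default LQ"):
        survival_complex(b, LQParameterTable.default(), Region.NUCLEUS)


def test_lq_table_csv_roundtrip(tmp_path):
    table = LQParameterTable.uniform(0.37, 0.021)
    table.set(ICode.ALPHA, "CS", "cross", "N", 0.56, 0.0)
    path = tmp_path / "lq.csv"
    table.to_csv(path)
    again = LQParameterTable.from_csv(path)
    assert again.entries == table.entries


def test_monte_carlo_fates_edge_cases(rng):
    alive, sf = monte_carlo_fates(np.ones(100), rng)
    assert sf == 1.0 and alive.all()
    alive, sf = monte_carlo_fates(np.zeros(100), rng)
    assert sf == 0.0 and not alive.any()


def test_monte_carlo_fates_binomial_bound(rng):
    n = 10**4
    _alive, sf = monte_carlo_fates(np.full(n, 0.5), rng)
    assert abs(sf - 0.5) < 5.0 * np.sqrt(0.25 / n)


def test_monte_carlo_fates_reject_bad_probabilities(rng):
    with pytest.raises(ValueError):
        monte_carlo_fates(np.array([1.2]), rng)


def test_tcp_closed_form_examples():
    assert tcp(np.array([0.5, 0.5]), sf=0.5, n_cells=2)[0] == pytest.approx(0.25)
    assert tcp(np.array([0.0, 0.0]), sf=0.0, n_cells=2)[0] == 1.0
    assert tcp(np.array([1.0, 0.0]), sf=0.5, n_cells=2)[1] == 0.0


def test_tcp_formulas_coincide_for_equal_probabilities():
    p = 0.3
    n = 7
    probs = np.full(n, p)
    tcp_poisson, tcp_product = tcp(probs, sf=p, n_cells=n)
    assert tcp_poisson == pytest.approx((1 - p) ** n)
    assert tcp_product == pytest.approx((1 - p) ** n)


def test_tcp_product_below_one_and_heterogeneity_direction():
    """log(1-p) is concave, so at a fixed mean survival a heterogeneous
    population gives a LOWER exact per-cell TCP product than a homogeneous
    one (the Poisson value at the mean)."""
    hom = tcp(np.full(4, 0.5), sf=0.5, n_cells=4)
    het = tcp(np.array([0.9, 0.1, 0.9, 0.1]), sf=0.5, n_cells=4)
    assert het[1] < hom[1] <= 1.0


def _fixed_dose_population(n=200, dose=2.0):
    """A stand-in population with every cell receiving the same self dose."""
    from celldose.geometry import ClusterSpec, Shape
    from celldose.scoeff import CellModel

    spec = ClusterSpec(Shape.SPHERE, {"radius_um": 40.0}, 13.0, CellModel(6.0, 5.0))
    from celldose.geometry import build_population

    pop = build_population(spec)
    pop.labeled[:] = True
    pop.activity_bq[:] = 1.0
    b = DoseBreakdown(n_cells=len(pop))
    b.add(
        (Region.NUCLEUS, ICode.ALPHA, Region.CELL_SURFACE, "self"),
        np.full(len(pop), dose),
    )
    return pop, b


def test_sf_curve_recovers_lq_closed_form_for_uniform_self_dose():
    """Uniform self-dose-only cluster: expected SF equals
    exp(-alpha D - beta D^2) exactly at every sweep point."""
    alpha, beta, dmax = 0.35, 0.04, 3.0
    pop, b = _fixed_dose_population(dose=dmax)
    params = SimpleLQ(alpha_self=alpha, beta_self=beta)
    curve = sf_curve(pop, b, params, tau_hours=1.0, target="N", seed=3, n_points=11)
    doses = curve.fraction_of_max.to_numpy() * dmax
    expected = np.exp(-alpha * doses - beta * doses**2)
    assert np.allclose(curve.sf_expected.to_numpy(), expected, rtol=1e-12)
    # the MC column tracks within binomial error
    se = np.sqrt(expected * (1 - expected) / len(pop)).clip(min=1e-9)
    assert np.all(np.abs(curve.sf_mc - expected) < 6.0 * se + 1e-12)


def test_sf_curve_starts_at_unity_and_expectation_monotone():
    pop, b = _fixed_dose_population(dose=5.0)
    params = SimpleLQ(alpha_self=0.5)
    curve = sf_curve(pop, b, params, tau_hours=1.0, target="N", seed=4, n_points=9)
    assert curve.sf_expected.iloc[0] == 1.0
    assert curve.sf_mc.iloc[0] == 1.0
    assert np.all(np.diff(curve.sf_expected) <= 1e-15)


def test_fixed_seed_reproduces_fates_and_curve():
    pop, b = _fixed_dose_population(dose=2.0)
    params = SimpleLQ(alpha_self=0.5)
    r1 = evaluate_survival(b, params, "N", seed=9)
    r2 = evaluate_survival(b, params, "N", seed=9)
    assert np.array_equal(r1.alive, r2.alive)
    assert r1.sf_mc == r2.sf_mc
    c1 = sf_curve(pop, b, params, 1.0, "N", seed=9, n_points=5)
    c2 = sf_curve(pop, b, params, 1.0, "N", seed=9, n_points=5)
    assert c1.equals(c2)
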