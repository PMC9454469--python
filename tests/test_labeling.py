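"""Label selection, activity sampling, radial profiles and assignment."""

import numpy as np
import pytest

from celldose.geometry import ClusterSpec, Shape, build_population, classify_penetration
from celldose.labeling import (
    ActivityDistributionSpec,
    SubcellularDistribution,
    assign,
    radial_profile,
    sample_activities,
    select_labeled,
    substream,
)
from celldose.scoeff import CellModel


@pytest.fixture()
def small_sphere():
    spec = ClusterSpec(
        Shape.SPHERE, {"radius_um": 60.0}, 13.0, CellModel(6.0, 5.0)
    )
    pop = build_population(spec)
    classify_penetration(pop)
    return pop


@pytest.fixture()
def surface_split():
    return SubcellularDistribution(f_surface=1.0)


def test_subcellular_split_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        SubcellularDistribution(0.5, 0.2, 0.1)
    with pytest.raises(ValueError):
        SubcellularDistribution(-0.1, 0.1, 1.0)
    split = SubcellularDistribution(0.2, 0.3, 0.5)
    assert [f for _r, f in split.items()] == [0.2, 0.3, 0.5]


def test_select_all_when_everyone_eligible(small_sphere):
    select_labeled(small_sphere, 100.0, seed=1)
    assert small_sphere.labeled.all()


def test_select_is_seed_deterministic(small_sphere):
    select_labeled(small_sphere, 40.0, seed=7)
    first = small_sphere.labeled.copy()
    select_labeled(small_sphere, 40.0, seed=7)
    assert np.array_equal(first, small_sphere.labeled)
    select_labeled(small_sphere, 40.0, seed=8)
    assert first.sum() == small_sphere.labeled.sum()
    assert not np.array_equal(first, small_sphere.labeled)


def test_requested_count_rounds_from_percent(small_sphere):
    select_labeled(small_sphere, 40.0, seed=3)
    assert small_sphere.labeled.sum() == round(0.40 * len(small_sphere))


def test_clamp_to_eligible_with_warning(small_sphere):
    small_sphere.eligible[:] = False
    small_sphere.eligible[:10] = True
    with pytest.warns(UserWarning, match="labeling all eligible"):
        select_labeled(small_sphere, 100.0, seed=1)
    assert small_sphere.labeled.sum() == 10


def test_zero_eligible_is_a_hard_error(small_sphere):
    small_sphere.eligible[:] = False
    with pytest.raises(ValueError, match="eligible"):
        select_labeled(small_sphere, 100.0, seed=1)


def test_uniform_sampling_gives_identical_activities(rng):
    acts = sample_activities("uniform", 0.02, 0.0, 10, rng)
    assert np.all(acts == 0.02)


def test_lognormal_sampling_mean_preserved(rng):
    """The -sigma^2/2 shift makes E[A] = <A> for every shape parameter."""
    n = 10**5
    for sigma in (0.3, 0.8, 1.5):
        acts = sample_activities("lognormal", 0.02, sigma, n, rng)
        assert np.all(acts > 0)
        se = acts.std(ddof=1) / np.sqrt(n)
        assert abs(acts.mean() - 0.02) < 3.0 * se


def test_normal_sampling_moments(rng):
    n = 10**5
    acts = sample_activities("normal", 1.0, 0.1, n, rng)  # truncation negligible
    assert np.all(acts > 0)
    assert acts.mean() == pytest.approx(1.0, abs=3.0 * 0.1 / np.sqrt(n))
    assert acts.std(ddof=1) == pytest.approx(0.1, rel=0.02)


def test_degree_zero_polynomial_profile_is_uniform():
    spec = ActivityDistributionSpec(
        method="radial_polynomial", radial_params=(2.5,), max_mean_activity_bq=1.0
    )
    profile = radial_profile(spec)
    r = np.linspace(0.0, 100.0, 7)
    assert np.allclose(profile(r), 2.5)


def test_linear_profile_through_zero_vanishes_at_center(small_sphere, surface_split):
    select_labeled(small_sphere, 100.0, seed=1)
    spec = ActivityDistributionSpec(
        method="radial_linear", radial_params=(0.0, 1.0), max_mean_activity_bq=0.05
    )
    assign(small_sphere, spec, surface_split, seed=1)
    center = np.flatnonzero(small_sphere.radii < 1e-9)
    assert small_sphere.activity_bq[center] == pytest.approx(0.0)


def test_radial_assignment_normalizes_mean_over_all_cells(small_sphere, surface_split):
    select_labeled(small_sphere, 100.0, seed=1)
    spec = ActivityDistributionSpec(
        method="radial_exponential", radial_params=(0.4,), max_mean_activity_bq=0.02
    )
    assign(small_sphere, spec, surface_split, seed=1)
    assert small_sphere.activity_bq.mean() == pytest.approx(0.02, rel=1e-12)


def test_negative_profile_rejected(small_sphere, surface_split):
    select_labeled(small_sphere, 100.0, seed=1)
    spec = ActivityDistributionSpec(
        method="radial_linear", radial_params=(10.0, -1.0), max_mean_activity_bq=0.05
    )
    with pytest.raises(ValueError, match="negative"):
        assign(small_sphere, spec, surface_split, seed=1)


def test_user_radial_table_interpolates(tmp_path, small_sphere, surface_split):
    table = tmp_path / "radial.csv"
    table.write_text("radius_um,relative_activity\n0,1.0\n60,2.0\n")
    select_labeled(small_sphere, 100.0, seed=1)
    spec = ActivityDistributionSpec(
        method="radial_user_table", radial_table=str(table), max_mean_activity_bq=0.02
    )
    assign(small_sphere, spec, surface_split, seed=1)
    acts = small_sphere.activity_bq
    outer = acts[small_sphere.radii > 50.0].mean()
    inner = acts[small_sphere.radii < 20.0].mean()
    assert outer > inner
    assert acts.mean() == pytest.approx(0.02, rel=1e-12)


def test_fourparam_lognormal_profile_nonnegative():
    spec = ActivityDistributionSpec(
        method="radial_lognormal4", radial_params=(1.0, 20.0, 10.0, 0.5),
        max_mean_activity_bq=1.0,
    )
    profile = radial_profile(spec)
    vals = profile(np.linspace(0.0, 120.0, 200))
    assert np.all(vals >= 0.0)
    assert vals.max() > 0.0


def test_uniform_assignment_dilution_identity(small_sphere, surface_split):
    """With 50% labeling, the mean over all cells is half the labeled mean."""
    select_labeled(small_sphere, 50.0, seed=2)
    spec = ActivityDistributionSpec(method="uniform", mean_activity_bq=0.02)
    assign(small_sphere, spec, surface_split, seed=2)
    n_lab = small_sphere.labeled.sum()
    assert small_sphere.activity_bq.sum() == pytest.approx(0.02 * n_lab)
    assert small_sphere.activity_bq.mean() == pytest.approx(
        0.02 * n_lab / len(small_sphere)
    )
    assert np.all(small_sphere.activity_bq[~small_sphere.labeled] == 0.0)


def test_assignment_is_bit_reproducible(small_sphere, surface_split):
    select_labeled(small_sphere, 80.0, seed=5)
    spec = ActivityDistributionSpec(method="lognormal", mean_activity_bq=0.02, sigma=0.7)
    assign(small_sphere, spec, surface_split, seed=5)
    first = small_sphere.activity_bq.copy()
    assign(small_sphere, spec, surface_split, seed=5)
    assert np.array_equal(first, small_sphere.activity_bq)


def test_ellipsoid_rejects_radial_methods(surface_split):
    spec = ClusterSpec(
        Shape.ELLIPSOID,
        {"semi_axis_x_um": 60.0, "semi_axis_y_um": 50.0, "semi_axis_z_um": 40.0},
        13.0,
        CellModel(6.0, 5.0),
    )
    pop = build_population(spec)
    classify_penetration(pop)
    select_labeled(pop, 100.0, seed=1)
    dist = ActivityDistributionSpec(
        method="radial_exponential", radial_params=(0.4,), max_mean_activity_bq=0.02
    )
    with pytest.raises(ValueError, match="ellipsoid"):
        assign(pop, dist, surface_split, seed=1)


def test_substreams_are_independent_and_stable():
    a = substream(42, "label-selection").random(4)
    b = substream(42, "activity-sampling").random(4)
    assert not np.allclose(a, b)
    assert np.array_equal(a, substream(42, "label-selection").random(4))
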