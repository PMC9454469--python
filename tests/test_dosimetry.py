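"""Decay counts, per-cell dose bookkeeping and radial summaries."""

import numpy as np
import pytest

from celldose.dosimetry import (
    compute_doses,
    decays_per_cell,
    per_cell_table,
    radial_summary,
    tau_physical_hours,
)
from celldose.geometry import ClusterSpec, Shape, build_population, classify_penetration
from celldose.labeling import (
    ActivityDistributionSpec,
    SubcellularDistribution,
    assign,
    select_labeled,
)
from celldose.scoeff import CellModel, Region


@pytest.fixture()
def surface_split():
    return SubcellularDistribution(f_surface=1.0)


def _uniform_population(radius=40.0, percent=100.0, mean_bq=0.02, seed=1):
    spec = ClusterSpec(Shape.SPHERE, {"radius_um": radius}, 13.0, CellModel(6.0, 5.0))
    pop = build_population(spec)
    classify_penetration(pop)
    select_labeled(pop, percent, seed)
    assign(
        pop,
        ActivityDistributionSpec(method="uniform", mean_activity_bq=mean_bq),
        SubcellularDistribution(f_surface=1.0),
        seed,
    )
    return pop


@pytest.mark.parametrize(
    "activity, tau, expected",
    [(0.0, 5.0, 0.0), (1.0, 1.0, 3600.0), (0.02, 1.11, 79.92)],
)
def test_decays_per_cell_unit_conversion(activity, tau, expected):
    assert decays_per_cell(activity, tau) == pytest.approx(expected)


def test_decays_rejects_negative_inputs():
    with pytest.raises(ValueError):
        decays_per_cell(-1.0, 1.0)
    with pytest.raises(ValueError):
        decays_per_cell(1.0, 0.0)


def test_tau_physical_is_half_life_over_ln2():
    assert tau_physical_hours(3600.0 * np.log(2.0)) == pytest.approx(1.0)


def test_isolated_labeled_cell_has_zero_cross_dose(surface_split, electron_50kev):
    spec = ClusterSpec(Shape.SPHERE, {"radius_um": 5.0}, 13.0, CellModel(6.0, 5.0))
    pop = build_population(spec)
    classify_penetration(pop)
    select_labeled(pop, 100.0, 1)
    assign(
        pop,
        ActivityDistributionSpec(method="uniform", mean_activity_bq=0.02),
        surface_split,
        1,
    )
    breakdown, _table = compute_doses(pop, electron_50kev, surface_split, 1.0)
    assert breakdown.total(Region.NUCLEUS, "cross") == pytest.approx(0.0)
    assert breakdown.total(Region.NUCLEUS, "self")[0] > 0.0


def test_two_cells_get_equal_cross_doses_by_symmetry(surface_split, electron_50kev):
    spec = ClusterSpec(Shape.PAIR, {"separation_um": 13.0}, 13.0, CellModel(6.0, 5.0))
    pop = build_population(spec)
    pop.labeled = np.array([True, True])
    pop.activity_bq = np.array([0.02, 0.02])
    breakdown, _ = compute_doses(pop, electron_50kev, surface_split, 1.0)
    cross = breakdown.total(Region.NUCLEUS, "cross")
    assert cross[0] == pytest.approx(cross[1], rel=1e-12)
    assert cross[0] > 0.0


def test_dose_components_are_linear_in_activity(surface_split, alpha_5mev):
    pop = _uniform_population(radius=30.0)
    b1, table = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    pop.activity_bq = pop.activity_bq * 3.0
    b3, _ = compute_doses(pop, alpha_5mev, surface_split, 1.0, table=table)
    for key, dose in b1.components.items():
        assert np.allclose(b3.components[key], 3.0 * dose, rtol=1e-12)


def test_dose_breakdown_additivity_and_positivity(surface_split, alpha_5mev):
    pop = _uniform_population(radius=30.0)
    breakdown, _ = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    for target in (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM):
        total = breakdown.total(target)
        parts = breakdown.total(target, "self") + breakdown.total(target, "cross")
        assert np.allclose(total, parts)
        assert np.all(total >= 0.0)


def test_alpha_energy_bookkeeping_against_direct_s_sum(surface_split, alpha_5mev):
    """Cross-dose accumulation reproduces a brute-force pair sum."""
    pop = _uniform_population(radius=30.0)
    breakdown, table = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    from celldose.decay import ICode
    from celldose.scoeff import cross_s

    decays = decays_per_cell(pop.activity_bq, 1.0)
    k = 0  # spot-check the first cell against an explicit loop
    expected = 0.0
    for j in np.flatnonzero(pop.labeled):
        if j == k:
            continue
        d = float(np.linalg.norm(pop.centers[j] - pop.centers[k]))
        s_kj = cross_s(alpha_5mev, pop.spec.cell, d, "CS", "N")[ICode.ALPHA]
        expected += decays[j] * s_kj
    got = breakdown.components[(Region.NUCLEUS, ICode.ALPHA, Region.CELL_SURFACE, "cross")][k]
    assert got == pytest.approx(expected, rel=1e-6)


def test_subcellular_split_weights_source_regions(alpha_5mev):
    pop = _uniform_population(radius=30.0)
    split = SubcellularDistribution(f_nucleus=0.25, f_cytoplasm=0.25, f_surface=0.5)
    breakdown, _ = compute_doses(pop, alpha_5mev, split, 1.0)
    from celldose.decay import ICode

    key_n = (Region.NUCLEUS, ICode.ALPHA, Region.NUCLEUS, "self")
    key_cs = (Region.NUCLEUS, ICode.ALPHA, Region.CELL_SURFACE, "self")
    assert key_n in breakdown.components and key_cs in breakdown.components
    # the nucleus self-source outdoses the surface source per unit fraction
    lab = pop.labeled
    assert np.all(
        breakdown.components[key_n][lab] / 0.25
        > breakdown.components[key_cs][lab] / 0.5
    )


def test_radial_summary_columns_and_bounds(surface_split, alpha_5mev):
    pop = _uniform_population(radius=40.0)
    breakdown, _ = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    frame = radial_summary(pop, breakdown, 1.0, bin_width_um=13.0)
    assert {
        "mean_activity_labeled_bq",
        "mean_self_dose_labeled_gy",
        "mean_cross_dose_labeled_gy",
        "mean_cross_dose_unlabeled_gy",
        "mean_decays_labeled",
        "mean_dose_all_gy",
    } <= set(frame.columns)
    # uniform all-labeled cluster: activity constant across occupied bins
    occupied = frame[frame.n_labeled > 0]
    assert np.allclose(occupied.mean_activity_labeled_bq, 0.02)
    # all-labeled: the unlabeled column is empty, reported as NaN
    assert occupied.mean_cross_dose_unlabeled_gy.isna().all()
    # mean dose per bin bounded by the per-cell extremes
    d_tot = breakdown.total(Region.NUCLEUS)
    assert occupied.mean_dose_all_gy.max() <= d_tot.max() + 1e-12
    assert occupied.mean_dose_all_gy.min() >= d_tot.min() - 1e-12


def test_radial_summary_rejects_bad_bins(surface_split, alpha_5mev):
    pop = _uniform_population(radius=30.0)
    breakdown, _ = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    with pytest.raises(ValueError):
        radial_summary(pop, breakdown, 1.0, bin_width_um=0.0)


def test_per_cell_table_shape_and_totals(surface_split, alpha_5mev):
    pop = _uniform_population(radius=30.0)
    breakdown, _ = compute_doses(pop, alpha_5mev, surface_split, 1.0)
    frame = per_cell_table(pop, breakdown, 1.0, Region.NUCLEUS)
    assert len(frame) == len(pop)
    assert np.allclose(
        frame["dose_total_N_gy"],
        frame["dose_self_N_gy"] + frame["dose_cross_N_gy"],
    )
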