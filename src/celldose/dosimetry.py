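"""From activities to decays to per-cell absorbed-dose breakdowns.

The number of decays in cell k is the time-integrated activity
``A_k * tau * 3600`` with ``tau`` in hours; for pure physical decay
``tau = T_p / ln 2``.  Doses are then linear bookkeeping over the
precomputed S table:

    D_self(T_k <- region) = f_region * decays_k * S_self(T <- region)
    D_cross(T_k)          = sum_{j != k} f_region * decays_j * S(T <- region_j, d_kj)

resolved by radiation type, source region and self/cross, for every target
region.  Cross sums run over the exact finite set of realized lattice
distances; pairs beyond the particle range plus two cell radii contribute
exactly zero and are skipped.  Accumulation order is fixed by the (z, y, x)
cell ordering so totals are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import ICode, RadiationSpectrum
from .geometry import Population
from .labeling import SubcellularDistribution
from .scoeff import CellModel, Region, SCoefficientSet, s_table
from .transport import KernelSet, default_models

TARGETS = (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM)


def tau_physical_hours(half_life_s: float) -> float:
    """Time-integrated activity coefficient T_p / ln 2, in hours."""
    if half_life_s <= 0:
        raise ValueError("half-life must be > 0")
    return half_life_s / 3600.0 / np.log(2.0)


def decays_per_cell(activity_bq, tau_hours: float):
    """Expected number of decays: activity x tau, hours converted to seconds."""
    activity = np.asarray(activity_bq, dtype=float)
    if np.any(activity < 0) or tau_hours <= 0:
        raise ValueError("activity must be >= 0 and tau > 0")
    out = activity * tau_hours * 3600.0
    return out if out.ndim else float(out)


#: dose-component key: (target, icode, source region, "self" | "cross")
ComponentKey = tuple[Region, ICode, Region, str]


@dataclass
class DoseBreakdown:
    """Per-cell absorbed doses resolved by target, radiation type, source
    region and self/cross.  All arrays share the population's cell order."""

    n_cells: int
    components: dict[ComponentKey, np.ndarray] = field(default_factory=dict)

    def add(self, key: ComponentKey, doses: np.ndarray) -> None:
        if key in self.components:
            self.components[key] = self.components[key] + doses
        else:
            self.components[key] = np.asarray(doses, dtype=float)

    def total(self, target: Region, kind: str | None = None) -> np.ndarray:
        """Summed dose to a target region; ``kind`` restricts to self/cross."""
        out = np.zeros(self.n_cells)
        for (tgt, _icode, _src, sc), d in self.components.items():
            if tgt is target and (kind is None or sc == kind):
                out = out + d
        return out

    def keys_for(self, target: Region) -> list[ComponentKey]:
        return [k for k in self.components if k[0] is target]


def realized_distances(pop: Population, cutoff_um: float | None = None) -> np.ndarray:
    """Distinct center-to-center distances from any cell to any labeled
    cell, optionally clipped at a transport cutoff."""
    labeled = pop.centers[pop.labeled]
    if len(labeled) == 0:
        return np.array([])
    d2 = set()
    block = 512
    for lo in range(0, len(pop), block):
        diff = pop.centers[lo : lo + block, None, :] - labeled[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        d2.update(np.unique(np.round(dist2, 4)).tolist())
    d = np.sqrt(np.sort(np.array(list(d2))))
    d = d[d > 1e-6]
    if cutoff_um is not None:
        d = d[d <= cutoff_um]
    return d


def max_transport_cutoff(spectrum: RadiationSpectrum, cell: CellModel, models: KernelSet) -> float:
    """Largest distance at which any emission can still deposit energy."""
    best = 0.0
    for line in spectrum.dosimetric_lines:
        model = models.model_for(line.icode)
        best = max(best, model.range_um(line.energy_mev))
    return best + 2.0 * cell.r_cell_um


def compute_doses(
    pop: Population,
    spectrum: RadiationSpectrum,
    subcell: SubcellularDistribution,
    tau_hours: float,
    models: KernelSet | None = None,
    table: SCoefficientSet | None = None,
    targets: tuple[Region, ...] = TARGETS,
) -> tuple[DoseBreakdown, SCoefficientSet]:
    """Per-cell dose breakdown for the population's current activities.

    The S table is built for exactly the realized lattice distances (or a
    precomputed one may be passed in); a missing distance is a hard error
    rather than an interpolation.
    """
    models = models or default_models()
    cell = pop.spec.cell
    decays = decays_per_cell(pop.activity_bq, tau_hours)
    sources = [reg for reg, _f in subcell.items()]

    cutoff = max_transport_cutoff(spectrum, cell, models)
    if table is None:
        dists = realized_distances(pop, cutoff)
        table = s_table(spectrum, cell, dists, sources=sources, targets=targets, models=models)

    breakdown = DoseBreakdown(n_cells=len(pop))
    labeled_idx = np.flatnonzero(pop.labeled)
    # pairwise distances to labeled cells, quantized onto the table grid
    if labeled_idx.size:
        diff = pop.centers[:, None, :] - pop.centers[None, labeled_idx, :]
        dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    for target in targets:
        for source, f_region in subcell.items():
            for icode in spectrum.icodes():
                key_self = table.self_s.get((target, source, icode))
                if key_self is None:
                    continue
                breakdown.add(
                    (target, icode, source, "self"), f_region * decays * key_self
                )
                if labeled_idx.size == 0 or len(table.distances) == 0:
                    continue
                svals = table.cross_s[(target, source, icode)]
                # map each realized pair distance onto the table, exact match
                in_range = (dmat > 1e-6) & (dmat <= cutoff)
                idx = np.searchsorted(table.distances, dmat[in_range] - 1e-5)
                if idx.size and (
                    np.any(idx >= len(table.distances))
                    or np.any(np.abs(table.distances[idx] - dmat[in_range]) > 1e-3)
                ):
                    raise KeyError("pair distance missing from the precomputed S table")
                smat = np.zeros_like(dmat)
                smat[in_range] = svals[idx]
                breakdown.add(
                    (target, icode, source, "cross"),
                    f_region * (smat @ decays[labeled_idx]),
                )
    return breakdown, table


def per_cell_table(
    pop: Population, breakdown: DoseBreakdown, tau_hours: float, target: Region
) -> pd.DataFrame:
    """The granular per-cell dump: position, labeling, activity, decays,
    self/cross/total dose to the chosen target, plus per-icode subtotals."""
    decays = decays_per_cell(pop.activity_bq, tau_hours)
    d_self = breakdown.total(target, "self")
    d_cross = breakdown.total(target, "cross")
    frame = pd.DataFrame(
        {
            "index": np.arange(len(pop)),
            "x_um": pop.centers[:, 0],
            "y_um": pop.centers[:, 1],
            "z_um": pop.centers[:, 2],
            "radius_um": pop.radii,
            "eligible": pop.eligible.astype(int),
            "labeled": pop.labeled.astype(int),
            "alive": pop.alive.astype(int),
            "activity_bq": pop.activity_bq,
            "decays": decays,
            f"dose_self_{target.value}_gy": d_self,
            f"dose_cross_{target.value}_gy": d_cross,
            f"dose_total_{target.value}_gy": d_self + d_cross,
        }
    )
    icodes = sorted({k[1] for k in breakdown.keys_for(target)}, key=lambda c: c.value)
    for icode in icodes:
        sub = np.zeros(len(pop))
        for (tgt, code, _src, _sc), d in breakdown.components.items():
            if tgt is target and code is icode:
                sub = sub + d
        frame[f"dose_{icode.value}_{target.value}_gy"] = sub
    return frame


def radial_summary(
    pop: Population,
    breakdown: DoseBreakdown,
    tau_hours: float,
    bin_width_um: float,
    target: Region = Region.NUCLEUS,
) -> pd.DataFrame:
    """Radial histogram of the six standard per-bin statistics.

    One row per radial bin from the cluster center: mean activity per
    labeled cell, mean self-dose to labeled cells, mean cross-dose to
    labeled cells, mean cross-dose to unlabeled cells, mean decays per
    labeled cell, and mean dose to all cells.  Bins with no qualifying
    cells report NaN (empty), not zero.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be > 0")
    if pop.spec.shape.dimensionality != 3:
        raise ValueError("radial summaries need a 3-D population")
    radii = pop.radii
    decays = decays_per_cell(pop.activity_bq, tau_hours)
    d_self = breakdown.total(target, "self")
    d_cross = breakdown.total(target, "cross")
    d_tot = d_self + d_cross
    n_bins = int(np.floor(radii.max() / bin_width_um)) + 1
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_width_um, (b + 1) * bin_width_um
        sel = (radii >= lo) & (radii < hi)
        lab = sel & pop.labeled
        unl = sel & ~pop.labeled

        def mean(mask, values):
            return float(values[mask].mean()) if np.any(mask) else np.nan

        rows.append(
            {
                "r_lo_um": lo,
                "r_hi_um": hi,
                "n_cells": int(sel.sum()),
                "n_labeled": int(lab.sum()),
                "mean_activity_labeled_bq": mean(lab, pop.activity_bq),
                "mean_self_dose_labeled_gy": mean(lab, d_self),
                "mean_cross_dose_labeled_gy": mean(lab, d_cross),
                "mean_cross_dose_unlabeled_gy": mean(unl, d_cross),
                "mean_decays_labeled": mean(lab, decays),
                "mean_dose_all_gy": mean(sel, d_tot),
            }
        )
    return pd.DataFrame(rows)
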