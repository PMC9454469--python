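"""Radiolabeling: which cells carry activity, and how much.

Labeled cells are drawn uniformly at random from the penetration-eligible
subset.  Initial activities then come either from a random distribution
(uniform, truncated normal, or a mean-preserving lognormal) or from a radial
profile of mean activity versus distance from the cluster center (linear,
exponential, polynomial up to degree 10, 4-parameter lognormal, or a
user-supplied table).  Radial profiles fix the *shape* of the activity
distribution; its scale is set so that the mean initial activity per cell,
averaged over ALL cells in the cluster, equals ``max_mean_activity_bq`` —
the same quantity that tops the activity sweep.  Because the total activity
is thereby fixed, the choice of radial profile has little effect when only
a thin surface layer is labeled.  Every cell shares one subcellular split
of its activity among nucleus, cytoplasm and cell surface.

The lognormal sampler uses ``ln A ~ Normal(ln<A> - sigma^2/2, sigma^2)`` so
that the distribution mean equals ``<A>`` for every shape parameter.  The
normal sampler redraws negative values (rejection); the induced upward mean
shift is negligible for sigma well below the mean and is documented in the
methods note.

Randomness is organized as named substreams of one master seed, so changing
the activity distribution never scrambles the labeled-subset selection.
"""

from __future__ import annotations

import csv
import enum
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Population, Shape


def substream(master_seed: int, *tags: str) -> np.random.Generator:
    """Independent, reproducible generator for a named purpose."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *keys]))


class LabelingMethod(enum.Enum):
    UNIFORM = "uniform"
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    RADIAL_LINEAR = "radial_linear"
    RADIAL_EXPONENTIAL = "radial_exponential"
    RADIAL_POLYNOMIAL = "radial_polynomial"
    RADIAL_LOGNORMAL4 = "radial_lognormal4"
    RADIAL_USER_TABLE = "radial_user_table"

    @property
    def is_radial(self) -> bool:
        return self.value.startswith("radial_")


@dataclass(frozen=True)
class SubcellularDistribution:
    """Fractions of cell activity in nucleus, cytoplasm and on the surface."""

    f_nucleus: float = 0.0
    f_cytoplasm: float = 0.0
    f_surface: float = 1.0

    def __post_init__(self) -> None:
        fs = (self.f_nucleus, self.f_cytoplasm, self.f_surface)
        if any(not 0.0 <= f <= 1.0 for f in fs):
            raise ValueError("subcellular fractions must lie in [0, 1]")
        if abs(sum(fs) - 1.0) > 1e-9:
            raise ValueError("subcellular fractions must sum to 1")

    def items(self):
        from .scoeff import Region

        pairs = [
            (Region.NUCLEUS, self.f_nucleus),
            (Region.CYTOPLASM, self.f_cytoplasm),
            (Region.CELL_SURFACE, self.f_surface),
        ]
        return [(reg, f) for reg, f in pairs if f > 0.0]


@dataclass(frozen=True)
class ActivityDistributionSpec:
    """How initial activity is distributed among the labeled cells."""

    method: LabelingMethod | str = LabelingMethod.UNIFORM
    percent_labeled: float = 100.0
    #: mean initial activity per labeled cell for the random methods (Bq)
    mean_activity_bq: float = 0.0
    #: SD (normal, Bq) or lognormal shape parameter (dimensionless)
    sigma: float = 0.0
    #: coefficients for the radial methods (see :func:`radial_profile`)
    radial_params: tuple[float, ...] = ()
    #: path of a ``radius_um,relative_activity`` table (radial_user_table)
    radial_table: str | None = None
    #: mean activity per cell over ALL cells for the radial methods — the
    #: quantity that tops the activity sweep (Bq)
    max_mean_activity_bq: float = 0.0

    def __post_init__(self) -> None:
        method = (
            self.method
            if isinstance(self.method, LabelingMethod)
            else LabelingMethod(self.method)
        )
        object.__setattr__(self, "method", method)
        if not 0.0 < self.percent_labeled <= 100.0:
            raise ValueError("percent_labeled must lie in (0, 100]")
        if method in (LabelingMethod.NORMAL, LabelingMethod.LOGNORMAL) and self.sigma <= 0:
            raise ValueError(f"{method.value} labeling needs sigma > 0")


def select_labeled(
    pop: Population, percent_labeled: float, seed: int
) -> Population:
    """Randomly label ``percent_labeled`` % of all cells among the eligible.

    The requested count is ``round(percent * n_cells / 100)``.  If it
    exceeds the eligible count the selection is clamped to all eligible
    cells with a warning, mirroring the interactive tool's behavior when a
    drug-penetration depth excludes part of the cluster.
    """
    if not 0.0 < percent_labeled <= 100.0:
        raise ValueError("percent_labeled must lie in (0, 100]")
    eligible_idx = np.flatnonzero(pop.eligible)
    if eligible_idx.size == 0:
        raise ValueError("no cells are eligible for labeling (penetration depth 0?)")
    requested = int(round(percent_labeled * len(pop) / 100.0))
    requested = max(requested, 1)
    if requested > eligible_idx.size:
        warnings.warn(
            f"requested {requested} labeled cells but only {eligible_idx.size} "
            "lie within the drug-penetration depth; labeling all eligible cells",
            stacklevel=2,
        )
        chosen = eligible_idx
    else:
        rng = substream(seed, "label-selection")
        chosen = rng.choice(eligible_idx, size=requested, replace=False)
    pop.labeled = np.zeros(len(pop), dtype=bool)
    pop.labeled[chosen] = True
    return pop


def sample_activities(
    method: LabelingMethod | str,
    mean_bq: float,
    sigma: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` initial activities (Bq) from a random labeling method."""
    method = method if isinstance(method, LabelingMethod) else LabelingMethod(method)
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_bq < 0:
        raise ValueError("mean activity must be >= 0")
    if method is LabelingMethod.UNIFORM:
        return np.full(n, float(mean_bq))
    if method is LabelingMethod.NORMAL:
        if sigma <= 0:
            raise ValueError("normal labeling needs sigma > 0")
        out = rng.normal(mean_bq, sigma, size=n)
        bad = out <= 0
        while np.any(bad):  # rejection: activities are strictly positive
            out[bad] = rng.normal(mean_bq, sigma, size=int(bad.sum()))
            bad = out <= 0
        return out
    if method is LabelingMethod.LOGNORMAL:
        if sigma <= 0:
            raise ValueError("lognormal labeling needs sigma > 0")
        if mean_bq <= 0:
            raise ValueError("lognormal labeling needs a positive mean")
        mu = np.log(mean_bq) - 0.5 * sigma**2
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    raise ValueError(f"{method.value} is not a random sampling method")


def _read_radial_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    radii, rel = [], []
    with Path(path).open(newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#") or row[0].strip() == "radius_um":
                continue
            radii.append(float(row[0]))
            rel.append(float(row[1]))
    if len(radii) < 2:
        raise ValueError(f"radial table {path}: need at least two rows")
    r = np.asarray(radii)
    if np.any(np.diff(r) <= 0):
        raise ValueError(f"radial table {path}: radii must increase")
    return r, np.asarray(rel)


def radial_profile(spec: ActivityDistributionSpec):
    """Relative mean activity versus distance r (um) from the cluster center.

    * linear       — params (a, b): a + b r
    * exponential  — params (k,): exp(k r); with the hottest-cell
      normalization this is activity maximal at the labeled surface and
      decaying inward for k > 0, the antibody-from-outside convention
    * polynomial   — params (c0 .. c10): sum c_i r^i
    * lognormal4   — params (a, b, c, s): a exp(-(ln((r-c)/b))^2 / (2 s^2))
      for r > c, else 0
    * user table   — linear interpolation, constant beyond the table ends
    """
    method = spec.method
    p = spec.radial_params
    if method is LabelingMethod.RADIAL_LINEAR:
        if len(p) != 2:
            raise ValueError("radial_linear needs params (intercept, slope)")
        return lambda r: p[0] + p[1] * np.asarray(r, dtype=float)
    if method is LabelingMethod.RADIAL_EXPONENTIAL:
        if len(p) != 1:
            raise ValueError("radial_exponential needs params (factor,)")
        return lambda r: np.exp(p[0] * np.asarray(r, dtype=float))
    if method is LabelingMethod.RADIAL_POLYNOMIAL:
        if not 1 <= len(p) <= 11:
            raise ValueError("radial_polynomial supports degree 0..10")
        return lambda r: np.polynomial.polynomial.polyval(np.asarray(r, dtype=float), p)
    if method is LabelingMethod.RADIAL_LOGNORMAL4:
        if len(p) != 4:
            raise ValueError("radial_lognormal4 needs params (a, b, c, s)")
        a, b, c, s = p

        def lognormal4(r):
            r = np.asarray(r, dtype=float)
            out = np.zeros_like(r)
            ok = r > c
            out[ok] = a * np.exp(-np.log((r[ok] - c) / b) ** 2 / (2.0 * s**2))
            return out

        return lognormal4
    if method is LabelingMethod.RADIAL_USER_TABLE:
        if spec.radial_table is None:
            raise ValueError("radial_user_table needs a table path")
        radii, rel = _read_radial_table(spec.radial_table)
        return lambda r: np.interp(np.asarray(r, dtype=float), radii, rel)
    raise ValueError(f"{method.value} is not a radial method")


def assign(
    pop: Population,
    spec: ActivityDistributionSpec,
    subcell: SubcellularDistribution,
    seed: int,
) -> Population:
    """Assign initial activities to the labeled cells.

    Radial methods evaluate the profile at each labeled cell's radius and
    rescale so the mean activity per cell over the whole cluster equals
    ``max_mean_activity_bq``; random methods draw from the requested
    distribution with mean ``mean_activity_bq`` per labeled cell.
    Unlabeled cells carry zero.  The subcellular split is recorded on the
    population.
    """
    labeled_idx = np.flatnonzero(pop.labeled)
    if labeled_idx.size == 0:
        raise ValueError("no labeled cells; run select_labeled first")
    method = spec.method
    activities = np.zeros(len(pop))
    if method.is_radial:
        if pop.spec.shape is Shape.ELLIPSOID:
            raise ValueError(
                "radial activity distributions are not available for the "
                "ellipsoid cluster; use uniform, normal or lognormal"
            )
        if method is LabelingMethod.RADIAL_USER_TABLE and pop.spec.shape is not Shape.SPHERE:
            raise ValueError("user radial tables are available only for spherical clusters")
        profile = radial_profile(spec)
        rel = np.asarray(profile(pop.radii[labeled_idx]), dtype=float)
        if np.any(rel < 0):
            raise ValueError("radial profile is negative at a labeled cell radius")
        total = rel.sum()
        if total <= 0:
            raise ValueError("radial profile vanishes on every labeled cell")
        # mean over ALL cells equals the knob; the profile sets the shape
        activities[labeled_idx] = spec.max_mean_activity_bq * len(pop) * rel / total
    else:
        rng = substream(seed, "activity-sampling")
        activities[labeled_idx] = sample_activities(
            method, spec.mean_activity_bq, spec.sigma, labeled_idx.size, rng
        )
    pop.activity_bq = activities
    pop.subcellular = subcell
    return pop
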