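"""Cellular self- and cross-dose S coefficients for concentric-sphere cells.

The cell is two concentric spheres (cell radius ``r_cell``, nucleus radius
``r_nucleus``) of unit-density water.  Source regions are the whole cell (C),
nucleus (N), cytoplasm (Cy) and cell surface (CS); target regions are C, N
and Cy.  The S coefficient is

    S(target <- source) = sum_lines  Delta_line * phi_line / m(target),

in Gy per decay, where ``Delta`` is the mean energy emitted per nuclear
transition of the line and ``phi`` the absorbed fraction.  Photon lines
contribute nothing.

Absorbed fractions are computed by a two-level Gauss-Legendre quadrature:
the source region is reduced to the probability density of the distance
``rho`` between emission point and the *target-sphere center* (a closed-form
pair-distance density for every region/geometry), and for each ``rho`` the
expected energy deposited in the target sphere is the direction average of
residual-energy differences at the chord entry and exit points (exact under
straight-line CSDA).  Cytoplasm targets are evaluated as cell minus nucleus,
which makes the energy partition C = N + Cy exact by construction.
"""

from __future__ import annotations

import enum
import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import ICode, RadiationSpectrum
from .transport import GY_G_PER_MEV, KernelSet, RangeEnergyModel, default_models

RHO_G_PER_UM3 = 1e-12  # unit-density water

_N_MU = 256  # direction nodes per distance
_N_RHO = 48  # distance nodes per smooth segment


class Region(enum.Enum):
    CELL = "C"
    NUCLEUS = "N"
    CYTOPLASM = "Cy"
    CELL_SURFACE = "CS"


SOURCE_REGIONS = (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM, Region.CELL_SURFACE)
TARGET_REGIONS = (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM)


def parse_region(token: str | Region) -> Region:
    if isinstance(token, Region):
        return token
    for reg in Region:
        if token.strip().lower() in (reg.value.lower(), reg.name.lower()):
            return reg
    raise ValueError(f"unknown region token {token!r}")


@dataclass(frozen=True)
class CellModel:
    """Concentric-sphere cell: radii in micrometers, unit-density water."""

    r_cell_um: float
    r_nucleus_um: float

    def __post_init__(self) -> None:
        if not 0 < self.r_nucleus_um <= self.r_cell_um:
            raise ValueError("require 0 < r_nucleus <= r_cell")
        if self.r_cell_um > 10.0:
            warnings.warn(
                "cell radius exceeds 10 um; the concentric-sphere model has "
                "been exercised mainly for smaller cells",
                stacklevel=2,
            )

    def volume_um3(self, region: Region) -> float:
        vc = 4.0 / 3.0 * np.pi * self.r_cell_um**3
        vn = 4.0 / 3.0 * np.pi * self.r_nucleus_um**3
        if region is Region.CELL:
            return vc
        if region is Region.NUCLEUS:
            return vn
        if region is Region.CYTOPLASM:
            return vc - vn
        raise ValueError(f"{region} has no volume")

    def mass_g(self, region: Region) -> float:
        return self.volume_um3(region) * RHO_G_PER_UM3


# ---------------------------------------------------------------------------
# point-source absorbed fraction in a sphere
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=8)
def _gl(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _phi_point(
    model: RangeEnergyModel, e0: float, rt: float, rho: np.ndarray, n_mu: int = _N_MU
) -> np.ndarray:
    """Fraction of ``e0`` deposited in a sphere of radius ``rt`` centered at
    the origin, for an isotropic point source at distance ``rho`` (array).

    The direction average is Gauss-Legendre over the direction cosine mu.
    The integrand has a kink where the path length to the sphere boundary
    equals the particle range L; that direction satisfies
    ``mu_L = (rt^2 - rho^2 - L^2) / (2 L rho)`` (both chord roots obey the
    same linear-in-mu equation), so each row is integrated over two
    segments split at mu_L, clamped into the admissible interval.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    phi = np.zeros_like(rho)
    x, w = _gl(n_mu // 2)
    L = model.range_um(e0)

    def two_segment(rr, a, b, mid, exterior):
        """Integrate the deposit over mu on [a, mid] + [mid, b] per row."""
        total = np.zeros(rr.shape[0])
        for lo, hi in ((a, mid), (mid, b)):
            mu = 0.5 * (lo + hi) + 0.5 * (hi - lo) * x[None, :]
            jac = 0.5 * (hi - lo) * w[None, :]
            disc = np.sqrt(np.maximum(rt**2 - rr**2 * (1.0 - mu**2), 0.0))
            t_out = np.maximum(-rr * mu + disc, 0.0)
            if exterior:
                t_in = np.maximum(-rr * mu - disc, 0.0)
                dep = model.residual_energy(e0, t_in) - model.residual_energy(e0, t_out)
            else:
                dep = e0 - model.residual_energy(e0, t_out)
            total += np.sum(dep * jac, axis=1)
        return total / (2.0 * e0)

    inside = rho <= rt
    if np.any(inside):
        rr = rho[inside][:, None]
        mu_l = np.clip((rt**2 - rr**2 - L**2) / (2.0 * L * rr), -1.0, 1.0)
        a = np.full_like(rr, -1.0)
        b = np.ones_like(rr)
        phi[inside] = two_segment(rr, a, b, mu_l, exterior=False)

    outside = ~inside
    if np.any(outside):
        rr = rho[outside][:, None]
        mu_star = np.sqrt(1.0 - (rt / rr) ** 2)
        a = np.full_like(rr, -1.0)
        b_full = -mu_star
        mu_l = (rt**2 - rr**2 - L**2) / (2.0 * L * rr)
        graze = np.sqrt(np.maximum(rr**2 - rt**2, 0.0))
        # if the particle stops before the grazing chord, directions beyond
        # mu_L deposit nothing: shrink the interval instead of splitting
        b = np.where(L < graze, np.clip(mu_l, a, b_full), b_full)
        mid = np.clip(mu_l, a, b)
        phi[outside] = two_segment(rr, a, b, mid, exterior=True)
    return phi


# ---------------------------------------------------------------------------
# source-region distance densities
# ---------------------------------------------------------------------------


def _nodes_on(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = _gl(n)
    return 0.5 * (a + b) + 0.5 * (b - a) * x, 0.5 * (b - a) * w


def _self_nodes(
    cell: CellModel, source: Region, rt: float, n_rho: int = _N_RHO, rho_max: float = np.inf
) -> tuple[np.ndarray, np.ndarray]:
    """Distance nodes/weights (pdf folded in) from the shared cell center.

    ``rho_max`` clips the integration to source points that can reach the
    target sphere at all (distance <= particle range + target radius);
    beyond it the absorbed fraction is identically zero, so dropping that
    mass concentrates nodes where the integrand lives.
    """
    rc, rn = cell.r_cell_um, cell.r_nucleus_um
    if source is Region.CELL_SURFACE:
        if rc > rho_max:
            return np.array([rc]), np.array([0.0])
        return np.array([rc]), np.array([1.0])
    bounds = {
        Region.NUCLEUS: (0.0, rn),
        Region.CYTOPLASM: (rn, rc),
        Region.CELL: (0.0, rc),
    }[source]
    a, b = bounds
    b_eff = min(b, rho_max)
    if b_eff <= a:
        return np.array([a]), np.array([0.0])
    edges = sorted({a, b_eff} | ({rt} if a < rt < b_eff else set()))
    nodes, weights = [], []
    norm = b**3 - a**3
    for lo, hi in zip(edges[:-1], edges[1:]):
        s, w = _nodes_on(lo, hi, n_rho)
        nodes.append(s)
        weights.append(w * 3.0 * s**2 / norm)
    return np.concatenate(nodes), np.concatenate(weights)


def _cross_nodes(
    cell: CellModel,
    source: Region,
    d: np.ndarray,
    n_rho: int = _N_RHO,
    rho_max: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance nodes/weights from the *target* cell center to emission
    points in the source region of a cell centered ``d`` away.

    Returns arrays of shape (len(d), n_nodes); cytoplasm sources use a
    signed combination of the cell- and nucleus-sphere densities.
    ``rho_max`` clips to emission points able to reach the target sphere.
    """
    d = np.asarray(d, dtype=float)[:, None]
    rc, rn = cell.r_cell_um, cell.r_nucleus_um
    x, w = _gl(n_rho)

    def clipped(lo, hi):
        hi = np.minimum(hi, rho_max)
        dead = (hi <= lo)
        hi = np.where(dead, lo + 1.0, hi)  # dummy interval, weight zeroed below
        s = 0.5 * (lo + hi) + 0.5 * (hi - lo) * x[None, :]
        jac = 0.5 * (hi - lo) * w[None, :] * ~dead
        return s, jac

    def sphere_volume(rs: float) -> tuple[np.ndarray, np.ndarray]:
        s, jac = clipped(d - rs, d + rs)
        pdf = 3.0 * s * (rs**2 - (d - s) ** 2) / (4.0 * d * rs**3)
        return s, jac * pdf

    if source is Region.CELL_SURFACE:
        s, jac = clipped(d - rc, d + rc)
        return s, jac * s / (2.0 * d * rc)
    if source is Region.CELL:
        return sphere_volume(rc)
    if source is Region.NUCLEUS:
        return sphere_volume(rn)
    if source is Region.CYTOPLASM:
        vc, vn = cell.volume_um3(Region.CELL), cell.volume_um3(Region.NUCLEUS)
        s_c, w_c = sphere_volume(rc)
        s_n, w_n = sphere_volume(rn)
        s = np.concatenate([s_c, s_n], axis=1)
        wts = np.concatenate([w_c * vc / (vc - vn), -w_n * vn / (vc - vn)], axis=1)
        return s, wts
    raise ValueError(f"invalid source region {source}")


def _target_radius(cell: CellModel, target: Region) -> float:
    if target is Region.CELL:
        return cell.r_cell_um
    if target is Region.NUCLEUS:
        return cell.r_nucleus_um
    raise ValueError(f"{target} is not a spherical target")


def _source_extent(cell: CellModel, source: Region) -> float:
    return cell.r_nucleus_um if source is Region.NUCLEUS else cell.r_cell_um


# ---------------------------------------------------------------------------
# absorbed fractions and S coefficients
# ---------------------------------------------------------------------------


def absorbed_fraction(
    model: RangeEnergyModel,
    e0: float,
    cell: CellModel,
    source: Region | str,
    target: Region | str,
    d: float | None = None,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> float:
    """Absorbed fraction phi(target <- source) for a single emission energy.

    ``d`` is the center-to-center distance to the source cell; ``None``
    means self-irradiation (source and target in the same cell).
    """
    source, target = parse_region(source), parse_region(target)
    if target is Region.CYTOPLASM:
        return absorbed_fraction(
            model, e0, cell, source, Region.CELL, d, n_rho, n_mu
        ) - absorbed_fraction(model, e0, cell, source, Region.NUCLEUS, d, n_rho, n_mu)
    rt = _target_radius(cell, target)
    if d is None:
        rho_max = model.range_um(e0) + rt
        nodes, weights = _self_nodes(cell, source, rt, n_rho, rho_max)
        return float(_phi_point(model, e0, rt, nodes, n_mu) @ weights)
    phis = _phi_cross_batch(model, e0, cell, source, rt, np.array([d]), n_rho, n_mu)
    return float(phis[0])


def _phi_cross_batch(
    model: RangeEnergyModel,
    e0: float,
    cell: CellModel,
    source: Region,
    rt: float,
    distances: np.ndarray,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> np.ndarray:
    """phi(target sphere radius rt <- source region at distances d), batched."""
    distances = np.asarray(distances, dtype=float)
    phis = np.zeros_like(distances)
    particle_range = model.range_um(e0)
    cutoff = particle_range + _source_extent(cell, source) + rt
    active = distances <= cutoff
    if not np.any(active):
        return phis
    s, wts = _cross_nodes(cell, source, distances[active], n_rho, particle_range + rt)
    flat = _phi_point(model, e0, rt, s.ravel(), n_mu).reshape(s.shape)
    phis[active] = np.sum(flat * wts, axis=1)
    return phis


def _lines_by_icode(spectrum: RadiationSpectrum):
    groups: dict[ICode, list] = {}
    for ln in spectrum.dosimetric_lines:
        groups.setdefault(ln.icode, []).append(ln)
    return groups


def self_s(
    spectrum: RadiationSpectrum,
    cell: CellModel,
    source: Region | str,
    target: Region | str,
    models: KernelSet | None = None,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> dict[ICode, float]:
    """Self S coefficients (Gy per decay), per radiation type."""
    models = models or default_models()
    source, target = parse_region(source), parse_region(target)
    if target not in TARGET_REGIONS:
        raise ValueError(f"{target} is not a valid target region")
    mass = cell.mass_g(target)
    out: dict[ICode, float] = {}
    for icode, lines in _lines_by_icode(spectrum).items():
        model = models.model_for(icode)
        s_val = sum(
            ln.delta_mev
            * absorbed_fraction(model, ln.energy_mev, cell, source, target, None, n_rho, n_mu)
            for ln in lines
        )
        out[icode] = s_val * GY_G_PER_MEV / mass
    return out


def cross_s(
    spectrum: RadiationSpectrum,
    cell: CellModel,
    d: float,
    source: Region | str,
    target: Region | str,
    models: KernelSet | None = None,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> dict[ICode, float]:
    """Cross S coefficients at center-to-center distance ``d`` (equal cells)."""
    if d < 2.0 * cell.r_cell_um - 1e-9:
        raise ValueError("cells overlap: require d >= 2 r_cell")
    table = cross_s_batch(spectrum, cell, np.array([d]), source, target, models, n_rho, n_mu)
    return {icode: float(vals[0]) for icode, vals in table.items()}


def cross_s_batch(
    spectrum: RadiationSpectrum,
    cell: CellModel,
    distances: np.ndarray,
    source: Region | str,
    target: Region | str,
    models: KernelSet | None = None,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> dict[ICode, np.ndarray]:
    """Cross S coefficients for a whole set of distances at once."""
    models = models or default_models()
    source, target = parse_region(source), parse_region(target)
    if target not in TARGET_REGIONS:
        raise ValueError(f"{target} is not a valid target region")
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 2.0 * cell.r_cell_um - 1e-9):
        raise ValueError("cells overlap: require d >= 2 r_cell")
    mass = cell.mass_g(target)
    out: dict[ICode, np.ndarray] = {}
    for icode, lines in _lines_by_icode(spectrum).items():
        model = models.model_for(icode)
        acc = np.zeros_like(distances)
        for ln in lines:
            if target is Region.CYTOPLASM:
                phi = _phi_cross_batch(
                    model, ln.energy_mev, cell, source, cell.r_cell_um, distances, n_rho, n_mu
                ) - _phi_cross_batch(
                    model, ln.energy_mev, cell, source, cell.r_nucleus_um, distances, n_rho, n_mu
                )
            else:
                phi = _phi_cross_batch(
                    model,
                    ln.energy_mev,
                    cell,
                    source,
                    _target_radius(cell, target),
                    distances,
                    n_rho,
                    n_mu,
                )
            acc += ln.delta_mev * phi
        out[icode] = acc * GY_G_PER_MEV / mass
    return out


# ---------------------------------------------------------------------------
# cached table over the realized lattice distances
# ---------------------------------------------------------------------------


@dataclass
class SCoefficientSet:
    """Self S plus cross S over the finite set of realized distances.

    Lookups are exact: the distances are the ones the lattice actually
    produces, so no interpolation is ever performed.
    """

    cell: CellModel
    distances: np.ndarray
    self_s: dict[tuple[Region, Region, ICode], float] = field(default_factory=dict)
    cross_s: dict[tuple[Region, Region, ICode], np.ndarray] = field(default_factory=dict)

    def cross_index(self, d: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.distances, np.asarray(d) - 1e-6)
        if np.any(idx >= len(self.distances)) or np.any(
            np.abs(self.distances[np.minimum(idx, len(self.distances) - 1)] - d) > 1e-5
        ):
            raise KeyError("distance not present in the precomputed S table")
        return idx

    def lookup_cross(self, target, source, icode: ICode, d) -> np.ndarray:
        vals = self.cross_s[(parse_region(target), parse_region(source), icode)]
        return vals[self.cross_index(np.atleast_1d(np.asarray(d, dtype=float)))]

    def to_dataframe(self) -> pd.DataFrame:
        """Output-tab style table: self row first, then one row per distance;
        one column per (target <- source, icode) combination."""
        cols: dict[str, list[float]] = {}
        keys = sorted(
            set(self.self_s) | set(self.cross_s),
            key=lambda k: (k[0].value, k[1].value, k[2].value),
        )
        for key in keys:
            target, source, icode = key
            name = f"S({target.value}<-{source.value})[{icode.value}]"
            col = [self.self_s.get(key, np.nan)]
            cross = self.cross_s.get(key)
            if cross is None:
                col.extend([np.nan] * len(self.distances))
            else:
                col.extend(list(cross))
            cols[name] = col
        index = pd.Index(
            ["self"] + [f"{d:.6g}" for d in self.distances], name="distance_um"
        )
        return pd.DataFrame(cols, index=index)


def s_table(
    spectrum: RadiationSpectrum,
    cell: CellModel,
    distances,
    sources=(Region.CELL_SURFACE,),
    targets=(Region.NUCLEUS, Region.CELL, Region.CYTOPLASM),
    models: KernelSet | None = None,
    n_rho: int = _N_RHO,
    n_mu: int = _N_MU,
) -> SCoefficientSet:
    """Precompute self and cross S for every realized lattice distance."""
    models = models or default_models()
    distances = np.unique(np.round(np.asarray(list(distances), dtype=float), 6))
    distances = distances[distances > 1e-9]
    table = SCoefficientSet(cell=cell, distances=distances)
    for source in (parse_region(s) for s in sources):
        for target in (parse_region(t) for t in targets):
            for icode, s_val in self_s(
                spectrum, cell, source, target, models, n_rho, n_mu
            ).items():
                table.self_s[(target, source, icode)] = s_val
            if len(distances):
                for icode, vals in cross_s_batch(
                    spectrum, cell, distances, source, target, models, n_rho, n_mu
                ).items():
                    table.cross_s[(target, source, icode)] = vals
    return table
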