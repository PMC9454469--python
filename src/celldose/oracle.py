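"""Brute-force Monte Carlo estimator of absorbed fractions and S coefficients.

Shares only the range-energy model with the analytic quadrature in
:mod:`celldose.scoeff`; the integration itself is independent (random decay
positions and directions, exact chord differencing of the residual-energy
profile), so agreement between the two is a genuine cross-check of the
numerical integration.

Sampling per history: a decay position uniform in the source region, an
isotropic direction, and the energy deposited in the target sphere computed
as the residual energy at the chord entry minus that at the chord exit —
exact under straight-line CSDA, free of step-size artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay import RadiationSpectrum
from .scoeff import CellModel, Region, _target_radius, parse_region
from .transport import GY_G_PER_MEV, KernelSet, default_models


@dataclass(frozen=True)
class OracleEstimate:
    """Monte Carlo S estimate with its standard error."""

    s_hat: float
    standard_error: float
    n_histories: int


def _sample_positions(
    cell: CellModel, source: Region, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions in the source region of a cell centered at the origin."""
    u = rng.random(n)
    if source is Region.CELL_SURFACE:
        r = np.full(n, cell.r_cell_um)
    elif source is Region.NUCLEUS:
        r = cell.r_nucleus_um * u ** (1.0 / 3.0)
    elif source is Region.CELL:
        r = cell.r_cell_um * u ** (1.0 / 3.0)
    elif source is Region.CYTOPLASM:
        rn3, rc3 = cell.r_nucleus_um**3, cell.r_cell_um**3
        r = (rn3 + u * (rc3 - rn3)) ** (1.0 / 3.0)
    else:
        raise ValueError(f"invalid source region {source}")
    mu = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(1.0 - mu**2)
    return np.column_stack([r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * mu])


def _isotropic(n: int, rng: np.random.Generator) -> np.ndarray:
    mu = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(1.0 - mu**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), mu])


def _deposit_in_sphere(model, e0, pos, direction, center, radius) -> np.ndarray:
    """Energy deposited inside a sphere by straight CSDA tracks."""
    rel = pos - center
    b = np.einsum("ij,ij->i", direction, rel)
    c = np.einsum("ij,ij->i", rel, rel) - radius**2
    disc = b * b - c
    dep = np.zeros(len(pos))
    hit = disc > 0
    if np.any(hit):
        root = np.sqrt(disc[hit])
        t_in = np.maximum(-b[hit] - root, 0.0)
        t_out = np.maximum(-b[hit] + root, 0.0)
        dep[hit] = model.residual_energy(e0, t_in) - model.residual_energy(e0, t_out)
    return dep


def estimate_s(
    spectrum: RadiationSpectrum,
    cell: CellModel,
    source: Region | str,
    target: Region | str,
    d: float | None = None,
    n_histories: int = 10**5,
    seed: int | np.random.Generator = 0,
    models: KernelSet | None = None,
) -> OracleEstimate:
    """Monte Carlo S coefficient (Gy per decay); ``d=None`` for self-dose.

    Each emission line is sampled with ``n_histories`` independent histories;
    line estimates are combined with their yields, standard errors in
    quadrature.
    """
    if n_histories < 10**3:
        raise ValueError("n_histories < 1000 gives meaningless error bars")
    models = models or default_models()
    source, target = parse_region(source), parse_region(target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.array([0.0, 0.0, 0.0 if d is None else float(d)])
    mass = cell.mass_g(target)

    s_hat = 0.0
    var = 0.0
    for line in spectrum.dosimetric_lines:
        model = models.model_for(line.icode)
        pos = _sample_positions(cell, source, n_histories, rng)
        direction = _isotropic(n_histories, rng)
        if target is Region.CYTOPLASM:
            dep = _deposit_in_sphere(
                model, line.energy_mev, pos, direction, center, cell.r_cell_um
            ) - _deposit_in_sphere(
                model, line.energy_mev, pos, direction, center, cell.r_nucleus_um
            )
        else:
            dep = _deposit_in_sphere(
                model, line.energy_mev, pos, direction, center, _target_radius(cell, target)
            )
        # per-history S contribution for this line
        scale = line.yield_per_decay * GY_G_PER_MEV / mass
        s_hat += scale * float(dep.mean())
        var += (scale * float(dep.std(ddof=1)) / np.sqrt(n_histories)) ** 2
    return OracleEstimate(s_hat=s_hat, standard_error=float(np.sqrt(var)), n_histories=n_histories)
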