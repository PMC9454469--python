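"""Range-energy relations and point-source dose kernels in unit-density water.

Charged-particle transport is modeled in the continuous-slowing-down
approximation (CSDA) along straight tracks: a particle of initial energy
``E0`` has a fixed range ``R(E0)``, and after traveling a path length ``x``
it retains the residual energy ``E(x) = R^-1(R(E0) - x)``.  The dose rate at
distance ``r`` from an isotropic point source is the stopping power at the
residual energy spread over the sphere of radius ``r``:

    D(r) = S(E(r)) / (4 pi r^2 rho),   rho = 1 g/cm^3.

Electrons default to the Cole empirical power law
``R[um] = 0.0431 (E[keV] + 0.367)^1.77 - 0.007``; a CSDA-table relation is
provided as a selectable alternative.  Alpha particles use a packaged
range-energy table, interpolated linearly in log-log space.  All media are
liquid water of unit density; angular scattering, straggling and delta rays
are outside the model.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .decay import ICode

#: Converts an energy density in MeV/um^3 to dose in Gy at 1 g/cm^3.
DOSE_GY_PER_MEV_PER_UM3 = 160.2176634
#: Converts (MeV deposited) / (gram) to Gy.
GY_G_PER_MEV = 1.602176634e-10


class RangeEnergyModel:
    """Base class: a strictly increasing range-energy relation R(E).

    Subclasses implement :meth:`range_um`, :meth:`energy_from_range` and
    :meth:`stopping_power`; residual energy and the point kernel follow.
    """

    particle: str = ""
    relation_name: str = ""
    #: (lo, hi) energy window in MeV inside which the relation was fitted.
    valid_energy_mev: tuple[float, float] = (0.0, np.inf)

    def range_um(self, energy_mev):
        raise NotImplementedError

    def energy_from_range(self, range_um):
        raise NotImplementedError

    def stopping_power(self, energy_mev):
        """dE/dx in MeV/um at the given energy."""
        raise NotImplementedError

    # -- derived quantities -------------------------------------------------

    def check_validity(self, energy_mev) -> None:
        lo, hi = self.valid_energy_mev
        e = np.asarray(energy_mev, dtype=float)
        if np.any((e > 0) & ((e < lo) | (e > hi))):
            warnings.warn(
                f"{self.relation_name}: energy outside the stated validity "
                f"window [{lo:g}, {hi:g}] MeV; extrapolating",
                stacklevel=2,
            )

    def csda_range(self, energy_mev):
        """Range in micrometers, with a validity-window check."""
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e <= 0):
            raise ValueError("energy must be > 0 MeV")
        self.check_validity(e)
        return self.range_um(e)

    def residual_energy(self, e0_mev, depth_um):
        """Energy remaining after a path of ``depth_um``; 0 at/beyond range."""
        depth = np.asarray(depth_um, dtype=float)
        if np.any(depth < 0):
            raise ValueError("depth must be >= 0")
        left = self.range_um(np.asarray(e0_mev, dtype=float)) - depth
        out = np.where(left > 0, self.energy_from_range(np.maximum(left, 0.0)), 0.0)
        return out if out.ndim else float(out)

    def point_dose_rate(self, e0_mev, r_um):
        """Absorbed dose in Gy per decay at distance ``r_um`` from an
        isotropic point source of a single particle of energy ``e0_mev``."""
        scalar = np.ndim(r_um) == 0
        r = np.atleast_1d(np.asarray(r_um, dtype=float))
        if np.any(r <= 0):
            raise ValueError("r must be > 0 um (the kernel is singular at r=0)")
        eres = np.atleast_1d(np.asarray(self.residual_energy(e0_mev, r)))
        dose = np.zeros_like(r)
        alive = eres > 0
        if np.any(alive):
            s = np.asarray(self.stopping_power(eres[alive]))
            dose[alive] = s / (4.0 * np.pi * r[alive] ** 2) * DOSE_GY_PER_MEV_PER_UM3
        return float(dose[0]) if scalar else dose


class ColeElectronRange(RangeEnergyModel):
    """Cole empirical electron range-energy power law in water.

    ``R[um] = 0.0431 (E[keV] + 0.367)^1.77 - 0.007``, inverted in closed
    form.  The default relation of the cellular S-coefficient literature.
    """

    particle = "electron"
    relation_name = "cole"
    valid_energy_mev = (4e-4, 10.0)

    _A = 0.0431
    _B = 0.367
    _P = 1.77
    _C = 0.007

    def range_um(self, energy_mev):
        e_kev = np.asarray(energy_mev, dtype=float) * 1e3
        r = self._A * (e_kev + self._B) ** self._P - self._C
        return r if r.ndim else float(r)

    def energy_from_range(self, range_um):
        r = np.asarray(range_um, dtype=float)
        e_kev = ((r + self._C) / self._A) ** (1.0 / self._P) - self._B
        e = np.maximum(e_kev, 0.0) * 1e-3
        return e if e.ndim else float(e)

    def stopping_power(self, energy_mev):
        e_kev = np.asarray(energy_mev, dtype=float) * 1e3
        drde_kev = self._A * self._P * (e_kev + self._B) ** (self._P - 1.0)
        s = 1e-3 / drde_kev  # MeV/um
        return s if s.ndim else float(s)


class TableRangeModel(RangeEnergyModel):
    """Range-energy relation from a packaged (energy, range) table,
    piecewise linear in log-log space; the stopping power is the exact
    derivative of the interpolant so that kernel integrals conserve energy."""

    def __init__(self, particle: str, relation_name: str, energy_mev, range_um):
        energy_mev = np.asarray(energy_mev, dtype=float)
        range_um_ = np.asarray(range_um, dtype=float)
        if energy_mev.ndim != 1 or energy_mev.size < 2:
            raise ValueError("need at least two table rows")
        if np.any(np.diff(energy_mev) <= 0) or np.any(np.diff(range_um_) <= 0):
            raise ValueError("table must be strictly increasing in E and R")
        self.particle = particle
        self.relation_name = relation_name
        self.valid_energy_mev = (float(energy_mev[0]), float(energy_mev[-1]))
        self._loge = np.log(energy_mev)
        self._logr = np.log(range_um_)
        self._slope = np.diff(self._logr) / np.diff(self._loge)

    def _segment(self, logx, knots):
        return np.clip(np.searchsorted(knots, logx, side="right") - 1, 0, len(self._slope) - 1)

    def range_um(self, energy_mev):
        loge = np.log(np.asarray(energy_mev, dtype=float))
        i = self._segment(loge, self._loge)
        logr = self._logr[i] + self._slope[i] * (loge - self._loge[i])
        r = np.exp(logr)
        return r if r.ndim else float(r)

    def energy_from_range(self, range_um):
        scalar = np.ndim(range_um) == 0
        r = np.atleast_1d(np.asarray(range_um, dtype=float))
        out = np.zeros_like(r)
        pos = r > 0
        if np.any(pos):
            logr = np.log(r[pos])
            i = self._segment(logr, self._logr)
            out[pos] = np.exp(self._loge[i] + (logr - self._logr[i]) / self._slope[i])
        return float(out[0]) if scalar else out

    def stopping_power(self, energy_mev):
        e = np.asarray(energy_mev, dtype=float)
        loge = np.log(e)
        i = self._segment(loge, self._loge)
        r = np.exp(self._logr[i] + self._slope[i] * (loge - self._loge[i]))
        s = e / (self._slope[i] * r)  # dE/dR for R = a E^b
        return s if s.ndim else float(s)


def _load_table(fname: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("celldose").joinpath("data").joinpath(fname).read_text()
    e, r = [], []
    for row in csv.reader(text.splitlines()):
        if not row or row[0].lstrip().startswith("#") or row[0].strip() == "energy_MeV":
            continue
        e.append(float(row[0]))
        r.append(float(row[1]))
    return np.asarray(e), np.asarray(r)


def alpha_range_model() -> TableRangeModel:
    """Packaged alpha range-energy table (liquid water, unit density)."""
    e, r = _load_table("alpha_range_water.csv")
    return TableRangeModel("alpha", "alpha-csda-table", e, r)


def electron_csda_model() -> TableRangeModel:
    """Alternative electron relation from a packaged CSDA range table."""
    e, r = _load_table("electron_csda_water.csv")
    return TableRangeModel("electron", "electron-csda-table", e, r)


@dataclass(frozen=True)
class KernelSet:
    """The pair of range-energy models used by all dose computations."""

    electron: RangeEnergyModel
    alpha: RangeEnergyModel

    def model_for(self, icode: ICode) -> RangeEnergyModel | None:
        """Model transporting the given radiation type; None for photons."""
        if icode.is_photon:
            return None
        if icode is ICode.ALPHA:
            return self.alpha
        return self.electron


def default_models(electron_relation: str = "cole") -> KernelSet:
    """Default kernel set: Cole electrons (or the CSDA-table alternative)
    plus the packaged alpha table."""
    if electron_relation == "cole":
        electron: RangeEnergyModel = ColeElectronRange()
    elif electron_relation in ("csda_table", "table"):
        electron = electron_csda_model()
    else:
        raise ValueError(f"unknown electron relation {electron_relation!r}")
    return KernelSet(electron=electron, alpha=alpha_range_model())
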