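"""Radiation emission data: built-in radionuclides, decay chains, user files.

A source is represented as a :class:`RadiationSpectrum`, a flat list of
:class:`EmissionLine` objects.  Each line carries a MIRD-style radiation-type
code (ICODE), a yield per parent nuclear transition, and an energy in MeV
(the mean energy for beta "average-energy" lines, the discrete energy
otherwise).  Decay chains are expanded under the assumption of secular
equilibrium: every daughter contributes its own emissions with yields scaled
by the cumulative branching fraction along the chain.

Photon lines (gamma, x-ray) are parsed and retained so the spectrum is a
faithful record of the decay scheme, but they are flagged non-dosimetric and
contribute nothing to any absorbed-dose computation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


class ICode(enum.Enum):
    """MIRD radiation-type codes resolved by the dose and bioeffect models."""

    ALPHA = "alpha"
    BETA_MINUS = "beta-"
    BETA_PLUS = "beta+"
    IC_ELECTRON = "ic"
    AUGER = "auger"
    GAMMA = "gamma"
    XRAY = "xray"

    @property
    def is_photon(self) -> bool:
        return self in (ICode.GAMMA, ICode.XRAY)

    @property
    def is_electron(self) -> bool:
        """True for every electron-like code (betas transported at their
        average energy, conversion and Auger electrons at their discrete
        energy)."""
        return self in (
            ICode.BETA_MINUS,
            ICode.BETA_PLUS,
            ICode.IC_ELECTRON,
            ICode.AUGER,
        )


_ICODE_ALIASES = {
    "alpha": ICode.ALPHA,
    "a": ICode.ALPHA,
    "beta-": ICode.BETA_MINUS,
    "beta_minus": ICode.BETA_MINUS,
    "b-": ICode.BETA_MINUS,
    "beta+": ICode.BETA_PLUS,
    "beta_plus": ICode.BETA_PLUS,
    "b+": ICode.BETA_PLUS,
    "ic": ICode.IC_ELECTRON,
    "ce": ICode.IC_ELECTRON,
    "ic_electron": ICode.IC_ELECTRON,
    "auger": ICode.AUGER,
    "gamma": ICode.GAMMA,
    "g": ICode.GAMMA,
    "xray": ICode.XRAY,
    "x": ICode.XRAY,
}


def parse_icode(token: str) -> ICode:
    try:
        return _ICODE_ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown radiation-type code {token!r}") from None


@dataclass(frozen=True)
class EmissionLine:
    """One emission: radiation type, yield per nuclear transition, energy.

    ``delta`` is the mean energy emitted per nuclear transition for this
    line (MeV per decay), the quantity the S-coefficient sum runs over.
    """

    icode: ICode
    yield_per_decay: float
    energy_mev: float

    def __post_init__(self) -> None:
        if self.yield_per_decay < 0:
            raise ValueError("yield_per_decay must be >= 0")
        if self.energy_mev <= 0:
            raise ValueError("energy must be > 0 MeV")

    @property
    def delta_mev(self) -> float:
        return self.yield_per_decay * self.energy_mev

    def scaled(self, factor: float) -> "EmissionLine":
        return EmissionLine(self.icode, self.yield_per_decay * factor, self.energy_mev)


@dataclass
class RadiationSpectrum:
    """Chain-expanded emission list for a source, plus bookkeeping."""

    lines: list[EmissionLine]
    source_name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError(f"spectrum {self.source_name!r} has no emission lines")

    def __iter__(self):
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def dosimetric_lines(self) -> list[EmissionLine]:
        """Lines that contribute to absorbed dose (photons excluded)."""
        return [ln for ln in self.lines if not ln.icode.is_photon]

    def total_delta_mev(self, icode: ICode | None = None) -> float:
        """Mean energy emitted per parent transition, optionally per ICODE."""
        return sum(
            ln.delta_mev for ln in self.lines if icode is None or ln.icode == icode
        )

    def icodes(self, dosimetric_only: bool = True) -> list[ICode]:
        seen: list[ICode] = []
        pool = self.dosimetric_lines if dosimetric_only else self.lines
        for ln in pool:
            if ln.icode not in seen:
                seen.append(ln.icode)
        return seen


@dataclass
class Radionuclide:
    """A nuclide with its own emissions and branched daughters."""

    name: str
    half_life_s: float
    emissions: list[EmissionLine] = field(default_factory=list)
    daughters: list[tuple["Radionuclide", float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("half_life must be > 0 s")
        total = sum(b for _, b in self.daughters)
        if any(not 0.0 <= b <= 1.0 for _, b in self.daughters) or total > 1.0 + 1e-9:
            raise ValueError("branching fractions must lie in [0,1] and sum to <= 1")


def make_monoenergetic(
    particle: str, energy_mev: float, yield_per_decay: float = 1.0
) -> RadiationSpectrum:
    """Single-line spectrum for a monoenergetic electron or alpha emitter."""
    if energy_mev <= 0:
        raise ValueError("energy must be > 0 MeV")
    if yield_per_decay <= 0:
        raise ValueError("yield must be > 0 per decay")
    icode = {"electron": ICode.IC_ELECTRON, "alpha": ICode.ALPHA}.get(particle)
    if icode is None:
        raise ValueError("particle must be 'electron' or 'alpha'")
    line = EmissionLine(icode, yield_per_decay, energy_mev)
    return RadiationSpectrum([line], f"mono-{particle}-{energy_mev:g}MeV")


def expand_chain(parent: Radionuclide) -> RadiationSpectrum:
    """Expand a decay chain under secular equilibrium.

    Every descendant's emissions are included with yields scaled by the
    product of branching fractions along the path from the parent.  Cyclic
    chain definitions are rejected.
    """
    lines: list[EmissionLine] = []

    def walk(nuclide: Radionuclide, weight: float, path: tuple[str, ...]) -> None:
        if nuclide.name in path:
            raise ValueError(f"cyclic decay chain at {nuclide.name!r}")
        for ln in nuclide.emissions:
            lines.append(ln.scaled(weight))
        for daughter, branching in nuclide.daughters:
            walk(daughter, weight * branching, path + (nuclide.name,))

    walk(parent, 1.0, ())
    return RadiationSpectrum(lines, f"{parent.name}+daughters")


# ---------------------------------------------------------------------------
# CSV dialect shared by user radiation files and the packaged tables
# ---------------------------------------------------------------------------

_HEADER = ["icode", "yield", "energy_MeV"]


def parse_user_radiation_file(path: str | Path) -> RadiationSpectrum:
    """Read a user radiation file: one emission per row, ``icode,yield,energy_MeV``.

    Comment lines start with ``#``; a header row is optional.  Malformed rows
    are reported with their line numbers.
    """
    path = Path(path)
    lines: list[EmissionLine] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if [c.strip().lower() for c in row[:1]] == ["icode"]:
                continue
            if len(row) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                icode = parse_icode(row[0])
                yld = float(row[1])
                energy = float(row[2])
                lines.append(EmissionLine(icode, yld, energy))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
    if not lines:
        raise ValueError(f"{path.name}: no emission lines found")
    return RadiationSpectrum(lines, path.stem)


def write_spectrum(spectrum: RadiationSpectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for ln in spectrum.lines:
            writer.writerow([ln.icode.value, repr(ln.yield_per_decay), repr(ln.energy_mev)])


# ---------------------------------------------------------------------------
# Packaged nuclide registry
# ---------------------------------------------------------------------------

def _data_dir():
    return resources.files("celldose").joinpath("data").joinpath("nuclides")


def available_nuclides() -> list[str]:
    return sorted(p.name[:-4] for p in _data_dir().iterdir() if p.name.endswith(".csv"))


def _load_raw(name: str) -> tuple[float, list[EmissionLine], list[tuple[str, float]]]:
    ref = _data_dir().joinpath(f"{name.lower()}.csv")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown nuclide {name!r}; available: {', '.join(available_nuclides())}"
        ) from None
    half_life = None
    emissions: list[EmissionLine] = []
    daughters: list[tuple[str, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("half_life_s:"):
                half_life = float(body.split(":", 1)[1])
            elif body.startswith("daughter:"):
                dname, branching = body.split(":", 1)[1].split()
                daughters.append((dname, float(branching)))
            continue
        row = [c.strip() for c in stripped.split(",")]
        if row[0].lower() == "icode":
            continue
        emissions.append(EmissionLine(parse_icode(row[0]), float(row[1]), float(row[2])))
    if half_life is None:
        raise ValueError(f"nuclide file {name}: missing '# half_life_s:' directive")
    return half_life, emissions, daughters


def load_nuclide(name: str) -> Radionuclide:
    """Build a :class:`Radionuclide` (with its full daughter tree) from the
    packaged data files."""

    def build(nm: str, path: tuple[str, ...]) -> Radionuclide:
        if nm in path:
            raise ValueError(f"cyclic chain in packaged data at {nm!r}")
        half_life, emissions, daughters = _load_raw(nm)
        return Radionuclide(
            name=nm,
            half_life_s=half_life,
            emissions=emissions,
            daughters=[(build(d, path + (nm,)), b) for d, b in daughters],
        )

    return build(name.lower(), ())


def nuclide_spectrum(name: str, include_daughters: bool = True) -> RadiationSpectrum:
    """Spectrum of a packaged nuclide, chain-expanded by default."""
    nuc = load_nuclide(name)
    if include_daughters:
        return expand_chain(nuc)
    return RadiationSpectrum(list(nuc.emissions), nuc.name)
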