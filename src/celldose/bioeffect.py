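"""Linear-quadratic bioeffect modeling: survival, SF curves, and TCP.

Survival of a cell is modeled with a modified linear-quadratic (LQ) law in
which self-dose and cross-dose act independently:

    P = exp(-a_self D_self - b_self D_self^2) * exp(-a_cross D_cross - b_cross D_cross^2)

The complex variant resolves the LQ parameters by radiation type (ICODE),
source region and self/cross for a chosen target region, multiplying one
exponential factor per dose component — an independent-interaction model
with no synergy terms between radiation types.

Cell fate is Bernoulli: a cell stays alive when a uniform random number
u in [0, 1) falls below its survival probability, which realizes survival
with probability exactly P.  The surviving fraction (SF) is reported both
as the Monte Carlo realization and as the deterministic expectation
mean(P_k); tumor control probability comes in the Poisson flavor
``(1 - SF)^n`` (n = all cells in the cluster) and as the exact per-cell
product ``prod(1 - P_i)`` evaluated on the pre-draw probabilities.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import ICode
from .dosimetry import DoseBreakdown, decays_per_cell
from .geometry import Population
from .labeling import substream
from .scoeff import Region, parse_region


def alpha_from_d0(d0_gy: float) -> float:
    """LQ alpha (Gy^-1) from a mean-lethal-dose D0, the dose reducing
    survival to 1/e on a pure-exponential curve: alpha = 1 / D0."""
    if d0_gy <= 0:
        raise ValueError("D0 must be > 0 Gy")
    return 1.0 / d0_gy


@dataclass(frozen=True)
class SimpleLQ:
    """Self/cross LQ parameters for the one-exponential-per-kind model."""

    alpha_self: float
    beta_self: float = 0.0
    alpha_cross: float = 0.0
    beta_cross: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha_self, self.beta_self, self.alpha_cross, self.beta_cross) < 0:
            raise ValueError("LQ parameters must be >= 0")


#: complex-table key: (icode, source region, "self"|"cross", target region)
LQKey = tuple[ICode, Region, str, Region]


@dataclass
class LQParameterTable:
    """Complex LQ parameters keyed by (icode, source, self|cross, target).

    A parameter missing for a dose component that is present in a
    breakdown is a hard error at compute time — no silent defaults.
    """

    entries: dict[LQKey, tuple[float, float]] = field(default_factory=dict)
    is_default: bool = False

    def set(self, icode: ICode, source, kind: str, target, alpha: float, beta: float) -> None:
        if alpha < 0 or beta < 0:
            raise ValueError("LQ parameters must be >= 0")
        if kind not in ("self", "cross"):
            raise ValueError("kind must be 'self' or 'cross'")
        self.entries[(icode, parse_region(source), kind, parse_region(target))] = (
            float(alpha),
            float(beta),
        )

    def get(self, icode: ICode, source: Region, kind: str, target: Region) -> tuple[float, float]:
        try:
            return self.entries[(icode, source, kind, target)]
        except KeyError:
            raise KeyError(
                f"no LQ parameters for ({icode.value}, {source.value}, {kind}, "
                f"target {target.value}); complex survival requires parameters "
                "for every dose component present"
            ) from None

    @classmethod
    def uniform(
        cls,
        alpha: float = 0.1,
        beta: float = 0.01,
        icodes=tuple(ICode),
        is_default: bool = False,
    ) -> "LQParameterTable":
        """One (alpha, beta) for every combination.  The library default
        (0.1 Gy^-1, 0.01 Gy^-2) is arbitrary and flagged, and its use at
        compute time emits a warning."""
        table = cls(is_default=is_default)
        sources = (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM, Region.CELL_SURFACE)
        targets = (Region.CELL, Region.NUCLEUS, Region.CYTOPLASM)
        for icode in icodes:
            if icode.is_photon:
                continue
            for src in sources:
                for kind in ("self", "cross"):
                    for tgt in targets:
                        table.set(icode, src, kind, tgt, alpha, beta)
        return table

    @classmethod
    def default(cls) -> "LQParameterTable":
        return cls.uniform(0.1, 0.01, is_default=True)

    # -- lossless CSV round trip -------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["icode", "source_region", "self_or_cross", "target", "alpha", "beta"])
            for (icode, src, kind, tgt), (a, b) in sorted(
                self.entries.items(), key=lambda kv: [x.value if hasattr(x, "value") else x for x in kv[0]]
            ):
                writer.writerow([icode.value, src.value, kind, tgt.value, repr(a), repr(b)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LQParameterTable":
        from .decay import parse_icode

        table = cls()
        with Path(path).open(newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lstrip().startswith("#") or row[0] == "icode":
                    continue
                table.set(
                    parse_icode(row[0]), row[1], row[2], row[3], float(row[4]), float(row[5])
                )
        return table


def survival_simple(d_self, d_cross, params: SimpleLQ):
    """Modified-LQ survival probability with independent self/cross effects."""
    d_self = np.asarray(d_self, dtype=float)
    d_cross = np.asarray(d_cross, dtype=float)
    if np.any(d_self < 0) or np.any(d_cross < 0):
        raise ValueError("doses must be >= 0")
    log_p = -(
        params.alpha_self * d_self
        + params.beta_self * d_self**2
        + params.alpha_cross * d_cross
        + params.beta_cross * d_cross**2
    )
    out = np.exp(log_p)
    return out if out.ndim else float(out)


def survival_complex(
    breakdown: DoseBreakdown, params: LQParameterTable, target: Region | str
) -> np.ndarray:
    """Per-cell survival from the component-resolved dose breakdown.

    The product over radiation types, source regions and self/cross of
    ``exp(-a D - b D^2)`` is evaluated as a summed log-survival.
    """
    target = parse_region(target)
    if params.is_default:
        warnings.warn(
            "complex survival evaluated with the arbitrary default LQ "
            "parameters; enter values relevant to your system",
            stacklevel=2,
        )
    log_p = np.zeros(breakdown.n_cells)
    for (tgt, icode, source, kind), dose in breakdown.components.items():
        if tgt is not target:
            continue
        alpha, beta = params.get(icode, source, kind, tgt)
        log_p -= alpha * dose + beta * dose**2
    return np.exp(log_p)


def monte_carlo_fates(
    probabilities: np.ndarray, rng: int | np.random.Generator
) -> tuple[np.ndarray, float]:
    """Draw alive/dead fates; returns (alive flags, surviving fraction)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alive = rng.random(p.shape) < p
    return alive, float(alive.mean())


def tcp(probabilities: np.ndarray, sf: float, n_cells: int) -> tuple[float, float]:
    """(TCP_poisson, TCP_product): ``(1 - SF)^n`` and ``prod(1 - P_i)``."""
    p = np.asarray(probabilities, dtype=float)
    tcp_poisson = float((1.0 - sf) ** n_cells)
    tcp_product = float(np.prod(1.0 - p))
    return tcp_poisson, tcp_product


@dataclass
class SurvivalResult:
    """Survival outcome for one activity level."""

    probabilities: np.ndarray
    alive: np.ndarray
    sf_mc: float
    sf_expected: float
    tcp_poisson: float
    tcp_product: float


def evaluate_survival(
    breakdown: DoseBreakdown,
    params: "LQParameterTable | SimpleLQ",
    target: Region | str,
    seed: int,
    stream: str = "fates",
) -> SurvivalResult:
    """Survival for one dose level; dispatches on simple vs complex LQ."""
    target = parse_region(target)
    if isinstance(params, SimpleLQ):
        p = np.asarray(
            survival_simple(
                breakdown.total(target, "self"), breakdown.total(target, "cross"), params
            )
        )
    else:
        p = survival_complex(breakdown, params, target)
    alive, sf_mc = monte_carlo_fates(p, substream(seed, stream))
    tcp_p, tcp_prod = tcp(p, sf_mc, len(p))
    return SurvivalResult(
        probabilities=p,
        alive=alive,
        sf_mc=sf_mc,
        sf_expected=float(p.mean()),
        tcp_poisson=tcp_p,
        tcp_product=tcp_prod,
    )


def sf_curve(
    pop: Population,
    breakdown: DoseBreakdown,
    params: LQParameterTable,
    tau_hours: float,
    target: Region | str,
    seed: int,
    n_points: int = 21,
) -> pd.DataFrame:
    """SF and TCP versus an activity sweep from zero to the configured maximum.

    The labeling pattern and the relative activity distribution are held
    fixed; every dose component scales linearly with activity, so the sweep
    rescales the precomputed breakdown.  Each sweep point draws its Monte
    Carlo fates from a fresh named substream of the master seed.

    Domains emitted: mean activity per cell / per labeled cell, mean decays
    per cell / per labeled cell, and mean absorbed dose to all / labeled /
    unlabeled cells, alongside SF_mc, SF_expected, TCP_poisson, TCP_product.
    """
    target = parse_region(target)
    labeled = pop.labeled
    decays = decays_per_cell(pop.activity_bq, tau_hours)
    d_total = breakdown.total(target)
    mean_act_all = float(pop.activity_bq.mean())
    mean_act_lab = float(pop.activity_bq[labeled].mean()) if labeled.any() else 0.0
    mean_dec_all = float(decays.mean())
    mean_dec_lab = float(decays[labeled].mean()) if labeled.any() else 0.0
    mean_dose_all = float(d_total.mean())
    mean_dose_lab = float(d_total[labeled].mean()) if labeled.any() else 0.0
    mean_dose_unl = float(d_total[~labeled].mean()) if (~labeled).any() else 0.0

    rows = []
    for i, frac in enumerate(np.linspace(0.0, 1.0, n_points)):
        scaled = DoseBreakdown(
            n_cells=breakdown.n_cells,
            components={k: v * frac for k, v in breakdown.components.items()},
        )
        res = evaluate_survival(scaled, params, target, seed, stream=f"fates-{i}")
        rows.append(
            {
                "fraction_of_max": frac,
                "mean_activity_per_cell_bq": frac * mean_act_all,
                "mean_activity_per_labeled_cell_bq": frac * mean_act_lab,
                "mean_decays_per_cell": frac * mean_dec_all,
                "mean_decays_per_labeled_cell": frac * mean_dec_lab,
                "mean_dose_to_cells_gy": frac * mean_dose_all,
                "mean_dose_to_labeled_cells_gy": frac * mean_dose_lab,
                "mean_dose_to_unlabeled_cells_gy": frac * mean_dose_unl,
                "sf_mc": res.sf_mc,
                "sf_expected": res.sf_expected,
                "tcp_poisson": res.tcp_poisson,
                "tcp_product": res.tcp_product,
            }
        )
    return pd.DataFrame(rows)
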