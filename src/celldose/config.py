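"""Run configuration and the end-to-end pipeline with its output dump.

A run is fully described by one YAML file (plus the master seed): source,
cell model, cluster geometry, labeling, subcellular split, time-integrated
activity coefficient, LQ parameters and sweep settings.  ``run`` executes
the whole pipeline and writes the output dump: a parameter echo sufficient
to reproduce the run, the self/cross S-coefficient table, the per-cell
table, radial summaries, the SF/TCP sweep and per-layer slice exports.
All physical quantities carry unit suffixes in their key names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import bioeffect, dosimetry, geometry, labeling
from .decay import (
    RadiationSpectrum,
    load_nuclide,
    make_monoenergetic,
    nuclide_spectrum,
    parse_icode,
    parse_user_radiation_file,
)
from .geometry import ClusterSpec, Population, Shape
from .labeling import ActivityDistributionSpec, SubcellularDistribution
from .scoeff import CellModel, Region, SCoefficientSet, parse_region
from .transport import default_models

_STAGES = ("source", "cell", "cluster", "labeling", "subcellular", "tau", "lq")


class ConfigError(ValueError):
    pass


def _require(cfg: dict, key: str, stage: str):
    if key not in cfg:
        raise ConfigError(f"config section '{stage}' is missing the field '{key}'")
    return cfg[key]


@dataclass
class RunConfig:
    """Parsed, validated run configuration (see ``from_dict`` for the schema)."""

    raw: dict
    seed: int
    spectrum: RadiationSpectrum
    half_life_s: float | None
    cell: CellModel
    cluster: ClusterSpec
    labeling: ActivityDistributionSpec
    subcell: SubcellularDistribution
    tau_hours: float
    lq_params: "bioeffect.LQParameterTable | bioeffect.SimpleLQ"
    target: Region
    sweep_points: int
    bin_width_um: float

    @classmethod
    def from_dict(cls, cfg: dict, base_dir: Path | None = None) -> "RunConfig":
        for stage in ("source", "cell", "cluster", "labeling"):
            if stage not in cfg:
                raise ConfigError(f"config is missing the required section '{stage}'")
        base_dir = base_dir or Path.cwd()
        seed = int(cfg.get("seed", 0))

        src = cfg["source"]
        kind = _require(src, "kind", "source")
        half_life = None
        if kind == "nuclide":
            name = _require(src, "name", "source")
            spectrum = nuclide_spectrum(name, src.get("include_daughters", True))
            half_life = load_nuclide(name).half_life_s
        elif kind == "monoenergetic":
            spectrum = make_monoenergetic(
                _require(src, "particle", "source"),
                float(_require(src, "energy_mev", "source")),
                float(src.get("yield", 1.0)),
            )
        elif kind == "file":
            spectrum = parse_user_radiation_file(base_dir / _require(src, "path", "source"))
        else:
            raise ConfigError(f"unknown source kind {kind!r}")

        cell_cfg = cfg["cell"]
        cell = CellModel(
            float(_require(cell_cfg, "r_cell_um", "cell")),
            float(_require(cell_cfg, "r_nucleus_um", "cell")),
        )

        clu = dict(cfg["cluster"])
        shape = Shape(_require(clu, "shape", "cluster"))
        spacing = float(_require(clu, "spacing_um", "cluster"))
        depth = clu.get("penetration_depth_um")
        dims = {
            k: float(v)
            for k, v in clu.items()
            if k not in ("shape", "spacing_um", "penetration_depth_um")
        }
        cluster = ClusterSpec(
            shape, dims, spacing, cell,
            None if depth is None else float(depth),
        )

        lab = dict(cfg["labeling"])
        radial_table = lab.get("radial_table")
        if radial_table is not None:
            radial_table = str(base_dir / radial_table)
        label_spec = ActivityDistributionSpec(
            method=lab.get("method", "uniform"),
            percent_labeled=float(lab.get("percent_labeled", 100.0)),
            mean_activity_bq=float(lab.get("mean_activity_bq", 0.0)),
            sigma=float(lab.get("sigma", 0.0)),
            radial_params=tuple(lab.get("radial_params", ())),
            radial_table=radial_table,
            max_mean_activity_bq=float(lab.get("max_mean_activity_bq", 0.0)),
        )

        sub = cfg.get("subcellular", {})
        subcell = SubcellularDistribution(
            f_nucleus=float(sub.get("f_nucleus", 0.0)),
            f_cytoplasm=float(sub.get("f_cytoplasm", 0.0)),
            f_surface=float(sub.get("f_surface", 1.0)),
        )

        tau_cfg = cfg.get("tau", {"kind": "physical"})
        if tau_cfg.get("kind", "hours") == "physical":
            if half_life is None:
                raise ConfigError(
                    "tau kind 'physical' needs a nuclide source (known half-life); "
                    "give tau hours explicitly instead"
                )
            tau_hours = dosimetry.tau_physical_hours(half_life)
        else:
            tau_hours = float(_require(tau_cfg, "hours", "tau"))
            if tau_hours <= 0:
                raise ConfigError("tau hours must be > 0")

        lq_cfg = cfg.get("lq", {"mode": "default"})
        mode = lq_cfg.get("mode", "default")
        if mode == "simple":
            lq_params: bioeffect.LQParameterTable | bioeffect.SimpleLQ = bioeffect.SimpleLQ(
                alpha_self=float(lq_cfg.get("alpha_self", 0.0)),
                beta_self=float(lq_cfg.get("beta_self", 0.0)),
                alpha_cross=float(lq_cfg.get("alpha_cross", 0.0)),
                beta_cross=float(lq_cfg.get("beta_cross", 0.0)),
            )
        elif mode == "complex":
            if "file" in lq_cfg:
                lq_params = bioeffect.LQParameterTable.from_csv(base_dir / lq_cfg["file"])
            else:
                table = bioeffect.LQParameterTable.uniform(
                    float(lq_cfg.get("base_alpha", 0.0)),
                    float(lq_cfg.get("base_beta", 0.0)),
                )
                for ov in lq_cfg.get("overrides", ()):
                    icode = parse_icode(str(ov["icode"]))
                    for src_reg in [ov["source"]] if "source" in ov else ["C", "N", "Cy", "CS"]:
                        for kind_sc in [ov["kind"]] if "kind" in ov else ["self", "cross"]:
                            for tgt in [ov["target"]] if "target" in ov else ["C", "N", "Cy"]:
                                table.set(
                                    icode, src_reg, kind_sc, tgt,
                                    float(ov.get("alpha", 0.0)),
                                    float(ov.get("beta", 0.0)),
                                )
                lq_params = table
        elif mode == "default":
            lq_params = bioeffect.LQParameterTable.default()
        else:
            raise ConfigError(f"unknown lq mode {mode!r}")

        return cls(
            raw=cfg,
            seed=seed,
            spectrum=spectrum,
            half_life_s=half_life,
            cell=cell,
            cluster=cluster,
            labeling=label_spec,
            subcell=subcell,
            tau_hours=tau_hours,
            lq_params=lq_params,
            target=parse_region(cfg.get("target_region", "N")),
            sweep_points=int(cfg.get("sweep", {}).get("n_points", 21)),
            bin_width_um=float(cfg.get("bin_width_um", spacing)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(cfg, base_dir=path.parent)


@dataclass
class RunResult:
    """Everything a run produces, before/after writing to disk."""

    config: RunConfig
    population: Population
    s_set: SCoefficientSet
    breakdown: dosimetry.DoseBreakdown
    survival: bioeffect.SurvivalResult
    per_cell: pd.DataFrame
    sf_curve: pd.DataFrame
    radial: pd.DataFrame | None
    warnings: list[str]


def run(config: RunConfig, outdir: str | Path | None = None, dry_run: bool = False) -> RunResult:
    """Execute the full pipeline; optionally write the output dump."""
    caught: list[warnings.WarningMessage] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        pop = geometry.build_population(config.cluster)
        if config.cluster.shape is not Shape.PAIR:
            geometry.classify_penetration(pop)
        if dry_run:
            return RunResult(
                config, pop, None, None, None, None, None, None,
                [str(w.message) for w in caught],
            )
        labeling.select_labeled(pop, config.labeling.percent_labeled, config.seed)
        labeling.assign(pop, config.labeling, config.subcell, config.seed)

        models = default_models()
        breakdown, s_set = dosimetry.compute_doses(
            pop, config.spectrum, config.subcell, config.tau_hours, models=models
        )
        survival = bioeffect.evaluate_survival(
            breakdown, config.lq_params, config.target, config.seed, stream="fates-final"
        )
        pop.alive = survival.alive
        curve = bioeffect.sf_curve(
            pop, breakdown, config.lq_params, config.tau_hours,
            config.target, config.seed, config.sweep_points,
        )
        per_cell = dosimetry.per_cell_table(pop, breakdown, config.tau_hours, config.target)
        radial = None
        if config.cluster.shape.dimensionality == 3:
            radial = dosimetry.radial_summary(
                pop, breakdown, config.tau_hours, config.bin_width_um, config.target
            )

    messages = [str(w.message) for w in caught]
    result = RunResult(
        config=config,
        population=pop,
        s_set=s_set,
        breakdown=breakdown,
        survival=survival,
        per_cell=per_cell,
        sf_curve=curve,
        radial=radial,
        warnings=messages,
    )
    if outdir is not None:
        write_output(result, Path(outdir))
    return result


def _echo_text(result: RunResult) -> str:
    """Plain-text parameter echo: the config plus every derived quantity a
    reader needs to reproduce and sanity-check the run."""
    cfg = result.config
    pop = result.population
    lines = [
        "# run parameter echo",
        yaml.safe_dump(cfg.raw, sort_keys=True).rstrip(),
        "# derived",
        f"n_cells: {len(pop)}",
        f"n_eligible: {int(pop.eligible.sum())}",
        f"n_labeled: {int(pop.labeled.sum())}",
        f"tau_hours: {cfg.tau_hours:.6g}",
        f"target_region: {cfg.target.value}",
        f"sf_mc_at_max: {result.survival.sf_mc:.6g}",
        f"sf_expected_at_max: {result.survival.sf_expected:.6g}",
        f"tcp_poisson_at_max: {result.survival.tcp_poisson:.6g}",
        f"tcp_product_at_max: {result.survival.tcp_product:.6g}",
    ]
    if result.warnings:
        lines.append("# warnings")
        lines.extend(f"- {w}" for w in result.warnings)
    return "\n".join(lines) + "\n"


def write_output(result: RunResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "parameters.txt").write_text(_echo_text(result))
    result.s_set.to_dataframe().to_csv(outdir / "s_coefficients.csv")
    result.per_cell.to_csv(outdir / "cells.csv", index=False)
    result.sf_curve.to_csv(outdir / "sf_curve.csv", index=False)
    if result.radial is not None:
        result.radial.to_csv(outdir / "radial_summary.csv", index=False)
    if result.config.cluster.shape.dimensionality == 3:
        slice_dir = outdir / "slices"
        slice_dir.mkdir(exist_ok=True)
        pop = result.population
        for layer, (z, idx) in enumerate(sorted(geometry.slices(pop).items())):
            frame = pd.DataFrame(
                {
                    "index": idx,
                    "x_um": pop.centers[idx, 0],
                    "y_um": pop.centers[idx, 1],
                    "z_um": pop.centers[idx, 2],
                    "labeled": pop.labeled[idx].astype(int),
                    "alive": pop.alive[idx].astype(int),
                }
            )
            frame.to_csv(slice_dir / f"layer_{layer:03d}.csv", index=False)
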