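# celldose

Cellular S-coefficient dosimetry and linear-quadratic bioeffect modeling for
radiolabeled multicellular populations.

Radiopharmaceuticals that carry alpha, beta or Auger-electron emitters kill
on the scale of single cells and micrometastases, where the absorbed dose is
set by *which* cells are labeled, *where* in the cell the activity sits, and
how far each radiation travels. `celldose` models this regime for people
designing or teaching radiopharmaceutical therapy: it builds populations of
identical two-concentric-sphere cells (cell + nucleus, unit-density water)
on a cubic lattice — cell pairs, planar colonies, or 3-D clusters shaped as
spheres, ellipsoids, rods and cones — assigns activity by random or radial
distributions (including a cold, drug-free core), computes self- and
cross-dose S coefficients analytically from CSDA range–energy relations, and
turns per-cell doses into survival and tumor control probabilities.

The core quantities:

* **S coefficient** `S(T←S) = Σ_i Δ_i φ_i(T←S) / m(T)` — absorbed dose to
  target region T per nuclear transition in source region S (Gy·Bq⁻¹·s⁻¹),
  summed over emission lines with mean emitted energy `Δ = y·E` and absorbed
  fraction `φ`, computed by pair-distance quadrature over a straight-track
  CSDA point kernel (an internal Monte Carlo oracle cross-checks every value).
* **Survival** `P_k = Π exp(−α D − β D²)` over dose components — a modified
  linear-quadratic model in which self-dose, cross-dose, each radiation type
  and each source region act independently.
* **TCP** `(1 − SF)ⁿ` (Poisson) and `Π_i (1 − P_i)` (exact per-cell product).

## Worked example

The packaged reference scenario models a 250-µm-diameter tumor spheroid
whose outer cell layer (~12 µm) binds a ²¹³Bi-labeled antibody: the ²¹³Bi
decay chain in equilibrium on the cell surface, nucleus as target, and an
alpha-only LQ response with α = 1/D₀ = 1/1.8 ≈ 0.56 Gy⁻¹.

```python
from celldose import CellModel, nuclide_spectrum, self_s, cross_s
from celldose.config import RunConfig, run
from celldose.examples import worked_example_config

cell = CellModel(r_cell_um=6.0, r_nucleus_um=5.0)
spec = nuclide_spectrum("bi213")          # chain-expanded, daughters in equilibrium
print(self_s(spec, cell, "CS", "N"))      # Gy per decay, by radiation type
print(cross_s(spec, cell, 13.0, "CS", "N"))

result = run(RunConfig.from_dict(worked_example_config(seed=1)), outdir="out")
```

The S coefficients show why only the alphas matter here (per ²¹³Bi decay,
surface source, nucleus target):

```
self  S(N<-CS)[alpha] = 2.767e-02 Gy/decay     cross @13um = 5.734e-03
self  S(N<-CS)[beta-] = 1.472e-04 Gy/decay     cross @13um = 2.958e-05
self  S(N<-CS)[ic   ] = 7.263e-07 Gy/decay     cross @13um = 1.456e-07
```

and the full run prints a two-component survival curve:

```
cells: 3473   labeled rim: 696
D =   2.1 Gy   SF_expected = 0.3661   SF_mc = 0.3711
D =   5.3 Gy   SF_expected = 0.1193   SF_mc = 0.1192
D =  10.6 Gy   SF_expected = 0.0375   SF_mc = 0.0394
D =  21.1 Gy   SF_expected = 0.0171   SF_mc = 0.0196
survivors at top: 64 (all unlabeled, outermost at r = 80 um; labeled rim starts at 113 um)
```

Survival first collapses as the labeled rim and every cell within alpha
range (~90 µm) of it is sterilized, then flattens into a tail: the unlabeled
core sits beyond the reach of the alphas, so raising the activity barely
moves the curve — the hallmark failure mode of a poorly penetrating
radiopharmaceutical, and the reason the tomographic slice export shows
survivors only at the cluster center.

The output directory holds the parameter echo, the S-coefficient table,
per-cell doses, radial histograms (mean activity / self-dose / cross-dose /
decays per bin), the SF/TCP sweep, and one CSV per tomographic layer.

## Command line

```bash
celldose sources list                    # packaged nuclides (213Bi, 111In, 211At, 223Ra, 225Ac, ...)
celldose sources show bi213              # chain-expanded emission table
celldose scoeff --particle electron --energy-mev 0.05 --distances-um 13,26
celldose run --config run.yaml --out out/ --seed 1
celldose sweep --config run.yaml --out sf.csv
celldose oracle --particle alpha --energy-mev 5 --distance-um 13 --histories 1000000
```

A config file is a single YAML document; every quantity carries a unit
suffix (`radius_um`, `max_mean_activity_bq`, `tau: {kind: hours, hours: 1.11}`).
`celldose run --dry-run` validates a config without computing.

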