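"""Ready-made run configurations.

``worked_example_config`` reproduces the published spheroid scenario: a
250-um-diameter tumor spheroid whose outer cell layer binds a
213Bi-labeled antibody.  The 213Bi chain (daughters in equilibrium) is the
source, all activity sits on the cell surface, the nucleus is the target,
and only alpha particles are radiotoxic (alpha = 1/D0 with D0 = 1.8 Gy);
Auger electrons and betas carry zero LQ parameters, which reproduces the
same response as default values for this scenario.
"""

from __future__ import annotations

import copy

from .bioeffect import alpha_from_d0

WORKED_EXAMPLE = {
    "seed": 1,
    "source": {"kind": "nuclide", "name": "bi213", "include_daughters": True},
    "cell": {"r_cell_um": 6.0, "r_nucleus_um": 5.0},
    "cluster": {
        "shape": "sphere",
        "radius_um": 125.0,
        "spacing_um": 13.0,
        "penetration_depth_um": 12.0,
    },
    "labeling": {
        "method": "radial_exponential",
        "percent_labeled": 100.0,
        "radial_params": [0.4],
        "max_mean_activity_bq": 0.02,
    },
    "subcellular": {"f_nucleus": 0.0, "f_cytoplasm": 0.0, "f_surface": 1.0},
    "tau": {"kind": "hours", "hours": 1.11},
    "lq": {
        "mode": "complex",
        "base_alpha": 0.0,
        "base_beta": 0.0,
        "overrides": [
            {"icode": "alpha", "alpha": alpha_from_d0(1.8), "beta": 0.0},
        ],
    },
    "target_region": "N",
    "sweep": {"n_points": 21},
    "bin_width_um": 13.0,
}


def worked_example_config(seed: int = 1) -> dict:
    """A deep copy of the worked-example configuration with the given seed."""
    cfg = copy.deepcopy(WORKED_EXAMPLE)
    cfg["seed"] = int(seed)
    return cfg
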