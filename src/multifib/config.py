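"""Run configuration: documented defaults and YAML loading.

All values are plain SI-derived units stated once here (mm, Pa, hours,
micrometres for the RVE side) and never rescaled internally.  The material
defaults describe an in-vitro tumour spheroid (radius 0.1 mm) growing into a
dense hydrated collagen gel (0.5 mm thick shell) and are design choices of
this package:

* tumour.mu / tumour.kappa (200 Pa / 1 kPa): spheroid aggregates measure in
  the 0.1-1 kPa stiffness range.
* tumour.k_o (1e-3 mm^2/(Pa h)): interstitial hydraulic conductivity of
  tumour tissue, two orders of magnitude above the dense-gel stroma.
* tumour.theta_s (0.02): the tracked solid skeleton is the ECM scaffold,
  which is sparse inside an in-vitro spheroid (cells contribute to the
  fluid-rich phase, and spheroids carry little collagen of their own).
* fibres.e_f (10 MPa parametric fibril stiffness): together with the
  density-normalised cross-section this gives the homogenised network a
  small-strain shear modulus of ~300 Pa, in the range measured for dense
  collagen hydrogels.
* fibres.theta_s (0.003): collagen volume fraction of a ~2.5 mg/ml gel.
* growth.plateau (1.35): free-growth radius increase of ~35%, which the
  stromal resistance reduces to ~25% at equilibrium.
* growth.gamma (0.08 /h): brings the Gompertz stretch within 2% of its
  plateau by ~50 h, matching spheroid growth saturating over a few days.
* fluid.viscosity_scale: converts the parametric fibre-drag permeability to
  physical units; calibrated so the undeformed stromal permeability is about
  two orders of magnitude below tumour k_o.
"""

from __future__ import annotations

import copy

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "geometry": {
        "r_tumour": 0.1,        # mm
        "pts_thickness": 0.5,   # mm
        "n_angular": 2,
        "n_radial_tumour": 2,
        "n_radial_pts": 3,
    },
    "tumour": {
        "mu": 200.0,            # Pa
        "kappa": 1000.0,        # Pa
        "k_o": 1.0e-3,          # mm^2/(Pa h)
        "theta_s": 0.02,
    },
    "fibres": {
        "e_f": 1.0e7,           # Pa
        "a_f": 2.5e-5,          # parametric cross-section
        "c0": 2.0,
        "theta_s": 0.003,
        "count_bounds": [60, 100],
        "side_length": 20.0,    # micrometres
        "eta_nominal": 2.0,     # common gel dimensionalisation factor
        "weld_tol": 0.03,
        "align_stretch": None,  # e.g. [1.246, 1.0, 1.231] for prealigned
    },
    "growth": {
        "plateau": 1.35,
        "gamma": 0.08,          # 1/h
    },
    "fluid": {
        "biot_modulus": 1.0e4,  # Pa (undrained bulk modulus)
        "viscosity_scale": 1.7e-6,
    },
    "solver": {
        "dt": 2.0,              # h
        "t_end": 60.0,          # h
        "grad_tol": 1e-8,
        "micro_tol": 1e-8,      # micro residual, relative to a_f * e_f
        "coupling_every": 1,
        "relax": 0.5,           # under-relaxation of the upscaled refresh
    },
    "output": {
        "dir": None,
        "every": 5,
    },
}

# the larger configuration (216 macro elements, 200-300 fibres per RVE);
# long-running
FULL_SCALE_OVERRIDES: dict = {
    "geometry": {"n_angular": 3, "n_radial_tumour": 3, "n_radial_pts": 5},
    "fibres": {"count_bounds": [200, 300]},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def full_scale_config() -> dict:
    cfg = default_config()
    _merge(cfg, copy.deepcopy(FULL_SCALE_OVERRIDES))
    return cfg


def _merge(base: dict, override: dict) -> dict:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path) -> dict:
    """Load a YAML config, filling unspecified keys with the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return _merge(cfg, user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
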