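"""Configuration loading and the default analysis parameters.

Configs are TOML (YAML accepted); unspecified blocks fall back to the
defaults below.  Every pipeline output embeds the fully resolved config so
results are traceable to the exact thresholds used.
"""

from __future__ import annotations

import copy
from pathlib import Path

DEFAULTS: dict = {
    "landscape": {
        "enabled": True,
        "sources": [[2.5, 0.0, 0.5, 1.0]],  # x, y, z (cm), flux
        "diffusion_constant": 0.025,          # cm^2/min
        "release_time": 0.0,                  # min
        "plane_height": 0.0,                  # cm
        "gradient_age": 200.0,                # min, quasi-static evaluation time
    },
    "simulation": {
        "seed": 0,
        "frame_rate": 20.0,
        "duration": 180.0,
        "run_speed": 0.8,
        "peristaltic_period": 1.0,
        "turn_hazard_up": 2.0,
        "turn_hazard_down": 8.0,
        "baseline_hazard": 4.0,
        "gradient_bias": 0.7,
        "p_stop": 0.95,
    },
    "cohorts": [
        {"name": "wildtype", "genotype": "wildtype", "n": 12},
        {"name": "pdm_silenced", "genotype": "pdm_silenced", "n": 12},
    ],
    "flashes": {"enabled": False, "n": 8, "duration": 6.0, "gap": 30.0,
                "first_onset": 30.0, "intensity": 18.0},
    "segmentation": {
        "theta_stop": None,
        "min_stop": 0.5,
        "min_run": 1.0,
        "theta_angle": 20.0,
        "theta_cast": 20.0,
        "theta_turn": 30.0,
        "smoothing_window": 0.3,
    },
    "waves": {"enabled": True, "rule": "pdm", "n_flashes": 4, "noise_sd": 0.1,
              "wave_period": 4.0, "wave_speed": 4.0},
    "dff": {"enabled": True, "mode": "prestimulus_window", "window": 2.0,
            "response_window": 5.0},
    "stats": {"level": 0.95},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Load a TOML or YAML config, merged over the package defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        user = yaml.safe_load(path.read_text()) or {}
    else:
        import tomllib

        user = tomllib.loads(path.read_text())
    return _merge(DEFAULTS, user)


def demo_config() -> dict:
    """The shipped end-to-end demo: small cohorts, all stages enabled."""
    return _merge(
        DEFAULTS,
        {
            "simulation": {"duration": 120.0},
            "cohorts": [
                {"name": "wildtype", "genotype": "wildtype", "n": 6},
                {"name": "pdm_silenced", "genotype": "pdm_silenced", "n": 6},
                {"name": "chrimson", "genotype": "chrimson", "n": 4},
            ],
            "flashes": {"enabled": True, "n": 3, "duration": 6.0, "gap": 24.0,
                        "first_onset": 20.0},
        },
    )
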