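"""Parameter configuration: YAML-backed model parameter sets.

The shipped ``default_isn`` configuration defines the control circuit: an
inhibition-stabilized network with broad SOM connectivity, a slow SOM rate
filter and a low pyramidal baseline rate.  All model constants live here;
nothing is hard-coded in the simulation code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .model import (
    ConnectivityParams,
    DynamicsParams,
    ModelParams,
    TonotopicGrid,
    calibrate_mu,
)

__all__ = ["load_params", "load_config", "default_params", "DEFAULT_CONFIG_NAME"]

DEFAULT_CONFIG_NAME = "default_isn"


def load_config(name_or_path: str | Path = DEFAULT_CONFIG_NAME) -> dict:
    """Load a raw configuration dict from a shipped name or a YAML file path."""
    path = Path(name_or_path)
    if path.suffix in (".yml", ".yaml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("sweepnet").joinpath(f"data/{name_or_path}.yaml")
        text = ref.read_text()
    return yaml.safe_load(text)


def params_from_config(cfg: dict) -> ModelParams:
    grid = TonotopicGrid(**cfg["grid"])
    conn = ConnectivityParams(
        W=np.asarray(cfg["weights"]["W"], float),
        lam=np.asarray(cfg["scales"]["lam"], float),
    )
    dyn_cfg = cfg["dynamics"]
    r0 = np.asarray(dyn_cfg["r0_hz"], float)
    mu = calibrate_mu(r0, conn)
    dyn = DynamicsParams(
        tau_m=np.asarray(dyn_cfg["tau_m_ms"], float) / 1e3,
        tau_r=np.asarray(dyn_cfg["tau_r_ms"], float) / 1e3,
        mu=mu,
        r0=r0,
    )
    stim = cfg["stimulus"]
    return ModelParams(
        grid=grid,
        conn=conn,
        dyn=dyn,
        amp=np.asarray(stim["amp"], float),
        sigma=np.asarray(stim["sigma"], float),
    )


def load_params(name_or_path: str | Path = DEFAULT_CONFIG_NAME) -> ModelParams:
    """Model parameters from a shipped configuration name or YAML path."""
    return params_from_config(load_config(name_or_path))


def default_params(n_points: int | None = None) -> ModelParams:
    """The control ISN parameter set; ``n_points`` optionally overrides the grid."""
    cfg = load_config(DEFAULT_CONFIG_NAME)
    if n_points is not None:
        cfg["grid"]["n_points"] = n_points
    return params_from_config(cfg)


def analysis_defaults(cfg: dict | None = None) -> dict:
    """DSI analysis settings (edge exclusion, post-stimulus settle horizon)."""
    cfg = cfg or load_config(DEFAULT_CONFIG_NAME)
    return cfg.get("analysis", {"edge_exclusion_oct": 0.5, "settle_s": 1.0})
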