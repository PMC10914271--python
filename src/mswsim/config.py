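"""YAML simulation configs mirroring the published parameter tables.

Two configs ship with the package: ``synthetic`` (γ-sweep / entropy
experiments with a random tradeoff seascape) and ``empirical`` (NSCLC
gefitinib therapy simulations). ``load_config`` reads any YAML file of the
same shape; ``sim_params_from_config`` builds :class:`~mswsim.abm.SimParams`.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import yaml

from .abm import SimParams
from .diffusion import VesselLayout

__all__ = ["load_config", "builtin_config", "sim_params_from_config", "vessel_layout_from_config"]

_SIM_KEYS = {
    "mutation_rate",
    "init_mutant_prob",
    "death_rate",
    "init_density",
    "init_shape",
    "init_radius",
    "init_side",
    "vessel_conc",
    "diffusion_rate",
    "n_steps",
    "dt",
    "rng_seed",
    "neighborhood",
    "net_loss_threshold",
}


def load_config(path) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a YAML mapping")
    return cfg


def builtin_config(name: str) -> Dict:
    """Load a shipped config (``"synthetic"`` or ``"empirical"``)."""
    ref = resources.files("mswsim") / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)


def sim_params_from_config(cfg: Dict, **overrides) -> SimParams:
    kwargs = {k: v for k, v in cfg.items() if k in _SIM_KEYS}
    kwargs.update(overrides)
    return SimParams(**kwargs)


def vessel_layout_from_config(cfg: Dict) -> VesselLayout:
    positions = [tuple(p) for p in cfg.get("vessels", [])]
    strength = cfg.get("vessel_conc", 1.0)
    return VesselLayout(positions=positions, strengths=[strength] * len(positions))
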