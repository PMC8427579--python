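"""YAML/JSON configuration for model fitting.

Example config::

    family: nb
    chains: 4
    iterations: 5000
    warmup: 2000
    retained: 3000
    seed: 1
    method: hmc
    drop_variables: [wb]
    priors:
      beta_sd: 5.0
      sigma_scale: 2.0
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from ingrowth.model.params import Priors
from ingrowth.model.sampler import FitConfig

__all__ = ["FitSettings", "load_fit_settings"]


@dataclasses.dataclass(frozen=True)
class FitSettings:
    family: str
    fit_config: FitConfig
    priors: Priors
    drop_variables: tuple[str, ...]


def load_fit_settings(path: str | Path) -> FitSettings:
    """Read a fit configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must contain a mapping")
    known_fit = {f.name for f in dataclasses.fields(FitConfig)}
    fit_kwargs = {k: v for k, v in raw.items() if k in known_fit}
    priors = Priors(**raw.get("priors", {}))
    unknown = set(raw) - known_fit - {"family", "priors", "drop_variables"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return FitSettings(
        family=str(raw.get("family", "nb")),
        fit_config=FitConfig(**fit_kwargs),
        priors=priors,
        drop_variables=tuple(raw.get("drop_variables", ())),
    )
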