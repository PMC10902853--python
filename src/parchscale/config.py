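"""TOML run configuration: flat sections, one per pipeline stage.

Sections and keys mirror the parameter dataclasses:

    [build]     d_shell, d_ion, d_b, shell_density, min_ion_separation,
                clash_cutoff, jitter, seed
    [schedule]  t_start_K, t_end_K, rate_K_per_ps, restraint_k_protein,
                restraint_k_ions, sample_interval_ps
    [count]     d_water, use_pbc, water_site, method
    [parch]     reference_cbar, scale, normalize_acf, integration,
                replicate_policy
    [synth]     n_residues, n_waters_per_residue, noise, seed

Unknown sections or keys are rejected so typos cannot silently fall back
to defaults. Command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .hydration_counter import CountParams
from .parch_core import ParchParams
from .synthetic import SyntheticScenario
from .system_builder import AnnealingSchedule, BuildParams

SECTION_TYPES = {
    "build": BuildParams,
    "schedule": AnnealingSchedule,
    "count": CountParams,
    "parch": ParchParams,
    "synth": SyntheticScenario,
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    """Parse a TOML config into {section: kwargs dict}, validating keys."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out: dict[str, dict] = {}
    for section, body in raw.items():
        if section not in SECTION_TYPES:
            raise ConfigError(f"{path}: unknown config section [{section}]")
        if not isinstance(body, dict):
            raise ConfigError(f"{path}: section [{section}] must be a table")
        allowed = {f.name for f in dataclasses.fields(SECTION_TYPES[section])}
        unknown = set(body) - allowed
        if unknown:
            raise ConfigError(
                f"{path}: unknown keys in [{section}]: {', '.join(sorted(unknown))}"
            )
        out[section] = dict(body)
    return out


def make_params(config: dict, section: str, **overrides):
    """Instantiate the dataclass for `section`, applying CLI overrides."""
    kwargs = dict(config.get(section, {}))
    for key, val in overrides.items():
        if val is not None:
            kwargs[key] = val
    return SECTION_TYPES[section](**kwargs)
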