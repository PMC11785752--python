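"""Configuration files: TOML or YAML with [dynamics] and [clamps] sections.

Example (TOML):

    [dynamics]
    h = 10.0
    gamma = 1.0
    t_end = 30.0

    [clamps]
    TNF = 1.0
"""

from __future__ import annotations

from pathlib import Path

from .dynamics import SimulationConfig

_DYNAMICS_FIELDS = {
    "h", "gamma", "alpha", "beta", "t_end", "t_max", "ss_tol",
    "rel_tol", "abs_tol", "cluster_tol", "phenotype_margin",
}


def load_config(path) -> tuple[SimulationConfig, dict[str, float]]:
    """Read a TOML (.toml) or YAML (.yml/.yaml) config file.

    Returns the :class:`SimulationConfig` (unspecified fields keep their
    defaults) and the clamp mapping (possibly empty).  Unknown keys in
    [dynamics] are rejected so typos do not silently fall back to defaults.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    elif suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format {suffix!r} (use TOML or YAML)")
    dynamics = dict(data.get("dynamics", {}))
    unknown = set(dynamics) - _DYNAMICS_FIELDS
    if unknown:
        raise ValueError(f"unknown [dynamics] keys: {sorted(unknown)}")
    cfg = SimulationConfig(**{k: float(v) for k, v in dynamics.items()})
    clamps = {str(k): float(v) for k, v in dict(data.get("clamps", {})).items()}
    return cfg, clamps
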