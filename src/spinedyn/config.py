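"""Run configuration, output writing, and run manifests.

A run configuration is a flat YAML mapping combining model parameters with
run-level settings (seed, protocol, cluster count, burn-in, output paths).
Unknown keys are rejected with the offending key named, and the seed is
mandatory so that no run is silently nondeterministic.  Outputs are plain
tabular text plus a YAML manifest sufficient to re-run the experiment
exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .params import ModelParams, ParamError
from .protocols import ProtocolResult

__all__ = ["RunConfig", "ConfigError", "load_config", "save_result"]


class ConfigError(ValueError):
    """Raised for malformed or invalid run configurations."""


RUN_KEYS = {
    "seed", "protocol", "n_clusters", "burn_in_days", "output_dir",
    "record_every", "n_days",
    # protocol-specific options
    "ltp_scale", "t_reset", "w_high", "w_low", "follow_days",
    "horizon", "sample_every", "with_offset", "post_days",
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration: model parameters plus run settings."""

    params: ModelParams
    seed: int
    protocol: str = "steady_state"
    n_clusters: int = 1_000
    burn_in_days: int = 50_000
    output_dir: str = "spinedyn_out"
    record_every: int = 1
    options: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.burn_in_days < 0:
            raise ConfigError(f"burn_in_days must be >= 0 (got {self.burn_in_days})")
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be >= 1 (got {self.n_clusters})")
        if self.record_every < 1:
            raise ConfigError(f"record_every must be >= 1 (got {self.record_every})")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML run configuration.

    Model parameters default to the standard values when omitted; the seed
    has no default.  Unknown keys raise :class:`ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    param_names = {f.name for f in dataclasses.fields(ModelParams)}
    params_kw, run_kw, options = {}, {}, {}
    for key, value in raw.items():
        if key in param_names:
            params_kw[key] = value
        elif key in ("seed", "protocol", "n_clusters", "burn_in_days",
                     "output_dir", "record_every"):
            run_kw[key] = value
        elif key in RUN_KEYS:
            options[key] = value
        else:
            raise ConfigError(f"{path}: unknown configuration key {key!r}")
    try:
        params = ModelParams.from_dict(params_kw)
    except (ParamError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if "seed" not in run_kw:
        raise ConfigError(f"{path}: a seed is required (no silent nondeterminism)")
    try:
        return RunConfig(params=params, options=options, **run_kw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_result(result: ProtocolResult, outdir: str | Path,
                extra_manifest: dict[str, Any] | None = None) -> Path:
    """Write a protocol result as a manifest plus tabular artifacts.

    The manifest (YAML) records the protocol name, seed, full parameter set,
    any extra options, the scalar summaries, and the artifact file names; it
    is sufficient to re-run the experiment exactly.  Tables are written as
    tab-separated text so results diff cleanly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for name, table in result.tables.items():
        fname = f"{result.name}_{name}.tsv"
        table.to_csv(outdir / fname, sep="\t", index=False)
        artifacts[name] = fname
    result.artifacts = artifacts
    from . import __version__

    defaults = ModelParams().to_dict()
    non_standard = {
        k: v for k, v in result.params_used.to_dict().items() if v != defaults[k]
    }
    manifest = {
        "protocol": result.name,
        "seed": result.seed,
        "spinedyn_version": __version__,
        "params": result.params_used.to_dict(),
        "non_standard_params": non_standard,
        "options": extra_manifest or {},
        "summaries": {k: float(v) for k, v in result.summaries.items()},
        "artifacts": artifacts,
    }
    manifest_path = outdir / f"{result.name}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
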