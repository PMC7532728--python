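"""Run configuration: a small validated YAML schema for pipeline runs.

Validation collects *all* violations rather than stopping at the first,
and rejects unknown keys so typos cannot silently change a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import CompetitionParams, DEFAULT_REPLICATES

__all__ = ["RunConfig", "validate_config", "load_config", "ConfigError"]

_TOP_KEYS = {
    "mode",
    "seed",
    "n_boot",
    "rounding",
    "propagation",
    "out_dir",
    "params",
    "design",
    "inputs",
    "treatments",
}
_PARAM_KEYS = {
    "lambda_i",
    "lambda_j",
    "alpha_ii",
    "alpha_ij",
    "alpha_jj",
    "alpha_ji",
    "g_i",
    "g_j",
    "theta",
}
_PROPAGATION = {"bootstrap", "taylor1", "taylor2", "mc"}


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | csv
    seed: int = 0
    n_boot: int = 50
    rounding: int = 2
    propagation: str = "bootstrap"
    out_dir: str = "results"
    treatments: tuple[str, ...] = ("dry", "wet")
    params: dict[str, CompetitionParams] | None = None  # per treatment; simulate mode
    design_replicates: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    input_seed_production: str | None = None  # csv mode
    input_germination: str | None = None


def validate_config(raw: str | dict) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML config; returns (config, violations).

    On any violation the config is ``None`` and the list names every
    problem found, including unknown keys.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            return None, [f"YAML parse error: {exc}"]
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        return None, ["config must be a mapping"]

    v: list[str] = []
    for key in data:
        if key not in _TOP_KEYS:
            v.append(f"unknown key: {key!r}")

    mode = data.get("mode", "simulate")
    if mode not in ("simulate", "csv"):
        v.append(f"mode must be 'simulate' or 'csv', got {mode!r}")

    seed = data.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        v.append(f"seed must be an integer, got {seed!r}")

    n_boot = data.get("n_boot", 50)
    if not isinstance(n_boot, int) or isinstance(n_boot, bool) or n_boot < 2:
        v.append(f"n_boot must be an integer >= 2, got {n_boot!r}")

    rounding = data.get("rounding", 2)
    if not isinstance(rounding, int) or isinstance(rounding, bool) or rounding < 0:
        v.append(f"rounding must be a non-negative integer, got {rounding!r}")

    propagation = data.get("propagation", "bootstrap")
    if propagation not in _PROPAGATION:
        v.append(f"propagation must be one of {sorted(_PROPAGATION)}, got {propagation!r}")

    treatments = tuple(data.get("treatments", ("dry", "wet")))
    if not treatments:
        v.append("treatments must be non-empty")

    params = None
    if "params" in data:
        raw_params = data["params"]
        if not isinstance(raw_params, dict):
            v.append("params must map treatment -> parameter mapping")
        else:
            params = {}
            for trt, pd_ in raw_params.items():
                if not isinstance(pd_, dict):
                    v.append(f"params[{trt!r}] must be a mapping")
                    continue
                for key in pd_:
                    if key not in _PARAM_KEYS:
                        v.append(f"unknown key: params[{trt!r}].{key}")
                try:
                    params[str(trt)] = CompetitionParams(
                        **{k: float(val) for k, val in pd_.items() if k in _PARAM_KEYS}
                    )
                except (TypeError, ValueError) as exc:
                    v.append(f"params[{trt!r}]: {exc}")

    replicates = dict(DEFAULT_REPLICATES)
    if "design" in data:
        dsg = data["design"]
        if not isinstance(dsg, dict) or set(dsg) - {"replicates"}:
            v.append("design accepts only the 'replicates' key")
        else:
            reps = dsg.get("replicates", {})
            try:
                replicates = {int(d): int(n) for d, n in reps.items()}
            except (TypeError, ValueError):
                v.append("design.replicates must map integer density -> integer count")
            else:
                for d, n in replicates.items():
                    if d < 0:
                        v.append(f"design.replicates: negative density {d}")
                    if n <= 0:
                        v.append(f"design.replicates: non-positive count {n} at density {d}")

    inp_sp = inp_germ = None
    if "inputs" in data:
        inputs = data["inputs"]
        if not isinstance(inputs, dict) or set(inputs) - {"seed_production", "germination"}:
            v.append("inputs accepts only 'seed_production' and 'germination' keys")
        else:
            inp_sp = inputs.get("seed_production")
            inp_germ = inputs.get("germination")
    if mode == "csv" and inp_sp is None:
        v.append("csv mode requires inputs.seed_production")
    if mode == "simulate" and params is None:
        v.append("simulate mode requires params (per-treatment parameter mappings)")

    if v:
        return None, v
    return (
        RunConfig(
            mode=mode,
            seed=seed,
            n_boot=n_boot,
            rounding=rounding,
            propagation=propagation,
            out_dir=str(data.get("out_dir", "results")),
            treatments=treatments,
            params=params,
            design_replicates=replicates,
            input_seed_production=inp_sp,
            input_germination=inp_germ,
        ),
        [],
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a config file, raising ``ConfigError`` on violations."""
    cfg, violations = validate_config(Path(path).read_text())
    if cfg is None:
        raise ConfigError(violations)
    return cfg
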