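"""Run configuration: YAML schema, validation, lossless round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .environment import EnvParams
from .model import ModelParams


class ConfigError(ValueError):
    """Configuration file violates the schema; message carries field paths."""


_DEFAULTS = {
    "delta": 0.0,
    "n_reps": 500,
    "seed": 0,
    "horizon": None,  # None -> 2<K>
    "init": "coexistence",  # or [NR0, NS0, xi0]
    "stop_at_absorption": True,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated model + environment + ensemble settings."""

    model: ModelParams
    env: EnvParams
    n_reps: int = 500
    seed: int = 0
    horizon: float | None = None
    init: str | tuple[int, int, int] = "coexistence"
    stop_at_absorption: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": {"s": self.model.s, "a": self.model.a, "nth": self.model.nth},
            "env": {
                "Kplus": self.env.Kplus,
                "Kminus": self.env.Kminus,
                "nu": self.env.nu,
                "delta": self.env.delta,
            },
            "n_reps": self.n_reps,
            "seed": self.seed,
            "horizon": self.horizon,
            "init": list(self.init) if isinstance(self.init, tuple) else self.init,
            "stop_at_absorption": self.stop_at_absorption,
        }
        if self.extras:
            d["extras"] = dict(self.extras)
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _require(d: dict, section: str, key: str):
    if key not in d:
        raise ConfigError(f"{section}.{key}: required field missing")
    return d[key]


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    msec = raw.get("model")
    esec = raw.get("env")
    if not isinstance(msec, dict):
        raise ConfigError("model: required section missing")
    if not isinstance(esec, dict):
        raise ConfigError("env: required section missing")
    try:
        model = ModelParams(
            s=float(_require(msec, "model", "s")),
            a=float(_require(msec, "model", "a")),
            nth=int(_require(msec, "model", "nth")),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    try:
        env = EnvParams(
            Kplus=float(_require(esec, "env", "Kplus")),
            Kminus=float(_require(esec, "env", "Kminus")),
            nu=float(_require(esec, "env", "nu")),
            delta=float(esec.get("delta", _DEFAULTS["delta"])),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    init = raw.get("init", _DEFAULTS["init"])
    if isinstance(init, (list, tuple)):
        if len(init) != 3:
            raise ConfigError("init: expected [NR0, NS0, xi0]")
        init = (int(init[0]), int(init[1]), int(init[2]))
        if init[2] not in (-1, 1):
            raise ConfigError("init[2]: xi0 must be -1 or +1")
    elif init != "coexistence":
        raise ConfigError(f"init: unknown rule {init!r}")

    horizon = raw.get("horizon", _DEFAULTS["horizon"])
    if horizon is not None:
        horizon = float(horizon)
        if horizon <= 0:
            raise ConfigError(f"horizon: must be positive, got {horizon}")
    n_reps = int(raw.get("n_reps", _DEFAULTS["n_reps"]))
    if n_reps < 1:
        raise ConfigError(f"n_reps: must be >= 1, got {n_reps}")

    known = {"model", "env", "init", "horizon", "n_reps", "seed", "stop_at_absorption", "extras"}
    extras = dict(raw.get("extras", {}))
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    return RunConfig(
        model=model,
        env=env,
        n_reps=n_reps,
        seed=int(raw.get("seed", _DEFAULTS["seed"])),
        horizon=horizon,
        init=init,
        stop_at_absorption=bool(raw.get("stop_at_absorption", _DEFAULTS["stop_at_absorption"])),
        extras=extras,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)
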