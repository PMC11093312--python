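"""Named configuration presets (flat TOML key-value files).

Controller presets ``insilico`` and ``invitro`` carry the published design
parameters verbatim; the pump-plant and PID presets are artifact-chosen
and documented as such in their files.  Users can point any loader at an
external TOML file instead of a shipped preset name.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .controllers import PIDConfig, SMCConfig
from .pump_model import PumpParams, PumpPlant, PumpState

__all__ = [
    "available_presets",
    "load_preset",
    "load_smc_config",
    "load_pid_config",
    "load_pump_plant",
]

_PREFIX = {"smc": "smc_", "pid": "pid_", "pump": "pump_"}


def _preset_dir():
    return resources.files("ionloop") / "presets"


def available_presets() -> dict[str, list[str]]:
    """Shipped preset names, grouped by kind (smc / pid / pump)."""
    out: dict[str, list[str]] = {k: [] for k in _PREFIX}
    for entry in _preset_dir().iterdir():
        if not entry.name.endswith(".toml"):
            continue
        stem = entry.name[:-5]
        for kind, prefix in _PREFIX.items():
            if stem.startswith(prefix):
                out[kind].append(stem[len(prefix):])
    return out


def load_preset(name: str, kind: str) -> dict:
    """Raw key-value mapping of a shipped preset or an external TOML path."""
    path = Path(name)
    if path.suffix == ".toml" and path.exists():
        return tomllib.loads(path.read_text())
    res = _preset_dir() / f"{_PREFIX[kind]}{name}.toml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        known = ", ".join(available_presets()[kind]) or "<none>"
        raise KeyError(f"unknown {kind} preset {name!r} (available: {known})")
    return tomllib.loads(text)


def load_smc_config(name: str = "invitro", **overrides) -> SMCConfig:
    data = load_preset(name, "smc") | overrides
    return SMCConfig(**data)


def load_pid_config(name: str = "insilico", **overrides) -> PIDConfig:
    data = load_preset(name, "pid") | overrides
    return PIDConfig(**data)


def load_pump_plant(name: str = "insilico", **overrides) -> PumpPlant:
    data = load_preset(name, "pump") | overrides
    x1 = data.pop("x1_init", 0.0)
    x2 = data.pop("x2_init", 0.0)
    T = data.pop("T", 1.0)
    substeps = int(data.pop("substeps", 10))
    return PumpPlant(params=PumpParams(**data), state=PumpState(x1, x2),
                     T=T, substeps=substeps)
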