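"""Plain-text configuration files and run manifests.

The config format is INI with four sections — [engine], [simulate],
[analyze], [power] — every key documented by its default.  Unknown
sections or keys are rejected rather than ignored, and a parsed config
re-serialises to the identical canonical text (lossless round trip).
Every artifact-producing run is stamped with a manifest carrying the
command, seed, config hash, and software version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .simulator import SimConfig


@dataclass
class ConfigFile:
    """Typed view of the four config sections with their defaults."""

    # [engine]
    practice_max_items: int = 100
    # [simulate]
    n: int = 87
    seed: int = 0
    mode: str = "engine"
    base_rate: float = 1.7
    age_slope: float = 0.0085
    trait_sd: float = 0.18
    item_sd: float = 0.35
    cond_noise_sd: float = 0.106
    inhibition_cost_sd: float = 0.11
    switching_cost_sd: float = 0.08
    error_proneness_sd: float = 0.5
    missingness: bool = False
    # [analyze]
    round_decimals: int = 2
    # [power]
    alpha_level: float = 0.05
    target_power: float = 0.80

    _SECTIONS = {
        "engine": ("practice_max_items",),
        "simulate": ("n", "seed", "mode", "base_rate", "age_slope", "trait_sd",
                     "item_sd", "cond_noise_sd", "inhibition_cost_sd",
                     "switching_cost_sd", "error_proneness_sd", "missingness"),
        "analyze": ("round_decimals",),
        "power": ("alpha_level", "target_power"),
    }

    def to_text(self) -> str:
        lines = []
        for section, keys in self._SECTIONS.items():
            lines.append(f"[{section}]")
            for k in keys:
                lines.append(f"{k} = {getattr(self, k)}")
            lines.append("")
        return "\n".join(lines)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n=self.n, seed=self.seed, mode=self.mode, base_rate=self.base_rate,
            age_slope=self.age_slope, trait_sd=self.trait_sd,
            item_sd=self.item_sd, cond_noise_sd=self.cond_noise_sd,
            inhibition_cost_sd=self.inhibition_cost_sd,
            switching_cost_sd=self.switching_cost_sd,
            error_proneness_sd=self.error_proneness_sd,
            missingness=self.missingness,
        )


class ConfigError(ValueError):
    """Malformed config file: unknown section/key or a bad value."""


def _coerce(name: str, raw: str):
    kind = ConfigFile.__dataclass_fields__[name].type
    raw = raw.strip()
    if kind == "bool":
        if raw not in ("True", "False", "true", "false"):
            raise ConfigError(f"{name}: expected a boolean, got {raw!r}")
        return raw in ("True", "true")
    if kind == "int":
        return int(raw)
    if kind == "float":
        return float(raw)
    return raw


def parse_config(text: str) -> ConfigFile:
    """Parse config text, rejecting unknown sections and keys."""
    cfg = ConfigFile()
    section = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", ";")):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section not in ConfigFile._SECTIONS:
                raise ConfigError(f"line {lineno}: unknown section [{section}]")
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        if section is None:
            raise ConfigError(f"line {lineno}: key outside any section")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in ConfigFile._SECTIONS[section]:
            raise ConfigError(f"line {lineno}: unknown key {key!r} in [{section}]")
        try:
            setattr(cfg, key, _coerce(key, value))
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"line {lineno}: bad value for {key}: {exc}") from exc
    return cfg


def load_config(path: str | Path | None) -> ConfigFile:
    if path is None:
        return ConfigFile()
    return parse_config(Path(path).read_text(encoding="utf-8"))


def config_hash(cfg: ConfigFile) -> str:
    """Short content hash of the canonical serialisation."""
    return hashlib.sha256(cfg.to_text().encode("utf-8")).hexdigest()[:12]


@dataclass
class RunManifest:
    """Provenance record written next to every artifact a run produces."""

    command: str
    seed: int
    config_hash: str
    version: str = __version__
    started_at: str = ""
    finished_at: str = ""
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text(encoding="utf-8")))


def now_iso() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
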