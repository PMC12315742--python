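"""Harmonization run configuration: strict schema, YAML save/load.

One canonical, human-readable dialect.  Unknown keys are rejected outright —
a typo like ``parametirc`` must fail loudly, not silently fall back to a
default.  ``save -> load -> save`` is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import HarmonizationError

METHODS = ("combat", "covbat", "sma", "linear", "icvae")

_INPUT_KEYS = {"mode", "parent_dirs", "route", "identifier", "exemplar",
               "mask", "mask_lh", "mask_rh", "space", "organized_file",
               "files"}
_OUTPUT_KEYS = {"out_dir", "organize_csv", "network_output"}
_METHOD_KEYS = {
    "combat": {"name", "parametric", "adjusted", "adjust_vars"},
    "covbat": {"name", "parametric", "adjusted", "adjust_vars",
               "covbat_parametric", "retention"},
    "sma": {"name", "fit_type", "z_variables", "zcuts", "target_site",
            "n_subsamples"},
    "linear": {"name", "model", "adjusted", "adjust_vars"},
    "icvae": {"name", "target_site", "epochs", "learning_rate", "batch_size"},
}
_TOP_KEYS = {"input", "demographics", "method", "output", "workers", "seed"}


def parse_zcut(value) -> object:
    """'0' -> 0 (categorical); '20,40' -> [20.0, 40.0] (ascending cutpoints)."""
    if value in (0, "0"):
        return 0
    if isinstance(value, (int, float)):
        return [float(value)]
    if isinstance(value, str):
        cuts = [float(v) for v in value.split(",") if v.strip() != ""]
    else:
        cuts = [float(v) for v in value]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise HarmonizationError(f"Zcut cutpoints must be strictly ascending: {cuts}")
    return cuts


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise HarmonizationError(f"unknown key(s) in {where}: {unknown}")


@dataclass
class HarmonizationConfig:
    """Validated run configuration (one method, one input mode)."""

    input: dict
    demographics: str
    method: dict
    output: dict
    workers: int = 0
    seed: int = 0
    _defaults: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        _reject_unknown(self.input, _INPUT_KEYS, "input")
        _reject_unknown(self.output, _OUTPUT_KEYS, "output")
        mode = self.input.get("mode")
        if mode not in ("sites", "filelist", "organized"):
            raise HarmonizationError(
                f"input.mode must be sites|filelist|organized, got {mode!r}")
        name = self.method.get("name")
        if name not in METHODS:
            raise HarmonizationError(
                f"method.name must be one of {METHODS}, got {name!r}")
        _reject_unknown(self.method, _METHOD_KEYS[name], f"method ({name})")
        if name == "sma" and "zcuts" in self.method:
            self.method["zcuts"] = {
                k: parse_zcut(v) for k, v in self.method["zcuts"].items()}
        if not isinstance(self.workers, int) or self.workers < 0:
            raise HarmonizationError("workers must be a non-negative integer")

    def to_dict(self) -> dict:
        return {
            "input": dict(self.input),
            "demographics": self.demographics,
            "method": dict(self.method),
            "output": dict(self.output),
            "workers": self.workers,
            "seed": self.seed,
        }

    def __eq__(self, other):
        return isinstance(other, HarmonizationConfig) and \
            self.to_dict() == other.to_dict()


def save_config(config: HarmonizationConfig, path) -> Path:
    path = Path(path)
    text = yaml.safe_dump(config.to_dict(), sort_keys=False,
                          default_flow_style=False)
    path.write_text(text)
    return path


def load_config(path) -> HarmonizationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise HarmonizationError("config file must hold a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    missing = sorted(k for k in ("input", "demographics", "method", "output")
                     if k not in raw)
    if missing:
        raise HarmonizationError(f"config is missing section(s): {missing}")
    return HarmonizationConfig(
        input=raw["input"], demographics=raw["demographics"],
        method=raw["method"], output=raw["output"],
        workers=raw.get("workers", 0), seed=raw.get("seed", 0),
    )
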