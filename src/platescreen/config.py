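"""YAML run configuration for the CLI.

Keys are namespaced per stage; unknown keys are rejected so that typos fail
loudly rather than silently falling back to defaults::

    io:
      screen_csv: screen.csv
      truth_yaml: truth.yaml
      decimal_places: 4
    qc:
      z_cutoff: 0.4
      sw_cutoff: 2.0
      cv_cutoff: 20.0
      sw_replicate_corrected: true
    fit:
      grmax_variant: single_top   # or top_two
      x0_scope: experiment        # or screen
    simulation:                   # SimTruth fields (see platescreen.sim)
      ...
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ValidationError
from .sim import SimTruth

_KNOWN = {
    "io": {"screen_csv", "truth_yaml", "decimal_places"},
    "qc": {"z_cutoff", "sw_cutoff", "cv_cutoff", "sw_replicate_corrected"},
    "fit": {"grmax_variant", "x0_scope"},
    "simulation": None,  # validated by SimTruth itself
    "seed": None,
}


@dataclass
class RunConfig:
    io: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    simulation: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cut in ("z_cutoff", "sw_cutoff", "cv_cutoff"):
            if cut in self.qc and float(self.qc[cut]) <= 0:
                raise ValidationError(f"qc.{cut} must be positive")
        variant = self.fit.get("grmax_variant", "single_top")
        if variant not in ("single_top", "top_two"):
            raise ValidationError(f"fit.grmax_variant: unknown value {variant!r}")
        scope = self.fit.get("x0_scope", "experiment")
        if scope not in ("experiment", "screen"):
            raise ValidationError(f"fit.x0_scope: unknown value {scope!r}")

    def sim_truth(self) -> SimTruth:
        if not self.simulation:
            raise ValidationError("config has no 'simulation' section")
        d = dict(self.simulation)
        d.setdefault("seed", self.seed)
        return SimTruth.from_dict(d)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    unknown = set(raw) - set(_KNOWN)
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in _KNOWN.items():
        if allowed is None or section not in raw:
            continue
        bad = set(raw[section] or {}) - allowed
        if bad:
            raise ValidationError(f"unknown config key(s) in {section!r}: {sorted(bad)}")
    return RunConfig(
        io=raw.get("io", {}) or {},
        qc=raw.get("qc", {}) or {},
        fit=raw.get("fit", {}) or {},
        simulation=raw.get("simulation"),
        seed=int(raw.get("seed", 0)),
    )
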