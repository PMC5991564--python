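"""Run configuration: flat key=value config files, seeds, logging.

The config format is deliberately minimal — one ``key = value`` pair per
line, ``#`` comments — so runs are scriptable and diffable.  CLI flags
override file values, which override the defaults below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    bootstrap_replicates: int = 1000
    detection_threshold: float = 0.03  # assay sensitivity: >3% mutant mtDNA
    logit_clamp_epsilon: float = 0.005
    respiratory_item: int = 8  # which NMDAS item is respiratory function
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not (0.0 < self.logit_clamp_epsilon < 0.5):
            raise ValueError("logit_clamp_epsilon must be in (0, 0.5)")
        if not (0.0 <= self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must be a proportion")


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional flat key=value file plus overrides."""
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            values[key] = raw
    field_types = {f.name: f.type for f in fields(RunConfig)}
    parsed = {}
    for key, raw in values.items():
        if key not in field_types:
            raise ValueError(f"unknown config key: {key}")
        typ = field_types[key]
        parsed[key] = raw if typ == "str" else (int(raw) if typ == "int" else float(raw))
    parsed.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**parsed)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
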