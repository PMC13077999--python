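"""Screen configuration: every analysis threshold in one (YAML-able) place.

Defaults are the screen's canonical settings: ladder 5e-8 … 5e-6, clump
r² < 0.001 in a 10,000-kb window, proxy r² > 0.9, palindrome MAF limit
0.42, at least 5 LD-independent instruments, radial outlier alpha 0.05
with iteration, Bonferroni control of the family-wise error rate at 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from mrscreen.instruments import DEFAULT_LADDER


@dataclass
class ScreenConfig:
    ladder: tuple = DEFAULT_LADDER
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2_min: float = 0.9
    maf_limit: float = 0.42
    min_instruments: int = 5
    radial_alpha: float = 0.05
    radial_iterate: bool = True
    radial_bonferroni: bool = True   # per-set alpha/J: keeps the screen's FWER calibrated
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0
    correction: str = "bonferroni"      # or "benjamini_hochberg"
    alpha_family: float = 0.05
    qq_lambda_bound: float = 1.1
    loo_sig_level: float = 0.05

    def __post_init__(self):
        self.ladder = tuple(float(x) for x in self.ladder)
        if self.correction not in ("bonferroni", "benjamini_hochberg"):
            raise ValueError(f"unknown correction {self.correction!r}")

    def replace(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)

    def digest(self) -> str:
        """Stable short hash of the configuration, for provenance."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
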