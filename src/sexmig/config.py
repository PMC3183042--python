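"""Run configuration: grid, demographic constants, conventions, alpha.

A single YAML file (any subset of keys) overridden by CLI flags; the fully
resolved configuration is embedded in every output JSON so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .inference import ParameterGrid
from .markers import ConventionConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    mig_min: float = 0.01
    mig_max: float = 10.0
    n_mig: int = 201
    n_p: int = 201
    duration: float = 1.0
    N: int = 1000
    alpha: float = 0.05
    ne_convention: str = "copy_count"
    short_branch_rule: str = "coalesced_or_same_pop"
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    _FIELDS = (
        "mig_min", "mig_max", "n_mig", "n_p", "duration", "N", "alpha",
        "ne_convention", "short_branch_rule", "log_level",
    )

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file plus keyword overrides.

        Overrides with value ``None`` are ignored so CLI flags can be
        passed through unconditionally.
        """
        values: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {k: values.pop(k) for k in list(values) if k in cls._FIELDS}
        cfg = cls(**known)
        cfg.extras = values
        cfg.grid()  # validate grid spec eagerly
        cfg.conventions()  # validate convention names eagerly
        return cfg

    def grid(self) -> ParameterGrid:
        p = np.linspace(0.0, 1.0, self.n_p)
        if not np.any(p == 0.5):  # keep the null line on the grid
            p = np.unique(np.append(p, 0.5))
        return ParameterGrid(
            mig_values=np.geomspace(self.mig_min, self.mig_max, self.n_mig),
            p_values=p,
        )

    def conventions(self) -> ConventionConfig:
        return ConventionConfig(
            ne_convention=self.ne_convention,
            short_branch_rule=self.short_branch_rule,
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
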