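"""Reading and writing patterns, surfaces and test results.

Pattern files are either a JSON list of ``{"marker", "branch", "count"}``
objects or a TSV with columns ``marker``/``branch``/``count``.  Marker
names A, X, Y, MT and branch names short/long are case-insensitive.
Surfaces are written as TSV with columns ``two_Nm``, ``p``, ``loglik``,
``in_ci``; test results as JSON.  All numbers use 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    Branch,
    LikelihoodSurface,
    ObservedPattern,
    PatternRecord,
    TestResult,
)
from .markers import MarkerClass

__all__ = [
    "read_pattern",
    "write_pattern",
    "write_surface_tsv",
    "write_test_result",
]

_FMT = "%.12g"


def _record_from_mapping(obj: dict, where: str) -> PatternRecord:
    try:
        marker = MarkerClass.parse(obj["marker"])
        branch = Branch.parse(obj["branch"])
        count = int(obj["count"])
        return PatternRecord(marker, branch, count)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed pattern record at {where}: {obj!r} ({exc})") from exc


def read_pattern(path: str | Path) -> ObservedPattern:
    """Load an observed pattern from a JSON or TSV file (format sniffed)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"pattern file {path} is empty")
    if text.lstrip().startswith(("[", "{")):
        data = json.loads(text)
        if isinstance(data, dict):
            data = data.get("pattern", data)
        if not isinstance(data, list):
            raise ValueError(f"pattern JSON in {path} must be a list of records")
        records = [
            _record_from_mapping(obj, f"{path}:{i}") for i, obj in enumerate(data)
        ]
    else:
        frame = pd.read_csv(path, sep="\t")
        missing = {"marker", "branch", "count"} - set(frame.columns)
        if missing:
            raise ValueError(f"pattern TSV {path} lacks columns: {sorted(missing)}")
        records = [
            _record_from_mapping(row, f"{path} row {i}")
            for i, row in enumerate(frame.to_dict("records"))
        ]
    return ObservedPattern(tuple(records))


def write_pattern(pattern: ObservedPattern, path: str | Path) -> None:
    data = [
        {"marker": r.marker.value, "branch": r.branch.value, "count": r.count}
        for r in pattern.records
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def write_surface_tsv(surface: LikelihoodSurface, path: str | Path) -> None:
    """Long-format TSV: one row per (2Nm, p) grid point."""
    mig, p = np.meshgrid(
        surface.grid.mig_values, surface.grid.p_values, indexing="ij"
    )
    frame = pd.DataFrame(
        {
            "two_Nm": mig.ravel(),
            "p": p.ravel(),
            "loglik": surface.loglik.ravel(),
            "in_ci": surface.ci_mask.ravel().astype(int),
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format=_FMT)


def write_test_result(
    result: TestResult, path: str | Path, run_config: dict | None = None
) -> None:
    """JSON test result, embedding the resolved run configuration."""
    payload = result.to_dict()
    if run_config is not None:
        payload["run_config"] = run_config
    Path(path).write_text(json.dumps(payload, indent=1, default=float) + "\n")
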