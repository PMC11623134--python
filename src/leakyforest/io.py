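"""CSV / JSON / YAML input-output and run manifests.

All predictor columns are read as categorical strings — never coerced to
numbers — because the library's whole subject is the encoding of nominal
levels ("007" stays "007"). Output directories receive plain CSVs plus a
``manifest.json`` capturing the configuration and master seed, which is
sufficient to reproduce every number bit-exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .simulation import SimulationConfig

__all__ = ["read_table", "write_results", "load_config"]

logger = logging.getLogger(__name__)


def read_table(path: str | Path, response: str) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Read a CSV of categorical columns; returns (frame, class_order).

    Every column is kept as a string; class_order is the sorted set of
    observed response labels.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise ValueError(f"{path} is empty")
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:  # pandas silently renames duplicates, so check the raw header
        raise ValueError(f"{path} has duplicate column names: {dups}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(frame) == 0:
        raise ValueError(f"{path} contains no data rows")
    if response not in frame.columns:
        raise KeyError(f"response column {response!r} not found in {path}")
    class_order = tuple(sorted(frame[response].unique()))
    return frame, class_order


def write_results(
    results: dict[str, pd.DataFrame],
    outdir: str | Path,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write named CSVs plus a manifest; overwrites idempotently with a warning."""
    if not results:
        raise ValueError("no results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in results.items():
        target = outdir / f"{name}.csv"
        if target.exists():
            logger.warning("overwriting %s", target)
        frame.to_csv(target, index=False)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "files": sorted(f"{name}.csv" for name in results),
    }
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        logger.warning("overwriting %s", manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON (fields mirror the dataclass)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return SimulationConfig.from_dict(data)
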