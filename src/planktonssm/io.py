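"""Reading and writing the on-disk survey layout.

A data directory holds two delimited text tables — ``lakes.csv`` (one row
per lake: lake_id, fish_present, temp_c, tot_p, tot_n, toc, veg_cover) and
``series.csv`` (lake_id, time_index, chla_obs, zoop_obs) — plus, for
synthetic data, ``truth.json`` with the generating hyperparameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .params import HyperParams

__all__ = ["write_dataset", "read_data", "read_truth", "load_structured"]

LAKES_FILE = "lakes.csv"
SERIES_FILE = "series.csv"
TRUTH_FILE = "truth.json"


def write_dataset(dataset, outdir) -> Path:
    """Write a SyntheticDataset as lakes.csv + series.csv + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lakes, series = dataset.to_frames()
    lakes.to_csv(outdir / LAKES_FILE, index=False)
    series.to_csv(outdir / SERIES_FILE, index=False)
    (outdir / TRUTH_FILE).write_text(json.dumps(dataset.truth.to_dict(), indent=1))
    return outdir


def read_data(datadir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the two survey tables; raises FileNotFoundError naming the
    missing file."""
    datadir = Path(datadir)
    frames = []
    for name in (LAKES_FILE, SERIES_FILE):
        path = datadir / name
        if not path.exists():
            raise FileNotFoundError(f"expected data file not found: {path}")
        frames.append(pd.read_csv(path))
    lakes, series = frames
    lakes["lake_id"] = lakes["lake_id"].astype(str)
    series["lake_id"] = series["lake_id"].astype(str)
    return lakes, series


def read_truth(datadir) -> HyperParams:
    path = Path(datadir) / TRUTH_FILE
    if not path.exists():
        raise FileNotFoundError(f"expected truth file not found: {path}")
    return HyperParams.from_dict(json.loads(path.read_text()))


def load_structured(path) -> dict:
    """Load a YAML or JSON config file (both are accepted everywhere)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
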