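"""On-disk dataset layout shared by the preprocessing and synthesis paths.

A dataset directory holds ``manifest.csv`` (one row per nodule: id, label,
the flattened 9x4 rating values, cube filename) and a ``cubes/`` directory
with one ``.npz`` per nodule.  Arrays are stored as float64, so a
write/read round-trip is bit-exact.  Downstream code reads synthetic and
real preprocessed datasets through the same functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ATTRIBUTE_NAMES, N_READERS
from .train import Dataset

_RATING_COLS = [f"{name}_r{j}" for name in ATTRIBUTE_NAMES
                for j in range(N_READERS)]


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  metadata: dict | None = None) -> Path:
    """Write manifest + cubes; returns the dataset directory."""
    out_dir = Path(out_dir)
    cube_dir = out_dir / "cubes"
    cube_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, nodule_id in enumerate(dataset.ids):
        safe = nodule_id.replace(":", "_").replace("/", "_")
        cube_file = f"{safe}.npz"
        np.savez_compressed(cube_dir / cube_file, cube=dataset.cubes[i])
        row = {"nodule_id": nodule_id, "label": int(dataset.labels[i]),
               "cube_file": cube_file}
        flat = dataset.ratings[i].reshape(-1)
        row.update({col: flat[j] for j, col in enumerate(_RATING_COLS)})
        rows.append(row)
    # %.17g round-trips float64 exactly through the text manifest
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False,
                              float_format="%.17g")
    if metadata is not None:
        (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=2))
    return out_dir


def read_dataset(in_dir: str | Path) -> Dataset:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv",
                           float_precision="round_trip")
    n = len(manifest)
    ratings = np.empty((n, 9, 4))
    cubes = np.empty((n, 32, 32, 32))
    for i, row in manifest.iterrows():
        ratings[i] = np.array([row[c] for c in _RATING_COLS]).reshape(9, 4)
        with np.load(in_dir / "cubes" / row["cube_file"]) as data:
            cubes[i] = data["cube"]
    return Dataset(ratings, cubes, manifest["label"].to_numpy(),
                   manifest["nodule_id"].astype(str).tolist())
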