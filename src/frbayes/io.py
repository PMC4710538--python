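"""Reading and writing consumption-experiment tables.

The on-disk format is plain comma-separated text with the header
columns ``predator_density, initial_prey, prey_eaten, exposure_hours,
replicate``; one row per replicate.  Files may mix predator densities;
reading groups rows into one :class:`~frbayes.inference.Dataset` per
density.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .inference import Dataset

__all__ = ["REQUIRED_COLUMNS", "read_observations", "write_observations"]

REQUIRED_COLUMNS = (
    "predator_density",
    "initial_prey",
    "prey_eaten",
    "exposure_hours",
    "replicate",
)


def read_observations(path: Union[str, Path]) -> dict[int, Dataset]:
    """Read a consumption table, validated, grouped by predator density.

    Malformed rows are reported with their file line number (the header
    is line 1).  ``prey_eaten > initial_prey`` is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        p, n0, ne, t = (
            row["predator_density"],
            row["initial_prey"],
            row["prey_eaten"],
            row["exposure_hours"],
        )
        if not np.isfinite([p, n0, ne, t]).all():
            errors.append(f"line {line}: non-numeric or missing value")
            continue
        if p < 1 or p != int(p):
            errors.append(f"line {line}: predator_density must be a positive integer, got {p}")
        if n0 < 1 or n0 != int(n0):
            errors.append(f"line {line}: initial_prey must be a positive integer, got {n0}")
        if ne < 0 or ne != int(ne):
            errors.append(f"line {line}: prey_eaten must be a non-negative integer, got {ne}")
        elif ne > n0:
            errors.append(f"line {line}: prey_eaten ({int(ne)}) exceeds initial_prey ({int(n0)})")
        if t <= 0:
            errors.append(f"line {line}: exposure_hours must be > 0, got {t}")
    if errors:
        raise ValueError(f"{path}: invalid observation rows:\n" + "\n".join(errors))
    out = {}
    for p, group in df.groupby("predator_density", sort=True):
        out[int(p)] = Dataset(
            predator_density=int(p),
            n0=group["initial_prey"].to_numpy(int),
            ne=group["prey_eaten"].to_numpy(int),
            t=group["exposure_hours"].to_numpy(float),
        )
    return out


def write_observations(
    datasets: Union[Dataset, Mapping[int, Dataset]], path: Union[str, Path]
) -> None:
    """Write one or several datasets as a single CSV table."""
    if isinstance(datasets, Dataset):
        datasets = {datasets.predator_density: datasets}
    frames = []
    for p in sorted(datasets):
        frame = datasets[p].to_frame()
        frame["replicate"] = np.arange(1, len(frame) + 1)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)[list(REQUIRED_COLUMNS)]
    table.to_csv(path, index=False)
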