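"""Reading and writing the pipeline's on-disk formats.

Count tables and truth tables are plain CSV; z-stacks are multi-page TIFF
(plane-major, both channels concatenated) with a JSON sidecar carrying the
geometry, channel layout and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from fociscreen.imaging import ZStack
from fociscreen.synthgen import RECORD_COLUMNS


class SchemaError(ValueError):
    """A CSV does not match the shared per-cell record schema."""


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a per-cell count table.

    Raises :class:`SchemaError` with an itemised message naming every
    missing column or type violation.
    """
    df = pd.read_csv(path)
    problems = [f"missing column: {c!r}" for c in RECORD_COLUMNS if c not in df.columns]
    if not problems:
        if not pd.api.types.is_integer_dtype(df["foci_count"]):
            problems.append("column 'foci_count' must be integer")
        elif (df["foci_count"] < 0).any():
            problems.append("column 'foci_count' contains negative values")
        if not pd.api.types.is_integer_dtype(df["cell_index"]):
            problems.append("column 'cell_index' must be integer")
        else:
            dup = df.duplicated(["individual_id", "condition", "cell_index"])
            if dup.any():
                problems.append(
                    "duplicate cell_index within an individual x condition"
                )
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def write_zstack(stack: ZStack, path, seed: int | None = None) -> None:
    """Write both channels as one plane-major multi-page TIFF + JSON sidecar."""
    path = Path(path)
    pages = np.concatenate([stack.nucleus, stack.foci], axis=0)
    tifffile.imwrite(path, pages)
    meta = {
        "n_planes": stack.n_planes,
        "plane_spacing_um": stack.plane_spacing_um,
        "pixel_size_um": stack.pixel_size_um,
        "channels": ["nucleus", "foci"],
        "page_order": "channel-major blocks of n_planes pages",
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_zstack(path) -> ZStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path)
    n = int(meta["n_planes"])
    if pages.shape[0] != 2 * n:
        raise ValueError(f"expected {2 * n} pages, found {pages.shape[0]}")
    return ZStack(
        nucleus=pages[:n],
        foci=pages[n:],
        plane_spacing_um=float(meta["plane_spacing_um"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )
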