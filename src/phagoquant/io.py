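"""Readers and writers for the package's tabular and image formats.

Census tables are CSV/TSV (or XLSX, so published data sheets can be
ingested directly) with one row per sample:

    sample_id, group, apo_total, apo_phagocytosed, microglia_total,
    region_volume_mm3 [, pouch_1 .. pouch_N]

Pouch histograms may instead come from a long companion table with
columns (sample_id, n_pouches, count); distances from a long table with
columns (sample_id, distance_um).  Image stacks are multi-page TIFF with
a YAML sidecar declaring the axis order, voxel sizes and frame interval.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .census import CellCensus
from .errors import ValidationError
from .motility import ZStackSeries

__all__ = [
    "read_census_table",
    "write_census_table",
    "read_stack",
    "write_stack",
    "write_json",
]

_REQUIRED_CENSUS_COLUMNS = (
    "sample_id",
    "group",
    "apo_total",
    "apo_phagocytosed",
    "microglia_total",
    "region_volume_mm3",
)
_POUCH_COL = re.compile(r"^pouch_(\d+)$")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_census_table(
    path: str | Path,
    pouch_table: str | Path | None = None,
    distance_table: str | Path | None = None,
) -> list[CellCensus]:
    """Read censuses from a wide table plus optional long companions.

    Wide ``pouch_N`` columns and a long pouch table are both accepted
    (the long table wins if both are present for a sample).  Validation
    failures name the offending rows.
    """
    df = _read_table(path)
    missing = [c for c in _REQUIRED_CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"census table missing required columns: {missing}")
    pouch_cols = {
        int(m.group(1)): c for c in df.columns if (m := _POUCH_COL.match(c))
    }
    long_pouches: dict[str, dict[int, int]] = {}
    if pouch_table is not None:
        pt = _read_table(pouch_table)
        for col in ("sample_id", "n_pouches", "count"):
            if col not in pt.columns:
                raise ValidationError(f"pouch table missing column {col!r}")
        for _, row in pt.iterrows():
            long_pouches.setdefault(str(row["sample_id"]), {})[
                int(row["n_pouches"])
            ] = int(row["count"])
    distances: dict[str, list[float]] = {}
    if distance_table is not None:
        dt = _read_table(distance_table)
        for col in ("sample_id", "distance_um"):
            if col not in dt.columns:
                raise ValidationError(f"distance table missing column {col!r}")
        for _, row in dt.iterrows():
            distances.setdefault(str(row["sample_id"]), []).append(
                float(row["distance_um"])
            )
    censuses: list[CellCensus] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        sample_id = str(row["sample_id"])
        hist = long_pouches.get(sample_id)
        if hist is None:
            hist = {
                n: int(row[c])
                for n, c in sorted(pouch_cols.items())
                if pd.notna(row[c]) and int(row[c]) > 0
            }
        try:
            censuses.append(
                CellCensus(
                    sample_id=sample_id,
                    group=str(row["group"]),
                    apo_total=int(row["apo_total"]),
                    apo_phagocytosed=int(row["apo_phagocytosed"]),
                    microglia_total=int(row["microglia_total"]),
                    pouch_histogram=hist,
                    region_volume_mm3=float(row["region_volume_mm3"]),
                    distances_um=distances.get(sample_id),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx} ({sample_id}): {exc}")
    if errors:
        raise ValidationError("invalid census rows:\n" + "\n".join(errors))
    return censuses


def write_census_table(censuses: list[CellCensus], path: str | Path) -> None:
    """Write censuses as a wide CSV (inverse of :func:`read_census_table`)."""
    max_n = max((max(c.pouch_histogram, default=0) for c in censuses), default=0)
    rows = []
    for c in censuses:
        row: dict[str, Any] = {
            "sample_id": c.sample_id,
            "group": c.group,
            "apo_total": c.apo_total,
            "apo_phagocytosed": c.apo_phagocytosed,
            "microglia_total": c.microglia_total,
            "region_volume_mm3": c.region_volume_mm3,
        }
        for n in range(1, max_n + 1):
            row[f"pouch_{n}"] = c.pouch_histogram.get(n, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stack(path: str | Path, sidecar: str | Path | dict | None = None) -> ZStackSeries:
    """Read a 4-D TIFF as a (t, z, y, x) series.

    ``sidecar`` (YAML path or dict) supplies ``axes`` (a permutation of
    "tzyx"), ``voxel_size_um`` ([dx, dy, dz]) and ``frame_interval_min``.
    A 3-D TIFF is treated as a single-frame z-stack; a 4-D TIFF without a
    declared axis order is an error.
    """
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    meta: dict[str, Any] = {}
    if isinstance(sidecar, dict):
        meta = sidecar
    elif sidecar is not None:
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if data.ndim == 3:
        data = data[None]
    elif data.ndim == 4:
        axes = meta.get("axes")
        if axes is None:
            raise ValidationError(
                "4-D TIFF without a sidecar 'axes' entry: declare the axis "
                "order explicitly (a permutation of 'tzyx')"
            )
        axes = str(axes).lower()
        if sorted(axes) != sorted("tzyx"):
            raise ValidationError(f"axes must be a permutation of 'tzyx'; got {axes!r}")
        data = np.transpose(data, [axes.index(a) for a in "tzyx"])
    else:
        raise ValidationError(f"expected a 3-D or 4-D TIFF; got shape {data.shape}")
    return ZStackSeries(
        data=data,
        voxel_size_um=tuple(meta.get("voxel_size_um", (0.1, 0.1, 1.0))),
        frame_interval_min=float(meta.get("frame_interval_min", 1.5)),
    )


def write_stack(
    stack: ZStackSeries, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write a series as TIFF (axes t,z,y,x) with an optional YAML sidecar."""
    tifffile.imwrite(str(path), stack.data.astype(np.float32), photometric="minisblack")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {
                    "axes": "tzyx",
                    "voxel_size_um": list(stack.voxel_size_um),
                    "frame_interval_min": stack.frame_interval_min,
                },
                fh,
            )


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
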