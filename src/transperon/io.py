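"""Readers and writers for the package's on-disk formats.

Images and label masks travel as TIFF (channel-major, ZYX within channel);
spot and truth tables as CSV; expression matrices as TSV (first column gene
ID, header row sample IDs); summaries as JSON.  Table writers accept a config
hash which is embedded as a leading ``#`` comment line so result bundles are
self-describing; readers skip such comments.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import Spot
from .enrich import ExpressionMatrix
from .errors import ValidationError

SPOT_COLUMNS = [
    "channel", "cell_id", "z_um", "y_um", "x_um", "intensity", "quality", "compartment",
]


def write_label_tiff(path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min(initial=0) < 0 or arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("labels must fit in uint16")
    tifffile.imwrite(str(path), arr.astype(np.uint16), photometric="minisblack")


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image_tiff(path, image: np.ndarray, config_hash: str | None = None) -> None:
    meta = {"config_hash": config_hash} if config_hash else None
    tifffile.imwrite(
        str(path),
        np.asarray(image, dtype=np.float32),
        photometric="minisblack",
        description=json.dumps(meta) if meta else None,
    )


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def _write_table(df: pd.DataFrame, path, sep: str, config_hash, index: bool) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")


def _read_table(path, sep: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def write_spot_table(path, spots, config_hash: str | None = None) -> None:
    rows = []
    for s in spots:
        z, y, x = s.position
        rows.append(
            {
                "channel": s.channel,
                "cell_id": -1 if s.cell_id is None else int(s.cell_id),
                "z_um": z,
                "y_um": y,
                "x_um": x,
                "intensity": s.intensity,
                "quality": s.quality,
                "compartment": s.compartment,
            }
        )
    df = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    _write_table(df, path, ",", config_hash, index=False)


def read_spot_table(path) -> list[Spot]:
    df = _read_table(path, ",")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    spots = []
    for row in df.itertuples(index=False):
        cell = None if row.cell_id < 0 else int(row.cell_id)
        spots.append(
            Spot(
                position=(float(row.z_um), float(row.y_um), float(row.x_um)),
                intensity=float(row.intensity),
                sigma_fit=(math.nan, math.nan, math.nan),
                quality=float(row.quality),
                channel=str(row.channel),
                cell_id=cell,
                compartment=str(row.compartment) if cell is not None else "unassigned",
            )
        )
    return spots


def write_csv(df: pd.DataFrame, path, config_hash: str | None = None, index=False) -> None:
    _write_table(df, path, ",", config_hash, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return _read_table(path, ",", **kwargs)


def write_tsv(df: pd.DataFrame, path, config_hash: str | None = None, index=True) -> None:
    _write_table(df, path, "\t", config_hash, index=index)


def read_expression_tsv(path, roles: dict[str, str], unit: str = "counts") -> ExpressionMatrix:
    df = _read_table(path, "\t", index_col=0)
    return ExpressionMatrix(values=df, roles=roles, unit=unit)


def write_json(data, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
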