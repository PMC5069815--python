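"""File-format plumbing: TIFF image naming contract and CSV tables.

Images are 16-bit grayscale TIFF, one file per plate/well/field/channel,
named ``<plate>_<well>_f<field>_<channel>.tif``.  Tables are UTF-8 CSV with
a header row; floats print at fixed precision so re-runs are byte-identical.
Pixel coordinates are 0-based (row, col) with the origin at the top-left.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

import pandas as pd
import tifffile

from .models import WellRecord, validate_layout

FLOAT_FORMAT = "%.6g"
_IMG_RE = re.compile(r"^(?P<plate>[^_]+)_(?P<well>[A-P]\d{2})_f(?P<field>\d+)"
                     r"_(?P<channel>[a-z0-9]+)\.tif$")


def image_filename(plate: str, well: str, field: int, channel: str) -> str:
    return f"{plate}_{well}_f{field}_{channel}.tif"


def write_well_images(record: WellRecord, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (field, channel), img in sorted(record.images.items()):
        path = out_dir / image_filename(record.plate, record.well, field, channel)
        tifffile.imwrite(path, img)
        written.append(path)
    return written


def read_well_images(images_dir, plate: str, well: str
                     ) -> Dict[Tuple[int, str], "object"]:
    images: Dict[Tuple[int, str], object] = {}
    for path in sorted(Path(images_dir).glob(f"{plate}_{well}_f*_*.tif")):
        m = _IMG_RE.match(path.name)
        if not m:
            continue
        images[(int(m["field"]), m["channel"])] = tifffile.imread(path)
    if not images:
        raise FileNotFoundError(
            f"no images for plate {plate!r} well {well!r} in {images_dir}")
    return images


def load_plate_records(images_dir, layout: pd.DataFrame) -> Dict[str, WellRecord]:
    """Rebuild WellRecords for every non-empty layout well from TIFFs."""
    records: Dict[str, WellRecord] = {}
    for entry in layout.itertuples(index=False):
        if entry.role == "empty":
            continue
        records[entry.well] = WellRecord(
            plate=entry.plate, well=entry.well, role=entry.role,
            compound=entry.compound, dose_m=entry.dose_M,
            replicate=int(entry.replicate),
            images=read_well_images(images_dir, entry.plate, entry.well))
    return records


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_layout(path) -> pd.DataFrame:
    return validate_layout(pd.read_csv(path))


def read_viability_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"compound", "dose_M", "replicate", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    return df
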