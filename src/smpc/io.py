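"""Table and image readers/writers with schema validation.

All tables are UTF-8 CSV with a header row and "." decimals (TSV via
``sep="\\t"``). Each schema lists the required, numerically typed
columns; unknown columns are preserved but reported. Images are 16-bit
TIFF (multi-frame for stacks) via :mod:`tifffile`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import FovImage
from .model import EfficacyModel
from .registry import METRIC_REGISTRY

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_fov_tiff",
    "write_fov_tiff",
    "read_model_json",
    "write_model_json",
]

#: schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "profiles": (("sample_id",), ()),          # metric columns checked below
    "targets": (("sample_id", "drug", "ex_vivo_auc"), ("ex_vivo_auc",)),
    "titration": (("conc_nM", "bound", "baits"), ("conc_nM", "bound", "baits")),
    "rfu": (("time_min", "rfu", "condition"), ("time_min", "rfu")),
    "viability": (("sample_id", "drug", "conc_nM", "viability_pct"),
                  ("conc_nM", "viability_pct")),
    "depolarization": (("sample", "peptide", "conc_uM", "depolarization"),
                       ("conc_uM", "depolarization")),
    "counts": (("fov_id", "count", "total_intensity", "saturated"),
               ("count", "total_intensity")),
}


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: column {col!r} has unparsable numeric value "
                f"{df[col][bad].iloc[0]!r} at row {row}"
            )
        df[col] = coerced
    return df


def read_table(path, schema_name: str, sep: str = ",") -> pd.DataFrame:
    """Read and validate a CSV/TSV table against a registered schema."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    required, numeric = SCHEMAS[schema_name]
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing!r}")
    if schema_name == "profiles":
        metric_cols = [c for c in df.columns if c in METRIC_REGISTRY]
        if not metric_cols:
            raise ValueError(f"{path}: no registry metric columns found")
        numeric = tuple(metric_cols)
    df = _coerce_numeric(df, numeric, path)
    extras = [c for c in df.columns
              if c not in required and c not in numeric]
    if schema_name == "profiles":
        extras = [c for c in extras if c not in METRIC_REGISTRY]
    if extras:
        warnings.warn(f"{path}: unknown column(s) preserved: {extras!r}")
    if schema_name == "counts" and "saturated" in df.columns:
        df["saturated"] = df["saturated"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).fillna(False)
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def read_fov_tiff(path, um_per_px: float = 0.2, channel: int = 532) -> FovImage:
    """Read a single- or multi-frame TIFF into a :class:`FovImage`."""
    pixels = tifffile.imread(Path(path))
    return FovImage(pixels=np.asarray(pixels, dtype=float),
                    um_per_px=um_per_px, channel=channel)


def write_fov_tiff(image: FovImage, path) -> Path:
    """Write an image or stack as 16-bit TIFF (values clipped to range)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_model_json(path) -> EfficacyModel:
    with open(path, encoding="utf-8") as fh:
        return EfficacyModel.from_dict(json.load(fh))


def write_model_json(model: EfficacyModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")
    return path
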