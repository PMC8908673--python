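"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: expression as genes x samples TSV, gene sets
as GMT, well-level growth / dose-response / Ct tables as long CSV, images as
TIFF with a YAML sidecar carrying the um-per-pixel calibration, and designed
ground truth as JSON. Every writer has a matching reader and tables
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .expression import ExpressionMatrix, GeneSignature
from .imaging import CalibratedImage

__all__ = [
    "write_expression_tsv", "read_expression_tsv",
    "write_gmt", "read_gmt",
    "write_table", "read_growth_csv", "read_dose_csv", "read_qpcr_csv",
    "write_image", "read_image", "write_json", "read_json",
]

GROWTH_COLUMNS = ["sample_id", "condition", "day", "replicate",
                  "luminescence", "is_blank"]
DOSE_COLUMNS = ["drug", "sample_id", "dose", "dose_unit", "replicate", "response"]
QPCR_COLUMNS = ["gene", "condition", "replicate", "ct"]


# -- expression -------------------------------------------------------------

def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path, scale: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(data=df, scale=scale)


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(signatures: list[GeneSignature], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


def read_gmt(path) -> dict[str, GeneSignature]:
    out: dict[str, GeneSignature] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = parts
            out[name] = GeneSignature(name=name, genes=genes)
    return out


# -- long tables ------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_growth_csv(path) -> pd.DataFrame:
    df = _read_csv(path, GROWTH_COLUMNS)
    df["is_blank"] = df["is_blank"].astype(bool)
    return df


def read_dose_csv(path) -> pd.DataFrame:
    return _read_csv(path, DOSE_COLUMNS)


def read_qpcr_csv(path) -> pd.DataFrame:
    return _read_csv(path, QPCR_COLUMNS)


# -- calibrated images ------------------------------------------------------

def write_image(img: CalibratedImage, path) -> None:
    """Write a TIFF plus a ``<name>.yaml`` sidecar with the calibration."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(img.pixels))
    sidecar = {"um_per_pixel": float(img.um_per_pixel), "channel": img.channel}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_image(path) -> CalibratedImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"calibration sidecar missing: {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    return CalibratedImage(
        pixels=pixels,
        um_per_pixel=float(meta["um_per_pixel"]),
        channel=str(meta.get("channel", "phase")),
    )


# -- JSON -------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
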