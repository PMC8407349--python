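"""TSV / YAML readers and writers for the pipeline's tabular interfaces.

All tables are UTF-8 tab-separated with a header row; feature tables have
features as rows and samples as columns.  Floating-point output is written at
6 significant digits by default (full precision on request), which keeps
repeated runs byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .containers import (
    FeatureCountMatrix,
    validate_gene_annotations,
    validate_genome_registry,
    validate_sample_info,
)

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.6g"


def read_count_table(path: PathLike, feature_kind: str = "genome") -> FeatureCountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return FeatureCountMatrix(frame, feature_kind=feature_kind)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_table(frame: pd.DataFrame, path: PathLike, full_precision: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fmt = None if full_precision else FLOAT_FORMAT
    frame.to_csv(path, sep="\t", float_format=fmt)


def read_genome_registry(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", index_col="genome_id", dtype={"marker_copies_estimated": "boolean"}
    )
    frame["marker_copies_estimated"] = frame["marker_copies_estimated"].fillna(False).astype(bool)
    try:
        return validate_genome_registry(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_sample_info(path: PathLike, meju_removal_day: int = 60) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    try:
        return validate_sample_info(frame, meju_removal_day=meju_removal_day)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_gene_annotations(path: PathLike, registry: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    frame["length_bp"] = frame["length_bp"].astype(int)
    try:
        return validate_gene_annotations(frame, registry)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_mag_quality(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="genome_id")
    for col in ("completeness", "contamination"):
        if col not in frame.columns:
            raise ValueError(f"{path}: MAG quality table missing column {col!r}")
    return frame


def read_yaml(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        return yaml.safe_load(handle) or {}


def write_yaml(obj: dict, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(obj, handle, sort_keys=True, default_flow_style=False)
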