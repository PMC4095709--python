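"""Reading score tables and writing analysis outputs.

The canonical input is a delimited text table (TSV; CSV is detected by
sniffing) with a header and columns ``id``, ``y`` and optionally ``u``.
BED-like interval files with a score column are also accepted: the score
is mapped to y and the coordinates are carried through untouched.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import Dataset
from .weights import compute_weights

__all__ = [
    "RunConfig",
    "read_dataset",
    "read_bed_scores",
    "read_table",
    "write_table",
]

logger = logging.getLogger("diffmix")

_FLOAT_FMT = "%.12g"  # 12 significant digits round-trips our scores


@dataclass
class RunConfig:
    """Pipeline configuration with the package defaults."""

    input: Optional[str] = None
    id_col: str = "id"
    y_col: str = "y"
    u_col: str = "u"
    weight_family: str = "huber"  # huber | tukey | none
    tail: str = "lower"  # lower | upper | two_tailed
    c: float = 1.345
    taper: float = 4.685
    z0: float = 0.1
    K_max: int = 6
    tol: float = 1e-5
    max_iter: int = 2000
    n_restarts: int = 5
    init_method: str = "kmeans"
    seed: int = 0
    output_prefix: str = "diffmix"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    if not head:
        raise ValueError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table with a header, sniffing the delimiter."""
    return pd.read_csv(path, sep=_sniff_sep(path))


def read_dataset(path, config: Optional[RunConfig] = None) -> Dataset:
    """Load a score table into a :class:`Dataset`.

    Rows with missing y are dropped (with a logged count). When a ``u``
    column is present and weighting is requested, weights come from the
    standardized intensities through the configured weight function;
    otherwise all weights are 1.
    """
    if config is None:
        config = RunConfig()
    df = read_table(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if config.y_col not in df.columns:
        raise ValueError(
            f"{path}: missing required column {config.y_col!r} "
            f"(found {list(df.columns)})"
        )
    y_raw = pd.to_numeric(df[config.y_col], errors="coerce")
    bad = y_raw.isna() & df[config.y_col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"{path}: non-numeric y value {df[config.y_col].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    keep = y_raw.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d rows with missing y", n_drop)
    df = df.loc[keep]
    y = y_raw.loc[keep].to_numpy(dtype=float)
    ids = (
        df[config.id_col].to_numpy()
        if config.id_col in df.columns
        else np.arange(y.size)
    )
    u = None
    w = None
    if config.u_col in df.columns and config.weight_family != "none":
        u = pd.to_numeric(df[config.u_col], errors="coerce").to_numpy(float)
        if np.isnan(u).any():
            raise ValueError(f"{path}: non-numeric or missing u values")
        w = compute_weights(
            u, family=config.weight_family, tail=config.tail,
            c=config.c, taper=config.taper,
        )
    elif config.u_col in df.columns:
        u = pd.to_numeric(df[config.u_col], errors="coerce").to_numpy(float)
    return Dataset(ids=ids, y=y, u=u, w=w)


def read_bed_scores(path, score_col: int = 4) -> Dataset:
    """Load a headerless BED-like interval file, mapping one column to y.

    ``score_col`` is the 0-based column index holding the score
    (default 4, the standard BED score slot). Unit ids are taken from
    the name column when present (chrom:start-end otherwise).
    Coordinates are carried through untouched -- no interval arithmetic
    is performed, so the 0/1-based convention of the input is
    irrelevant here.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] <= score_col:
        raise ValueError(
            f"{path}: BED file has {df.shape[1]} columns, "
            f"score column {score_col} requested"
        )
    y = pd.to_numeric(df.iloc[:, score_col], errors="coerce")
    if y.isna().any():
        row = int(np.nonzero(y.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: non-numeric score at data row {row + 1}")
    if df.shape[1] > 3 and score_col != 3:
        ids = df.iloc[:, 3].astype(str).to_numpy()
    else:
        ids = (
            df.iloc[:, 0].astype(str)
            + ":" + df.iloc[:, 1].astype(str)
            + "-" + df.iloc[:, 2].astype(str)
        ).to_numpy()
    return Dataset(ids=ids, y=y.to_numpy(dtype=float))


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
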