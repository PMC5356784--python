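"""CSV round-tripping with provenance headers.

Every artifact the pipeline writes is a plain CSV preceded by ``#``-prefixed
provenance lines (package version and the flat run configuration) that any
downstream CSV reader can skip.  Floating-point fields are serialized with 6
significant digits so that identical runs produce byte-identical files.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .errors import SchemaError

__all__ = ["read_table", "write_table", "read_wells_csv"]

FLOAT_FORMAT = "%.6g"

WELL_COLUMNS = ["sample_id", "well_id", "channel", "n_total", "n_positive"]


def write_table(df: pd.DataFrame, path, provenance: Optional[Mapping] = None) -> None:
    """Write a CSV with ``#`` provenance header lines and %.6g floats."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# ddcnv {__version__}\n")
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (provenance lines skipped)."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc


def read_wells_csv(path) -> pd.DataFrame:
    """Read and validate a wells table (``sample_id,well_id,channel,n_total,n_positive``)."""
    df = read_table(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col in ("n_total", "n_positive"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != values.round()) | (values < 0)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{path}: row {row}: column {col} must be a non-negative integer")
        df[col] = values.astype(int)
    return df
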