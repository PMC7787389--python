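"""Person-record ingestion: surname normalization and the 0-100 SES index."""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SESIndex",
    "normalize_ses",
    "assign_person_ses",
    "normalize_surname",
    "read_records",
]

_WS = re.compile(r"\s+")


@dataclass
class SESIndex:
    """Block-level socioeconomic index.

    ``raw`` holds the raw incomes x_i keyed by block id; ``normalized``
    the min-max rescale z_i = 100 * (x_i - min x) / (max x - min x).
    When at least two distinct raw values exist, min(z) = 0 and
    max(z) = 100; when all incomes are equal every z_i is 0.
    """

    raw: pd.Series
    normalized: pd.Series

    def __getitem__(self, block_id) -> float:
        return float(self.normalized[block_id])

    def __contains__(self, block_id) -> bool:
        return block_id in self.normalized.index


def normalize_ses(raw_incomes: Mapping[str, float] | pd.Series) -> SESIndex:
    """Min-max normalize block incomes to the 0-100 range."""
    raw = pd.Series(raw_incomes, dtype=float)
    if raw.empty:
        raise ValueError("normalize_ses requires at least one income")
    bad = raw.index[~np.isfinite(raw.values)]
    if len(bad):
        raise ValueError(f"non-finite income for block(s): {list(bad[:5])}")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        z = pd.Series(0.0, index=raw.index)
    else:
        z = 100.0 * (raw - lo) / (hi - lo)
    return SESIndex(raw=raw, normalized=z)


def assign_person_ses(
    records: pd.DataFrame,
    ses: SESIndex,
    on_missing: str = "drop",
) -> pd.DataFrame:
    """Attach each person the normalized SES of their block.

    ``on_missing`` is ``"drop"`` (default; unmatched records are removed
    with a logged count) or ``"error"``.
    """
    if on_missing not in ("drop", "error"):
        raise ValueError(f"on_missing must be 'drop' or 'error', got {on_missing!r}")
    matched = records["block_id"].isin(ses.normalized.index)
    n_missing = int((~matched).sum())
    if n_missing:
        if on_missing == "error":
            bad = records.loc[~matched, "block_id"].unique()
            raise KeyError(f"{n_missing} records in unknown blocks, e.g. {list(bad[:5])}")
        logger.info("assign_person_ses: dropped %d records with unknown blocks", n_missing)
    out = records.loc[matched].copy()
    out["ses"] = out["block_id"].map(ses.normalized)
    return out


def normalize_surname(token: str) -> str:
    """Canonical surname form: trimmed, uppercased, diacritics stripped,
    internal whitespace collapsed to single spaces."""
    decomposed = unicodedata.normalize("NFKD", str(token))
    ascii_form = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return _WS.sub(" ", ascii_form.strip()).upper()


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a delimited person-record table and normalize its surnames.

    ``column_map`` maps this package's canonical column names
    (``paternal_surname``, ``maternal_surname``, ``x``, ``y``,
    ``block_id``, ``block_income``, ...) to the file's column names, for
    registries with other headers. Records whose surnames are empty after
    normalization are dropped with a logged count.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"block_id": str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in ("paternal_surname", "maternal_surname"):
        if col not in df.columns:
            raise ValueError(f"input table lacks required column {col!r}")
        df[col] = df[col].astype(str).map(normalize_surname)
    empty = (df["paternal_surname"] == "") | (df["maternal_surname"] == "")
    if empty.any():
        logger.info("read_records: dropped %d records with empty surnames", int(empty.sum()))
        df = df.loc[~empty]
    return df.reset_index(drop=True)
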