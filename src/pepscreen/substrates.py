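"""Substrate selection: expression averaging and top-N abundance ranking.

The digestion substrates are the most abundantly expressed, manually
annotated proteins of the source tissue.  Expression comes in as a
delimited table with one row per protein, replicate intensity columns
(three by default, matching a triplicate microarray design), and a boolean
``annotated`` flag; abundance is the arithmetic mean across replicates and
spread is the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, InputError, SchemaError

DEFAULT_REPLICATE_COLUMNS = ("rep1", "rep2", "rep3")


@dataclass(frozen=True)
class ExpressionRecord:
    """Replicate intensities and their summary for one probe/protein."""

    accession: str
    replicate_values: tuple[float, ...]
    mean_value: float
    sd_value: float
    annotated: bool


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated substrate protein, optionally carrying its expression."""

    accession: str
    sequence: str
    description: str = ""
    expression: ExpressionRecord | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.accession!r} has an empty sequence")


def read_expression_table(
    path,
    *,
    accession_column: str = "accession",
    replicate_columns: Sequence[str] = DEFAULT_REPLICATE_COLUMNS,
    annotated_column: str = "annotated",
) -> pd.DataFrame:
    """Read a tab- or comma-delimited expression table with a header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [
        c for c in (accession_column, *replicate_columns, annotated_column)
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"expression table {path} lacks columns {missing}")
    return df


def average_replicates(
    records: pd.DataFrame,
    replicate_columns: Sequence[str] = DEFAULT_REPLICATE_COLUMNS,
    *,
    accession_column: str = "accession",
    annotated_column: str = "annotated",
) -> list[ExpressionRecord]:
    """Summarize replicate intensities row by row, preserving row order.

    Mean is the arithmetic mean and sd the sample (n-1) standard deviation
    of the named replicate columns.  A missing or non-numeric value raises
    an :class:`InputError` naming the offending row and column.
    """
    if not replicate_columns:
        raise InputError("at least one replicate column is required")
    out: list[ExpressionRecord] = []
    for idx, row in records.iterrows():
        values = []
        for col in replicate_columns:
            if col not in row:
                raise InputError(f"row {idx}: missing replicate column {col!r}")
            try:
                v = float(row[col])
            except (TypeError, ValueError):
                raise InputError(
                    f"row {idx} ({row.get(accession_column, '?')}): "
                    f"non-numeric value {row[col]!r} in column {col!r}"
                ) from None
            if np.isnan(v):
                raise InputError(f"row {idx}: missing value in column {col!r}")
            if v < 0:
                raise InputError(f"row {idx}: negative intensity {v} in column {col!r}")
            values.append(v)
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out.append(
            ExpressionRecord(
                accession=str(row[accession_column]),
                replicate_values=tuple(values),
                mean_value=float(arr.mean()),
                sd_value=sd,
                annotated=_as_bool(row.get(annotated_column, True), idx),
            )
        )
    return out


def _as_bool(value, idx) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise InputError(f"row {idx}: cannot interpret annotated flag {value!r}")


def select_top_expressed(
    records: Iterable[ExpressionRecord],
    proteome: Mapping[str, "ProteinRecord | str"],
    n: int = 50,
    *,
    require_annotated: bool = True,
) -> list[ProteinRecord]:
    """Pick the ``n`` most abundant (optionally annotated-only) substrates.

    Records are ranked by mean expression, descending; ties are broken by
    ascending accession string so the selection is independent of input
    order.  Every selected record must have a sequence in ``proteome``
    (a mapping accession -> ProteinRecord or raw sequence).
    """
    if n < 0:
        raise InputError("n must be >= 0")
    pool = [r for r in records if r.annotated] if require_annotated else list(records)
    pool.sort(key=lambda r: (-r.mean_value, r.accession))
    chosen = pool[:n]
    missing = [r.accession for r in chosen if r.accession not in proteome]
    if missing:
        raise CrossReferenceError(
            f"no FASTA sequence for selected accessions: {', '.join(sorted(missing))}"
        )
    out = []
    for rec in chosen:
        entry = proteome[rec.accession]
        if isinstance(entry, ProteinRecord):
            out.append(
                ProteinRecord(
                    accession=rec.accession,
                    sequence=entry.sequence,
                    description=entry.description,
                    expression=rec,
                )
            )
        else:
            out.append(
                ProteinRecord(accession=rec.accession, sequence=str(entry), expression=rec)
            )
    return out
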