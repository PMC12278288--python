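"""Completeness screening and per-variable standardization.

The pipeline's case handling is deliberate: countries with any missing
indicator are removed, never imputed, so cluster structure rests only on
fully observed records.  Standardization is applied per variable after
screening; the default ``zscore`` mode rescales to unit sample SD because
k-means on mixed-scale indicators (DALY rates ~1e4 next to protein grams
~1e1) would otherwise be dominated by the large-scale columns.  ``center``
mode (mean subtraction only) is kept for literal replication of analyses
that scale by centering alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import IndicatorTable
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of completeness screening."""

    n_input: int
    n_retained: int
    dropped: tuple[tuple[str, tuple[str, ...]], ...]  # (country, missing columns)

    def __post_init__(self) -> None:
        assert self.n_retained + len(self.dropped) == self.n_input


def screen_completeness(table: IndicatorTable) -> tuple[IndicatorTable, ScreenReport]:
    """Drop every country with at least one missing cell.

    Row order is preserved; the report lists each dropped country with the
    names of its missing columns.  Raises :class:`ValidationError` if no row
    survives, since the downstream pipeline cannot run on an empty table.
    """
    mask = table.values.isna()
    keep = ~mask.any(axis=1)
    dropped = tuple(
        (country, tuple(mask.columns[mask.loc[country]]))
        for country in table.values.index[~keep]
    )
    retained = table.values.loc[keep]
    if retained.shape[0] == 0:
        raise ValidationError("completeness screening removed every country")
    report = ScreenReport(
        n_input=int(table.values.shape[0]),
        n_retained=int(retained.shape[0]),
        dropped=dropped,
    )
    return IndicatorTable(values=retained, themes=table.themes), report


def standardize(table: IndicatorTable, mode: str = "zscore") -> IndicatorTable:
    """Standardize each column: ``center`` subtracts the mean, ``zscore``
    additionally divides by the sample SD (denominator n-1).

    Must run on a screened (fully observed) table.  A zero-variance column
    under ``zscore`` becomes all zeros with a logged warning rather than an
    error: a constant indicator carries no clustering information either way.
    """
    if mode not in ("center", "zscore"):
        raise ValidationError(f"unknown standardization mode {mode!r}")
    if table.values.isna().any().any():
        raise ValidationError("standardize requires a fully observed table; screen first")
    values = table.values - table.values.mean(axis=0)
    if mode == "zscore":
        sd = table.values.std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "zero-variance columns set to 0 under zscore: %s",
                list(sd.index[degenerate]),
            )
            sd = sd.mask(degenerate, 1.0)
        values = values / sd
    return IndicatorTable(values=values, themes=table.themes)
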