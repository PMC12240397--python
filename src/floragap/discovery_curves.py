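"""Decade-binned discovery series and taxonomist (effort) counts.

Description years are binned into calendar decades [1751-1760], [1761-1770],
..., [2011-2020]; the default analysis window 1753-2020 therefore spans 27
decades, with 1753-1760 falling in the first bin.  The regression abscissa
used by the model-fitting modules is the integer decade index t = 1..n, not
the calendar year, which keeps the nonlinear fits well conditioned.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = (1753, 2020)

__all__ = [
    "DEFAULT_WINDOW",
    "DecadeSeries",
    "EffortSeries",
    "decade_starts",
    "decade_index",
    "bin_by_decade",
    "tokenize_authors",
    "count_taxonomists",
]


def _first_decade_start(start_year: int) -> int:
    # decades run ...1 to ...0 (1751-1760), so snap down to the nearest ...1
    return start_year - ((start_year - 1) % 10)


def decade_starts(window: tuple[int, int] = DEFAULT_WINDOW) -> np.ndarray:
    """Calendar start years (1751, 1761, ...) of the decades covering *window*."""
    start, end = window
    if end <= start:
        raise ValueError(f"window end {end} must exceed start {start}")
    first = _first_decade_start(start)
    return np.arange(first, end + 1, 10)


def decade_index(years: np.ndarray, window: tuple[int, int] = DEFAULT_WINDOW) -> np.ndarray:
    """0-based decade bin index for each year (years outside window -> -1)."""
    years = np.asarray(years)
    first = _first_decade_start(window[0])
    idx = (years - first) // 10
    idx = np.where((years < window[0]) | (years > window[1]), -1, idx)
    return idx.astype(int)


@dataclass
class DecadeSeries:
    """Per-decade and cumulative description counts for one stratum."""

    stratum: str
    decade_start: np.ndarray
    described: np.ndarray
    window: tuple[int, int] = DEFAULT_WINDOW
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.decade_start = np.asarray(self.decade_start, dtype=int)
        self.described = np.asarray(self.described, dtype=float)
        if self.decade_start.shape != self.described.shape:
            raise ValueError("decade_start and described must align")

    @property
    def n(self) -> int:
        return len(self.decade_start)

    @property
    def t_index(self) -> np.ndarray:
        """Integer abscissa 1..n used for model fitting."""
        return np.arange(1, self.n + 1)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.described)

    @property
    def total(self) -> float:
        return float(self.described.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "decade_start": self.decade_start,
                "t_index": self.t_index,
                "described": self.described,
                "cumulative": self.cumulative,
            }
        )


@dataclass
class EffortSeries:
    """Taxonomists active per decade and the resulting per-capita description rate."""

    stratum: str
    decade_start: np.ndarray
    taxonomists: np.ndarray
    described: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.decade_start = np.asarray(self.decade_start, dtype=int)
        self.taxonomists = np.asarray(self.taxonomists, dtype=int)
        if np.any(self.taxonomists < 0):
            raise ValueError("taxonomist counts must be non-negative")
        if self.described is None:
            self.described = np.zeros_like(self.taxonomists, dtype=float)
        self.described = np.asarray(self.described, dtype=float)

    @property
    def species_per_taxonomist(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.described / self.taxonomists
        return np.where(self.taxonomists > 0, out, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "decade_start": self.decade_start,
                "taxonomists": self.taxonomists,
                "described": self.described,
                "species_per_taxonomist": self.species_per_taxonomist,
            }
        )


def bin_by_decade(
    years,
    window: tuple[int, int] = DEFAULT_WINDOW,
    stratum: str = "all",
) -> DecadeSeries:
    """Bin a multiset of description years into decade counts.

    Years outside *window* are rejected (not binned); their count is recorded
    on the returned series so conservation can be audited.
    """
    years = np.asarray(pd.Series(years).dropna(), dtype=float).astype(int)
    starts = decade_starts(window)
    idx = decade_index(years, window)
    rejected = int(np.sum(idx < 0))
    counts = np.bincount(idx[idx >= 0], minlength=len(starts))[: len(starts)]
    return DecadeSeries(
        stratum=stratum,
        decade_start=starts,
        described=counts,
        window=window,
        n_rejected=rejected,
    )


_EX_SPLIT = re.compile(r"\s+ex\.?\s+", flags=re.IGNORECASE)
_SEPARATORS = re.compile(r"\s+et\s+|&|,", flags=re.IGNORECASE)


def tokenize_authors(authorship: str) -> list[str]:
    """Split a botanical authorship string into normalized author tokens.

    Separators are "&", ",", and " et "; in "A ex B" citations the pre-"ex"
    author (who supplied the name but did not publish it) is discarded.
    Tokens are case-folded with periods and excess whitespace stripped.
    """
    if not isinstance(authorship, str) or not authorship.strip():
        return []
    # keep only the publishing author(s) after the last " ex "
    parts = _EX_SPLIT.split(authorship)
    publishing = parts[-1]
    tokens = []
    for raw in _SEPARATORS.split(publishing):
        tok = raw.replace(".", " ").casefold()
        tok = " ".join(tok.split())
        if tok:
            tokens.append(tok)
    return tokens


def count_taxonomists(
    names: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
    stratum: str = "all",
    year_col: str = "resolved_year",
    author_col: str = "authorship",
) -> EffortSeries:
    """Count distinct describing authors per decade from authorship strings.

    An author active in several decades contributes once to each decade's
    count (per-decade distinctness).  Rows with an empty authorship are
    skipped with a warning.
    """
    starts = decade_starts(window)
    per_decade_authors: list[set[str]] = [set() for _ in starts]
    described = np.zeros(len(starts))
    skipped = 0
    idx = decade_index(names[year_col].to_numpy(), window)
    for i, auth in zip(idx, names[author_col]):
        if i < 0:
            continue
        toks = tokenize_authors(auth)
        if not toks:
            skipped += 1
            continue
        per_decade_authors[i].update(toks)
        described[i] += 1
    if skipped:
        warnings.warn(f"{skipped} records skipped: empty authorship", stacklevel=2)
    counts = np.array([len(s) for s in per_decade_authors])
    return EffortSeries(
        stratum=stratum, decade_start=starts, taxonomists=counts, described=described
    )
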