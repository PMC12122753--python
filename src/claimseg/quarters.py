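"""Calendar-quarter arithmetic for claims tables.

German statutory health insurance bills outpatient care per calendar
quarter, so all lookback windows are defined in quarters. Quarters are
written ``"2016Q3"`` in files and handled as integer indices
(``year * 4 + quarter - 1``) internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def q_index(label: str) -> int:
    """``"2016Q3"`` -> integer index (year*4 + quarter-1)."""
    year, q = label.split("Q")
    q = int(q)
    if not 1 <= q <= 4:
        raise ValueError(f"invalid quarter label {label!r}")
    return int(year) * 4 + q - 1


def q_label(index: int) -> str:
    """Integer index -> ``"2016Q3"``."""
    return f"{index // 4}Q{index % 4 + 1}"


def q_index_series(labels: pd.Series) -> pd.Series:
    """Vectorised :func:`q_index` for a Series of labels."""
    year = labels.str.slice(0, 4).astype(int)
    quarter = labels.str.slice(5, 6).astype(int)
    return year * 4 + quarter - 1


def quarter_of_date(date) -> int:
    """Quarter index of a datetime-like value."""
    ts = pd.Timestamp(date)
    return ts.year * 4 + (ts.month - 1) // 3


@dataclass(frozen=True)
class LookbackWindow:
    """The ``n`` calendar quarters strictly before an index quarter.

    The index quarter itself is excluded: contacts in the quarter of the
    emergency department visit do not count as care *prior* to it.
    """

    index_quarter: int
    quarters: tuple[int, ...]

    def __post_init__(self):
        if len(self.quarters) not in (4, 8):
            raise ValueError("lookback window must span 4 or 8 quarters")
        if any(q >= self.index_quarter for q in self.quarters):
            raise ValueError("lookback quarters must precede the index quarter")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(q_label(q) for q in self.quarters)

    def __contains__(self, q: int) -> bool:
        return q in self.quarters


def lookback_quarters(index_quarter: int | str, n: int) -> LookbackWindow:
    """Return the ``n`` quarters immediately preceding ``index_quarter``.

    ``n`` is 4 (one year, used for the care indicators) or 8 (two years,
    used for diagnosis validation).
    """
    if n not in (4, 8):
        raise ValueError("n must be 4 or 8")
    idx = q_index(index_quarter) if isinstance(index_quarter, str) else int(index_quarter)
    return LookbackWindow(idx, tuple(range(idx - n, idx)))


def random_date_in_quarter(q: int, rng: np.random.Generator) -> pd.Timestamp:
    """Uniform random calendar day within quarter index ``q``."""
    year, quarter = q // 4, q % 4
    start = pd.Timestamp(year=year, month=3 * quarter + 1, day=1)
    end = start + pd.DateOffset(months=3)
    days = (end - start).days
    return start + pd.Timedelta(days=int(rng.integers(0, days)))
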