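"""Partial-precision FAERS dates.

FAERS quarterly extracts carry dates as bare digit strings in mixed
precision: ``YYYYMMDD``, ``YYYYMM`` or ``YYYY``.  Day-level arithmetic
(duplicate matching, time to onset) is only meaningful at full precision,
so every parse returns an explicit precision tag and downstream code
refuses to subtract anything coarser than a day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PRECISION_DAY = "day"
PRECISION_MONTH = "month"
PRECISION_YEAR = "year"
PRECISION_NONE = "none"


def parse_dates(raw: pd.Series) -> pd.DataFrame:
    """Parse a series of FAERS date strings.

    Returns a DataFrame aligned with ``raw`` holding:

    ``date``
        ``datetime64[ns]``; partial dates are anchored at the first day of
        the period, invalid or empty strings become ``NaT``.
    ``precision``
        one of ``day`` / ``month`` / ``year`` / ``none``.
    """
    s = raw.astype("string").str.strip().fillna("")
    # keep digits only; FAERS occasionally pads with whitespace
    digits = s.str.replace(r"\D", "", regex=True)
    n = digits.str.len()

    precision = np.select(
        [n == 8, n == 6, n == 4],
        [PRECISION_DAY, PRECISION_MONTH, PRECISION_YEAR],
        default=PRECISION_NONE,
    )
    padded = digits.copy()
    padded[n == 6] = digits[n == 6] + "01"
    padded[n == 4] = digits[n == 4] + "0101"
    padded[~np.isin(n, (4, 6, 8))] = pd.NA

    date = pd.to_datetime(padded, format="%Y%m%d", errors="coerce")
    # calendar-invalid strings (e.g. 20219999) downgrade to no precision
    precision = np.where(date.isna(), PRECISION_NONE, precision)
    return pd.DataFrame({"date": date, "precision": precision}, index=raw.index)


def day_diff(
    later: pd.DataFrame, earlier: pd.DataFrame
) -> pd.Series:
    """Day difference ``later - earlier``; NaN unless both are full precision."""
    ok = (later["precision"] == PRECISION_DAY) & (
        earlier["precision"] == PRECISION_DAY
    )
    diff = (later["date"] - earlier["date"]).dt.days.astype("float")
    return diff.where(ok)


def format_dates(date: pd.Series, precision: pd.Series) -> pd.Series:
    """Render back to FAERS digit strings at the stated precision."""
    out = pd.Series("", index=date.index, dtype="string")
    d = pd.to_datetime(date)
    out[precision == PRECISION_DAY] = d.dt.strftime("%Y%m%d")
    out[precision == PRECISION_MONTH] = d.dt.strftime("%Y%m")
    out[precision == PRECISION_YEAR] = d.dt.strftime("%Y")
    return out.fillna("")
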