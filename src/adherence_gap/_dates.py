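"""Integer-day calendar helpers.

All interval arithmetic in the package runs on integer day numbers
(days since 1970-01-01); tables expose ordinary datetime columns.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

EPOCH = pd.Timestamp("1970-01-01")


def day_number(dates) -> np.ndarray:
    """Convert datetime-like scalars/arrays to integer day numbers."""
    if isinstance(dates, (pd.Timestamp, dt.date, dt.datetime, str)):
        return int((pd.Timestamp(dates) - EPOCH).days)
    arr = pd.to_datetime(pd.Series(dates))
    return ((arr - EPOCH).dt.days).to_numpy()


def from_day_number(days):
    """Convert integer day numbers back to pandas timestamps."""
    if np.isscalar(days):
        return EPOCH + pd.Timedelta(days=int(days))
    return EPOCH + pd.to_timedelta(np.asarray(days, dtype="int64"), unit="D")
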