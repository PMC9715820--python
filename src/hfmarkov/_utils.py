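"""Small shared helpers: calendar-month arithmetic and presentation rounding."""

from __future__ import annotations

import calendar
import datetime as _dt

import numpy as np


def add_months(d: _dt.date, months: int) -> _dt.date:
    """Add calendar months, clamping day-of-month overflow to the month end.

    2020-10-31 + 4 months -> 2021-02-28. Window starts are always computed
    from the baseline date directly (baseline + 4*(k-1) months), never by
    chaining additions, so clamping cannot drift.
    """
    m = d.month - 1 + months
    year = d.year + m // 12
    month = m % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return _dt.date(year, month, day)


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero (the convention used in printed clinical tables).

    numpy/python round half to even; tables such as 0.145 -> 0.15 round half up
    in magnitude. Works on scalars and arrays.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def validate_distribution(v, name: str = "distribution", atol: float = 1e-9) -> np.ndarray:
    """Validate a probability vector: nonnegative, sums to 1 within ``atol``."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {v.shape}")
    if np.any(v < -atol):
        raise ValueError(f"{name} has negative entries: {v}")
    s = v.sum()
    if abs(s - 1.0) > max(atol, 1e-9):
        raise ValueError(f"{name} must sum to 1 (got {s:.12g})")
    return np.clip(v, 0.0, None)
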