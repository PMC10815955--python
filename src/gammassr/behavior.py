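"""Behavioral endpoint aggregation: locomotor-activity window sums and social-interaction time.

Activity tables hold beam-break counts per fixed time bin (default 10 min)
from dosing; endpoints are sums over bin-aligned windows such as 0–90 min or
80–150 min. Social interaction is scored per rat pair (the pair is the
statistical unit): the endpoint is the total time in active, non-aggressive
social behavior over the test (default 600 s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError

ACTIVITY_WINDOW_90 = (0.0, 90.0)
ACTIVITY_WINDOW_LATE = (80.0, 150.0)
DEFAULT_TEST_DURATION_S = 600.0


def _check_activity_table(t: pd.DataFrame) -> None:
    req = {"subject", "arm", "bin_start_min", "bin_minutes", "counts"}
    missing = req - set(t.columns)
    if missing:
        raise IntegrityError(f"activity table missing columns {sorted(missing)}")
    if (t["counts"] < 0).any():
        raise IntegrityError("activity counts must be non-negative")


def activity_sum(t: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Per-subject total counts over ``[t0, t1)`` minutes since dosing.

    The window must be aligned to bin edges and lie inside the recorded span;
    misaligned or out-of-range windows raise rather than pro-rate, so
    endpoints remain exact sums.
    """
    _check_activity_table(t)
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError(f"empty activity window {window}")
    bin_w = float(t["bin_minutes"].iloc[0])
    if not np.allclose(t["bin_minutes"], bin_w):
        raise IntegrityError("mixed bin widths in activity table")
    for edge in window:
        if abs(edge / bin_w - round(edge / bin_w)) > 1e-9:
            raise ConfigurationError(
                f"window edge {edge} min not aligned to {bin_w}-min bins"
            )
    span_end = float(t["bin_start_min"].max()) + bin_w
    if t0 < float(t["bin_start_min"].min()) or t1 > span_end:
        raise ConfigurationError(f"window {window} outside recorded span (0, {span_end})")
    sel = t[(t["bin_start_min"] >= t0) & (t["bin_start_min"] < t1)]
    out = (
        sel.groupby(["subject", "arm"], sort=False)["counts"]
        .sum()
        .reset_index()
        .rename(columns={"counts": "value"})
    )
    return out


def social_endpoint(t: pd.DataFrame) -> pd.DataFrame:
    """Per-pair social-interaction time in seconds (the pair is the unit)."""
    req = {"pair", "arm", "social_s"}
    missing = req - set(t.columns)
    if missing:
        raise IntegrityError(f"social table missing columns {sorted(missing)}")
    dur = t["test_duration_s"] if "test_duration_s" in t.columns else DEFAULT_TEST_DURATION_S
    if (t["social_s"] < 0).any() or (t["social_s"] > dur).any():
        raise IntegrityError("social time outside [0, test_duration]")
    out = t[["pair", "arm", "social_s"]].rename(
        columns={"pair": "subject", "social_s": "value"}
    )
    return out.reset_index(drop=True)
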