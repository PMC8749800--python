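"""Temporal gait parameters of bilateral lower limbs from detected events.

With the sensor on the right foot, the opposite (left) foot's contact and
departure are read from the OHS and OTO events of the right foot's
signal. For one stride bounded by heel strikes at ``T_HS`` and
``T_HS_next``:

* ``DST1 = T_OTO - T_HS`` (loading response),
  ``DST2 = T_TO - T_OHS`` (pre-swing), ``DSTt = DST1 + DST2``;
* right stance ``T_sta_R = T_TO - T_HS`` and stride
  ``T_str_R = T_HS_next - T_HS``;
* left stance ``T_sta_L = T_OTO_next - T_OHS`` (from this stride's OHS to
  the next stride's OTO) and stride ``T_str_L = T_OHS_next - T_OHS``;
* signed symmetry indexes
  ``SIS_ta = (T_sta_L - T_sta_R) / (0.5 (T_sta_L + T_sta_R))`` and
  ``SIS_tr = (T_str_L - T_str_R) / (0.5 (T_str_L + T_str_R))`` — the sign
  is retained so both the magnitude and the direction of the left/right
  difference are expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GaitEventSet

__all__ = [
    "RelativeEventTimes",
    "GPBLLRecord",
    "relative_times",
    "compute_gpbll",
    "records_from_events",
    "average_records",
    "records_to_frame",
]


@dataclass
class RelativeEventTimes:
    """OHS and OTO expressed relative to the stride's reference heel strike."""

    T_OHS_0: Optional[float] = None
    T_OTO_0: Optional[float] = None


@dataclass
class GPBLLRecord:
    """The nine temporal gait parameters of bilateral lower limbs (one stride).

    Times in ms; symmetry indexes are dimensionless signed fractions,
    bounded in (-2, 2) by construction. ``DSTt == DST1 + DST2`` exactly.
    """

    stride_index: int
    DST1: float
    DST2: float
    DSTt: float
    T_str_L: float
    T_str_R: float
    T_sta_L: float
    T_sta_R: float
    SIS_tr: float
    SIS_ta: float

    _FIELDS = ("DST1", "DST2", "DSTt", "T_str_L", "T_str_R",
               "T_sta_L", "T_sta_R", "SIS_tr", "SIS_ta")


def relative_times(events: GaitEventSet, T_HS_ref: float) -> RelativeEventTimes:
    """Express a stride's OHS/OTO relative to a reference heel strike.

    Missing events yield absent (``None``) fields.
    """
    rel = RelativeEventTimes()
    if events.T_OHS is not None:
        rel.T_OHS_0 = events.T_OHS - T_HS_ref
    if events.T_OTO is not None:
        rel.T_OTO_0 = events.T_OTO - T_HS_ref
    return rel


def _sis(left: float, right: float) -> float:
    return (left - right) / (0.5 * (left + right))


def compute_gpbll(events: GaitEventSet) -> GPBLLRecord:
    """Compute the bilateral parameters for one stride.

    Requires HS, TO, OHS, OTO of this stride plus the next stride's HS,
    OHS and OTO; raises ``ValueError`` naming the first missing event.
    """
    needed = ("T_HS", "T_TO", "T_OHS", "T_OTO",
              "T_HS_next", "T_OHS_next", "T_OTO_next")
    for name in needed:
        if getattr(events, name) is None:
            raise ValueError(
                f"stride {events.stride_index}: cannot compute bilateral "
                f"parameters, event {name} is absent")
    dst1 = events.T_OTO - events.T_HS
    dst2 = events.T_TO - events.T_OHS
    t_sta_l = events.T_OTO_next - events.T_OHS
    t_str_l = events.T_OHS_next - events.T_OHS
    t_sta_r = events.T_TO - events.T_HS
    t_str_r = events.T_HS_next - events.T_HS
    return GPBLLRecord(
        stride_index=events.stride_index,
        DST1=dst1, DST2=dst2, DSTt=dst1 + dst2,
        T_str_L=t_str_l, T_str_R=t_str_r,
        T_sta_L=t_sta_l, T_sta_R=t_sta_r,
        SIS_tr=_sis(t_str_l, t_str_r),
        SIS_ta=_sis(t_sta_l, t_sta_r),
    )


def records_from_events(events: Sequence[GaitEventSet]) -> List[GPBLLRecord]:
    """Per-stride records for every stride with a complete event set.

    Incomplete strides are skipped with a warning; one bad stride never
    aborts the rest of the trial.
    """
    out = []
    for ev in events:
        try:
            out.append(compute_gpbll(ev))
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return out


def average_records(
    records: Sequence[GPBLLRecord],
    k: int = 5,
    sliding: bool = False,
) -> List[GPBLLRecord]:
    """Field-wise means over runs of ``k`` consecutive records.

    The default (``k=5``, matching a ~5 m walk at typical stride length)
    averages non-overlapping runs; ``sliding=True`` uses every window of
    ``k`` consecutive records instead. Fewer than ``k`` records yield an
    empty list; ``k=1`` is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(records)
    if len(records) < k:
        return []
    starts = range(0, len(records) - k + 1) if sliding \
        else range(0, len(records) - k + 1, k)
    out = []
    for s in starts:
        run = records[s:s + k]
        means = {f: float(np.mean([getattr(r, f) for r in run]))
                 for f in GPBLLRecord._FIELDS}
        out.append(GPBLLRecord(stride_index=run[0].stride_index, **means))
    return out


def records_to_frame(records: Sequence[GPBLLRecord]) -> pd.DataFrame:
    """Tabulate records, one row per stride (or per averaged run)."""
    cols = ("stride_index",) + GPBLLRecord._FIELDS
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=list(cols))
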