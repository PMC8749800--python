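"""Triangle thresholding (knee-point) localisation of gradient turning points.

A gradient turning point (GTP) is the sample of a monotone curve segment
that lies farthest from the chord joining two reference points P_A(t1, u1)
and P_B(t2, u2). With the chord

    U(T) = ((u2 - u1)/(t2 - t1)) (T - t1) + u1,

the perpendicular distance of each sample Q(T) from the chord is

    D(T) = |U(T) - Q(T)| / sqrt(1 + ((u2 - u1)/(t2 - t1))^2),

and the GTP is argmax_{t1 <= T <= t2} D(T), ties broken by the earliest
time. The construction is invariant to a common positive rescaling of the
curve and both reference values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TTAQuery", "TTAResult", "tta_gtp"]


@dataclass
class TTAQuery:
    """A curve segment and its two chord reference points.

    ``t``/``q`` sample the curve over the closed interval between ``t1``
    and ``t2`` (inclusive of both endpoints); ``(t1, u1)`` is P_A and
    ``(t2, u2)`` is P_B. The reference points need not be in temporal
    order: the stored segment is always ordered by time.
    """

    t1: float
    u1: float
    t2: float
    u2: float
    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.t.size != self.q.size:
            raise ValueError("t and q must have the same length")
        if self.t1 == self.t2:
            raise ValueError("reference points must differ in time")
        if self.t1 > self.t2:
            # keep P_A/P_B labels but store the segment left-to-right
            self.t1, self.t2 = self.t2, self.t1
            self.u1, self.u2 = self.u2, self.u1
        if self.t.size and (self.t[0] < self.t1 - 1e-9 or self.t[-1] > self.t2 + 1e-9):
            raise ValueError("segment extends beyond the reference interval")

    @classmethod
    def from_channel(cls, t: np.ndarray, u: np.ndarray, i1: int, i2: int) -> "TTAQuery":
        """Build a query from a sampled channel and two sample indices."""
        lo, hi = (i1, i2) if i1 <= i2 else (i2, i1)
        return cls(t1=float(t[i1]), u1=float(u[i1]),
                   t2=float(t[i2]), u2=float(u[i2]),
                   t=t[lo:hi + 1], q=u[lo:hi + 1])


@dataclass
class TTAResult:
    """Outcome of a triangle-thresholding search."""

    T_GTP: float
    D_max: float
    D: np.ndarray


def tta_gtp(query: TTAQuery) -> TTAResult:
    """Locate the gradient turning point of a curve segment.

    Raises ``ValueError`` for segments shorter than 3 samples (no interior
    point exists) or coincident reference times.
    """
    t, q = query.t, query.q
    if t.size < 3:
        raise ValueError("TTA needs a segment of at least 3 samples")
    slope = (query.u2 - query.u1) / (query.t2 - query.t1)
    chord = slope * (t - query.t1) + query.u1
    dist = np.abs(chord - q) / np.sqrt(1.0 + slope * slope)
    k = int(np.argmax(dist))  # argmax returns the earliest tie
    return TTAResult(T_GTP=float(t[k]), D_max=float(dist[k]), D=dist)
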