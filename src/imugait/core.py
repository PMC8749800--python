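"""Core containers for foot-mounted inertial gait data.

Axis and sign conventions follow the in-shoe sensor frame: ``A_y`` is
positive in the posterior direction (negative anterior), ``A_z`` positive
superior (gravity baseline +1 g during stance), and ``G_x`` positive in
plantarflexion, negative in dorsiflexion. Timestamps are milliseconds on
the acquisition grid (10 ms at the default 100 Hz), strides are half-open
intervals ``[start, end)`` bounded by successive heel strikes of the
instrumented foot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

__all__ = [
    "FootMotionSignal",
    "Stride",
    "GaitEventSet",
    "snap_ms",
    "segment_strides",
    "filter_effective_strides",
]

#: measurement ranges of the in-shoe sensor; values beyond these are
#: physically saturated readings
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

_CHANNEL_ALIASES = {
    "ax": "A_x", "ay": "A_y", "az": "A_z",
    "gx": "G_x", "gy": "G_y", "gz": "G_z",
    "ex": "E_x", "ey": "E_y", "ez": "E_z",
}


def snap_ms(value: float, dt_ms: float) -> float:
    """Round a time in ms to the sample grid, half-up."""
    return float(np.floor(np.asarray(value) / dt_ms + 0.5) * dt_ms)


def _canonical_channel(name: str) -> str:
    key = name.replace("_", "").lower()
    if key not in _CHANNEL_ALIASES:
        raise ValueError(f"unknown channel {name!r}")
    return _CHANNEL_ALIASES[key]


@dataclass
class FootMotionSignal:
    """Multichannel foot-motion time series from one in-shoe sensor.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (positive).
    t : ndarray
        Time in ms, strictly increasing with constant step ``1000/sample_rate``.
    A_x, A_y, A_z : ndarray
        Acceleration in g (medial+/lateral-, posterior+/anterior-,
        superior+/inferior-).
    G_x, G_y, G_z : ndarray
        Angular velocity in deg/s (plantarflexion+, eversion+, adduction+).
    E_x, E_y, E_z : ndarray, optional
        Sole-to-ground angles (roll/pitch/yaw) in deg.
    side : str
        Which foot carries the sensor, ``"left"`` or ``"right"``.
    """

    sample_rate: float
    t: np.ndarray
    A_x: np.ndarray
    A_y: np.ndarray
    A_z: np.ndarray
    G_x: np.ndarray
    G_y: np.ndarray
    G_z: np.ndarray
    E_x: Optional[np.ndarray] = None
    E_y: Optional[np.ndarray] = None
    E_z: Optional[np.ndarray] = None
    side: str = "right"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        for name in ("A_x", "A_y", "A_z", "G_x", "G_y", "G_z",
                     "E_x", "E_y", "E_z"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValueError(f"channel {name} length {arr.size} != t length {n}")
            setattr(self, name, arr)
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                i = int(np.argmax(steps <= 0))
                raise ValueError(f"t must be strictly increasing (violated at row {i + 1})")
            expected = 1000.0 / self.sample_rate
            if not np.allclose(steps, expected, rtol=0, atol=1e-6 * expected):
                i = int(np.argmax(np.abs(steps - expected) > 1e-6 * expected))
                raise ValueError(
                    f"t must be uniformly sampled at {expected:g} ms "
                    f"(gap of {steps[i]:g} ms at row {i + 1})"
                )

    @property
    def dt_ms(self) -> float:
        """Sample period in ms."""
        return 1000.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.t.size

    def channel(self, name: str) -> np.ndarray:
        """Return a channel by name (``"G_x"``/``"Gx"`` style both accepted)."""
        arr = getattr(self, _canonical_channel(name))
        if arr is None:
            raise ValueError(f"channel {name!r} not present in this signal")
        return arr

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (clipped to range)."""
        i = int(np.floor((t_ms - self.t[0]) / self.dt_ms + 0.5))
        return int(np.clip(i, 0, self.t.size - 1))


@dataclass
class Stride:
    """One gait cycle between two successive heel strikes, ``[start, end)``."""

    index: int
    start_ms: float
    end_ms: float
    effective: bool = True

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("stride end must follow its start")

    @property
    def gc_ms(self) -> float:
        """Gait-cycle duration in ms."""
        return self.end_ms - self.start_ms


@dataclass
class GaitEventSet:
    """Timestamps (ms) of the bilateral gait events detected in one stride.

    Any event may be ``None`` when detection failed for that stride. When
    all are present they satisfy
    ``T_HS < T_footflat <= T_OTO < T_OHS < T_TO < T_HS_next``, and
    ``T_OTO = T_footflat + 2% GC`` by construction.
    """

    stride_index: int
    T_HS: Optional[float] = None
    T_footflat: Optional[float] = None
    T_OTO: Optional[float] = None
    T_OHS: Optional[float] = None
    T_TO: Optional[float] = None
    T_HS_next: Optional[float] = None
    T_OHS_next: Optional[float] = None
    T_OTO_next: Optional[float] = None

    _OWN = ("T_HS", "T_footflat", "T_OTO", "T_OHS", "T_TO")
    _ALL = _OWN + ("T_HS_next", "T_OHS_next", "T_OTO_next")

    def is_complete(self) -> bool:
        """True when every event needed for the bilateral parameters is set."""
        return all(getattr(self, f) is not None for f in self._ALL)

    def ordering_ok(self) -> bool:
        """Check the within-stride event ordering on the present events."""
        seq = [self.T_HS, self.T_footflat, self.T_OTO, self.T_OHS,
               self.T_TO, self.T_HS_next]
        present = [v for v in seq if v is not None]
        ok = all(a <= b for a, b in zip(present, present[1:]))
        if self.T_HS is not None and self.T_footflat is not None:
            ok = ok and self.T_HS < self.T_footflat
        if self.T_OTO is not None and self.T_OHS is not None:
            ok = ok and self.T_OTO < self.T_OHS
        return ok


def segment_strides(signal: FootMotionSignal, hs_times: Sequence[float]) -> List[Stride]:
    """Divide a trial into strides at successive heel-strike timestamps.

    Returns ``n - 1`` half-open strides for ``n`` heel strikes; their union
    partitions ``[first HS, last HS)`` with no gaps or overlaps.
    """
    hs = [float(h) for h in hs_times]
    if sorted(hs) != hs:
        raise ValueError("hs_times must be sorted")
    if len(hs) < 2:
        warnings.warn("fewer than 2 heel strikes: no strides to segment", stacklevel=2)
        return []
    t0, t1 = signal.t[0], signal.t[-1]
    if hs[0] < t0 or hs[-1] > t1:
        raise ValueError("heel-strike times fall outside the signal time range")
    return [Stride(index=i, start_ms=a, end_ms=b)
            for i, (a, b) in enumerate(zip(hs, hs[1:]))]


def _resample_gx(signal: FootMotionSignal, stride: Stride, n_points: int) -> np.ndarray:
    lo = signal.index_at(stride.start_ms)
    hi = signal.index_at(stride.end_ms)
    seg_t = signal.t[lo:hi + 1]
    seg = signal.G_x[lo:hi + 1]
    grid = np.linspace(seg_t[0], seg_t[-1], n_points)
    return np.interp(grid, seg_t, seg)


def _template_correlation(wave: np.ndarray, template: np.ndarray) -> float:
    if np.ptp(wave) == 0 or np.ptp(template) == 0:
        return 0.0
    return float(np.corrcoef(wave, template)[0, 1])


def filter_effective_strides(
    strides: Sequence[Stride],
    signal: FootMotionSignal,
    template_corr_min: float = 0.8,
    predicate: Optional[Callable[[np.ndarray, np.ndarray], bool]] = None,
    n_template_points: int = 101,
) -> List[Stride]:
    """Flag which strides are usable for parameter estimation.

    The first two and last two strides of the trial are always marked
    non-effective (gait initiation/termination). Remaining strides are
    compared, after resampling their G_x waveform to a common length,
    against the pointwise-median stride template; strides whose Pearson
    correlation with the template falls below ``template_corr_min`` are
    marked non-effective. ``predicate(wave, template) -> bool`` may replace
    the correlation rule. Returns a new list with updated flags; the input
    is not modified. The operation is idempotent.
    """
    out = [replace(s) for s in strides]
    if not out:
        return out
    for s in out:
        s.effective = True
    for s in out[:2] + out[-2:]:
        s.effective = False
    if not any(s.effective for s in out):
        return out
    waves = np.array([_resample_gx(signal, s, n_template_points) for s in out])
    template = np.median(waves, axis=0)
    if predicate is None:
        def predicate(wave, tmpl):  # noqa: F811 - default rule
            return _template_correlation(wave, tmpl) >= template_corr_min
    for pos, s in enumerate(out):
        if s.effective and not predicate(waves[pos], template):
            s.effective = False
    return out
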