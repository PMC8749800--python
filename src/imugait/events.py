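"""Rule-based detection of bilateral gait events from one foot's signal.

The detector chains, per gait cycle (Fig-7-style streaming order):

1. heel strike (HS) — the sharp A_y valley immediately following the
   cycle's dominant A_y maximum;
2. foot-flat — the gradient turning point of the configured channel
   between the post-HS rotation burst and the 20%-GC anchor, found by
   triangle thresholding; opposite toe off (OTO) is foot-flat + 2% GC;
3. toe off (TO) — the first valley of the W-shaped A_y pattern after the
   foot-flat segment;
4. opposite heel strike (OHS) — the gradient turning point between the
   first threshold crossing after foot-flat and the channel's pre-TO
   extremum.

Every anchor fraction and amplitude threshold lives in
:class:`DetectionConfig`; the defaults are the published operating point
(G_x channel, thresholds 0.15 g / 1.15 g / 30 deg/s, 20%-GC OTO anchor,
2%-GC OTO offset, 40%-GC OHS window start). Detection is causal per
stride: only samples up to the current stride's end are consulted, and
the gait-cycle length entering the fractional anchors is the previous
heel-strike pair's, so the algorithm ports to a streaming device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import FootMotionSignal, GaitEventSet, Stride, snap_ms
from .tta import TTAQuery, tta_gtp

__all__ = [
    "DetectionConfig",
    "detect_hs",
    "detect_to",
    "detect_footflat_and_oto",
    "detect_ohs",
    "detect_all_events",
    "events_to_frame",
]

#: channel value during quiet foot-flat; A_z rests on gravity (+1 g)
_BASELINES = {"A_y": 0.0, "A_z": 1.0, "G_x": 0.0}


@dataclass
class DetectionConfig:
    """Tunable parameters of the event detector.

    ``channel`` selects which sagittal-plane signal carries the
    foot-flat/OHS turning points (``"G_x"`` default — the best-agreeing
    feature — with ``"A_y"``/``"A_z"`` selectable for the candidate
    comparison). ``thr_*`` are the amplitude gates marking the end of the
    foot-flat baseline; the A_z gate is an absolute level on the raw
    channel, i.e. ~0.15 g above its 1 g gravity baseline.
    """

    channel: str = "G_x"
    thr_Ay: float = 0.15            # g
    thr_Az: float = 1.15            # g, absolute (gravity included)
    thr_Gx: float = 30.0            # deg/s
    oto_anchor_frac: float = 0.20   # P_A location for foot-flat, frac of GC
    oto_offset_frac: float = 0.02   # OTO = foot-flat + this frac of GC
    ohs_window_start_frac: float = 0.40
    hs_prominence_frac: float = 0.6     # of A_y peak-to-peak range
    hs_valley_window_ms: float = 100.0  # search span after the A_y maximum
    hs_min_separation_ms: float = 300.0
    to_prominence: float = 0.3      # g, minimum W-valley prominence
    to_search_start_frac: float = 0.20
    to_search_end_frac: float = 0.92
    peak_prominence_frac: float = 0.25  # of within-stride amplitude

    def __post_init__(self) -> None:
        if self.channel.replace("_", "").lower() not in ("gx", "ay", "az"):
            raise ValueError("channel must be one of G_x, A_y, A_z")
        self.channel = {"gx": "G_x", "ay": "A_y", "az": "A_z"}[
            self.channel.replace("_", "").lower()]
        if not (0 < self.oto_anchor_frac < self.ohs_window_start_frac < 1):
            raise ValueError("need 0 < oto_anchor_frac < ohs_window_start_frac < 1")
        if min(self.thr_Ay, self.thr_Az, self.thr_Gx, self.oto_offset_frac) <= 0:
            raise ValueError("thresholds and the OTO offset must be positive")

    def threshold(self) -> float:
        """Amplitude gate for the configured channel, relative to baseline."""
        if self.channel == "G_x":
            return self.thr_Gx
        if self.channel == "A_y":
            return self.thr_Ay
        return self.thr_Az - _BASELINES["A_z"]


def _prominent_extrema(x: np.ndarray, prominence: float,
                       minima: bool = False) -> np.ndarray:
    """Indices of local maxima (or minima) with at least the given prominence.

    A local extremum is a sample strictly beyond both neighbours; plateaus
    contribute their first sample (``find_peaks`` left edge convention).
    """
    data = -x if minima else x
    if prominence <= 0:
        prominence = np.finfo(float).tiny
    idx, _ = find_peaks(data, prominence=prominence)
    return idx


def detect_hs(signal: FootMotionSignal,
              cfg: Optional[DetectionConfig] = None) -> List[float]:
    """Detect heel strikes from the A_y maximum-plus-sharp-valley signature.

    Per cycle, the dominant A_y maximum is located first and the HS is the
    minimum of A_y in the short window immediately after it. Cycles
    without a qualifying maximum produce no HS. Returns sorted timestamps
    in ms.
    """
    cfg = cfg or DetectionConfig()
    ay = signal.A_y
    span = float(np.ptp(ay))
    if span <= 0:
        return []
    distance = max(1, int(round(cfg.hs_min_separation_ms / signal.dt_ms)))
    peaks, _ = find_peaks(ay, prominence=cfg.hs_prominence_frac * span,
                          distance=distance)
    window = max(1, int(round(cfg.hs_valley_window_ms / signal.dt_ms)))
    out: List[float] = []
    for p in peaks:
        lo, hi = p + 1, min(p + 1 + window, ay.size)
        if hi - lo < 1:
            warnings.warn(f"no valley window after A_y maximum at "
                          f"{signal.t[p]:.0f} ms; cycle skipped", stacklevel=2)
            continue
        k = lo + int(np.argmin(ay[lo:hi]))
        out.append(float(signal.t[k]))
    return sorted(out)


def detect_to(signal: FootMotionSignal, hs_times: Sequence[float],
              cfg: Optional[DetectionConfig] = None) -> List[Optional[float]]:
    """Detect toe off per stride: the first W-pattern valley of A_y.

    The search runs from past the foot-flat segment (``to_search_start_frac``
    of the cycle) to just before the next heel strike, and accepts the
    first valley whose prominence clears ``to_prominence``. Strides
    without the pattern yield ``None``. Returns one entry per stride
    (``len(hs_times) - 1``).
    """
    cfg = cfg or DetectionConfig()
    ay = signal.A_y
    out: List[Optional[float]] = []
    for h, nh in zip(hs_times, hs_times[1:]):
        gc = nh - h
        lo = signal.index_at(h + cfg.to_search_start_frac * gc)
        hi = signal.index_at(h + cfg.to_search_end_frac * gc)
        if hi - lo < 3:
            out.append(None)
            continue
        valleys = _prominent_extrema(ay[lo:hi + 1], cfg.to_prominence, minima=True)
        out.append(float(signal.t[lo + valleys[0]]) if valleys.size else None)
    return out


def _stride_peak_prominence(ch: np.ndarray, baseline: float,
                            lo: int, hi: int, frac: float) -> float:
    amp = float(np.max(np.abs(ch[lo:hi + 1] - baseline)))
    return frac * amp if amp > 0 else np.finfo(float).tiny


def detect_footflat_and_oto(
    signal: FootMotionSignal,
    stride: Stride,
    cfg: Optional[DetectionConfig] = None,
    gc_ref: Optional[float] = None,
) -> Tuple[Optional[float], Optional[float]]:
    """Locate foot-flat (gradient turning point) and derive OTO.

    P_A sits at ``oto_anchor_frac`` of the cycle after HS (most feet are
    flat by then); P_B is the channel's prominent local maximum nearest in
    time to P_A (both directions searched, earlier wins a tie). The
    foot-flat is the farthest-from-chord sample between them, and
    ``T_OTO = T_footflat + oto_offset_frac * GC`` snapped to the grid.
    ``gc_ref`` is the cycle length used for the fractional arithmetic
    (the previous heel-strike pair's in streaming use); it defaults to the
    stride's own duration.
    """
    cfg = cfg or DetectionConfig()
    gc = gc_ref if gc_ref is not None else stride.gc_ms
    ch = signal.channel(cfg.channel)
    baseline = _BASELINES[cfg.channel]
    lo = signal.index_at(stride.start_ms)
    hi = signal.index_at(stride.end_ms) - 1  # stride interval is half-open
    # causal buffer: foot-flat candidates live before heel rise, so the
    # reference-maximum search stops at the OHS window start
    hi = min(hi, signal.index_at(stride.start_ms + cfg.ohs_window_start_frac * gc))
    pa_idx = signal.index_at(stride.start_ms + cfg.oto_anchor_frac * gc)
    if not (lo < pa_idx < hi):
        warnings.warn(f"stride {stride.index}: 20%-GC anchor outside stride",
                      stacklevel=2)
        return None, None
    prom = _stride_peak_prominence(ch, baseline, lo, hi, cfg.peak_prominence_frac)
    # include a short pre-HS context so an impact maximum at the stride's
    # left edge keeps its full flank (and hence its prominence); candidate
    # maxima before the heel strike itself are still discarded
    search_lo = max(0, lo - max(1, int(round(0.05 * gc / signal.dt_ms))))
    maxima = search_lo + _prominent_extrema(ch[search_lo:hi + 1], prom)
    maxima = maxima[maxima >= lo]
    if maxima.size == 0:
        warnings.warn(f"stride {stride.index}: no local maximum for the "
                      f"foot-flat reference point", stacklevel=2)
        return None, None
    # nearest to P_A in time; earlier wins ties; the chord needs an
    # interior sample, so maxima within 2 samples of P_A are unusable
    order = np.argsort(np.abs(maxima - pa_idx), kind="stable")
    usable = [int(maxima[j]) for j in order if abs(int(maxima[j]) - pa_idx) >= 2]
    if not usable:
        warnings.warn(f"stride {stride.index}: no usable local maximum for "
                      f"the foot-flat reference point", stacklevel=2)
        return None, None
    pb_idx = usable[0]
    query = TTAQuery.from_channel(signal.t, ch, pa_idx, pb_idx)
    t_ff = tta_gtp(query).T_GTP
    t_oto = t_ff + snap_ms(cfg.oto_offset_frac * gc, signal.dt_ms)
    return float(t_ff), float(t_oto)


def detect_ohs(
    signal: FootMotionSignal,
    stride: Stride,
    T_footflat: float,
    T_TO: float,
    cfg: Optional[DetectionConfig] = None,
    gc_ref: Optional[float] = None,
) -> Optional[float]:
    """Locate opposite heel strike as the slope break after heel rise.

    After the foot-flat state (and no earlier than
    ``ohs_window_start_frac`` of the cycle) the channel is monitored for
    its first sample whose amplitude relative to the foot-flat baseline
    exceeds the channel threshold — that sample is P_A. P_B is the
    channel's most prominent local maximum (minimum for A_y) before TO.
    OHS is the gradient turning point between them.
    """
    cfg = cfg or DetectionConfig()
    gc = gc_ref if gc_ref is not None else stride.gc_ms
    ch = signal.channel(cfg.channel)
    baseline = _BASELINES[cfg.channel]
    start = max(T_footflat + signal.dt_ms,
                stride.start_ms + cfg.ohs_window_start_frac * gc)
    lo = signal.index_at(start)
    hi = signal.index_at(T_TO)
    if hi - lo < 3:
        warnings.warn(f"stride {stride.index}: OHS window too short", stacklevel=2)
        return None
    dev = np.abs(ch[lo:hi + 1] - baseline)
    crossings = np.nonzero(dev > cfg.threshold())[0]
    if crossings.size == 0:
        warnings.warn(f"stride {stride.index}: channel never exceeded the "
                      f"baseline threshold before TO; OHS absent", stacklevel=2)
        return None
    pa_idx = lo + int(crossings[0])
    minima = cfg.channel == "A_y"  # A_y swings negative toward TO
    seg_lo = pa_idx + 1
    prom = _stride_peak_prominence(ch, baseline, seg_lo, hi, cfg.peak_prominence_frac)
    extrema = seg_lo + _prominent_extrema(ch[seg_lo:hi + 1], prom, minima=minima)
    if extrema.size:
        vals = ch[extrema]
        pb_idx = int(extrema[int(np.argmin(vals) if minima else np.argmax(vals))])
    else:
        # monotone run-up to TO: fall back to the extreme sample before TO
        seg = ch[seg_lo:hi + 1]
        pb_idx = seg_lo + int(np.argmin(seg) if minima else np.argmax(seg))
    if pb_idx - pa_idx < 2:
        warnings.warn(f"stride {stride.index}: OHS segment too short", stacklevel=2)
        return None
    query = TTAQuery.from_channel(signal.t, ch, pa_idx, pb_idx)
    return float(tta_gtp(query).T_GTP)


def detect_all_events(
    signal: FootMotionSignal,
    cfg: Optional[DetectionConfig] = None,
) -> List[GaitEventSet]:
    """Run the full per-stride event chain over a trial.

    Heel strikes are detected first; every stride from the second heel
    strike on (the first completed cycle fixes the GC length for the
    fractional anchors) is processed with the streaming-order chain
    foot-flat/OTO → TO → OHS. Detection failures leave individual events
    absent but never abort the remaining strides. Returns one
    :class:`GaitEventSet` per processed stride, with next-stride links
    filled where available.
    """
    cfg = cfg or DetectionConfig()
    hs = detect_hs(signal, cfg)
    if len(hs) < 3:
        if len(hs) > 0:
            warnings.warn("fewer than 3 heel strikes; no complete cycle to "
                          "process", stacklevel=2)
        return []
    to_all = detect_to(signal, hs, cfg)
    out: List[GaitEventSet] = []
    for i in range(1, len(hs) - 1):
        stride = Stride(index=i, start_ms=hs[i], end_ms=hs[i + 1])
        gc_prev = hs[i] - hs[i - 1]
        ev = GaitEventSet(stride_index=i, T_HS=hs[i], T_HS_next=hs[i + 1])
        t_ff, t_oto = detect_footflat_and_oto(signal, stride, cfg, gc_ref=gc_prev)
        ev.T_footflat, ev.T_OTO = t_ff, t_oto
        ev.T_TO = to_all[i]
        if t_ff is not None and ev.T_TO is not None:
            ev.T_OHS = detect_ohs(signal, stride, t_ff, ev.T_TO, cfg,
                                  gc_ref=gc_prev)
        out.append(ev)
    for prev, nxt in zip(out, out[1:]):
        prev.T_OHS_next = nxt.T_OHS
        prev.T_OTO_next = nxt.T_OTO
    return out


def events_to_frame(events: Sequence[GaitEventSet]):
    """Event table: one row per stride, ms units, NaN for absent events."""
    import pandas as pd

    cols = ["stride_index", "T_HS", "T_footflat", "T_OTO", "T_OHS", "T_TO"]
    rows = [{c: getattr(ev, c) for c in cols} for ev in events]
    return pd.DataFrame(rows, columns=cols)
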