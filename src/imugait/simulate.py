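"""Seedable synthetic foot-motion trials with exact ground-truth events.

The generator emits piecewise-linear waveform templates, not a
musculoskeletal simulation: it guarantees exactly the morphological
features that carry the gait events and nothing more. Per stride,

* ``G_x`` (plantarflexion rate) rises to a short post-heel-strike rotation
  burst, settles to the zero baseline at foot-flat with a concave corner,
  stays flat through mid-stance, then after heel rise climbs at a low
  slope that breaks upward at opposite heel strike (OHS) and peaks shortly
  before toe off, before the swing-phase reversal;
* ``A_y`` (posterior acceleration) carries a tall maximum immediately
  followed by a sharp valley at each heel strike, and a W-shaped pattern
  whose first valley marks toe off;
* ``A_z`` mirrors the same structure around the +1 g gravity baseline.

Gait timing is programmable: asymmetry of the stance-phase time is
injected as a constant shift of the OHS fraction (solved exactly from the
signed symmetry-index definition), while asymmetry of the stride time —
which in sustained walking is necessarily a drift of the contralateral
events — is injected as a geometric ramp of the cycle durations centred
on the base cycle. All event times land on the sample grid, so the ground
truth is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import FootMotionSignal, GaitEventSet, snap_ms
from .parameters import GPBLLRecord, records_from_events

__all__ = ["GaitSpec", "GroundTruth", "generate_trial", "generate_paired_measurements"]


@dataclass
class GaitSpec:
    """Programmable description of a synthetic walking trial.

    Timing defaults are the canonical healthy-gait subdivision: stance
    occupies 60% of the gait cycle (GC), foot-flat occurs at 8% GC, OTO at
    foot-flat + 2% GC, and OHS at 50% GC. ``asym_tr``/``asym_ta`` are the
    signed symmetry-index targets for stride time and stance-phase time.
    ``noise_sd`` is the additive Gaussian noise level expressed as a
    fraction of each channel's peak-to-baseline amplitude. All randomness
    flows from ``seed``; the post-noise moving-average smoothing window is
    part of the spec for reproducibility.
    """

    n_strides: int = 10
    gc_ms: float = 1000.0
    stance_frac: float = 0.60
    footflat_frac: float = 0.08
    oto_frac: Optional[float] = None     # defaults to footflat_frac + 0.02
    ohs_frac: float = 0.50
    asym_tr: float = 0.0
    asym_ta: float = 0.0
    gc_sd_ms: float = 0.0                # stride-to-stride cycle variability
    slope_low: float = 1.0               # deg/s per ms, heel rise to OHS
    slope_high: float = 3.0              # deg/s per ms, OHS to pre-TO peak
    noise_sd: float = 0.0
    seed: int = 0
    sample_rate: float = 100.0
    smooth_window: int = 3
    lead_ms: float = 400.0
    # template amplitudes (free parameters with documented defaults)
    gx_hs_peak: float = 120.0            # deg/s, post-HS rotation burst
    gx_swing_trough: float = -150.0      # deg/s, mid-swing dorsiflexion
    gx_peak_after_ohs_frac: float = 0.07  # pre-TO G_x peak, frac of GC past OHS
    ay_hs_peak: float = 2.0              # g, pre-HS maximum
    ay_hs_valley: float = -1.5           # g, sharp valley at HS
    ay_post_bump: float = 0.3            # g, loading-response rebound
    ay_ohs_level: float = -0.2           # g, A_y at the OHS slope break
    ay_w_first: float = -1.0             # g, first W valley (TO)
    ay_w_mid: float = -0.1               # g, W centre peak
    ay_w_second: float = -0.7            # g, second W valley
    az_hs_peak: float = 2.2              # g, impact spike over the 1 g baseline
    az_ohs_level: float = 1.3            # g, A_z at the OHS slope break
    az_peak: float = 2.0                 # g, pre-TO A_z maximum
    az_swing_trough: float = 0.6         # g, swing minimum

    def __post_init__(self) -> None:
        if self.oto_frac is None:
            self.oto_frac = self.footflat_frac + 0.02
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.gc_ms <= 0 or self.sample_rate <= 0:
            raise ValueError("gc_ms and sample_rate must be positive")
        dt = 1000.0 / self.sample_rate
        if abs(self.gc_ms / dt - round(self.gc_ms / dt)) > 1e-9:
            raise ValueError("gc_ms must be a whole number of sample periods")
        if not (0 < self.footflat_frac < self.oto_frac < self.ohs_frac
                < self.stance_frac < 1):
            raise ValueError("event fractions must satisfy "
                             "0 < footflat < oto < ohs < stance < 1")
        if not (self.slope_high > self.slope_low >= 0):
            raise ValueError("slope_high must exceed slope_low >= 0")
        ohs_eff = self.ohs_frac + self._ohs_shift()
        if not (0.42 < ohs_eff and
                ohs_eff + self.gx_peak_after_ohs_frac <= self.stance_frac):
            raise ValueError(
                "programmed stance asymmetry pushes OHS outside the "
                "detectable window (after heel rise, before the G_x peak)")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def _ohs_shift(self) -> float:
        """Constant OHS-fraction shift realising the SIS_ta target."""
        a = self.asym_ta
        return self.stance_frac * (1.0 - (1.0 + a / 2.0) / (1.0 - a / 2.0))

    def _gc_ratio(self) -> float:
        """Per-stride cycle-duration ratio realising the SIS_tr target."""
        s = self.asym_tr
        return 1.0 + 4.0 * s / (2.0 - s)

    def cycle_durations(self) -> np.ndarray:
        """Programmed grid-snapped GC durations for every stride."""
        r = self._gc_ratio()
        centre = (self.n_strides - 1) / 2.0
        base = np.array([self.gc_ms * r ** (i - centre)
                         for i in range(self.n_strides)])
        if self.gc_sd_ms > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed), 0x6c]))
            base = base + rng.normal(0.0, self.gc_sd_ms, self.n_strides)
        gcs = [snap_ms(g, self.dt_ms) for g in base]
        if min(gcs) < 500.0:
            raise ValueError("programmed stride-time asymmetry shrinks a "
                             "cycle below 500 ms; reduce n_strides or asym_tr")
        return np.asarray(gcs)


@dataclass
class GroundTruth:
    """Exact per-stride event annotations of a generated trial."""

    hs: np.ndarray          # n_strides + 1 heel strikes, ms
    gc: np.ndarray          # per-stride cycle duration, ms
    footflat: np.ndarray
    oto: np.ndarray
    ohs: np.ndarray
    to: np.ndarray

    @property
    def n_strides(self) -> int:
        return self.gc.size

    def event_sets(self) -> List[GaitEventSet]:
        """Ground-truth events packaged like the detector's output."""
        out = []
        for i in range(self.n_strides):
            ev = GaitEventSet(
                stride_index=i,
                T_HS=float(self.hs[i]),
                T_footflat=float(self.footflat[i]),
                T_OTO=float(self.oto[i]),
                T_OHS=float(self.ohs[i]),
                T_TO=float(self.to[i]),
                T_HS_next=float(self.hs[i + 1]),
            )
            if i + 1 < self.n_strides:
                ev.T_OHS_next = float(self.ohs[i + 1])
                ev.T_OTO_next = float(self.oto[i + 1])
            out.append(ev)
        return out

    def gpbll_records(self) -> List[GPBLLRecord]:
        """True bilateral gait parameters implied by the programmed events.

        The trial's last stride has no successor, so it contributes no
        record.
        """
        return records_from_events(
            [ev for ev in self.event_sets() if ev.is_complete()])


def _knots_to_channel(t: np.ndarray, knots: List[Tuple[float, float]],
                      baseline: float) -> np.ndarray:
    pts = sorted(knots)
    kt, kv = [], []
    for time, value in pts:
        if kt and time <= kt[-1]:
            continue  # keep the first knot on coincident grid times
        kt.append(time)
        kv.append(value)
    return np.interp(t, kt, kv, left=baseline, right=baseline)


def generate_trial(spec: GaitSpec) -> Tuple[FootMotionSignal, GroundTruth]:
    """Synthesise one walking trial and its exact ground truth.

    Two calls with the same spec (same seed) produce bit-identical
    signals.
    """
    dt = spec.dt_ms
    rg = lambda x: snap_ms(x, dt)  # noqa: E731
    gcs = spec.cycle_durations()
    n = spec.n_strides
    hs = np.empty(n + 1)
    hs[0] = rg(spec.lead_ms)
    for i in range(n):
        hs[i + 1] = hs[i] + gcs[i]

    ohs_frac = spec.ohs_frac + spec._ohs_shift()
    footflat = np.array([hs[i] + rg(spec.footflat_frac * gcs[i]) for i in range(n)])
    oto = np.array([footflat[i] + rg((spec.oto_frac - spec.footflat_frac) * gcs[i])
                    for i in range(n)])
    ohs = np.array([hs[i] + rg(ohs_frac * gcs[i]) for i in range(n)])
    to = np.array([hs[i] + rg(spec.stance_frac * gcs[i]) for i in range(n)])

    tail = rg(0.30 * gcs[-1])
    t = np.arange(0.0, hs[-1] + tail + dt / 2, dt)

    gx_knots: List[Tuple[float, float]] = [(0.0, 0.0)]
    ay_knots: List[Tuple[float, float]] = [(0.0, 0.0)]
    az_knots: List[Tuple[float, float]] = [(0.0, 1.0)]

    # The moving-average smoothing (window w) displaces asymmetric corners
    # by half the window: a steep-into-flat settling corner emerges one
    # sample late, a shallow-into-steep valley one sample early. The knots
    # that carry foot-flat and toe off are pre-compensated by that
    # half-width so the observable morphology places each event exactly at
    # its programmed grid time.
    comp = ((spec.smooth_window - 1) // 2) * dt

    def add_stride(h: float, gc: float, ff: float, t_ohs: float, t_to: float,
                   nh: float) -> None:
        hr = h + rg(0.40 * gc)           # heel-rise onset
        pk = t_ohs + rg(spec.gx_peak_after_ohs_frac * gc)
        trough = h + rg(0.78 * gc)
        v_low = spec.slope_low * (t_ohs - hr)
        v_high = v_low + spec.slope_high * (pk - t_ohs)
        gx_knots.extend([
            (h, 0.0),
            (h + rg(0.03 * gc), spec.gx_hs_peak),
            (ff - comp, 0.0), (hr, 0.0),
            (t_ohs, v_low), (pk, v_high),
            (trough, spec.gx_swing_trough),
            (nh, 0.0),
        ])
        ay_knots.extend([
            (h, spec.ay_hs_valley),
            (h + 2 * dt, spec.ay_post_bump),
            (ff, 0.0), (hr, 0.0),
            (t_ohs, spec.ay_ohs_level),
            (t_to + comp, spec.ay_w_first),
            (t_to + rg(0.05 * gc), spec.ay_w_mid),
            (t_to + rg(0.10 * gc), spec.ay_w_second),
            (t_to + rg(0.15 * gc), 0.0),
            (nh - 7 * dt, 0.0),
            (nh - 3 * dt, spec.ay_hs_peak),
        ])
        az_knots.extend([
            (h, spec.az_hs_peak),
            (ff, 1.0), (hr, 1.0),
            (t_ohs, spec.az_ohs_level),
            (pk, spec.az_peak),
            (trough, spec.az_swing_trough),
            (nh - 3 * dt, 1.0),
        ])

    # lead-in: approach to the first heel strike
    ay_knots.extend([(hs[0] - 7 * dt, 0.0), (hs[0] - 3 * dt, spec.ay_hs_peak)])
    az_knots.append((hs[0] - 3 * dt, 1.0))
    for i in range(n):
        add_stride(hs[i], gcs[i], footflat[i], ohs[i], to[i], hs[i + 1])
    # truncated pseudo-stride after the last heel strike so the final HS
    # signature is complete
    h, gc = hs[-1], gcs[-1]
    ff_last = h + rg(spec.footflat_frac * gc)
    gx_knots.extend([(h, 0.0), (h + rg(0.03 * gc), spec.gx_hs_peak), (ff_last, 0.0)])
    ay_knots.extend([(h, spec.ay_hs_valley), (h + 2 * dt, spec.ay_post_bump),
                     (ff_last, 0.0)])
    az_knots.extend([(h, spec.az_hs_peak), (ff_last, 1.0)])

    gx = _knots_to_channel(t, gx_knots, 0.0)
    ay = _knots_to_channel(t, ay_knots, 0.0)
    az = _knots_to_channel(t, az_knots, 1.0)
    ax = np.zeros_like(t)
    gy = np.zeros_like(t)
    gz = np.zeros_like(t)

    rng = np.random.default_rng(spec.seed)
    channels = {"A_x": (ax, 0.0), "A_y": (ay, 0.0), "A_z": (az, 1.0),
                "G_x": (gx, 0.0), "G_y": (gy, 0.0), "G_z": (gz, 0.0)}
    out = {}
    for name, (arr, baseline) in channels.items():
        scale = float(np.max(np.abs(arr - baseline)))
        if spec.noise_sd > 0 and scale > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd * scale, arr.size)
        if spec.smooth_window > 1:
            arr = uniform_filter1d(arr, size=spec.smooth_window, mode="nearest")
        out[name] = arr

    signal = FootMotionSignal(
        sample_rate=spec.sample_rate, t=t,
        A_x=out["A_x"], A_y=out["A_y"], A_z=out["A_z"],
        G_x=out["G_x"], G_y=out["G_y"], G_z=out["G_z"],
        side="right",
    )
    truth = GroundTruth(hs=hs, gc=gcs, footflat=footflat, oto=oto, ohs=ohs, to=to)
    return signal, truth


_TIME_QUANTITIES = ("T_OHS_0", "T_OTO_0")
_GPBLL_QUANTITIES = ("DST1", "DST2", "DSTt", "T_str_L", "T_str_R",
                     "T_sta_L", "T_sta_R", "SIS_tr", "SIS_ta")


def generate_paired_measurements(
    spec: GaitSpec,
    jitter_sd_ms: float,
    quantity: str = "T_OHS_0",
    jitter_prop: float = 0.0,
):
    """Emulate a two-system comparison on one synthetic trial.

    Ground-truth values act as the reference system; the test system reads
    the same values plus seeded Gaussian jitter (optionally proportional
    to the value, which induces a proportional bias), snapped to the
    sample grid for time-valued quantities — reproducing the tied,
    discrete paired data a 100 Hz comparison yields. ``quantity`` is one
    of the relative event times (``"T_OHS_0"``, ``"T_OTO_0"``) or a
    bilateral-parameter field name.
    """
    from .agreement import PairedMeasurements

    _, truth = generate_trial(spec)
    if quantity in _TIME_QUANTITIES:
        rel = (truth.ohs if quantity == "T_OHS_0" else truth.oto) - truth.hs[:-1]
        ref = np.asarray(rel, dtype=float)
        snap = True
    elif quantity in _GPBLL_QUANTITIES:
        records = truth.gpbll_records()
        ref = np.array([getattr(r, quantity) for r in records], dtype=float)
        snap = quantity not in ("SIS_tr", "SIS_ta")
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9a17]))
    test = ref + jitter_prop * (ref - ref.mean()) + rng.normal(0.0, jitter_sd_ms, ref.size)
    if snap:
        test = np.floor(test / spec.dt_ms + 0.5) * spec.dt_ms
    return PairedMeasurements(x_ref=ref, x_test=test, label=quantity)
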