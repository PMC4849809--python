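"""Oxygen-uptake (MO2) extraction from respirometry traces.

Three chamber designs are supported.  In a closed respirometer the fish
depletes the sealed volume and MO2 follows from the rate of decline of
dissolved O2:

    MO2 = (Vr - Vf) * dO2 / (dt * bw)

with respirometer volume Vr, fish volume Vf and body mass bw.  In
flow-through respirometry the Fick principle applies at a known flow Fw:

    MO2 = Fw * (O2_in - O2_out) / bw

Intermittent-flow respirometry alternates closed measurement phases with
flush phases; each measurement phase is treated as a short closed run.

All MO2 values are in mg O2 per kg per hour; ambient oxygen is reported as
PO2 in kPa so the output feeds directly into Pcrit estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import OxygenQuantity, WaterConditions, convert_o2, o2_solubility

__all__ = [
    "RespirometerConfig",
    "RespirometryTrace",
    "MO2Series",
    "mo2_closed",
    "mo2_flow_through",
    "mo2_intermittent",
]


@dataclass(frozen=True)
class RespirometerConfig:
    """Chamber geometry, animal mass and operating mode.

    volume_respirometer and volume_fish in litres, body_mass in kg,
    flow_rate in L/h (flow modes only).
    """

    volume_respirometer: float
    volume_fish: float
    body_mass: float
    mode: str  # closed | flow_through | intermittent
    conditions: WaterConditions
    flow_rate: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("closed", "flow_through", "intermittent"):
            raise ValueError(f"unknown respirometer mode {self.mode!r}")
        if not self.volume_respirometer > self.volume_fish >= 0:
            raise ValueError(
                "require volume_respirometer > volume_fish >= 0, got "
                f"Vr={self.volume_respirometer}, Vf={self.volume_fish}"
            )
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if self.mode == "flow_through" and (self.flow_rate is None or self.flow_rate <= 0):
            raise ValueError("flow_through mode requires flow_rate > 0")

    @property
    def effective_volume(self) -> float:
        """Water volume actually available to hold oxygen, Vr - Vf (L)."""
        return self.volume_respirometer - self.volume_fish


@dataclass
class RespirometryTrace:
    """A time series of dissolved-oxygen readings from one chamber.

    timestamps are hours and must be strictly increasing; o2 values share
    one unit.  phase_labels ('measure'/'flush') are only meaningful in
    intermittent mode.
    """

    timestamps: np.ndarray
    o2: np.ndarray
    o2_unit: str
    config: RespirometerConfig
    phase_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.timestamps.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if self.timestamps.size != self.o2.size:
            raise ValueError("timestamps and o2 must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.o2 < 0):
            raise ValueError("o2 values must be >= 0")
        if self.phase_labels is not None:
            self.phase_labels = np.asarray(self.phase_labels, dtype=object)
            if self.phase_labels.size != self.o2.size:
                raise ValueError("phase_labels must match trace length")
            if self.config.mode != "intermittent" and np.any(self.phase_labels == "flush"):
                raise ValueError("flush labels are only valid in intermittent mode")

    def concentrations_mg_per_l(self) -> np.ndarray:
        """O2 readings as mg/L (needs conditions when the unit is a pressure)."""
        return _as_unit(self.o2, self.o2_unit, "mg_per_L", self.config.conditions)

    def po2_kpa(self) -> np.ndarray:
        """O2 readings as PO2 in kPa."""
        return _as_unit(self.o2, self.o2_unit, "kPa", self.config.conditions)


@dataclass
class MO2Series:
    """Paired ambient PO2 (kPa) / MO2 (mg O2 kg-1 h-1) observations."""

    po2: np.ndarray
    mo2: np.ndarray
    window_span: np.ndarray
    quality: np.ndarray = field(default=None)  # 'ok' | 'suspect' | 'washout'
    r_squared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.po2 = np.asarray(self.po2, dtype=float)
        self.mo2 = np.asarray(self.mo2, dtype=float)
        self.window_span = np.asarray(self.window_span, dtype=float)
        if not (self.po2.size == self.mo2.size == self.window_span.size):
            raise ValueError("po2, mo2 and window_span must have equal length")
        if self.quality is None:
            self.quality = np.array(["ok"] * self.po2.size, dtype=object)
        if not np.all(np.isfinite(self.mo2)):
            raise ValueError("mo2 values must be finite")

    def __len__(self) -> int:
        return int(self.po2.size)


def _as_unit(values, unit, target, conditions):
    # vectorized wrapper over the scalar converter; the scalar path carries
    # all the unit/conditions validation
    return np.array(
        [convert_o2(OxygenQuantity(float(v), unit), target, conditions).value for v in values]
    )


def _slope(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of c against t and fit r^2."""
    t = t - t.mean()
    denom = float(t @ t)
    slope = float(t @ (c - c.mean())) / denom
    resid = (c - c.mean()) - slope * t
    sst = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    return slope, r2


def _window_bounds(timestamps: np.ndarray, window: float | int) -> list[slice]:
    """Contiguous, non-overlapping windows, by sample count (int) or hours (float)."""
    n = timestamps.size
    out: list[slice] = []
    if isinstance(window, (int, np.integer)):
        if window < 2:
            raise ValueError("window must span at least 2 samples")
        if window > n:
            raise ValueError(f"window of {window} samples exceeds trace length {n}")
        # consecutive windows share an endpoint so their spans tile the trace
        for s in range(0, n - window + 1, window - 1):
            out.append(slice(s, s + window))
        return out
    span = float(window)
    if span <= 0:
        raise ValueError("window span must be positive")
    if span > timestamps[-1] - timestamps[0]:
        raise ValueError("window span exceeds trace duration")
    start = 0
    while start < n - 1:
        stop = int(np.searchsorted(timestamps, timestamps[start] + span, side="right"))
        if stop - start < 2:
            stop = start + 2
        if stop > n:
            break
        out.append(slice(start, stop))
        start = stop
    return out


def mo2_closed(trace: RespirometryTrace, window: float | int) -> MO2Series:
    """MO2 from a closed-respirometry trace.

    Within each window the change in O2 concentration is taken as the
    least-squares slope of concentration against time (identical to the
    first-minus-last difference for two-sample windows).  Windows where O2
    rises give non-positive MO2 and are flagged ``suspect`` but retained.

    Parameters
    ----------
    trace : RespirometryTrace
        Must have ``config.mode == 'closed'``.
    window : int or float
        Number of samples (int) or window span in hours (float).
    """
    if trace.config.mode != "closed":
        raise ValueError(f"mo2_closed requires mode='closed', got {trace.config.mode!r}")
    conc = trace.concentrations_mg_per_l()
    po2 = trace.po2_kpa()
    cfg = trace.config
    slices = _window_bounds(trace.timestamps, window)
    mo2, mean_po2, spans, qual, r2s = [], [], [], [], []
    for sl in slices:
        slope, r2 = _slope(trace.timestamps[sl], conc[sl])
        rate = cfg.effective_volume * (-slope) / cfg.body_mass
        mo2.append(rate)
        mean_po2.append(float(po2[sl].mean()))
        spans.append(float(trace.timestamps[sl][-1] - trace.timestamps[sl][0]))
        qual.append("suspect" if rate <= 0 else "ok")
        r2s.append(r2)
    return MO2Series(
        po2=np.array(mean_po2),
        mo2=np.array(mo2),
        window_span=np.array(spans),
        quality=np.array(qual, dtype=object),
        r_squared=np.array(r2s),
    )


def mo2_flow_through(
    trace: RespirometryTrace,
    o2_in: np.ndarray,
    washout_residence_times: float = 3.0,
) -> MO2Series:
    """MO2 from inflow/outflow concentrations at a fixed flow rate.

    Per sample, MO2 = Fw * (C_in - C_out) / bw with concentrations in mg/L;
    PO2 is reported as the outflow PO2.  No wash-out deconvolution is
    attempted: samples within ``washout_residence_times`` chamber residence
    times (Vr/Fw) of the trace start, or of any step change in the inflow,
    are flagged ``washout``.
    """
    cfg = trace.config
    if cfg.mode != "flow_through":
        raise ValueError(f"mo2_flow_through requires mode='flow_through', got {cfg.mode!r}")
    if cfg.flow_rate is None or cfg.flow_rate <= 0:
        raise ValueError("flow_rate is required for flow-through MO2")
    o2_in = np.asarray(o2_in, dtype=float)
    if o2_in.size != trace.o2.size:
        raise ValueError("o2_in must match trace length")
    c_out = trace.concentrations_mg_per_l()
    c_in = _as_unit(o2_in, trace.o2_unit, "mg_per_L", cfg.conditions)
    po2_out = trace.po2_kpa()
    mo2 = cfg.flow_rate * (c_in - c_out) / cfg.body_mass

    residence = cfg.volume_respirometer / cfg.flow_rate
    horizon = washout_residence_times * residence
    t = trace.timestamps
    # times at which the inflow concentration changes, plus the trace start
    change_times = [t[0]]
    steps = np.nonzero(np.abs(np.diff(c_in)) > 1e-9)[0]
    change_times.extend(t[i + 1] for i in steps)
    qual = np.array(["ok"] * t.size, dtype=object)
    for ct in change_times:
        qual[(t >= ct) & (t < ct + horizon)] = "washout"
    qual[mo2 <= 0] = np.where(qual[mo2 <= 0] == "washout", "washout", "suspect")
    return MO2Series(
        po2=po2_out,
        mo2=mo2,
        window_span=np.zeros_like(mo2),
        quality=qual,
    )


def mo2_intermittent(trace: RespirometryTrace, min_samples: int = 3) -> MO2Series:
    """One MO2 per closed measurement phase of an intermittent-flow trace.

    Flush-labelled samples are excluded; each contiguous ``measure`` phase
    with at least ``min_samples`` samples is fit by least squares as in
    :func:`mo2_closed`, with the slope-fit r^2 reported per phase.  Shorter
    phases are skipped (not an error).
    """
    cfg = trace.config
    if cfg.mode != "intermittent":
        raise ValueError(f"mo2_intermittent requires mode='intermittent', got {cfg.mode!r}")
    if trace.phase_labels is None:
        raise ValueError("intermittent traces need phase_labels")
    conc = trace.concentrations_mg_per_l()
    po2 = trace.po2_kpa()
    is_measure = trace.phase_labels == "measure"
    # contiguous runs of measure samples
    mo2, mean_po2, spans, qual, r2s = [], [], [], [], []
    idx = np.flatnonzero(is_measure)
    if idx.size:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        for run in runs:
            if run.size < min_samples:
                continue
            slope, r2 = _slope(trace.timestamps[run], conc[run])
            rate = cfg.effective_volume * (-slope) / cfg.body_mass
            mo2.append(rate)
            mean_po2.append(float(po2[run].mean()))
            spans.append(float(trace.timestamps[run][-1] - trace.timestamps[run][0]))
            qual.append("suspect" if rate <= 0 else "ok")
            r2s.append(r2)
    return MO2Series(
        po2=np.array(mean_po2),
        mo2=np.array(mo2),
        window_span=np.array(spans),
        quality=np.array(qual, dtype=object),
        r_squared=np.array(r2s),
    )
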