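"""Beat segmentation and TTFM patency metrics.

Five metrics summarize a graft flow (and pressure) waveform per beat:

* mean flow rate        Q_mean = (1/T) ∫ Q dt            (reported in mL/min)
* pulsatility index     PI = (Q_max − Q_min)/Q_mean
* diastolic/systolic ratio   D/S = |V_dia| / |V_sys|
* diastolic filling %   DF% = 100·|V_dia| / |V_tot|
* diastolic resistance index DRI = (p̄_dia/|Q̄|_dia) / (p̄_sys/|Q̄|_sys)

where V are delivered volumes based on the *absolute* flow rate, and the
phase means in DRI likewise use |Q|.  DF% and D/S are directly related,
DF% = 100·DS/(1+DS), and DRI = (p̄_dia/p̄_sys)·(T_dia/T_sys)/DS; both
identities hold beat by beat for the implementations here and are asserted
in the test suite.

Segmentation comes either from simulated aortic-valve events (systole =
valve-open interval) or from ECG-like markers (beat start = R peak, with a
systole-end time per beat).  Phase integrals use the trapezoid rule on the
record's native time grid, with linear interpolation at phase boundaries.
Across beats the median is reported, matching the robust summaries used for
intraoperative data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Beat",
    "BeatSegmentation",
    "PatencyMetrics",
    "MetricUndefinedError",
    "segment_beats",
    "segment_from_valve_events",
    "q_mean",
    "pulsatility_index",
    "ds_ratio_and_df",
    "dri",
    "compute_all",
    "metrics_from_simulation",
]


class MetricUndefinedError(ValueError):
    """A metric's denominator vanished (e.g. zero mean or phase flow)."""


@dataclass(frozen=True)
class Beat:
    start: float
    sys_end: float
    end: float

    @property
    def T(self) -> float:
        return self.end - self.start

    @property
    def T_sys(self) -> float:
        return self.sys_end - self.start

    @property
    def T_dia(self) -> float:
        return self.end - self.sys_end


@dataclass
class BeatSegmentation:
    beats: list[Beat]
    source: str  # "valve-events" | "ECG-markers"

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)


def segment_beats(
    beat_starts: np.ndarray,
    systole_ends: np.ndarray,
    source: str = "ECG-markers",
) -> BeatSegmentation:
    """Segment beats from marker times.

    ``beat_starts`` are R-peak-like beat onset times; ``systole_ends`` give
    one systole-end time per beat, inside that beat.  The last (incomplete)
    beat — the one with no following start — is discarded.
    """
    starts = np.asarray(beat_starts, dtype=float)
    ends = np.asarray(systole_ends, dtype=float)
    if len(starts) < 3:
        raise ValueError("need at least 3 beat-start markers (2 complete beats)")
    if np.any(np.diff(starts) <= 0) or np.any(np.diff(ends) <= 0):
        raise ValueError("marker times must be strictly increasing")
    beats = []
    for k in range(len(starts) - 1):
        inside = ends[(ends > starts[k]) & (ends < starts[k + 1])]
        if len(inside) != 1:
            raise ValueError(
                f"beat starting at t={starts[k]:.3f}s must contain exactly one "
                f"systole-end marker, found {len(inside)}"
            )
        beats.append(Beat(float(starts[k]), float(inside[0]), float(starts[k + 1])))
    return BeatSegmentation(beats, source)


def segment_from_valve_events(
    open_times: np.ndarray, close_times: np.ndarray
) -> BeatSegmentation:
    """Segmentation from aortic-valve events of a simulation.

    Systole is the valve-open interval; diastole is the remainder of the beat
    (valve close to the next opening).  Edge beats without a full
    open–close–open triple are discarded.
    """
    return segment_beats(open_times, close_times, source="valve-events")


# ---------------------------------------------------------------------------
# phase integration helpers
# ---------------------------------------------------------------------------

def _window(t: np.ndarray, x: np.ndarray, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Samples of x on [t0, t1] with interpolated endpoint values."""
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError(f"interval [{t0:.4f}, {t1:.4f}] not covered by samples")
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    xx = np.concatenate(([np.interp(t0, t, x)], x[inner], [np.interp(t1, t, x)]))
    steps = np.diff(tt)
    if len(steps) and steps.max() > 5.0 * max(np.median(np.diff(t)), 1e-12):
        raise ValueError("gap in samples inside the integration interval")
    return tt, xx


def _integral(t: np.ndarray, x: np.ndarray, t0: float, t1: float) -> float:
    tt, xx = _window(t, x, t0, t1)
    return float(np.trapezoid(xx, tt))


# ---------------------------------------------------------------------------
# per-beat metrics
# ---------------------------------------------------------------------------

def q_mean(t: np.ndarray, Q: np.ndarray, beat: Beat) -> float:
    """Beat-mean flow in mL/min (inputs are mL/s on a time grid in s)."""
    return _integral(t, Q, beat.start, beat.end) / beat.T * 60.0


def pulsatility_index(t: np.ndarray, Q: np.ndarray, beat: Beat) -> float:
    tt, qq = _window(t, Q, beat.start, beat.end)
    qm = np.trapezoid(qq, tt) / beat.T
    if abs(qm) <= 1e-12 * max(np.max(np.abs(qq)), 1e-300):
        raise MetricUndefinedError("PI undefined: beat-mean flow is zero")
    return float((qq.max() - qq.min()) / qm)


def ds_ratio_and_df(t: np.ndarray, Q: np.ndarray, beat: Beat) -> tuple[float, float]:
    """Diastolic/systolic delivered-volume ratio and diastolic filling %.

    Delivered volumes use the absolute flow rate in each phase.
    """
    absQ = np.abs(Q)
    v_sys = _integral(t, absQ, beat.start, beat.sys_end)
    v_dia = _integral(t, absQ, beat.sys_end, beat.end)
    if v_sys == 0:
        raise MetricUndefinedError("D/S undefined: zero systolic delivered volume")
    ds = v_dia / v_sys
    return float(ds), float(100.0 * v_dia / (v_dia + v_sys))


def dri(t: np.ndarray, Q: np.ndarray, p: np.ndarray, beat: Beat) -> float:
    """Diastolic resistance index from aligned flow and pressure waveforms."""
    absQ = np.abs(Q)
    qbar_sys = _integral(t, absQ, beat.start, beat.sys_end) / beat.T_sys
    qbar_dia = _integral(t, absQ, beat.sys_end, beat.end) / beat.T_dia
    if qbar_sys == 0 or qbar_dia == 0:
        raise MetricUndefinedError("DRI undefined: zero phase-mean flow")
    pbar_sys = _integral(t, p, beat.start, beat.sys_end) / beat.T_sys
    pbar_dia = _integral(t, p, beat.sys_end, beat.end) / beat.T_dia
    return float((pbar_dia / qbar_dia) / (pbar_sys / qbar_sys))


# ---------------------------------------------------------------------------
# record-level driver
# ---------------------------------------------------------------------------

@dataclass
class PatencyMetrics:
    """Per-beat metric table plus across-beat medians."""

    per_beat: pd.DataFrame            # one row per beat
    median: dict[str, float]
    failed_beats: list[tuple[int, str]] = field(default_factory=list)
    has_pressure: bool = True

    def to_json(self, path) -> None:
        payload = {
            "median": self.median,
            "per_beat": self.per_beat.to_dict(orient="records"),
            "failed_beats": self.failed_beats,
            "has_pressure": self.has_pressure,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tidy_csv(self, path) -> None:
        tidy = self.per_beat.reset_index(names="beat").melt(
            id_vars="beat", var_name="metric", value_name="value"
        )
        tidy.to_csv(path, index=False)


def compute_all(
    t: np.ndarray,
    flow: np.ndarray,
    segmentation: BeatSegmentation,
    pressure: np.ndarray | None = None,
) -> PatencyMetrics:
    """All five metrics per beat, with across-beat medians.

    DRI is omitted (with a warning) when no pressure waveform is supplied.
    Beats on which a metric is undefined are recorded and excluded from the
    medians.
    """
    t = np.asarray(t, dtype=float)
    flow = np.asarray(flow, dtype=float)
    rows, failed = [], []
    for k, beat in enumerate(segmentation):
        row: dict[str, float] = {}
        try:
            row["q_mean"] = q_mean(t, flow, beat)
            row["pi"] = pulsatility_index(t, flow, beat)
            row["ds_ratio"], row["df_pct"] = ds_ratio_and_df(t, flow, beat)
            if pressure is not None:
                row["dri"] = dri(t, flow, pressure, beat)
        except (MetricUndefinedError, ValueError) as exc:
            failed.append((k, str(exc)))
            continue
        rows.append(row)
    if pressure is None:
        warnings.warn("no pressure waveform supplied: DRI unavailable", stacklevel=2)
    if not rows:
        raise MetricUndefinedError("no beat yielded a full metric set")
    per_beat = pd.DataFrame(rows)
    med = {c: float(per_beat[c].median()) for c in per_beat.columns}
    return PatencyMetrics(
        per_beat=per_beat,
        median=med,
        failed_beats=failed,
        has_pressure=pressure is not None,
    )


def metrics_from_simulation(result, pressure_signal: str = "aortic_pressure") -> PatencyMetrics:
    """Patency metrics of a simulated run, segmented by aortic-valve events.

    Flow is the graft (probe-site) flow; pressure defaults to central aortic
    pressure, which is the pressure the diastolic resistance index is defined
    on.
    """
    seg = segment_from_valve_events(
        result.events["aortic_valve_open"], result.events["aortic_valve_close"]
    )
    return compute_all(
        result.t,
        result.signals["graft_flow"],
        seg,
        pressure=result.signals[pressure_signal],
    )
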