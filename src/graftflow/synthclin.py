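"""Synthetic intraoperative cohort generation and comparison statistics.

The verification stage of the study design needs records shaped like
intraoperative TTFM data: per graft, a flow waveform (mL/min), a peripheral
(radial-like) pressure waveform, ECG-style beat markers (R peak and systole
end), and a patency class label.  This module generates such cohorts from the
closed-loop simulator — sampling per-patient physiology from the parameter
registry's distributions, per-graft stenosis severity from the class ranges,
transforming central to peripheral pressure, and adding seeded measurement
noise — and provides the statistics used to compare cohorts: N-point
moving-average central-pressure estimation, MAD/median variability, per-class
median/IQR summaries, and rank-based two-group tests with an exact
enumeration path at small n.

Patency classes follow a configurable convention on true diameter reduction:
patent < 50 %, questionable 50–74 %, failed >= 75 %.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .distributions import default_distributions
from .metrics import compute_all, segment_beats
from .model import SimulationError, simulate
from .parameters import ModelParameters, build_default_parameters

__all__ = [
    "CLASS_RANGES",
    "CLASS_ORDER",
    "ClinicalRecord",
    "CohortSummary",
    "generate_cohort",
    "peripheral_from_central",
    "estimate_central_pressure",
    "mad_over_median",
    "compare_groups",
    "record_metrics",
    "hemodynamic_parameters",
    "summarize_by_class",
    "write_cohort",
    "read_cohort",
]

CLASS_ORDER = ("patent", "questionable", "failed")
#: true diameter-reduction ranges per patency class (%, upper bound capped at
#: 90 so every graft stays within the stenosis element's validity)
CLASS_RANGES: dict[str, tuple[float, float]] = {
    "patent": (0.0, 50.0),
    "questionable": (50.0, 75.0),
    "failed": (75.0, 90.0),
}

#: per-patient physiology sampled for cohort generation (registry subset)
PATIENT_PARAMETERS = ("T", "R0_SVB", "C_sa", "E_max_lv", "C1", "V0_1")


@dataclass
class ClinicalRecord:
    patient_id: str
    graft_id: str
    t: np.ndarray                 # s
    flow: np.ndarray              # mL/min at the probe
    pressure: np.ndarray          # peripheral pressure, mmHg
    r_peaks: np.ndarray           # beat-onset marker times, s
    systole_ends: np.ndarray      # one per beat interval, s
    patency_class: str
    true_pct: float               # ground truth, hidden from the analysis stage

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.flow) == len(self.pressure)):
            raise ValueError("waveforms must be time-aligned and equal length")
        if len(self.r_peaks) < 5:
            raise ValueError("records need at least 4 complete beats")
        if self.patency_class not in CLASS_RANGES:
            raise ValueError(f"unknown patency class {self.patency_class!r}")
        lo, hi = CLASS_RANGES[self.patency_class]
        if not (lo <= self.true_pct < hi or (self.patency_class == "failed" and self.true_pct == hi)):
            raise ValueError(
                f"true_pct {self.true_pct} inconsistent with class {self.patency_class!r}"
            )


# ---------------------------------------------------------------------------
# pressure transforms
# ---------------------------------------------------------------------------

def peripheral_from_central(
    t: np.ndarray,
    p_central: np.ndarray,
    resonance_hz: float = 8.0,
    damping: float = 0.3,
    amplification: float = 10.0,
) -> np.ndarray:
    """Radial-like waveform from a central one.

    A second-order resonant low-pass (natural frequency ``resonance_hz``,
    damping ratio ``damping``) reshapes the waveform — sharpening the
    systolic peak and delaying it, as peripheral wave amplification does —
    and the pulsatile component is then rescaled so the peripheral systolic
    peak exceeds the central one by ``amplification`` mmHg.
    """
    dt = float(np.median(np.diff(t)))
    wn = 2.0 * math.pi * resonance_hz
    num, den = [wn**2], [1.0, 2.0 * damping * wn, wn**2]
    b, a, _ = sps.cont2discrete((num, den), dt, method="bilinear")
    b = np.atleast_1d(np.squeeze(b))
    a = np.atleast_1d(np.squeeze(a))
    # warm start on a repeated copy so the filter transient dies out
    y = sps.lfilter(b, a, np.concatenate([p_central, p_central]))[len(p_central):]
    mean = y.mean()
    span = y.max() - mean
    if span <= 0:
        return y
    target = (p_central.max() + amplification) - mean
    return mean + (y - mean) * (target / span)


def estimate_central_pressure(
    t: np.ndarray,
    p_peripheral: np.ndarray,
    T: float,
    window_fraction: float = 0.25,
) -> tuple[float, float]:
    """(SBP, DBP) estimate from a peripheral waveform.

    Central systolic pressure is approximated as the maximum of an N-point
    moving average whose window spans ``window_fraction``·T; diastolic
    pressure is the waveform minimum.
    """
    if not (0.0 < window_fraction <= 0.5):
        raise ValueError("window_fraction must lie in (0, 0.5]")
    if t[-1] - t[0] < T:
        raise ValueError("need at least one full beat of samples")
    dt = float(np.median(np.diff(t)))
    n = max(int(round(window_fraction * T / dt)), 1)
    if n > len(p_peripheral):
        raise ValueError("moving-average window longer than the record")
    kernel = np.ones(n) / n
    smooth = np.convolve(p_peripheral, kernel, mode="valid")
    return float(smooth.max()), float(p_peripheral.min())


# ---------------------------------------------------------------------------
# robust statistics
# ---------------------------------------------------------------------------

def mad_over_median(values) -> float:
    """Median absolute deviation relative to the median (scale-free spread)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite values")
    med = np.median(x)
    if med == 0:
        raise ValueError("median is zero; relative MAD undefined")
    return float(np.median(np.abs(x - med)) / med)


@dataclass(frozen=True)
class GroupTestReport:
    test: str            # "rank-sum" | "signed-rank"
    method: str          # "exact" | "normal"
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return float(w_obs), count / total


def _exact_signedrank_p(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    n = len(d)
    count = 0
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return float(w_obs), count / 2**n


def compare_groups(
    a, b, paired: bool = False, method: str = "auto"
) -> GroupTestReport:
    """Nonparametric two-group comparison (two-sided).

    Unpaired data use the rank-sum test, paired data the signed-rank test.
    ``method`` 'exact' enumerates the null distribution (feasible for
    n <= 10 per group), 'normal' uses the large-sample approximation, and
    'auto' picks exact at small n.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length groups")
    if method == "auto":
        method = "exact" if max(len(a), len(b)) <= 10 else "normal"

    if paired:
        d = a - b
        d = d[d != 0]
        if len(d) == 0:
            raise ValueError("all paired differences are tied at zero; test degenerate")
        if method == "exact":
            stat, p = _exact_signedrank_p(d)
        else:
            res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        return GroupTestReport("signed-rank", method, stat, p, len(a), len(b))

    if method == "exact":
        stat, p = _exact_ranksum_p(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupTestReport("rank-sum", method, stat, p, len(a), len(b))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_patient(rng: np.random.Generator, base: ModelParameters) -> ModelParameters:
    dists = {d.name: d for d in default_distributions()}
    overrides = {name: float(dists[name].sample(1, rng)[0]) for name in PATIENT_PARAMETERS}
    return base.replace(**overrides)


def _record_from_simulation(
    res,
    patient_id: str,
    graft_id: str,
    patency_class: str,
    pct: float,
    rng: np.random.Generator,
    flow_noise_sd: float,
    jitter_sd: float,
    skip_beats: int,
) -> ClinicalRecord:
    T = res.params.T
    t0 = skip_beats * T
    mask = res.t >= t0
    t = res.t[mask] - t0
    central = res.signals["aortic_pressure"][mask]
    flow = res.signals["graft_flow"][mask] * 60.0  # mL/min, TTFM convention

    peripheral = peripheral_from_central(t, central)
    n_complete = res.n_beats - skip_beats
    r_peaks = np.arange(n_complete + 1) * T
    closes = res.events["aortic_valve_close"] - t0
    sys_ends = []
    for k in range(n_complete):
        inside = closes[(closes > k * T) & (closes < (k + 1) * T)]
        sys_ends.append(float(inside[0]) if len(inside) else (k + 0.35) * T)
    sys_ends = np.asarray(sys_ends)

    if flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, flow_noise_sd, size=flow.shape)
    if jitter_sd > 0:
        r_peaks = r_peaks + np.concatenate(([0.0], rng.normal(0.0, jitter_sd, len(r_peaks) - 1)))
        sys_ends = sys_ends + rng.normal(0.0, jitter_sd, len(sys_ends))
        r_peaks.sort(); sys_ends.sort()
    # keep markers within the record span
    r_peaks = np.clip(r_peaks, t[0], t[-1])
    return ClinicalRecord(
        patient_id=patient_id, graft_id=graft_id, t=t, flow=flow,
        pressure=peripheral, r_peaks=r_peaks, systole_ends=sys_ends,
        patency_class=patency_class, true_pct=pct,
    )


def generate_cohort(
    n_patients: int = 41,
    grafts_per_patient: int = 3,
    class_mix: tuple[float, float, float] = (0.5, 0.3, 0.2),
    seed: int = 0,
    flow_noise_sd: float = 2.0,
    jitter_sd: float = 0.010,
    n_beats: int = 8,
    skip_beats: int = 2,
    base: ModelParameters | None = None,
    max_retries: int = 5,
) -> list[ClinicalRecord]:
    """A seeded synthetic cohort of ``n_patients × grafts_per_patient`` records.

    Per patient, a physiology subset is drawn from the registry
    distributions; per graft, a patency class from ``class_mix`` and a true
    stenosis percentage uniform within the class range.  Failed simulations
    are resampled with bounded retries.
    """
    if not math.isclose(sum(class_mix), 1.0, abs_tol=1e-9):
        raise ValueError("class_mix must sum to 1 over the three classes")
    rng = np.random.default_rng(seed)
    base = base or build_default_parameters()
    records: list[ClinicalRecord] = []
    for ip in range(n_patients):
        pid = f"P{ip + 1:03d}"
        for ig in range(grafts_per_patient):
            gid = f"{pid}-G{ig + 1}"
            cls = CLASS_ORDER[rng.choice(3, p=class_mix)]
            lo, hi = CLASS_RANGES[cls]
            for attempt in range(max_retries):
                patient = _sample_patient(rng, base)
                pct = float(rng.uniform(lo, hi))
                try:
                    res = simulate(patient.replace(stenosis_pct=pct), n_beats=n_beats)
                except (SimulationError, ValueError):
                    continue
                records.append(_record_from_simulation(
                    res, pid, gid, cls, pct, rng, flow_noise_sd, jitter_sd, skip_beats
                ))
                break
            else:
                raise RuntimeError(
                    f"simulation kept failing for {gid} after {max_retries} retries"
                )
    return records


# ---------------------------------------------------------------------------
# cohort analysis
# ---------------------------------------------------------------------------

def record_metrics(record: ClinicalRecord):
    """Patency metrics of one record, segmented by its ECG-like markers."""
    seg = segment_beats(record.r_peaks, record.systole_ends)
    return compute_all(record.t, record.flow / 60.0, seg, pressure=record.pressure)


def hemodynamic_parameters(record: ClinicalRecord, window_fraction: float = 0.25) -> dict[str, float]:
    """SAP/DAP/MAP/PP (estimated central, mmHg), cardiac period T and DTF."""
    T = float(np.median(np.diff(record.r_peaks)))
    sbp, dbp = estimate_central_pressure(record.t, record.pressure, T, window_fraction)
    map_ = float(np.trapezoid(record.pressure, record.t) / (record.t[-1] - record.t[0]))
    t_sys = np.array([
        e - s for s, e in zip(record.r_peaks[:-1], record.systole_ends)
    ])
    dtf = float(np.median(1.0 - t_sys / np.diff(record.r_peaks)))
    return {"SAP": sbp, "DAP": dbp, "MAP": map_, "PP": sbp - dbp, "T": T, "DTF": dtf}


@dataclass
class CohortSummary:
    """Per-class metric summaries and cohort-level variability/tests."""

    class_table: pd.DataFrame          # rows: (class, metric); median, iqr bounds, n
    variability: dict[str, float]      # MAD/median per hemodynamic parameter
    trends: dict[str, str]             # metric -> "decreasing"|"increasing"|"non-monotone"
    tests: list[GroupTestReport] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        import json

        payload = {
            "class_table": self.class_table.reset_index().to_dict(orient="records"),
            "variability": self.variability,
            "trends": self.trends,
            "tests": [t.__dict__ for t in self.tests],
            "notes": self.notes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def summarize_by_class(
    records: list[ClinicalRecord],
    metrics_table: pd.DataFrame | None = None,
) -> CohortSummary:
    """Median/IQR per patency class, variability measures and trend directions.

    ``metrics_table`` (one row per record, metric columns plus a
    ``patency_class`` column) is computed from the records when not given.
    Between-class rank-sum tests compare adjacent severity classes; they are
    skipped with a notice when only one class is present.
    """
    if metrics_table is None:
        rows = []
        for rec in records:
            m = record_metrics(rec).median
            m["patency_class"] = rec.patency_class
            rows.append(m)
        metrics_table = pd.DataFrame(rows)
    counts = metrics_table["patency_class"].value_counts()
    present = [c for c in CLASS_ORDER if c in counts.index]
    if any(counts[c] < 2 for c in present):
        raise ValueError("each represented class needs at least 2 records")

    metric_cols = [c for c in metrics_table.columns if c != "patency_class"]
    rows = []
    for cls in present:
        sub = metrics_table[metrics_table["patency_class"] == cls]
        for mcol in metric_cols:
            q1, med, q3 = np.percentile(sub[mcol].dropna(), [25, 50, 75])
            rows.append({"patency_class": cls, "metric": mcol,
                         "median": med, "iqr_low": q1, "iqr_high": q3, "n": len(sub)})
    class_table = pd.DataFrame(rows).set_index(["patency_class", "metric"])

    trends = {}
    for mcol in metric_cols:
        meds = [class_table.loc[(c, mcol), "median"] for c in present]
        if len(meds) < 2:
            trends[mcol] = "single-class"
        elif all(x > y for x, y in zip(meds, meds[1:])):
            trends[mcol] = "decreasing"
        elif all(x < y for x, y in zip(meds, meds[1:])):
            trends[mcol] = "increasing"
        else:
            trends[mcol] = "non-monotone"

    variability = {}
    hemo = pd.DataFrame([hemodynamic_parameters(r) for r in records])
    for col in hemo.columns:
        variability[col] = mad_over_median(hemo[col])

    tests: list[GroupTestReport] = []
    notes: list[str] = []
    if len(present) < 2:
        notes.append("single-class cohort: between-class tests skipped")
    else:
        for ca, cb in zip(present, present[1:]):
            for mcol in metric_cols:
                a = metrics_table.loc[metrics_table["patency_class"] == ca, mcol].dropna()
                b = metrics_table.loc[metrics_table["patency_class"] == cb, mcol].dropna()
                tests.append(compare_groups(a, b, paired=False, method="normal"))
                notes.append(f"rank-sum {ca} vs {cb} on {mcol}")
    return CohortSummary(class_table=class_table, variability=variability,
                         trends=trends, tests=tests, notes=notes)


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------

def write_cohort(records: list[ClinicalRecord], outdir: str | Path) -> Path:
    """One waveform CSV and one marker CSV per record, plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        stem = rec.graft_id
        pd.DataFrame({
            "time_s": rec.t, "flow_mlmin": rec.flow, "pressure_mmhg": rec.pressure,
        }).to_csv(outdir / f"{stem}_waveform.csv", index=False)
        nmax = len(rec.r_peaks)
        pd.DataFrame({
            "r_peak_s": rec.r_peaks,
            "systole_end_s": np.concatenate([rec.systole_ends, [np.nan] * (nmax - len(rec.systole_ends))]),
        }).to_csv(outdir / f"{stem}_markers.csv", index=False)
        manifest.append({
            "patient_id": rec.patient_id, "graft_id": rec.graft_id,
            "patency_class": rec.patency_class, "true_pct": rec.true_pct,
        })
    path = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(path, index=False)
    return path


def read_cohort(outdir: str | Path) -> list[ClinicalRecord]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        stem = row["graft_id"]
        wf = pd.read_csv(outdir / f"{stem}_waveform.csv")
        mk = pd.read_csv(outdir / f"{stem}_markers.csv")
        records.append(ClinicalRecord(
            patient_id=row["patient_id"], graft_id=stem,
            t=wf["time_s"].to_numpy(), flow=wf["flow_mlmin"].to_numpy(),
            pressure=wf["pressure_mmhg"].to_numpy(),
            r_peaks=mk["r_peak_s"].to_numpy(),
            systole_ends=mk["systole_end_s"].dropna().to_numpy(),
            patency_class=row["patency_class"], true_pct=float(row["true_pct"]),
        ))
    return records
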