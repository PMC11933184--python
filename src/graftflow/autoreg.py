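"""Autoregulation emulation: iterative intramyocardial resistance tuning.

A healthy coronary microcirculation dilates to hold myocardial perfusion and
its transmural distribution constant in the face of an upstream stenosis.
Here that behaviour is emulated statically: two multiplicative knobs on the
bed's reference resistances — an overall scale and a subendo/subepi tilt —
are adjusted by a damped fixed-point iteration until the beat-median graft
flow and the endo–epi flow ratio return to their un-stenosed reference
values.  For stenoses within the dilation reserve the overall scale settles
below one (vasodilation), decreasing with severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import metrics_from_simulation
from .model import SimulationError, SimulationResult, endo_epi_flow_ratio, simulate
from .parameters import ModelParameters

__all__ = ["AutoregTarget", "AutoregResult", "reference_state", "tune_autoregulation"]


@dataclass(frozen=True)
class AutoregTarget:
    """Un-stenosed reference values the tuning tries to restore."""

    q_mean: float                 # mL/min, beat-median graft flow
    endo_epi: float               # beat-mean subendo/subepi flow ratio
    rel_tol: float = 0.01
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if not (np.isfinite(self.q_mean) and self.q_mean > 0):
            raise ValueError("reference q_mean must be finite and positive")
        if not (np.isfinite(self.endo_epi) and self.endo_epi > 0):
            raise ValueError("reference endo-epi ratio must be finite and positive")


@dataclass
class AutoregResult:
    scale_overall: float          # multiplies all layer reference resistances
    scale_endo_epi: float         # tilts subendo vs subepi reference resistance
    result: SimulationResult
    iterations: int
    history: list[dict] = field(repr=False, default_factory=list)
    converged: bool = True


def _with_knobs(params: ModelParameters, s_all: float, s_tilt: float) -> ModelParameters:
    """Apply the two resistance knobs through the endo-epi weighting.

    The overall knob scales R0_1, R0_m, R0_2 together; the tilt knob divides
    the reference endo/epi volume ratio (smaller tilt -> relatively larger
    subendocardial volumes -> lower subendocardial resistance).
    """
    return params.replace(
        R0_1=params.R0_1 * s_all,
        R0_m=params.R0_m * s_all,
        R0_2=params.R0_2 * s_all,
        endo_epi_ratio=params.endo_epi_ratio / s_tilt,
    )


def _measure(params: ModelParameters, n_beats: int) -> tuple[float, float, SimulationResult]:
    res = simulate(params, n_beats=n_beats)
    q = metrics_from_simulation(res).median["q_mean"]
    ratio = endo_epi_flow_ratio(res)
    return q, ratio, res


def reference_state(
    params: ModelParameters, n_beats: int = 10, rel_tol: float = 0.01, max_iter: int = 50
) -> AutoregTarget:
    """Reference targets from the un-stenosed run (stenosis forced to 0 %)."""
    q, ratio, res = _measure(params.replace(stenosis_pct=0.0), n_beats)
    if not res.converged:
        raise RuntimeError("reference run did not reach a periodic steady state")
    return AutoregTarget(q_mean=q, endo_epi=ratio, rel_tol=rel_tol, max_iter=max_iter)


def tune_autoregulation(
    params: ModelParameters,
    pct_s: float,
    target: AutoregTarget | None = None,
    n_beats: int = 10,
    damping: float = 0.5,
) -> AutoregResult:
    """Restore reference flow and transmural balance at a given severity.

    Multiplicative updates with exponent ``damping``: flow scales roughly
    inversely with bed resistance, so s_all ← s_all·(Q/Q_ref)^damping; the
    endo-epi tilt is corrected analogously.  Raises on non-convergence
    within ``target.max_iter`` iterations — expected once the severity
    exhausts the emulated dilation reserve.
    """
    if not (0.0 <= pct_s <= 90.0):
        raise ValueError("pct_s must lie in [0, 90] %")
    if target is None:
        target = reference_state(params, n_beats=n_beats)
    p = params.replace(stenosis_pct=float(pct_s))

    s_all, s_tilt = 1.0, 1.0
    history: list[dict] = []
    for it in range(1, target.max_iter + 1):
        try:
            q, ratio, res = _measure(_with_knobs(p, s_all, s_tilt), n_beats)
        except SimulationError as exc:
            raise RuntimeError(
                f"autoregulation tuning did not converge at pct_s = {pct_s} %: "
                f"the model diverged at knob settings s_all={s_all:.4g}, "
                f"s_tilt={s_tilt:.4g} ({exc}); trajectory: "
                + ", ".join(f"(q={h['q_mean']:.1f}, s={h['s_all']:.3f})" for h in history[-5:])
            ) from exc
        err_q = (q - target.q_mean) / target.q_mean
        err_r = (ratio - target.endo_epi) / target.endo_epi
        history.append(
            {"iter": it, "s_all": s_all, "s_tilt": s_tilt, "q_mean": q,
             "endo_epi": ratio, "err_q": err_q, "err_ratio": err_r}
        )
        if abs(err_q) <= target.rel_tol and abs(err_r) <= target.rel_tol:
            return AutoregResult(s_all, s_tilt, res, it, history)
        s_all *= (q / target.q_mean) ** damping
        s_tilt *= (ratio / target.endo_epi) ** damping
        s_all = float(np.clip(s_all, 1e-3, 10.0))
        s_tilt = float(np.clip(s_tilt, 0.1, 10.0))
    raise RuntimeError(
        f"autoregulation tuning did not converge in {target.max_iter} iterations "
        f"at pct_s = {pct_s} % (dilation reserve exceeded); trajectory: "
        + ", ".join(f"(q={h['q_mean']:.1f}, s={h['s_all']:.3f})" for h in history[-5:])
    )
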