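"""Closed-loop 0D cardiovascular circulation with a grafted coronary bed.

The network is a lumped-parameter closed loop: two time-varying-elastance
ventricles with pressure-gated valves, passive atria, systemic and pulmonary
arterial compartments (compliance + characteristic resistance + inertance),
microvascular bed resistances and venous compartments.  A bypass-graft branch
(resistance + inertance + optional stenosis element) leaves the systemic
arterial node and perfuses a three-layer intramyocardial bed whose layer
resistances depend on instantaneous vascular volume, R = R0·(V0/V)², and whose
compliant compartments feel an external intramyocardial pressure rising
linearly with wall depth, p_im = depth·p_lv.  During systole the deep
(subendocardial) layer is squeezed, which produces the diastolic-dominant
graft flow waveform characteristic of coronary perfusion.

State vector (17 entries): chamber volumes V_lv, V_rv, V_la, V_ra; vascular
compartment volumes V_sa, V_sv, V_pa, V_pv; inertial flows Q_sa, Q_pa, Q_g;
per-layer intramyocardial arterial and venous volumes V1_j, V2_j (j = epi,
mid, endo).  Integration is fixed-step classical Runge–Kutta, compiled with
numba; a simulation of 10 beats at the default step runs in well under a
second after JIT warm-up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .parameters import ModelParameters
from .stenosis import drop_coefficients, geometry_from_pct

__all__ = [
    "SimulationResult",
    "SimulationError",
    "elastance_waveform",
    "diastole_duration",
    "layer_resistance",
    "intramyocardial_pressure",
    "state_derivative",
    "initial_state",
    "simulate",
    "endo_epi_flow_ratio",
    "STATE_NAMES",
]

STATE_NAMES = (
    "V_lv", "V_rv", "V_la", "V_ra",
    "V_sa", "V_sv", "V_pa", "V_pv",
    "Q_sa", "Q_pa", "Q_g",
    "V1_epi", "V1_mid", "V1_endo",
    "V2_epi", "V2_mid", "V2_endo",
    "Q_av", "V_g",
)
_NY = len(STATE_NAMES)


class SimulationError(RuntimeError):
    """Raised when integration diverges (non-finite state)."""


# ---------------------------------------------------------------------------
# elementary constitutive laws
# ---------------------------------------------------------------------------

def diastole_duration(T: float, slope: float = 0.8, intercept: float = -0.17) -> float:
    """Diastole duration T_dia for a cardiac period T via an affine relation.

    T_dia = slope·T + intercept.  The default coefficients make the diastolic
    time fraction increase with T (slower heart rates spend proportionally
    more time in diastole), which is the physiologically observed behaviour.
    """
    if not (0.4 <= T <= 1.5):
        raise ValueError(f"cardiac period T={T} outside supported range [0.4, 1.5] s")
    t_dia = slope * T + intercept
    if not (0.0 < t_dia < T):
        raise ValueError(
            f"diastole-duration coefficients give T_dia={t_dia:.4f} outside (0, T={T})"
        )
    return t_dia


def elastance_waveform(
    t: float | np.ndarray,
    T: float,
    E_max: float,
    E_min: float,
    dia_slope: float = 0.8,
    dia_intercept: float = -0.17,
) -> float | np.ndarray:
    """Time-varying chamber elastance, periodic in T, peak exactly E_max.

    Activation is a raised-cosine confined to systole (duration T − T_dia),
    so the waveform and its first derivative are continuous, the peak value
    is E_max irrespective of T, and the value during diastole is E_min.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if E_max <= E_min:
        raise ValueError("E_max must exceed E_min")
    t_sys = T - diastole_duration(T, dia_slope, dia_intercept)
    phi = np.mod(t, T)
    act = _activation_np(phi, t_sys)
    out = E_min + (E_max - E_min) * act
    return float(out) if np.isscalar(t) else out


#: default fraction of systole at which activation peaks; late peak keeps the
#: ventricle ejecting through most of systole
ACT_PEAK_FRACTION = 0.65


def _activation_np(phi: np.ndarray, t_sys: float, peak_frac: float = ACT_PEAK_FRACTION) -> np.ndarray:
    """Vectorized twin of the kernel's activation function."""
    t_p = peak_frac * t_sys
    rise = 0.5 * (1.0 - np.cos(np.pi * phi / t_p))
    fall = 0.5 * (1.0 + np.cos(np.pi * (phi - t_p) / (t_sys - t_p)))
    return np.where(phi < t_p, rise, np.where(phi < t_sys, fall, 0.0))


def layer_resistance(V: float, R0: float, V0: float) -> float:
    """Volume-dependent layer resistance R = R0·(V0/V)²."""
    if V <= 0:
        raise ValueError("vascular volume must be positive (collapsed vessel outside model validity)")
    if V0 <= 0 or R0 < 0:
        raise ValueError("V0 must be positive and R0 non-negative")
    return R0 * (V0 / V) ** 2


def intramyocardial_pressure(p_lv: float, depth_fraction: float) -> float:
    """External tissue pressure on a layer: rises linearly with wall depth."""
    if not (0.0 <= depth_fraction <= 1.0):
        raise ValueError("depth_fraction must lie in [0, 1]")
    return depth_fraction * p_lv


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

# Index map for the packed parameter vector consumed by the numba kernel.
_IP = {name: i for i, name in enumerate((
    "T", "Tsys",
    "E_max_lv", "E_min_lv", "E_max_rv", "E_min_rv",
    "R_mv", "R_av", "R_tv", "R_pav",
    "C_sa", "R_sa", "L_sa", "R0_SVB", "C_sv", "R_sv",
    "C_pa", "R_pa", "L_pa", "R_PVB", "C_pv", "R_pvv",
    "C_la", "C_ra",
    "R_graft", "L_graft",
    "sten_a", "sten_b", "sten_c",
    "V0_lv", "V0_rv", "V0_la", "V0_ra",
    "Vun_sa", "Vun_sv", "Vun_pa", "Vun_pv",
    "valve_w", "act_peak", "L_av", "C_graft", "Vun_g", "L_sten",
))}
_NP_SCALAR = len(_IP)
# per-layer blocks appended after the scalars: C1_j, V01_j, C2_j, V02_j,
# R01_j, R0m_j, R02_j, depth_j  (3 entries each)
_OFF_C1 = _NP_SCALAR
_OFF_V01 = _OFF_C1 + 3
_OFF_C2 = _OFF_V01 + 3
_OFF_V02 = _OFF_C2 + 3
_OFF_R01 = _OFF_V02 + 3
_OFF_R0M = _OFF_R01 + 3
_OFF_R02 = _OFF_R0M + 3
_OFF_DEPTH = _OFF_R02 + 3
_NPV = _OFF_DEPTH + 3


def layer_weights(endo_epi_ratio: float) -> np.ndarray:
    """Reference-volume shares of the (epi, mid, endo) layers.

    The subendocardial share is ``ratio`` times the subepicardial one, the
    mid-wall share is their average, and the three sum to one so that the
    total reference volume is conserved when the ratio changes.
    """
    r = endo_epi_ratio
    w = np.array([1.0, 0.5 * (1.0 + r), r])
    return w / w.sum()


def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten a ModelParameters into the kernel's parameter vector."""
    pv = np.zeros(_NPV)
    t_dia = diastole_duration(params.T, params.dia_slope, params.dia_intercept)
    pv[_IP["T"]] = params.T
    pv[_IP["Tsys"]] = params.T - t_dia
    for name in (
        "E_max_lv", "E_min_lv", "E_max_rv", "E_min_rv",
        "R_mv", "R_av", "R_tv", "R_pav",
        "C_sa", "R_sa", "L_sa", "R0_SVB", "C_sv", "R_sv",
        "C_pa", "R_pa", "L_pa", "R_PVB", "C_pv", "R_pvv",
        "C_la", "C_ra", "R_graft", "L_graft",
        "V0_lv", "V0_rv", "V0_la", "V0_ra",
        "Vun_sa", "Vun_sv", "Vun_pa", "Vun_pv",
    ):
        pv[_IP[name]] = getattr(params, name)
    pv[_IP["valve_w"]] = params.valve_smoothing
    pv[_IP["act_peak"]] = params.act_peak_fraction
    pv[_IP["L_av"]] = params.L_av
    pv[_IP["C_graft"]] = params.C_graft
    pv[_IP["Vun_g"]] = params.Vun_g
    pv[_IP["L_sten"]] = params.L_sten

    if params.stenosis_enabled:
        geom = geometry_from_pct(
            params.stenosis_pct, params.stenosis_D0, params.stenosis_l_s,
            D_s=params.stenosis_Ds, K_t=params.stenosis_Kt, K_u=params.stenosis_Ku,
        )
        a, b, c = drop_coefficients(geom, params.mu, params.rho)
    else:
        a = b = c = 0.0
    pv[_IP["sten_a"]] = a
    pv[_IP["sten_b"]] = b
    pv[_IP["sten_c"]] = c

    w = layer_weights(params.endo_epi_ratio)
    pv[_OFF_C1:_OFF_C1 + 3] = params.C1 * w
    pv[_OFF_V01:_OFF_V01 + 3] = params.V0_1 * w
    pv[_OFF_C2:_OFF_C2 + 3] = params.C2 * w
    pv[_OFF_V02:_OFF_V02 + 3] = params.venous_v0_factor * params.V0_1 * w
    # series resistance of a layer scales inversely with its volume share
    pv[_OFF_R01:_OFF_R01 + 3] = params.R0_1 / (3.0 * w)
    pv[_OFF_R0M:_OFF_R0M + 3] = params.R0_m / (3.0 * w)
    pv[_OFF_R02:_OFF_R02 + 3] = params.R0_2 / (3.0 * w)
    pv[_OFF_DEPTH:_OFF_DEPTH + 3] = np.asarray(params.depth_fractions)
    return pv


# ---------------------------------------------------------------------------
# compiled right-hand side and integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _vflow(dp: float, R: float, w: float) -> float:
    """Pressure-gated valve flow: exact diode for dp<=0, C1-smoothed near 0."""
    if dp <= 0.0:
        return 0.0
    if dp < w:
        return dp * dp / (2.0 * w * R)
    return (dp - 0.5 * w) / R


@njit(cache=True)
def _activation(phi: float, t_sys: float, peak_frac: float) -> float:
    t_p = peak_frac * t_sys
    if phi < t_p:
        return 0.5 * (1.0 - math.cos(math.pi * phi / t_p))
    if phi < t_sys:
        return 0.5 * (1.0 + math.cos(math.pi * (phi - t_p) / (t_sys - t_p)))
    return 0.0


@njit(cache=True)
def _rhs(t: float, y: np.ndarray, pv: np.ndarray, dy: np.ndarray) -> None:
    T = pv[0]
    t_sys = pv[1]
    phi = t % T
    act = _activation(phi, t_sys, pv[38])
    E_lv = pv[3] + (pv[2] - pv[3]) * act
    E_rv = pv[5] + (pv[4] - pv[5]) * act

    p_lv = E_lv * (y[0] - pv[29])
    p_rv = E_rv * (y[1] - pv[30])
    p_la = (y[2] - pv[31]) / pv[22]
    p_ra = (y[3] - pv[32]) / pv[23]
    p_sa = (y[4] - pv[33]) / pv[10]
    p_sv = (y[5] - pv[34]) / pv[14]
    p_pa = (y[6] - pv[35]) / pv[16]
    p_pv = (y[7] - pv[36]) / pv[20]

    w = pv[37]
    q_mv = _vflow(p_la - p_lv, pv[6], w)
    q_tv = _vflow(p_ra - p_rv, pv[8], w)
    q_pav = _vflow(p_rv - p_pa, pv[9], w)

    # aortic valve: diode in series with resistance and root inertance.
    # y[17] is the branch flow; only its positive part carries volume.
    # characteristic (proximal aortic) resistance R_sa sits in this branch,
    # between the valve and the arterial compliance node.
    dp_av = p_lv - p_sa
    q_av = y[17] if y[17] > 0.0 else 0.0
    if y[17] > 0.0 or dp_av > 0.0:
        dq_av = (dp_av - (pv[7] + pv[11]) * q_av) / pv[39]
    else:
        dq_av = -y[17] / 0.001  # pull residual negative flow back to zero

    q_sa = y[8]
    q_pa = y[9]
    q_g = y[10]
    p_g = (y[18] - pv[41]) / pv[40]
    q_sv = (p_sv - p_ra) / pv[15]
    q_pvv = (p_pv - p_la) / pv[21]

    # intramyocardial layers
    sum_inv_r1 = 0.0
    sum_p_over_r1 = 0.0
    p1 = np.empty(3)
    p2 = np.empty(3)
    r1 = np.empty(3)
    for j in range(3):
        c1 = pv[_OFF_C1 + j]
        v01 = pv[_OFF_V01 + j]
        c2 = pv[_OFF_C2 + j]
        v02 = pv[_OFF_V02 + j]
        v1 = y[11 + j]
        v2 = y[14 + j]
        p_im = pv[_OFF_DEPTH + j] * p_lv
        p1[j] = (v1 - v01) / c1 + p_im
        p2[j] = (v2 - v02) / c2 + p_im
        r1[j] = pv[_OFF_R01 + j] * (v01 / v1) ** 2
        sum_inv_r1 += 1.0 / r1[j]
        sum_p_over_r1 += p1[j] / r1[j]
    # stenosis branch treated quasi-statically (its inertial time constant is
    # far below the step): solve a_eff*q + b*q|q| = p_g - p_bed in closed form
    r_bed = 1.0 / sum_inv_r1
    p_bed = sum_p_over_r1 * r_bed
    a_eff = pv[26] + r_bed
    b_t = pv[27]
    dp_s = p_g - p_bed
    if b_t > 0.0:
        q_s = math.copysign(
            (-a_eff + math.sqrt(a_eff * a_eff + 4.0 * b_t * abs(dp_s))) / (2.0 * b_t),
            dp_s,
        )
    else:
        q_s = dp_s / a_eff
    p_gd = p_bed + r_bed * q_s

    q2_total = 0.0
    for j in range(3):
        v01 = pv[_OFF_V01 + j]
        v02 = pv[_OFF_V02 + j]
        v1 = y[11 + j]
        v2 = y[14 + j]
        rm = pv[_OFF_R0M + j] * ((v01 + v02) / (v1 + v2)) ** 2
        r2 = pv[_OFF_R02 + j] * (v02 / v2) ** 2
        q1 = (p_gd - p1[j]) / r1[j]
        qm = (p1[j] - p2[j]) / rm
        q2 = (p2[j] - p_ra) / r2
        dy[11 + j] = q1 - qm
        dy[14 + j] = qm - q2
        q2_total += q2

    dy[0] = q_mv - q_av
    dy[1] = q_tv - q_pav
    dy[2] = q_pvv - q_mv
    dy[3] = q_sv + q2_total - q_tv
    dy[4] = q_av - q_sa - q_g
    dy[5] = q_sa - q_sv
    dy[6] = q_pav - q_pa
    dy[7] = q_pa - q_pvv
    dy[8] = (p_sa - p_sv - pv[13] * q_sa) / pv[12]
    dy[9] = (p_pa - p_pv - (pv[17] + pv[19]) * q_pa) / pv[18]
    # graft conduit: aorta -> R_graft/L_graft -> compliant graft node
    dy[10] = (p_sa - p_g - pv[24] * q_g) / pv[25]
    dy[18] = q_g - q_s
    dy[17] = dq_av


@njit(cache=True)
def _integrate(
    y0: np.ndarray, pv: np.ndarray, dt: float, n_steps: int, save_every: int
) -> tuple[np.ndarray, bool]:
    n_save = n_steps // save_every + 1
    out = np.empty((n_save, y0.shape[0]))
    y = y0.copy()
    k1 = np.empty_like(y)
    k2 = np.empty_like(y)
    k3 = np.empty_like(y)
    k4 = np.empty_like(y)
    tmp = np.empty_like(y)
    out[0] = y
    isave = 1
    ok = True
    for i in range(n_steps):
        t = i * dt
        _rhs(t, y, pv, k1)
        for m in range(y.shape[0]):
            tmp[m] = y[m] + 0.5 * dt * k1[m]
        _rhs(t + 0.5 * dt, tmp, pv, k2)
        for m in range(y.shape[0]):
            tmp[m] = y[m] + 0.5 * dt * k2[m]
        _rhs(t + 0.5 * dt, tmp, pv, k3)
        for m in range(y.shape[0]):
            tmp[m] = y[m] + dt * k3[m]
        _rhs(t + dt, tmp, pv, k4)
        for m in range(y.shape[0]):
            y[m] += dt / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
        if not math.isfinite(y[4]):
            ok = False
            break
        # collapsed intramyocardial vessels are outside model validity
        for m in range(11, 17):
            if y[m] <= 0.0:
                ok = False
                break
        if not ok:
            break
        if (i + 1) % save_every == 0:
            out[isave] = y
            isave += 1
    if not ok:
        return out[:isave], False
    return out, True


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Beat-resolved output of one closed-loop run."""

    t: np.ndarray
    signals: dict[str, np.ndarray]
    events: dict[str, np.ndarray]
    n_beats: int
    dt: float
    converged: bool
    periodicity_residuals: np.ndarray  # one per adjacent beat pair
    volume_drift: float                # relative drift of total blood volume
    params: ModelParameters = field(repr=False)

    @property
    def periodicity_residual(self) -> float:
        return float(self.periodicity_residuals[-1])

    def to_csv(self, path) -> None:
        """Waveforms as CSV: time_s column then one column per named signal."""
        import pandas as pd

        cols = {"time_s": self.t}
        for name in sorted(self.signals):
            cols[name] = self.signals[name]
        pd.DataFrame(cols).to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "parameters_hash": self.params.content_hash(),
            "dt": self.dt,
            "n_beats": self.n_beats,
            "converged": bool(self.converged),
            "periodicity_residual": self.periodicity_residual,
            "volume_drift": self.volume_drift,
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def initial_state(params: ModelParameters) -> np.ndarray:
    """Starting state at a beat boundary, near the default operating point.

    Pressures are mapped to volumes through each run's own compliances, so the
    start point stays close to the limit cycle under moderate parameter
    changes and the run settles within a few beats.
    """
    y = np.zeros(_NY)
    y[0] = params.V0_lv + 88.0           # end-diastolic LV filling volume
    y[1] = params.V0_rv + 94.0
    y[2] = params.V0_la + params.C_la * 5.5
    y[3] = params.V0_ra + params.C_ra * 4.1
    y[4] = params.Vun_sa + params.C_sa * 90.0
    y[5] = params.Vun_sv + params.C_sv * 8.1
    y[6] = params.Vun_pa + params.C_pa * 11.8
    y[7] = params.Vun_pv + params.C_pv * 6.7
    y[8] = 68.0
    y[9] = 47.0
    y[10] = 1.0
    w = layer_weights(params.endo_epi_ratio)
    p1 = np.array([60.0, 57.0, 55.0])
    p2 = np.array([18.0, 14.0, 10.0])
    y[11:14] = params.V0_1 * w + params.C1 * w * p1
    y[14:17] = params.venous_v0_factor * params.V0_1 * w + params.C2 * w * p2
    y[17] = 0.0
    y[18] = params.Vun_g + params.C_graft * 81.5
    return y


def state_derivative(state: np.ndarray, t: float, params: ModelParameters) -> np.ndarray:
    """Time derivative of the full state at time t (network right-hand side)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (_NY,):
        raise ValueError(f"state must have {_NY} entries")
    pv = pack_parameters(params)
    dy = np.empty(_NY)
    _rhs(float(t), y, pv, dy)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.nonzero(~np.isfinite(dy))[0]]
        raise SimulationError(f"non-finite rate for state component(s): {', '.join(bad)}")
    return dy


def _derived_signals(t: np.ndarray, Y: np.ndarray, params: ModelParameters, pv: np.ndarray) -> dict[str, np.ndarray]:
    T, t_sys = pv[0], pv[1]
    phi = np.mod(t, T)
    act = _activation_np(phi, t_sys, pv[_IP["act_peak"]])
    E_lv = params.E_min_lv + (params.E_max_lv - params.E_min_lv) * act
    E_rv = params.E_min_rv + (params.E_max_rv - params.E_min_rv) * act
    p_lv = E_lv * (Y[:, 0] - params.V0_lv)
    p_rv = E_rv * (Y[:, 1] - params.V0_rv)
    p_sa = (Y[:, 4] - params.Vun_sa) / params.C_sa
    p_la = (Y[:, 2] - params.V0_la) / params.C_la
    p_ra = (Y[:, 3] - params.V0_ra) / params.C_ra

    w = layer_weights(params.endo_epi_ratio)
    c1 = params.C1 * w
    v01 = params.V0_1 * w
    r01 = params.R0_1 / (3.0 * w)
    depths = np.asarray(params.depth_fractions)
    q_g = Y[:, 10]
    p_g = (Y[:, 18] - params.Vun_g) / params.C_graft
    p1 = np.empty((len(t), 3))
    r1 = np.empty((len(t), 3))
    for j in range(3):
        v1 = Y[:, 11 + j]
        p1[:, j] = (v1 - v01[j]) / c1[j] + depths[j] * p_lv
        r1[:, j] = r01[j] * (v01[j] / v1) ** 2
    r_bed = 1.0 / (1.0 / r1).sum(axis=1)
    p_bed = (p1 / r1).sum(axis=1) * r_bed
    pvv = pack_parameters(params)
    a_eff = pvv[_IP["sten_a"]] + r_bed
    b_t = pvv[_IP["sten_b"]]
    dp_s = p_g - p_bed
    if b_t > 0:
        q_s = np.copysign(
            (-a_eff + np.sqrt(a_eff**2 + 4.0 * b_t * np.abs(dp_s))) / (2.0 * b_t), dp_s
        )
    else:
        q_s = dp_s / a_eff
    p_gd = p_bed + r_bed * q_s
    q_layers = (p_gd[:, None] - p1) / r1

    q_av = np.maximum(Y[:, 17], 0.0)
    return {
        "aortic_pressure": p_sa,
        "graft_flow": q_g,
        "graft_pressure": p_g,
        "stenosis_flow": q_s,
        "bed_pressure": p_gd,
        "q_epi": q_layers[:, 0],
        "q_mid": q_layers[:, 1],
        "q_endo": q_layers[:, 2],
        "p_lv": p_lv,
        "p_rv": p_rv,
        "p_la": p_la,
        "p_ra": p_ra,
        "V_lv": Y[:, 0].copy(),
        "V_rv": Y[:, 1].copy(),
        "q_av": q_av,
    }


def _crossing_times(t: np.ndarray, x: np.ndarray, rising: bool) -> np.ndarray:
    """Linear-interpolated zero crossings of x(t) in the requested direction."""
    s = np.sign(x)
    if rising:
        idx = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0]
    else:
        idx = np.nonzero((s[:-1] > 0) & (s[1:] <= 0))[0]
    if len(idx) == 0:
        return np.empty(0)
    x0, x1 = x[idx], x[idx + 1]
    frac = np.where(x1 != x0, x0 / (x0 - x1), 0.0)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def simulate(
    params: ModelParameters,
    n_beats: int = 10,
    dt: float | None = None,
    convergence_tol: float = 1e-3,
) -> SimulationResult:
    """Integrate the closed loop for ``n_beats`` cardiac periods.

    The run is flagged converged when the relative L2 difference between the
    last two beats is below ``convergence_tol`` on both aortic pressure and
    graft flow.  Divergence (non-finite state) raises :class:`SimulationError`;
    mere non-convergence is flagged, not fatal.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    T = params.T
    if dt is None:
        dt = T / 2000.0
    if dt > T / 500.0:
        raise ValueError("dt must resolve the beat: dt <= T/500")
    steps_per_beat = int(round(T / dt))
    dt = T / steps_per_beat
    n_steps = steps_per_beat * n_beats

    pv = pack_parameters(params)
    y0 = initial_state(params)
    Y, ok = _integrate(y0, pv, dt, n_steps, 1)
    if not ok:
        raise SimulationError(
            "integration diverged (non-finite state); try a smaller dt or "
            "check parameter magnitudes"
        )
    t = np.arange(Y.shape[0]) * dt
    signals = _derived_signals(t, Y, params, pv)

    # beat-to-beat periodicity residuals on aortic pressure and graft flow
    residuals = np.empty(n_beats - 1)
    spb = steps_per_beat
    for k in range(n_beats - 1):
        r = 0.0
        for name in ("aortic_pressure", "graft_flow"):
            a = signals[name][k * spb:(k + 1) * spb]
            b = signals[name][(k + 1) * spb:(k + 2) * spb]
            denom = np.linalg.norm(b)
            r = max(r, np.linalg.norm(a - b) / denom if denom > 0 else np.inf)
        residuals[k] = r

    vol_idx = [0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14, 15, 16, 18]
    total0 = Y[0, vol_idx].sum()
    drift = float(np.abs(Y[:, vol_idx].sum(axis=1) - total0).max() / total0)

    q_av = signals["q_av"]
    events = {
        "aortic_valve_open": _crossing_times(t, q_av, rising=True),
        "aortic_valve_close": _crossing_times(t, q_av, rising=False),
    }
    return SimulationResult(
        t=t,
        signals=signals,
        events=events,
        n_beats=n_beats,
        dt=dt,
        converged=bool(residuals[-1] < convergence_tol),
        periodicity_residuals=residuals,
        volume_drift=drift,
        params=params,
    )


def endo_epi_flow_ratio(result: SimulationResult, n_last_beats: int = 1) -> float:
    """Ratio of beat-mean subendocardial to subepicardial layer inflow.

    Means are trapezoid integrals over the last ``n_last_beats`` beats divided
    by the interval length.
    """
    T = result.params.T
    t = result.t
    mask = t >= t[-1] - n_last_beats * T
    tt = t[mask]
    q_endo = np.trapezoid(result.signals["q_endo"][mask], tt) / (tt[-1] - tt[0])
    q_epi = np.trapezoid(result.signals["q_epi"][mask], tt) / (tt[-1] - tt[0])
    if q_epi == 0:
        raise ValueError("subepicardial mean flow is zero; ratio undefined")
    return float(q_endo / q_epi)
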