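"""Young–Tsai stenosis pressure-drop element.

The pressure loss over a discrete stenosis is the sum of a viscous
(Poiseuille-like) term, a turbulent expansion-loss term and an inertial term:

    Δp = 4·K_v·μ/(π·D0³) · Q
       + ρ·K_t/(2·A0²) · (A0/A_s − 1)² · Q·|Q|
       + ρ·K_u·l_s/A0 · dQ/dt

with the geometry-dependent viscous coefficient

    K_v = 32 · (0.83·l_s + 1.64·D_s)/D0 · (A0/A_s)².

K_t = 1.52 and K_u = 1.2 are shape-independent empirical constants.  The
turbulent term is written with Q·|Q| (an odd extension of Q²) so that
reversing the flow reverses the pressure drop; graft flow can transiently
reverse within a beat.

All geometry is in CGS (cm, cm²), viscosity in poise, density in g/mL and flow
in mL/s, so Δp comes out in dyn/cm² and is converted to mmHg at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMHG_PER_DYN_CM2",
    "StenosisGeometry",
    "geometry_from_pct",
    "kv_coefficient",
    "pressure_drop",
    "drop_coefficients",
    "linear_resistance_equivalent",
]

#: 1 mmHg in dyn/cm² (CODATA standard gravity and Hg density)
DYN_CM2_PER_MMHG = 1333.223874
MMHG_PER_DYN_CM2 = 1.0 / DYN_CM2_PER_MMHG


@dataclass(frozen=True)
class StenosisGeometry:
    """Geometry and empirical constants of one discrete stenosis."""

    pct_s: float          # percentage diameter reduction
    D0: float             # unstenosed diameter, cm
    l_s: float            # effective stenosis length, cm
    D_s: float            # vena-contracta diameter, cm
    K_t: float = 1.52
    K_u: float = 1.2

    @property
    def A0(self) -> float:
        return math.pi * (self.D0 / 2.0) ** 2

    @property
    def A_s(self) -> float:
        return self.A0 * (1.0 - self.pct_s / 100.0) ** 2


def geometry_from_pct(
    pct_s: float,
    D0: float,
    l_s: float,
    *,
    D_s: float | None = None,
    K_t: float = 1.52,
    K_u: float = 1.2,
) -> StenosisGeometry:
    """Build the stenosis geometry for a given percentage diameter reduction.

    The stenotic area follows A_s = A0·(1 − pct/100)²; the vena-contracta
    diameter defaults to D_s = D0·(1 − pct/100) when not given explicitly.
    Full occlusion (pct ≥ 100) is outside the validity of the pressure-drop
    relation and is rejected.
    """
    if not (0.0 <= pct_s < 100.0):
        raise ValueError(f"pct_s must lie in [0, 100), got {pct_s}")
    if D0 <= 0 or l_s <= 0:
        raise ValueError("D0 and l_s must be positive")
    if D_s is None:
        D_s = D0 * (1.0 - pct_s / 100.0)
    if D_s > D0:
        raise ValueError("vena-contracta diameter cannot exceed D0")
    return StenosisGeometry(pct_s=pct_s, D0=D0, l_s=l_s, D_s=D_s, K_t=K_t, K_u=K_u)


def kv_coefficient(geom: StenosisGeometry) -> float:
    """Geometry-dependent viscous coefficient K_v (dimensionless)."""
    area_ratio = geom.A0 / geom.A_s
    return 32.0 * (0.83 * geom.l_s + 1.64 * geom.D_s) / geom.D0 * area_ratio**2


def drop_coefficients(
    geom: StenosisGeometry, mu: float, rho: float
) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of Δp = a·Q + b·Q·|Q| + c·dQ/dt in mmHg/mL/s units.

    a: mmHg·s/mL (viscous), b: mmHg·s²/mL² (turbulent), c: mmHg·s²/mL (inertial).
    """
    kv = kv_coefficient(geom)
    a = 4.0 * kv * mu / (math.pi * geom.D0**3)
    b = rho * geom.K_t / (2.0 * geom.A0**2) * (geom.A0 / geom.A_s - 1.0) ** 2
    c = rho * geom.K_u * geom.l_s / geom.A0
    return (a * MMHG_PER_DYN_CM2, b * MMHG_PER_DYN_CM2, c * MMHG_PER_DYN_CM2)


def pressure_drop(
    Q_s: float, dQdt: float, geom: StenosisGeometry, mu: float, rho: float
) -> float:
    """Instantaneous stenosis pressure drop in mmHg.

    Odd in (Q_s, dQdt): Δp(−Q, −dQ/dt) = −Δp(Q, dQ/dt).
    """
    if not (math.isfinite(Q_s) and math.isfinite(dQdt)):
        raise ValueError("Q_s and dQdt must be finite")
    a, b, c = drop_coefficients(geom, mu, rho)
    return a * Q_s + b * Q_s * abs(Q_s) + c * dQdt


def linear_resistance_equivalent(geom: StenosisGeometry, mu: float) -> float:
    """Viscous-term resistance 4·K_v·μ/(π·D0³), converted to mmHg·s/mL.

    With K_t = K_u = 0 (or steady flow through an unstenosed element) the
    stenosis reduces exactly to this linear resistance.
    """
    return 4.0 * kv_coefficient(geom) * mu / (math.pi * geom.D0**3) * MMHG_PER_DYN_CM2
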