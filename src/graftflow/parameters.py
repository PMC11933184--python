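"""Parameter registry and validated model parameters for the 0D circulation.

The model works in clinical units throughout: pressure in mmHg, volume in mL,
time in s, so resistances are mmHg·s/mL, compliances mL/mmHg and inertances
mmHg·s²/mL.  Blood viscosity and density are kept in CGS (poise, g/mL) because
the stenosis element evaluates the Young–Tsai relation in CGS internally.

The registry lists the 39 tunable constants (38 physiological/geometric ones
plus the stenosis percentage) that drive the sensitivity and uncertainty
analyses.  A handful of structural constants (unstressed chamber volumes,
layer depth fractions, the venous-to-arterial reference-volume factor, valve
smoothing width, the stenosis shape constants K_t and K_u) are deliberately
outside the registry: they define the model's topology rather than its
physiology and are exposed as ordinary attributes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParamSpec",
    "REGISTRY",
    "REGISTRY_NAMES",
    "ModelParameters",
    "build_default_parameters",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter value violates a model invariant."""


@dataclass(frozen=True)
class ParamSpec:
    name: str
    default: float
    units: str
    description: str


#: The 39 registry entries (includes the stenosis percentage).
REGISTRY: tuple[ParamSpec, ...] = (
    ParamSpec("T", 0.8, "s", "cardiac period"),
    ParamSpec("E_max_lv", 3.0, "mmHg/mL", "maximum left-ventricular elastance"),
    ParamSpec("E_min_lv", 0.06, "mmHg/mL", "minimum left-ventricular elastance"),
    ParamSpec("E_max_rv", 0.7, "mmHg/mL", "maximum right-ventricular elastance"),
    ParamSpec("E_min_rv", 0.04, "mmHg/mL", "minimum right-ventricular elastance"),
    ParamSpec("dia_slope", 0.8, "-", "slope of the affine diastole-duration law T_dia = a·T + b"),
    ParamSpec("dia_intercept", -0.17, "s", "intercept of the diastole-duration law"),
    ParamSpec("R_mv", 0.005, "mmHg·s/mL", "mitral valve resistance"),
    ParamSpec("R_av", 0.008, "mmHg·s/mL", "aortic valve resistance"),
    ParamSpec("R_tv", 0.005, "mmHg·s/mL", "tricuspid valve resistance"),
    ParamSpec("R_pav", 0.008, "mmHg·s/mL", "pulmonary valve resistance"),
    ParamSpec("C_sa", 1.3, "mL/mmHg", "systemic arterial compliance"),
    ParamSpec("R_sa", 0.08, "mmHg·s/mL", "systemic arterial characteristic resistance"),
    ParamSpec("L_sa", 0.0008, "mmHg·s²/mL", "systemic arterial inertance"),
    ParamSpec("R0_SVB", 1.2, "mmHg·s/mL", "systemic vascular bed reference resistance"),
    ParamSpec("C_sv", 60.0, "mL/mmHg", "systemic venous compliance"),
    ParamSpec("R_sv", 0.05, "mmHg·s/mL", "systemic venous resistance"),
    ParamSpec("C_pa", 5.0, "mL/mmHg", "pulmonary arterial compliance"),
    ParamSpec("R_pa", 0.03, "mmHg·s/mL", "pulmonary arterial characteristic resistance"),
    ParamSpec("L_pa", 0.0008, "mmHg·s²/mL", "pulmonary arterial inertance"),
    ParamSpec("R_PVB", 0.08, "mmHg·s/mL", "pulmonary vascular bed resistance"),
    ParamSpec("C_pv", 16.0, "mL/mmHg", "pulmonary venous compliance"),
    ParamSpec("R_pvv", 0.02, "mmHg·s/mL", "pulmonary venous resistance"),
    ParamSpec("C_la", 12.0, "mL/mmHg", "left atrial (passive) compliance"),
    ParamSpec("C_ra", 15.0, "mL/mmHg", "right atrial (passive) compliance"),
    ParamSpec("R_graft", 10.0, "mmHg·s/mL", "lumped conduit resistance (graft plus recipient artery stump)"),
    ParamSpec("L_graft", 0.02, "mmHg·s²/mL", "lumped graft inertance"),
    ParamSpec("C1", 0.005, "mL/mmHg", "total intramyocardial arterial-side compliance"),
    ParamSpec("V0_1", 2.5, "mL", "total intramyocardial arterial-side reference volume"),
    ParamSpec("C2", 0.02, "mL/mmHg", "total intramyocardial venous-side compliance"),
    ParamSpec("R0_1", 90.0, "mmHg·s/mL", "per-layer arterial-side reference resistance (equal-split layer)"),
    ParamSpec("R0_m", 155.0, "mmHg·s/mL", "per-layer mid-compartment reference resistance"),
    ParamSpec("R0_2", 50.0, "mmHg·s/mL", "per-layer venous-side reference resistance"),
    ParamSpec("endo_epi_ratio", 1.2, "-", "subendocardial/subepicardial reference-volume ratio"),
    ParamSpec("mu", 0.035, "poise", "blood dynamic viscosity"),
    ParamSpec("rho", 1.06, "g/mL", "blood density"),
    ParamSpec("stenosis_l_s", 0.3, "cm", "effective stenosis length"),
    ParamSpec("stenosis_D0", 0.167, "cm", "unstenosed graft diameter at the stenosis (distal conduit)"),
    ParamSpec("stenosis_pct", 0.0, "%", "stenosis percentage (diameter reduction)"),
)

REGISTRY_NAMES: tuple[str, ...] = tuple(s.name for s in REGISTRY)
_DEFAULTS: dict[str, float] = {s.name: s.default for s in REGISTRY}

# Registry entries that may legitimately be negative or zero.
_SIGN_EXEMPT = {"dia_intercept", "stenosis_pct"}
# Entries that must be strictly positive.
_STRICT_POSITIVE = {
    "T", "E_max_lv", "E_min_lv", "E_max_rv", "E_min_rv",
    "C_sa", "C_sv", "C_pa", "C_pv", "C_la", "C_ra",
    "C1", "C2", "V0_1", "endo_epi_ratio", "mu", "rho",
    "stenosis_l_s", "stenosis_D0", "dia_slope",
}


@dataclass
class ModelParameters:
    """Complete, validated constant set for one simulation.

    All registry entries are direct attributes; structural constants follow.
    """

    # --- registry (39 entries) ---
    T: float = _DEFAULTS["T"]
    E_max_lv: float = _DEFAULTS["E_max_lv"]
    E_min_lv: float = _DEFAULTS["E_min_lv"]
    E_max_rv: float = _DEFAULTS["E_max_rv"]
    E_min_rv: float = _DEFAULTS["E_min_rv"]
    dia_slope: float = _DEFAULTS["dia_slope"]
    dia_intercept: float = _DEFAULTS["dia_intercept"]
    R_mv: float = _DEFAULTS["R_mv"]
    R_av: float = _DEFAULTS["R_av"]
    R_tv: float = _DEFAULTS["R_tv"]
    R_pav: float = _DEFAULTS["R_pav"]
    C_sa: float = _DEFAULTS["C_sa"]
    R_sa: float = _DEFAULTS["R_sa"]
    L_sa: float = _DEFAULTS["L_sa"]
    R0_SVB: float = _DEFAULTS["R0_SVB"]
    C_sv: float = _DEFAULTS["C_sv"]
    R_sv: float = _DEFAULTS["R_sv"]
    C_pa: float = _DEFAULTS["C_pa"]
    R_pa: float = _DEFAULTS["R_pa"]
    L_pa: float = _DEFAULTS["L_pa"]
    R_PVB: float = _DEFAULTS["R_PVB"]
    C_pv: float = _DEFAULTS["C_pv"]
    R_pvv: float = _DEFAULTS["R_pvv"]
    C_la: float = _DEFAULTS["C_la"]
    C_ra: float = _DEFAULTS["C_ra"]
    R_graft: float = _DEFAULTS["R_graft"]
    L_graft: float = _DEFAULTS["L_graft"]
    C1: float = _DEFAULTS["C1"]
    V0_1: float = _DEFAULTS["V0_1"]
    C2: float = _DEFAULTS["C2"]
    R0_1: float = _DEFAULTS["R0_1"]
    R0_m: float = _DEFAULTS["R0_m"]
    R0_2: float = _DEFAULTS["R0_2"]
    endo_epi_ratio: float = _DEFAULTS["endo_epi_ratio"]
    mu: float = _DEFAULTS["mu"]
    rho: float = _DEFAULTS["rho"]
    stenosis_l_s: float = _DEFAULTS["stenosis_l_s"]
    stenosis_D0: float = _DEFAULTS["stenosis_D0"]
    stenosis_pct: float = _DEFAULTS["stenosis_pct"]

    # --- structural constants (not screened) ---
    stenosis_enabled: bool = True
    stenosis_Kt: float = 1.52
    stenosis_Ku: float = 1.2
    #: vena-contracta diameter; None means D_s = D0·(1 − pct/100)
    stenosis_Ds: float | None = None
    #: mid-depth fractions of the three myocardial layers (epi, mid, endo)
    depth_fractions: tuple[float, float, float] = (1.0 / 6.0, 0.5, 5.0 / 6.0)
    #: venous-side reference volume as a multiple of the arterial-side one
    venous_v0_factor: float = 2.0
    #: unstressed chamber volumes (mL)
    V0_lv: float = 10.0
    V0_rv: float = 10.0
    V0_la: float = 5.0
    V0_ra: float = 5.0
    #: unstressed vascular compartment volumes (mL), bookkeeping only
    Vun_sa: float = 450.0
    Vun_sv: float = 2700.0
    Vun_pa: float = 90.0
    Vun_pv: float = 350.0
    #: pressure half-width over which valve opening is smoothed (mmHg)
    valve_smoothing: float = 0.1
    #: fraction of systole at which chamber activation peaks
    act_peak_fraction: float = 0.65
    #: aortic valve / root inertance (mmHg·s²/mL)
    L_av: float = 0.008
    #: graft conduit compliance (mL/mmHg) and its unstressed volume (mL)
    C_graft: float = 0.004
    Vun_g: float = 0.5
    #: structural inertance of the stenosis branch (mmHg·s²/mL)
    L_sten: float = 0.0005

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in REGISTRY_NAMES:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not _finite(v):
                raise ParameterError(f"parameter {name!r} is not a finite number: {v!r}")
            if name in _STRICT_POSITIVE and v <= 0:
                raise ParameterError(f"parameter {name!r} must be > 0, got {v}")
            if name not in _SIGN_EXEMPT and name not in _STRICT_POSITIVE and v < 0:
                raise ParameterError(f"parameter {name!r} must be >= 0, got {v}")
        if self.E_max_lv <= self.E_min_lv:
            raise ParameterError("E_max_lv must exceed E_min_lv")
        if self.E_max_rv <= self.E_min_rv:
            raise ParameterError("E_max_rv must exceed E_min_rv")
        if not (0.0 <= self.stenosis_pct < 100.0):
            raise ParameterError("stenosis_pct must lie in [0, 100)")
        d = self.depth_fractions
        if not (0.0 < d[0] < d[1] < d[2] < 1.0):
            raise ParameterError("depth fractions must be strictly increasing within (0, 1)")

    # -- convenience -----------------------------------------------------

    def registry_values(self) -> dict[str, float]:
        """The 39 screened parameters as an ordered mapping."""
        return {name: float(getattr(self, name)) for name in REGISTRY_NAMES}

    def replace(self, **overrides: float) -> "ModelParameters":
        """A copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_fractions"] = list(self.depth_fractions)
        return d

    def content_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def build_default_parameters(
    config: str | Path | Mapping[str, object] | None = None,
) -> ModelParameters:
    """Build a fully populated :class:`ModelParameters` from defaults plus overrides.

    ``config`` may be a mapping, a path to a YAML/JSON file with flat
    ``key: value`` entries, or ``None`` for pure defaults.  Unknown keys raise
    ``ParameterError`` naming them; invalid values raise ``ParameterError``
    naming the field.
    """
    overrides: dict[str, object] = {}
    if config is not None:
        if isinstance(config, (str, Path)):
            text = Path(config).read_text()
            loaded = yaml.safe_load(text) or {}
            if not isinstance(loaded, dict):
                raise ParameterError(f"config file {config} must contain a mapping")
            overrides = dict(loaded)
        else:
            overrides = dict(config)

    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = sorted(set(overrides) - valid)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {', '.join(unknown)}")
    if "depth_fractions" in overrides:
        overrides["depth_fractions"] = tuple(overrides["depth_fractions"])  # type: ignore[arg-type]
    return ModelParameters(**overrides)  # type: ignore[arg-type]
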