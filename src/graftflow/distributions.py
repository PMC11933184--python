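"""Parameter uncertainty distributions driving screening and UQ sampling.

Each screened parameter carries either a truncated-normal distribution
(truncated at mean ± 2·sd for screening; UQ uses ± 1.96·sd) or a uniform
one.  By default the stenosis percentage is uniform on [0, 75] % (severities
beyond 75 % diameter reduction are outside the studied range) and the
subendocardial/subepicardial volume ratio is uniform over the same span a
± 2·sd truncated normal would cover; every other registry entry is truncated
normal with sd equal to 25 % of its mean — the convention used when no
literature value is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import REGISTRY

__all__ = [
    "ParameterDistribution",
    "default_distributions",
    "write_registry_csv",
    "read_registry_csv",
]


@dataclass(frozen=True)
class ParameterDistribution:
    """One parameter's marginal uncertainty distribution.

    ``family`` is ``"truncnorm"`` or ``"uniform"``.  For a truncated normal
    the bounds are mean ± ``n_sd``·sd and sampling/ppf use the renormalized
    truncated density (no clipping, which would put probability atoms on the
    bounds).
    """

    name: str
    family: str
    mean: float
    sd: float
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("truncnorm", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "truncnorm" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if not (self.lower < self.upper):
            raise ValueError(f"{self.name}: requires lower < upper")

    @classmethod
    def truncated_normal(
        cls, name: str, mean: float, sd: float, n_sd: float = 2.0, units: str = ""
    ) -> "ParameterDistribution":
        return cls(name, "truncnorm", mean, sd, mean - n_sd * sd, mean + n_sd * sd, units)

    @classmethod
    def uniform(cls, name: str, lower: float, upper: float, units: str = "") -> "ParameterDistribution":
        mean = 0.5 * (lower + upper)
        sd = (upper - lower) / np.sqrt(12.0)
        return cls(name, "uniform", mean, sd, lower, upper, units)

    def as_uniform(self) -> "ParameterDistribution":
        """Uniform distribution over the same range (robustness check mode)."""
        if self.family == "uniform":
            return self
        return ParameterDistribution.uniform(self.name, self.lower, self.upper, self.units)

    def with_truncation(self, n_sd: float) -> "ParameterDistribution":
        """Same distribution re-truncated at mean ± n_sd·sd (truncnorm only)."""
        if self.family != "truncnorm":
            return self
        return replace(self, lower=self.mean - n_sd * self.sd, upper=self.mean + n_sd * self.sd)

    # -- sampling --------------------------------------------------------

    def _frozen(self):
        if self.family == "uniform":
            return stats.uniform(loc=self.lower, scale=self.upper - self.lower)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def ppf(self, u):
        """Inverse CDF mapping of quantiles in [0, 1] to physical values."""
        return self._frozen().ppf(u)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Independent draws; truncation by rejection for truncated normals."""
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, size=n)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=n - filled)
            keep = draw[(draw >= self.lower) & (draw <= self.upper)]
            out[filled:filled + len(keep)] = keep
            filled += len(keep)
        return out

    def truncated_mean(self) -> float:
        """Analytic mean of the (possibly truncated) distribution."""
        return float(self._frozen().mean())


#: registry entries that default to uniform distributions
_UNIFORM_DEFAULT = {"stenosis_pct", "endo_epi_ratio"}
#: maximum stenosis severity considered (% diameter reduction)
STENOSIS_PCT_RANGE = (0.0, 75.0)


def default_distributions(all_uniform: bool = False) -> list[ParameterDistribution]:
    """The 39 default marginals, ordered as the parameter registry.

    ``all_uniform=True`` replaces every truncated normal by a uniform over
    the same range — a robustness check that the ranking of influential
    parameters is not an artifact of distribution entropy.
    """
    dists: list[ParameterDistribution] = []
    for spec in REGISTRY:
        if spec.name == "stenosis_pct":
            d = ParameterDistribution.uniform(spec.name, *STENOSIS_PCT_RANGE, units=spec.units)
        elif spec.name in _UNIFORM_DEFAULT:
            sd = 0.25 * abs(spec.default)
            d = ParameterDistribution.uniform(
                spec.name, spec.default - 2 * sd, spec.default + 2 * sd, units=spec.units
            )
        else:
            sd = 0.25 * abs(spec.default)
            d = ParameterDistribution.truncated_normal(
                spec.name, spec.default, sd, n_sd=2.0, units=spec.units
            )
        dists.append(d.as_uniform() if all_uniform else d)
    return dists


def write_registry_csv(dists: list[ParameterDistribution], path: str | Path) -> None:
    pd.DataFrame([d.__dict__ for d in dists]).to_csv(path, index=False)


def read_registry_csv(path: str | Path) -> list[ParameterDistribution]:
    df = pd.read_csv(path)
    required = {"name", "family", "mean", "sd", "lower", "upper"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
    return [
        ParameterDistribution(
            name=row["name"], family=row["family"], mean=float(row["mean"]),
            sd=float(row["sd"]), lower=float(row["lower"]), upper=float(row["upper"]),
            units=str(row.get("units", "")),
        )
        for _, row in df.iterrows()
    ]
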