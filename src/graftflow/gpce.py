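"""Regression-based polynomial chaos expansion with Sobol index extraction.

Nine uncertain inputs drive the closed-loop model: stenosis percentage
(uniform on [0, 75] %), and truncated normals (± 1.96·sd, i.e. the central
95 % of the density) for peripheral resistance R0_SVB, systemic arterial
compliance and characteristic resistance, a graft cross-section scale, graft
inertance, intramyocardial arterial compliance C1 and reference volume V0_1,
and cardiac period T.  The graft cross-section scale stands in for the
conduit's unstressed area: it scales the lumped graft resistance as s⁻²
(Poiseuille) and the stenosis reference diameter as √s.

The expansion uses a total-degree orthonormal Legendre basis after mapping
every input to [−1, 1] over its (bounded) range.  For the uniform input this
basis is exactly orthonormal; for the truncated normals the uniform-weight
orthogonality is an approximation, so the analytic Sobol indices are
cross-checked against Monte-Carlo pick-freeze estimates on the fitted
surrogate in the test suite.  Coefficients are fitted by least squares with
a configurable collocation factor (regression points per basis term); the
expansion order is chosen by k-fold cross-validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ParameterDistribution
from .metrics import metrics_from_simulation
from .model import SimulationError, simulate
from .parameters import ModelParameters, build_default_parameters

__all__ = [
    "UQ_PARAMETER_NAMES",
    "default_uq_distributions",
    "apply_uq_sample",
    "sample_inputs",
    "required_sample_count",
    "filter_unphysical",
    "PceModel",
    "fit_pce",
    "select_order_by_cv",
    "SobolIndices",
    "sobol_from_pce",
    "sobol_main_pick_freeze",
    "UqReport",
    "run_uq_stage",
]

#: the nine UQ inputs, in canonical order
UQ_PARAMETER_NAMES = (
    "stenosis_pct", "R0_SVB", "C_sa", "R_sa",
    "graft_area_scale", "L_graft", "C1", "V0_1", "T",
)

RESPONSE_METRICS = ("q_mean", "pi", "ds_ratio", "dri")


def default_uq_distributions(
    base: ModelParameters | None = None, sd_fraction: float = 0.25
) -> list[ParameterDistribution]:
    """The nine UQ marginals: uniform stenosis, ±1.96·sd truncated normals."""
    p = base or build_default_parameters()
    dists = [ParameterDistribution.uniform("stenosis_pct", 0.0, 75.0, units="%")]
    means = {
        "R0_SVB": p.R0_SVB, "C_sa": p.C_sa, "R_sa": p.R_sa,
        "graft_area_scale": 1.0, "L_graft": p.L_graft,
        "C1": p.C1, "V0_1": p.V0_1, "T": p.T,
    }
    for name in UQ_PARAMETER_NAMES[1:]:
        m = means[name]
        dists.append(
            ParameterDistribution.truncated_normal(name, m, sd_fraction * abs(m), n_sd=1.96)
        )
    return dists


def apply_uq_sample(values: dict[str, float], base: ModelParameters | None = None) -> ModelParameters:
    """Model parameters for one UQ sample.

    The graft area scale s maps onto R_graft/s² and D0·√s; all other UQ
    names are registry parameters and pass through directly.
    """
    p = base or build_default_parameters()
    overrides = {k: v for k, v in values.items() if k != "graft_area_scale"}
    s = values.get("graft_area_scale", 1.0)
    if s <= 0:
        raise ValueError("graft_area_scale must be positive")
    overrides["R_graft"] = p.R_graft / s**2
    overrides["stenosis_D0"] = p.stenosis_D0 * math.sqrt(s)
    return p.replace(**overrides)


def sample_inputs(
    dists: list[ParameterDistribution], n: int, seed: int = 0
) -> np.ndarray:
    """n independent joint draws (n × k matrix), deterministic given seed."""
    rng = np.random.default_rng(seed)
    return np.column_stack([d.sample(n, rng) for d in dists])


def required_sample_count(d: int, order: int, collocation_factor: float = 2.0) -> int:
    """Regression sample count: collocation factor × C(d+order, order)."""
    if d < 1 or order < 0:
        raise ValueError("d must be >= 1 and order >= 0")
    return int(round(collocation_factor * math.comb(d + order, order)))


# ---------------------------------------------------------------------------
# unphysical-run filtering
# ---------------------------------------------------------------------------

def _diastolic_peak(result) -> bool:
    """True when the last beat's aortic-pressure maximum falls in diastole."""
    opens = result.events["aortic_valve_open"]
    closes = result.events["aortic_valve_close"]
    if len(opens) < 2:
        raise ValueError("run has no complete beat; cannot segment for filtering")
    t0, t1 = opens[-2], opens[-1]
    close_in = closes[(closes > t0) & (closes < t1)]
    if len(close_in) != 1:
        raise ValueError("ambiguous systole end in the last beat")
    tc = close_in[0]
    t, p = result.t, result.signals["aortic_pressure"]
    mask = (t >= t0) & (t <= t1)
    t_peak = t[mask][np.argmax(p[mask])]
    return bool(t_peak > tc)


def filter_unphysical(runs: list) -> tuple[list[int], dict]:
    """Indices of physiologically plausible runs plus a removal report.

    A run whose aortic pressure peaks during diastole of its last beat is
    an obvious artifact of independently sampled parameters and is removed.
    Filtering is idempotent: applying it to the kept set removes nothing.
    """
    kept, removed = [], []
    for i, run in enumerate(runs):
        if run is None:
            continue  # failed simulations handled upstream
        (removed if _diastolic_peak(run) else kept).append(i)
    return kept, {
        "removed_ids": removed,
        "n_total": len(runs),
        "fraction_removed": len(removed) / len(runs) if runs else 0.0,
    }


# ---------------------------------------------------------------------------
# PCE core
# ---------------------------------------------------------------------------

def _multi_indices(d: int, order: int) -> list[tuple[int, ...]]:
    return [
        alpha
        for total in range(order + 1)
        for alpha in sorted(
            a for a in itertools.product(range(total + 1), repeat=d) if sum(a) == total
        )
    ]


def _legendre_orthonormal(z: np.ndarray, deg: int) -> np.ndarray:
    """Orthonormal Legendre polynomial of given degree on [−1, 1]."""
    c = np.zeros(deg + 1)
    c[deg] = 1.0
    return np.polynomial.legendre.legval(z, c) * math.sqrt(2 * deg + 1)


@dataclass
class PceModel:
    """Fitted expansion for one or more response metrics."""

    indices: list[tuple[int, ...]]
    coeffs: np.ndarray              # (n_basis, n_responses)
    lower: np.ndarray               # per-input bounds for the [-1,1] map
    upper: np.ndarray
    names: list[str]
    response_names: list[str]
    order: int
    residual_rms: np.ndarray        # per response
    cv_table: pd.DataFrame | None = None

    @property
    def n_basis(self) -> int:
        return len(self.indices)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.lower) / (self.upper - self.lower) - 1.0

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.asarray(X, dtype=float))
        Psi = np.ones((Z.shape[0], self.n_basis))
        for b, alpha in enumerate(self.indices):
            for j, deg in enumerate(alpha):
                if deg:
                    Psi[:, b] *= _legendre_orthonormal(Z[:, j], deg)
        return Psi

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.design_matrix(X) @ self.coeffs


def _bounds_from_dists(dists: list[ParameterDistribution]) -> tuple[np.ndarray, np.ndarray]:
    return (np.array([d.lower for d in dists]), np.array([d.upper for d in dists]))


def fit_pce(
    samples: np.ndarray,
    responses: np.ndarray,
    order: int,
    dists: list[ParameterDistribution],
    response_names: list[str] | None = None,
) -> PceModel:
    """Least-squares fit of a total-degree-``order`` expansion."""
    X = np.asarray(samples, dtype=float)
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    indices = _multi_indices(d, order)
    if n < len(indices):
        raise ValueError(
            f"{n} samples cannot determine {len(indices)} coefficients; "
            "draw more samples or lower the order"
        )
    lower, upper = _bounds_from_dists(dists)
    model = PceModel(
        indices=indices,
        coeffs=np.zeros((len(indices), Y.shape[1])),
        lower=lower, upper=upper,
        names=[dd.name for dd in dists],
        response_names=response_names or [f"y{i}" for i in range(Y.shape[1])],
        order=order,
        residual_rms=np.zeros(Y.shape[1]),
    )
    Psi = model.design_matrix(X)
    coeffs, _, rank, _ = np.linalg.lstsq(Psi, Y, rcond=None)
    if rank < len(indices):
        raise ValueError(
            "regression system is rank deficient; draw more samples"
        )
    model.coeffs = coeffs
    model.residual_rms = np.sqrt(np.mean((Psi @ coeffs - Y) ** 2, axis=0))
    return model


def select_order_by_cv(
    samples: np.ndarray,
    responses: np.ndarray,
    dists: list[ParameterDistribution],
    max_order: int = 2,
    k: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """k-fold cross-validated RMSE per candidate order; lowest order wins ties."""
    X = np.asarray(samples, dtype=float)
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k = {k} folds exceed n = {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    min_train = n - max(len(f) for f in folds)
    feasible = [
        o for o in range(1, max_order + 1)
        if len(_multi_indices(X.shape[1], o)) <= min_train
    ]
    if not feasible:
        raise ValueError(
            f"no candidate order is identifiable from {min_train} training samples"
        )
    rows = []
    for order in feasible:
        sq = np.zeros(Y.shape[1])
        count = 0
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            model = fit_pce(X[train], Y[train], order, dists)
            pred = model.predict(X[fold])
            sq += np.sum((pred - Y[fold]) ** 2, axis=0)
            count += len(fold)
        rows.append({"order": order, **{
            f"rmse_{i}": float(np.sqrt(s / count)) for i, s in enumerate(sq)
        }, "rmse_mean": float(np.sqrt(sq.sum() / (count * Y.shape[1])))})
    table = pd.DataFrame(rows).set_index("order")
    best = int(table["rmse_mean"].idxmin())  # idxmin returns the first (lowest) order on ties
    return best, table


# ---------------------------------------------------------------------------
# Sobol indices
# ---------------------------------------------------------------------------

@dataclass
class SobolIndices:
    """Main and total variance shares per input, per response metric."""

    main: pd.DataFrame    # rows: inputs, columns: responses
    total: pd.DataFrame

    def ranking(self, response: str) -> list[str]:
        return list(self.total[response].sort_values(ascending=False).index)


def sobol_from_pce(model: PceModel) -> SobolIndices:
    """Variance decomposition read off the orthonormal-basis coefficients.

    main_i sums squared coefficients of terms involving input i alone;
    total_i sums those of every term involving i.  For an order-1 expansion
    the two coincide exactly.
    """
    alphas = np.array(model.indices)
    c2 = model.coeffs**2
    nonconst = alphas.sum(axis=1) > 0
    var = c2[nonconst].sum(axis=0)
    # a numerically-zero variance (constant response) has no decomposition
    var = np.where(var <= 1e-20 * (c2.sum(axis=0) + 1e-300), 0.0, var)
    if np.any(var == 0):
        flat = [model.response_names[i] for i in np.nonzero(var == 0)[0]]
        raise ValueError(f"zero output variance for response(s): {', '.join(flat)}")
    d = alphas.shape[1]
    main = np.zeros((d, c2.shape[1]))
    total = np.zeros_like(main)
    for i in range(d):
        only_i = (alphas[:, i] > 0) & (alphas.sum(axis=1) == alphas[:, i])
        any_i = alphas[:, i] > 0
        main[i] = c2[only_i].sum(axis=0) / var
        total[i] = c2[any_i].sum(axis=0) / var
    return SobolIndices(
        main=pd.DataFrame(main, index=model.names, columns=model.response_names),
        total=pd.DataFrame(total, index=model.names, columns=model.response_names),
    )


def sobol_main_pick_freeze(
    model: PceModel, n: int = 20000, seed: int = 0
) -> pd.DataFrame:
    """Monte-Carlo pick-freeze main indices on the fitted surrogate.

    Independent cross-check of :func:`sobol_from_pce` that does not rely on
    basis orthogonality: S_i = Cov(f(X), f(X'_i)) / Var(f(X)), where X'_i
    shares coordinate i with X and resamples the rest.
    """
    rng = np.random.default_rng(seed)
    d = len(model.names)
    U = model.lower + (model.upper - model.lower) * rng.random((n, d))
    V = model.lower + (model.upper - model.lower) * rng.random((n, d))
    fU = model.predict(U)
    mean = fU.mean(axis=0)
    var = fU.var(axis=0)
    out = np.zeros((d, fU.shape[1]))
    for i in range(d):
        W = V.copy()
        W[:, i] = U[:, i]
        fW = model.predict(W)
        out[i] = ((fU * fW).mean(axis=0) - mean * fW.mean(axis=0)) / var
    return pd.DataFrame(out, index=model.names, columns=model.response_names)


# ---------------------------------------------------------------------------
# full UQ stage
# ---------------------------------------------------------------------------

@dataclass
class UqReport:
    """Provenance and results of one UQ stage run."""

    sobol: SobolIndices
    order: int
    cv_table: pd.DataFrame
    samples: np.ndarray
    responses: pd.DataFrame
    kept: list[int]
    filter_report: dict
    n_failed: int
    seed: int

    def most_influential(self, response: str) -> str:
        return self.sobol.ranking(response)[0]


def _default_runner(values: dict[str, float], n_beats: int, base: ModelParameters | None):
    params = apply_uq_sample(values, base=base)
    return simulate(params, n_beats=n_beats)


def run_uq_stage(
    n: int | None = None,
    seed: int = 0,
    max_order: int = 2,
    collocation_factor: float = 2.0,
    dists: list[ParameterDistribution] | None = None,
    base: ModelParameters | None = None,
    n_beats: int = 10,
    k_folds: int = 10,
    runner=None,
) -> UqReport:
    """Sample → simulate → metrics → filter → CV order selection → Sobol.

    ``runner(values_dict)`` may be supplied for testing with surrogates; it
    must return a SimulationResult.  Aborts when more than half the runs fail
    or are filtered out.
    """
    dists = dists or default_uq_distributions(base)
    names = [d.name for d in dists]
    if n is None:
        n = required_sample_count(len(dists), max_order, collocation_factor)
    X = sample_inputs(dists, n, seed=seed)

    run = runner or (lambda values: _default_runner(values, n_beats, base))
    results, n_failed = [], 0
    for row in X:
        values = dict(zip(names, row))
        try:
            results.append(run(values))
        except (SimulationError, ValueError):
            results.append(None)
            n_failed += 1

    alive = [i for i, r in enumerate(results) if r is not None]
    kept_alive, report = filter_unphysical([results[i] for i in alive])
    kept = [alive[i] for i in kept_alive]
    report["n_failed"] = n_failed
    report["removed_ids"] = [alive[i] for i in report["removed_ids"]]
    if len(kept) < 0.5 * n:
        raise RuntimeError(
            f"only {len(kept)}/{n} runs usable after failures and filtering; "
            f"report: {report}"
        )

    rows = []
    for i in kept:
        m = metrics_from_simulation(results[i])
        rows.append({k: m.median[k] for k in RESPONSE_METRICS})
    Y = pd.DataFrame(rows, index=kept)

    order, cv_table = select_order_by_cv(
        X[kept], Y.to_numpy(), dists, max_order=max_order, k=min(k_folds, len(kept)), seed=seed
    )
    model = fit_pce(X[kept], Y.to_numpy(), order, dists, response_names=list(RESPONSE_METRICS))
    return UqReport(
        sobol=sobol_from_pce(model),
        order=order,
        cv_table=cv_table,
        samples=X,
        responses=Y,
        kept=kept,
        filter_report=report,
        n_failed=n_failed,
        seed=seed,
    )
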