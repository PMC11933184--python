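"""Morris elementary-effects screening.

One-at-a-time trajectories on a p-level grid in the unit hypercube, mapped to
physical values through each parameter's inverse CDF.  For parameter i the
elementary effect of a trajectory step is EE_i = (f(x + Δe_i) − f(x))/±Δ in
normalized coordinates; the screening measures are μ* (mean absolute EE) and
σ (standard deviation of EEs), combined into the single score √(μ*² + σ²)
used for ranking.

Trajectory selection follows a spread-maximizing strategy: an oversampled
pool of random trajectories is generated and a greedy max–min rule keeps the
r trajectories whose point sets are farthest apart.  This approximates the
published efficient selection schemes while remaining simple and exactly
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ParameterDistribution, default_distributions  # noqa: F401

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "build_trajectories",
    "map_to_physical",
    "elementary_effects",
    "converge_r",
    "default_distributions",
]


@dataclass
class MorrisDesign:
    """r trajectories of (k+1) points each, in normalized [0,1]^k coordinates."""

    X: np.ndarray           # (r*(k+1), k) design points
    r: int
    k: int
    p: int
    delta: float
    names: list[str]

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    def trajectory(self, i: int) -> np.ndarray:
        m = self.k + 1
        return self.X[i * m:(i + 1) * m]

    def validate(self) -> None:
        """Audit: consecutive points differ in exactly one coordinate by ±Δ."""
        m = self.k + 1
        for i in range(self.r):
            traj = self.trajectory(i)
            for a, b in zip(traj[:-1], traj[1:]):
                diff = b - a
                changed = np.nonzero(np.abs(diff) > 1e-12)[0]
                if len(changed) != 1 or not np.isclose(abs(diff[changed[0]]), self.delta):
                    raise AssertionError("trajectory step is not a single ±Δ move")


@dataclass
class MorrisResult:
    """Per-parameter screening measures with ranking (rank 1 = most influential)."""

    table: pd.DataFrame     # index: parameter names; mu_star, sigma, score, rank
    n_dropped: int          # elementary effects lost to non-finite responses

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


def _single_trajectory(rng: np.random.Generator, k: int, p: int, delta: float) -> np.ndarray:
    """One random Morris trajectory on the p-level grid."""
    grid = np.arange(p) / (p - 1)
    base_levels = grid[grid <= 1.0 - delta + 1e-12]
    x = rng.choice(base_levels, size=k)
    order = rng.permutation(k)
    traj = np.empty((k + 1, k))
    traj[0] = x
    cur = x.copy()
    for step, i in enumerate(order):
        d = delta if rng.random() < 0.5 else -delta
        if cur[i] + d > 1.0 + 1e-12 or cur[i] + d < -1e-12:
            d = -d
        cur = cur.copy()
        cur[i] += d
        traj[step + 1] = cur
    return traj


def build_trajectories(
    dists: list[ParameterDistribution],
    r: int,
    p: int = 4,
    seed: int = 0,
    oversample: int = 200,
) -> MorrisDesign:
    """Build a spread-maximizing Morris design for the given marginals.

    ``oversample`` candidate trajectories are generated; a greedy max–min
    rule (on the summed Euclidean distance between trajectory point sets)
    keeps the ``r`` most spread-out ones.  Δ = p/(2(p−1)), the standard
    choice which makes each level equally probable to be sampled.
    """
    if r < 1:
        raise ValueError("r must be at least 1")
    if p < 2 or p % 2:
        raise ValueError("p must be an even integer >= 2")
    if oversample < r:
        raise ValueError(f"oversample ({oversample}) must be >= r ({r})")
    k = len(dists)
    delta = p / (2.0 * (p - 1))
    rng = np.random.default_rng(seed)
    pool = np.stack([_single_trajectory(rng, k, p, delta) for _ in range(oversample)])

    # pairwise spread: sum of point-to-point distances between trajectories
    flat = pool.reshape(oversample, -1)
    # distance between trajectories approximated on flattened point sets;
    # adequate for spread maximization and far cheaper than all point pairs
    d2 = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=-1)
    dist = np.sqrt(d2)

    selected = [int(np.unravel_index(np.argmax(dist), dist.shape)[0])]
    if r > 1:
        selected.append(int(np.unravel_index(np.argmax(dist), dist.shape)[1]))
    while len(selected) < r:
        rest = [i for i in range(oversample) if i not in selected]
        min_d = dist[np.ix_(rest, selected)].min(axis=1)
        selected.append(rest[int(np.argmax(min_d))])
    X = pool[selected].reshape(r * (k + 1), k)
    return MorrisDesign(X=X, r=r, k=k, p=p, delta=delta, names=[d.name for d in dists])


def map_to_physical(design: MorrisDesign, dists: list[ParameterDistribution]) -> np.ndarray:
    """Map normalized design points to physical values via inverse CDFs."""
    if [d.name for d in dists] != design.names:
        raise ValueError("distribution list does not match the design's parameters")
    out = np.empty_like(design.X)
    for j, d in enumerate(dists):
        out[:, j] = d.ppf(design.X[:, j])
    return out


def elementary_effects(design: MorrisDesign, responses: np.ndarray) -> MorrisResult:
    """Screening measures from responses evaluated at every design point.

    ``responses`` is a length-``n_points`` vector of one scalar metric.
    Non-finite responses (failed runs) invalidate the elementary effects of
    the steps they participate in; those are dropped pairwise and counted.
    """
    f = np.asarray(responses, dtype=float)
    if f.shape != (design.n_points,):
        raise ValueError(
            f"expected {design.n_points} responses, got shape {f.shape}"
        )
    k, m = design.k, design.k + 1
    ees: list[list[float]] = [[] for _ in range(k)]
    n_dropped = 0
    for i in range(design.r):
        traj = design.trajectory(i)
        fi = f[i * m:(i + 1) * m]
        for s in range(k):
            a, b = traj[s], traj[s + 1]
            j = int(np.argmax(np.abs(b - a)))
            step = b[j] - a[j]
            if not (np.isfinite(fi[s]) and np.isfinite(fi[s + 1])):
                n_dropped += 1
                continue
            ees[j].append((fi[s + 1] - fi[s]) / step)
    mu_star = np.empty(k)
    sigma = np.empty(k)
    for j in range(k):
        if not ees[j]:
            raise ValueError(
                f"all elementary effects missing for parameter {design.names[j]!r}"
            )
        arr = np.asarray(ees[j])
        mu_star[j] = np.abs(arr).mean()
        sigma[j] = arr.std(ddof=1) if len(arr) > 1 else 0.0
    score = np.sqrt(mu_star**2 + sigma**2)
    table = pd.DataFrame(
        {"mu_star": mu_star, "sigma": sigma, "score": score}, index=design.names
    )
    table["rank"] = table["score"].rank(ascending=False, method="first").astype(int)
    return MorrisResult(table=table, n_dropped=n_dropped)


def converge_r(
    dists: list[ParameterDistribution],
    runner,
    r_start: int = 10,
    r_step: int = 10,
    top_n: int = 3,
    p: int = 4,
    seed: int = 0,
    r_cap: int = 200,
    oversample_factor: int = 4,
) -> tuple[int, MorrisResult]:
    """Grow r in steps until the top-``top_n`` ranking stabilizes.

    ``runner`` maps an (n, k) matrix of physical parameter values to a
    length-n response vector.  Returns the final r and its screening result;
    raises if the ranking is still changing at ``r_cap``.
    """
    prev_top: list[str] | None = None
    r = r_start
    while r <= r_cap:
        design = build_trajectories(
            dists, r, p=p, seed=seed, oversample=max(oversample_factor * r, r)
        )
        responses = runner(map_to_physical(design, dists))
        result = elementary_effects(design, np.asarray(responses))
        top = result.top(top_n)
        if prev_top is not None and top == prev_top:
            return r, result
        prev_top = top
        r += r_step
    raise RuntimeError(
        f"top-{top_n} ranking did not stabilize by r = {r_cap}; "
        "the response may be too noisy for screening at this budget"
    )
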