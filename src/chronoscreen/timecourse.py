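"""Time-course significance analysis for pooled-screen aging profiles.

For every strain we ask whether its representation in the pool changes over
the time course consistently in both replicate pools.  The alternative model
fits the stacked replicate log2 ratios with a natural cubic spline in time;
the null model is a flat intercept.  The statistic is the residual-sum-of-
squares ratio ``F = (rss0 - rss1) / (rss1 + delta)`` — a raw RSS ratio
rather than a scaled F, because calibration comes from a permutation null,
not an F distribution.  Day labels are permuted within each replicate
(shared across strains, so the cross-strain dependence structure survives
into the null) and the null statistics are pooled across strains: five time
points admit only 120 distinct permutations, far too few per strain.
Empirical p-values are converted to Storey q-values with a fixed-lambda
pi0 estimate, and strains with q below a cutoff (0.1 by default) are called
significantly over- or under-represented over the course of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .tagio import AgingProfileMatrix

__all__ = [
    "NaturalSplineBasis",
    "spline_basis",
    "strain_statistic",
    "NullDistribution",
    "permutation_null",
    "empirical_pvalues",
    "estimate_pi0",
    "qvalues",
    "significant_strains",
    "timecourse_test",
]

F_GUARD = 1e-8  # keeps F finite when the spline interpolates exactly
F_CAP = 1e12


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline regression basis with fixed knots.

    ``df`` columns beyond the intercept: the identity plus ``df - 1``
    curvature terms, linear beyond the boundary knots.  ``df = 1`` is exactly
    the linear basis {1, t}.
    """

    knots: tuple[float, ...]  # boundary + interior, sorted

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def design(self, x) -> np.ndarray:
        """Design matrix (len(x) rows, df + 1 columns including intercept)."""
        x = np.asarray(x, dtype=float)
        xi = np.asarray(self.knots)
        cols = [np.ones_like(x), x]
        if len(xi) > 2:
            last, penult = xi[-1], xi[-2]

            def d(k):
                num = np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - last, 0, None) ** 3
                return num / (last - xi[k])

            d_penult = d(len(xi) - 2)
            cols.extend(d(k) - d_penult for k in range(len(xi) - 2))
        return np.column_stack(cols)


def spline_basis(days, df: int | None = None) -> NaturalSplineBasis:
    """Natural cubic spline basis over the sampled days.

    Boundary knots at the first and last distinct day; ``df - 1`` interior
    knots at the day quantiles.  Default ``df = min(3, T - 2)`` for T
    distinct days; ``df`` may not exceed ``T - 2`` (the design would be rank
    deficient at the observed days).
    """
    distinct = np.unique(np.asarray(days, dtype=float))
    t = len(distinct)
    if t < 3:
        raise InputError("need at least 3 distinct days for a time-course basis")
    if df is None:
        df = min(3, t - 2)
    if df < 1 or df > t - 2:
        raise InputError(f"df={df} outside [1, {t - 2}] for {t} distinct days")
    interior = np.quantile(distinct, [i / df for i in range(1, df)]) if df > 1 else np.array([])
    knots = np.concatenate([[distinct[0]], interior, [distinct[-1]]])
    return NaturalSplineBasis(knots=tuple(float(k) for k in np.unique(knots)))


def _rss_pair(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    rss0 = float(((y - y.mean()) ** 2).sum())
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ coef) ** 2).sum())
    return rss0, min(rss0, rss1)  # nested models: rss1 <= rss0 up to round-off


def strain_statistic(days, values, basis: NaturalSplineBasis) -> tuple[float, float, float]:
    """(F_stat, rss0, rss1) for one strain's stacked replicate observations.

    ``days``/``values`` are the non-masked observations of both replicates
    stacked into one vector; both models are ordinary least squares on that
    stack, so a trend must be shared across replicates to reduce rss1.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    X = basis.design(days)
    if len(values) < X.shape[1] + 1 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("degenerate design: too few observations for the basis")
    rss0, rss1 = _rss_pair(values, X)
    f = min((rss0 - rss1) / (rss1 + F_GUARD), F_CAP)
    return max(f, 0.0), rss0, rss1


@dataclass
class NullDistribution:
    """Pooled permutation null: B permutations x n strains statistics."""

    values: np.ndarray  # flat, pooled across strains
    B: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def _replicate_arrays(profiles: AgingProfileMatrix) -> tuple[np.ndarray, list, pd.Index]:
    reps = sorted(profiles.replicates)
    days = profiles.days
    idx = profiles.replicates[reps[0]].index
    Y = np.stack([profiles.replicates[r].loc[idx, days].to_numpy(dtype=float) for r in reps])
    return Y, days, idx  # shape (R, n, T)


def _stat_matrix(Y: np.ndarray, X_rows: np.ndarray) -> np.ndarray:
    """Vectorized F statistics for complete-case strains.

    ``Y``: (R, n, T) observations; ``X_rows``: (R, T, p) per-replicate design
    rows (already permuted if building a null).  Stacks replicates to a
    (R*T, n) response matrix and projects once — the design is shared across
    strains.
    """
    R, n, T = Y.shape
    ys = Y.transpose(0, 2, 1).reshape(R * T, n)
    X = X_rows.reshape(R * T, -1)
    rss0 = ((ys - ys.mean(axis=0)) ** 2).sum(axis=0)
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ ys
    rss1 = np.maximum((ys**2).sum(axis=0) - (proj**2).sum(axis=0), 0.0)
    rss1 = np.minimum(rss1, rss0)
    return np.clip((rss0 - rss1) / (rss1 + F_GUARD), 0.0, F_CAP)


def observed_statistics(
    profiles: AgingProfileMatrix, basis: NaturalSplineBasis | None = None
) -> pd.DataFrame:
    """Per-strain F statistic, rss0, rss1 and testable flag on replicate profiles."""
    basis = basis or spline_basis(profiles.days)
    Y, days, idx = _replicate_arrays(profiles)
    rows = []
    day_arr = np.asarray(days, dtype=float)
    for i, sid in enumerate(idx):
        obs = Y[:, i, :]
        mask = ~np.isnan(obs)
        d = np.concatenate([day_arr[mask[r]] for r in range(obs.shape[0])])
        v = obs[mask]
        try:
            f, rss0, rss1 = strain_statistic(d, v, basis)
            rows.append({"strain_id": sid, "F_stat": f, "rss0": rss0, "rss1": rss1, "testable": True})
        except InputError:
            rows.append(
                {"strain_id": sid, "F_stat": np.nan, "rss0": np.nan, "rss1": np.nan, "testable": False}
            )
    return pd.DataFrame(rows).set_index("strain_id")


def permutation_null(
    profiles: AgingProfileMatrix,
    basis: NaturalSplineBasis | None = None,
    B: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Pooled permutation null distribution of the time-course statistic.

    For each of the B iterations one random permutation of the non-reference
    day labels is drawn per replicate — independent across replicates, shared
    across all strains within a replicate — and every strain's statistic is
    recomputed.  The reference day stays pinned: its log2 ratio is identically
    zero by construction (zero variance across strains), so day labels
    including the reference are not exchangeable and permuting it would bias
    the null.  All ``B x n`` values are pooled.  Only complete-case strains
    (no masked day in either replicate) enter the null; strains with masked
    days are rare after QC and their observed statistics are still computed.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    basis = basis or spline_basis(profiles.days)
    Y, days, _ = _replicate_arrays(profiles)
    complete = ~np.isnan(Y).any(axis=(0, 2))
    Y = Y[:, complete, :]
    if Y.shape[1] == 0:
        raise InputError("no complete-case strains for the permutation null")
    day_arr = np.asarray(days, dtype=float)
    base_rows = basis.design(day_arr)  # (T, p)
    movable = np.flatnonzero(day_arr != profiles.reference_day)
    rng = np.random.default_rng(seed)
    R, _, T = Y.shape
    pooled = []
    for _ in range(B):
        X_rows = []
        for _r in range(R):
            order = np.arange(T)
            order[movable] = movable[rng.permutation(len(movable))]
            X_rows.append(base_rows[order])
        pooled.append(_stat_matrix(Y, np.stack(X_rows)))
    return NullDistribution(values=np.concatenate(pooled), B=B, seed=seed)


def empirical_pvalues(f_stats, null: NullDistribution) -> np.ndarray:
    """Pooled-permutation p-values: ``p = (1 + #{null >= F}) / (1 + |null|)``."""
    if null.values.size == 0:
        raise InputError("empty null distribution")
    sorted_null = np.sort(null.values)
    f = np.asarray(f_stats, dtype=float)
    n_ge = len(sorted_null) - np.searchsorted(sorted_null, f, side="left")
    p = (1.0 + n_ge) / (1.0 + len(sorted_null))
    p[np.isnan(f)] = np.nan
    return p


def estimate_pi0(pvals, lam: float = 0.5) -> float:
    """Fixed-lambda estimate of the proportion of true nulls.

    ``pi0 = #{p > lambda} / ((1 - lambda) * m)``, clipped to [1/m, 1].  With
    thousands of strains the fixed-lambda estimator is stable; smoothing
    across lambdas buys little here.
    """
    if not 0.0 < lam < 1.0:
        raise ConfigurationError("lambda must lie in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    m = len(p)
    if m < 20:
        raise InputError(f"pi0 estimation needs >= 20 p-values, got {m}")
    pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(pvals, pi0: float = 1.0) -> np.ndarray:
    """Storey q-values by the step-up running minimum.

    With p sorted ascending, ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j``;
    mapped back to input order.  All q <= pi0 and q is monotone
    non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = pi0 * m * ps[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


def significant_strains(results: pd.DataFrame, q_cutoff: float = 0.1) -> list[str]:
    """Strain ids with q-value at or below the cutoff."""
    return sorted(results.index[results["q_value"] <= q_cutoff])


def timecourse_test(
    profiles: AgingProfileMatrix,
    df: int | None = None,
    B: int = 1000,
    seed: int = 0,
    lam: float = 0.5,
) -> pd.DataFrame:
    """Full per-strain significance analysis on replicate-level profiles.

    Returns a DataFrame indexed by strain with F_stat, rss0, rss1, p_value,
    q_value and a testable flag.  B below 100 gives coarse p-values (the
    smallest attainable p is ``1/(B*n + 1)``).
    """
    basis = spline_basis(profiles.days, df)
    obs = observed_statistics(profiles, basis)
    null = permutation_null(profiles, basis, B=B, seed=seed)
    obs["p_value"] = empirical_pvalues(obs["F_stat"].to_numpy(), null)
    pi0 = estimate_pi0(obs["p_value"].to_numpy(), lam)
    obs["q_value"] = qvalues(obs["p_value"].to_numpy(), pi0)
    obs.attrs["pi0"] = pi0
    obs.attrs["B"] = B
    obs.attrs["n_null"] = int(null.values.size)
    return obs
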