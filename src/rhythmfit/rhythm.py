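"""Rhythmicity test battery for replicated time courses.

All tests consume a :class:`~rhythmfit.timecourse.TimeCourse` whose replicate
observations enter as independent ``(t, y)`` points. Permutation null
distributions shuffle the pooled values across the present slots while the
time stamps stay fixed; selection over a (period, phase) grid is absorbed
into the null by taking the grid maximum for every permutation, so the
reported p-values are familywise-valid without a separate Bonferroni step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import stats

from .timecourse import TimeCourse

__all__ = [
    "RhythmTestConfig",
    "RhythmTestResult",
    "DiffRhythmResult",
    "HarmonicFit",
    "linear_detrend",
    "lomb_scargle_periodogram",
    "ls_permutation_test",
    "kendall_tau",
    "jtk_cycle_test",
    "umbrella_rain_test",
    "harmonic_regression_fit",
    "differential_rhythmicity_test",
]

_PERM_BLOCK = 500  # permutations processed per vectorized block


@dataclass
class RhythmTestConfig:
    """Shared configuration for the test battery.

    ``period_min``/``period_max`` bound the periodogram search (6-50 h);
    ``period`` is the single candidate period of the rank-based tests (24 h);
    ``jtk_periods`` is the template period grid of the JTK-style test.
    """

    period_min: float = 6.0
    period_max: float = 50.0
    period: float = 24.0
    jtk_periods: tuple[float, ...] = (20.0, 24.0, 28.0)
    n_permutations: int = 5000
    oversampling: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.period_min < self.period_max:
            raise ValueError("need 0 < period_min < period_max")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["jtk_periods"] = list(self.jtk_periods)
        return d


@dataclass
class RhythmTestResult:
    method: str
    statistic: float
    p_value: float
    period_estimate: float | None = None
    phase_estimate: float | None = None
    config: dict[str, Any] = field(default_factory=dict)
    flags: dict[str, Any] = field(default_factory=dict)


@dataclass
class DiffRhythmResult:
    statistic: float
    p_value: float
    fit_a: "HarmonicFit"
    fit_b: "HarmonicFit"
    detrend_a: dict[str, float]
    detrend_b: dict[str, float]
    period: float
    method: str = "wald_chi2"


def _permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """(1 + #{null >= observed}) / (1 + N); respects the 1/(N+1) floor."""
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + null.size)


def _permuted_values(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(np.tile(y, (n, 1)), axis=1)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def linear_detrend(tc: TimeCourse) -> TimeCourse:
    """Subtract the OLS line fitted to all present (t, value) points.

    The fitted slope/intercept are recorded in ``meta["detrend"]``.
    """
    if np.unique(tc.times).size < 3:
        raise ValueError("linear detrending needs >= 3 distinct time points")
    t, y = tc.observations()
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    slope, intercept = np.polyfit(t, y, 1)
    resid = tc.values - (slope * tc.times[:, None] + intercept)
    return tc.with_values(
        resid, detrend={"slope": float(slope), "intercept": float(intercept)}
    )


# ---------------------------------------------------------------------------
# Lomb-Scargle
# ---------------------------------------------------------------------------

def _ls_frequency_grid(tc: TimeCourse, config: RhythmTestConfig) -> np.ndarray:
    span = float(np.ptp(tc.times))
    if span <= 0:
        raise ValueError("empty or degenerate time axis")
    if config.period_max > span:
        warnings.warn(
            f"period_max {config.period_max} h exceeds the {span} h data span; "
            "long-period powers are poorly constrained",
            stacklevel=3,
        )
    df = 1.0 / (config.oversampling * span)
    f_lo, f_hi = 1.0 / config.period_max, 1.0 / config.period_min
    return np.arange(f_lo, f_hi + 0.5 * df, df)


def _ls_design(t: np.ndarray, freqs: np.ndarray):
    """Per-frequency phase-shifted cosine/sine bases of the classical periodogram."""
    omega = 2.0 * np.pi * freqs[None, :]  # (1, F)
    two_wt = 2.0 * omega * t[:, None]
    tau = np.arctan2(np.sin(two_wt).sum(axis=0), np.cos(two_wt).sum(axis=0)) / (
        2.0 * omega[0]
    )
    arg = omega * t[:, None] - omega * tau[None, :]
    c = np.cos(arg)
    s = np.sin(arg)
    return c, s, (c**2).sum(axis=0), (s**2).sum(axis=0)


def _ls_power_matrix(Y: np.ndarray, design, variance: float) -> np.ndarray:
    """Normalized powers for each row of centered value matrix ``Y``."""
    c, s, cc, ss = design
    with np.errstate(invalid="ignore", divide="ignore"):
        power = ((Y @ c) ** 2 / cc + (Y @ s) ** 2 / ss) / (2.0 * variance)
    return np.nan_to_num(power, nan=0.0, posinf=0.0)


def lomb_scargle_periodogram(
    tc: TimeCourse, config: RhythmTestConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Classical normalized Lomb-Scargle periodogram over pooled observations.

    Returns ``(periods, powers)`` on a grid uniform in frequency between
    ``1/period_max`` and ``1/period_min`` with spacing ``1/(oversampling * span)``.
    A constant series yields all-zero powers.
    """
    config = config or RhythmTestConfig()
    t, y = tc.observations()
    if y.size < 4:
        raise ValueError("need >= 4 present observations for a periodogram")
    freqs = _ls_frequency_grid(tc, config)
    design = _ls_design(t, freqs)
    var = float(np.var(y, ddof=1))
    if var == 0.0:
        return 1.0 / freqs, np.zeros_like(freqs)
    power = _ls_power_matrix((y - y.mean())[None, :], design, var)[0]
    return 1.0 / freqs, power


def ls_permutation_test(
    tc: TimeCourse, config: RhythmTestConfig | None = None
) -> RhythmTestResult:
    """Permutation test on the peak of the Lomb-Scargle periodogram."""
    config = config or RhythmTestConfig()
    t, y = tc.observations()
    if y.size < 4:
        raise ValueError("need >= 4 present observations")
    freqs = _ls_frequency_grid(tc, config)
    design = _ls_design(t, freqs)
    var = float(np.var(y, ddof=1))
    if var == 0.0:
        return RhythmTestResult(
            "lomb_scargle_perm", 0.0, 1.0, None, None, config.to_dict(),
            {"constant_series": True},
        )
    yc = y - y.mean()
    obs_power = _ls_power_matrix(yc[None, :], design, var)[0]
    k = int(np.argmax(obs_power))
    observed = float(obs_power[k])

    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_permutations)
    done = 0
    while done < config.n_permutations:
        m = min(_PERM_BLOCK, config.n_permutations - done)
        Y = _permuted_values(yc, m, rng)
        null[done : done + m] = _ls_power_matrix(Y, design, var).max(axis=1)
        done += m
    return RhythmTestResult(
        method="lomb_scargle_perm",
        statistic=observed,
        p_value=_permutation_pvalue(observed, null),
        period_estimate=float(1.0 / freqs[k]),
        phase_estimate=None,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# Kendall tau / JTK-style template test
# ---------------------------------------------------------------------------

def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _sign_pairs(Y: np.ndarray, iu) -> np.ndarray:
    """Pairwise value-difference signs for each row of ``Y`` (int8)."""
    return np.sign(Y[:, iu[0]] - Y[:, iu[1]]).astype(np.int8)


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected (tau-b) Kendall rank correlation.

    Direct pair-count implementation; the JTK-style test uses the same
    machinery vectorized over templates and permutations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    iu = _pair_indices(x.size)
    dx = _sign_pairs(x[None, :], iu)[0].astype(float)
    dy = _sign_pairs(y[None, :], iu)[0].astype(float)
    n0 = dx.size
    denom = np.sqrt((n0 - np.sum(dx == 0)) * (n0 - np.sum(dy == 0)))
    if denom == 0:
        return np.nan
    return float(np.dot(dx, dy) / denom)


def _jtk_grid(times: np.ndarray, config: RhythmTestConfig) -> list[tuple[float, float]]:
    diffs = np.diff(np.unique(times))
    step = float(diffs.min()) if diffs.size else 4.0
    grid = []
    for p in config.jtk_periods:
        for phi in np.arange(0.0, p - 1e-9, step):
            grid.append((float(p), float(phi)))
    return grid


def jtk_cycle_test(
    tc: TimeCourse, config: RhythmTestConfig | None = None
) -> RhythmTestResult:
    """JTK-style test: max Kendall tau against phased cosine templates.

    Templates ``cos(2*pi*(t - phi)/p)`` span a period grid around 24 h and a
    phase grid on the sampling interval. The permutation null re-maximizes
    tau over the whole grid for every shuffle, which controls the selection
    effect the way a Bonferroni correction would, without its conservatism.
    """
    config = config or RhythmTestConfig()
    if np.unique(tc.times).size < 4:
        raise ValueError("need >= 4 time points")
    t, y = tc.observations()
    grid = _jtk_grid(tc.times, config)
    templates = np.stack(
        [np.cos(2.0 * np.pi * (t - phi) / p) for p, phi in grid]
    )  # (G, n)

    iu = _pair_indices(y.size)
    n0 = iu[0].size
    d_templates = _sign_pairs(templates, iu).astype(np.float32)  # (G, K)
    ties_templates = (d_templates == 0).sum(axis=1)
    dy = _sign_pairs(y[None, :], iu).astype(np.float32)
    ties_y = float((dy[0] == 0).sum())  # invariant under permutation
    denom = np.sqrt((n0 - ties_templates) * (n0 - ties_y))
    if np.any(denom == 0):
        return RhythmTestResult(
            "jtk_template", np.nan, 1.0, None, None, config.to_dict(),
            {"constant_series": True},
        )

    def max_tau(d_rows: np.ndarray) -> np.ndarray:
        taus = (d_rows @ d_templates.T) / denom  # (m, G)
        return taus

    obs_taus = max_tau(dy)[0]
    g = int(np.argmax(obs_taus))
    observed = float(obs_taus[g])

    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_permutations)
    done = 0
    while done < config.n_permutations:
        m = min(_PERM_BLOCK, config.n_permutations - done)
        Y = _permuted_values(y, m, rng)
        d_perm = _sign_pairs(Y, iu).astype(np.float32)
        null[done : done + m] = max_tau(d_perm).max(axis=1)
        done += m
    return RhythmTestResult(
        method="jtk_template",
        statistic=observed,
        p_value=_permutation_pvalue(observed, null),
        period_estimate=grid[g][0],
        phase_estimate=grid[g][1],
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# RAIN-style umbrella test
# ---------------------------------------------------------------------------

def _umbrella_layout(tc: TimeCourse, period: float):
    """Fold times modulo the period into ordered groups; build per-peak masks."""
    t_idx = tc.observation_time_index()
    folded = np.mod(tc.times, period)
    positions = np.unique(folded)
    group_of_time = np.searchsorted(positions, folded)
    g = group_of_time[t_idx]  # group of each observation
    sizes = np.bincount(g, minlength=positions.size).astype(float)
    return positions, g, sizes


def _mack_wolfe_moments(sizes: np.ndarray, k: int) -> tuple[float, float]:
    """Null mean and variance of the umbrella statistic peaked at group k."""
    n = sizes
    N1 = n[: k + 1].sum()
    N2 = n[k:].sum()
    N = n.sum()
    sq = (n**2).sum()
    mean = (N1**2 + N2**2 - sq - n[k] ** 2) / 4.0
    var = (
        2.0 * (N1**3 + N2**3)
        + 3.0 * (N1**2 + N2**2)
        - (n**2 * (2.0 * n + 3.0)).sum()
        - n[k] ** 2 * (2.0 * n[k] + 3.0)
        + 12.0 * n[k] * N1 * N2
        - 12.0 * n[k] ** 2 * N
    ) / 72.0
    return float(mean), float(var)


def umbrella_rain_test(
    tc: TimeCourse, config: RhythmTestConfig | None = None
) -> RhythmTestResult:
    """RAIN-style rank test: rise to an unknown peak position, then fall.

    Times are folded modulo ``config.period``; for every candidate peak
    position a Mack-Wolfe umbrella statistic is assembled from pairwise
    Mann-Whitney counts (ties counted 1/2) and standardized by its null
    moments; the statistic is the maximum over peak positions and its
    p-value comes from the shared max-over-grid permutation null.
    """
    config = config or RhythmTestConfig()
    period = config.period
    if period > np.ptp(tc.times):
        warnings.warn(f"period {period} h exceeds the data span", stacklevel=2)
    positions, g, sizes = _umbrella_layout(tc, period)
    n_groups = positions.size
    if n_groups < 5:
        raise ValueError("need >= 5 distinct time points within one period")
    t, y = tc.observations()
    n = y.size

    # candidate peaks need >= 2 groups on each arm
    peaks = [k for k in range(n_groups) if k >= 1 and n_groups - k >= 2]
    masks = []
    moments = []
    gi = g[:, None]
    gj = g[None, :]
    for k in peaks:
        rising = (gi < gj) & (gj <= k)  # count y_u < y_v
        falling = (gj >= k) & (gj < gi)  # falling arm: count y_v > y_u reversed
        masks.append((rising | falling).ravel().astype(np.float32))
        moments.append(_mack_wolfe_moments(sizes, k))
    M = np.stack(masks)  # (P_k, n*n)
    mu = np.array([m for m, _ in moments])
    sd = np.sqrt(np.maximum([v for _, v in moments], 1e-300))

    def stats_for(Y: np.ndarray) -> np.ndarray:
        less = (Y[:, :, None] < Y[:, None, :]).astype(np.float32)
        ties = (Y[:, :, None] == Y[:, None, :]).astype(np.float32)
        C = (less + 0.5 * ties).reshape(Y.shape[0], -1)
        A = C @ M.T  # (m, P_k)
        return (A - mu) / sd

    obs = stats_for(y[None, :])[0]
    k_best = int(np.argmax(obs))
    observed = float(obs[k_best])

    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_permutations)
    done = 0
    block = max(1, min(_PERM_BLOCK, 2_000_000 // (n * n)))
    while done < config.n_permutations:
        m = min(block, config.n_permutations - done)
        Y = _permuted_values(y, m, rng)
        null[done : done + m] = stats_for(Y).max(axis=1)
        done += m
    return RhythmTestResult(
        method="umbrella_rain",
        statistic=observed,
        p_value=_permutation_pvalue(observed, null),
        period_estimate=period,
        phase_estimate=float(positions[peaks[k_best]]),
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# harmonic regression and differential rhythmicity
# ---------------------------------------------------------------------------

@dataclass
class HarmonicFit:
    """First-harmonic regression ``y ~ mesor + bc*cos(2 pi t/p) + bs*sin(2 pi t/p)``."""

    mesor: float
    cos_coef: float
    sin_coef: float
    cov: np.ndarray  # 3x3, order (mesor, cos, sin)
    period: float
    robust: bool
    n_obs: int

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.cos_coef, self.sin_coef))

    @property
    def peak_time(self) -> float:
        """Peak of the fitted harmonic in hours, in [0, period)."""
        phi = np.arctan2(self.sin_coef, self.cos_coef)
        return float((phi * self.period / (2.0 * np.pi)) % self.period)


def _harmonic_design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * t / period
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def harmonic_regression_fit(
    tc: TimeCourse, period: float, robust: bool = False
) -> HarmonicFit:
    """Fit the first harmonic at a fixed period; robust switches OLS to Huber."""
    t, y = tc.observations()
    if y.size < 4:
        raise ValueError("need >= 4 present observations")
    X = _harmonic_design(t, period)
    if np.linalg.cond(X) > 1e8:
        raise ValueError(
            f"collinear harmonic design at period {period} h (aliasing with the sampling grid)"
        )
    if robust:
        import statsmodels.api as sm

        res = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        beta = np.asarray(res.params)
        cov = np.asarray(res.bcov_scaled)
    else:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(y.size - 3, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
    return HarmonicFit(
        mesor=float(beta[0]),
        cos_coef=float(beta[1]),
        sin_coef=float(beta[2]),
        cov=cov,
        period=float(period),
        robust=robust,
        n_obs=y.size,
    )


def _wald_statistic(fa: HarmonicFit, fb: HarmonicFit) -> float:
    d = np.array([fa.cos_coef - fb.cos_coef, fa.sin_coef - fb.sin_coef])
    V = fa.cov[1:, 1:] + fb.cov[1:, 1:]
    return float(d @ np.linalg.solve(V, d))


def differential_rhythmicity_test(
    a: TimeCourse,
    b: TimeCourse,
    period: float = 24.0,
    robust: bool = True,
    n_permutations: int = 0,
    seed: int | None = None,
) -> DiffRhythmResult:
    """Test whether two series have different first-harmonic rhythms.

    Both series are linearly detrended, fitted by (robust) harmonic
    regression at the shared ``period``, and compared with a Wald quadratic
    form on the difference of the (cos, sin) coefficient pairs against a
    chi-squared(2) reference. With ``n_permutations > 0`` the p-value comes
    instead from shuffling values between the two series within each time
    point (OLS fits, for tractability).
    """
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        sa, sb = set(a.times.tolist()), set(b.times.tolist())
        raise ValueError(
            f"time grids differ; unmatched times: {sorted(sa ^ sb) or 'same set, different order'}"
        )
    da = linear_detrend(a)
    db = linear_detrend(b)
    fa = harmonic_regression_fit(da, period, robust=robust)
    fb = harmonic_regression_fit(db, period, robust=robust)
    W = _wald_statistic(fa, fb)

    if n_permutations > 0:
        p = _diff_permutation_p(da, db, period, W, n_permutations, seed)
        method = "label_permutation"
    else:
        p = float(stats.chi2.sf(W, df=2))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        method = "wald_chi2_robust" if robust else "wald_chi2"
    return DiffRhythmResult(
        statistic=W,
        p_value=p,
        fit_a=fa,
        fit_b=fb,
        detrend_a=da.meta["detrend"],
        detrend_b=db.meta["detrend"],
        period=period,
        method=method,
    )


def _ols_wald_batch(Ya, Yb, pa, Xa, Xb) -> np.ndarray:
    """Wald statistics for batches of (a, b) observation vectors (OLS fits)."""
    beta_a = Ya @ pa["pinv_a"].T
    beta_b = Yb @ pa["pinv_b"].T
    ra = Ya - beta_a @ Xa.T
    rb = Yb - beta_b @ Xb.T
    s2a = (ra**2).sum(axis=1) / max(Ya.shape[1] - 3, 1)
    s2b = (rb**2).sum(axis=1) / max(Yb.shape[1] - 3, 1)
    Va = s2a[:, None, None] * pa["xtxi_a"][None, 1:, 1:]
    Vb = s2b[:, None, None] * pa["xtxi_b"][None, 1:, 1:]
    V = Va + Vb
    d = beta_a[:, 1:] - beta_b[:, 1:]
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
    w = (
        d[:, 0] ** 2 * V[:, 1, 1]
        - 2.0 * d[:, 0] * d[:, 1] * V[:, 0, 1]
        + d[:, 1] ** 2 * V[:, 0, 0]
    ) / det
    return w


def _diff_permutation_p(
    da: TimeCourse,
    db: TimeCourse,
    period: float,
    observed_robust_W: float,
    n_permutations: int,
    seed: int | None,
) -> float:
    ta, ya = da.observations()
    tb, yb = db.observations()
    Xa = _harmonic_design(ta, period)
    Xb = _harmonic_design(tb, period)
    pre = {
        "pinv_a": np.linalg.pinv(Xa),
        "pinv_b": np.linalg.pinv(Xb),
        "xtxi_a": np.linalg.inv(Xa.T @ Xa),
        "xtxi_b": np.linalg.inv(Xb.T @ Xb),
    }
    observed = _ols_wald_batch(ya[None, :], yb[None, :], pre, Xa, Xb)[0]

    rng = np.random.default_rng(seed)
    # shuffle pooled values within each time point, across both conditions
    ia = da.observation_time_index()
    ib = db.observation_time_index()
    pooled = np.concatenate([ya, yb])
    owner_a = np.concatenate([np.ones_like(ia, bool), np.zeros_like(ib, bool)])
    tidx = np.concatenate([ia, ib])
    null = np.empty(n_permutations)
    order = np.argsort(tidx, kind="stable")
    tidx_sorted = tidx[order]
    bounds = np.searchsorted(tidx_sorted, np.arange(tidx.max() + 2))
    done = 0
    while done < n_permutations:
        m = min(_PERM_BLOCK, n_permutations - done)
        P = np.tile(pooled[order], (m, 1))
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s > 1:
                P[:, s:e] = rng.permuted(P[:, s:e], axis=1)
        back = np.empty_like(P)
        back[:, order] = P
        null[done : done + m] = _ols_wald_batch(
            back[:, owner_a], back[:, ~owner_a], pre, Xa, Xb
        )
        done += m
    return _permutation_pvalue(observed, null)
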