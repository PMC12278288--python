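"""Per-variable contribution statistics for a fitted clustering.

For each indicator we ask how strongly it separates the clusters of its own
theme, reporting three quantities side by side:

* a Shapiro–Wilk normality flag (the rationale for preferring rank-based
  and robust statistics over ANOVA);
* the Kruskal–Wallis H statistic with its chi-square p-value — a rank-based
  k-sample location test, robust to non-normality;
* a robust R² from an MM-regression fit of the one-way group-means model —
  the proportion of (outlier-downweighted) variance the cluster labels
  explain.

Kruskal–Wallis and the MM estimator are implemented here; Shapiro–Wilk
delegates to scipy's vetted routine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .data_io import IndicatorTable
from .errors import DegenerateInputError, ValidationError

# Tukey bisquare tuning constants: c0 gives the S-estimate a 50% breakdown
# point, c1 gives the final M-step 95% efficiency at the Gaussian model.
_C0 = 1.547645
_C1 = 4.685061


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalityResult:
    w_stat: float
    p_value: float


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk W and p for a sample of 3..5000 non-constant values."""
    y = np.asarray(values, float)
    if not 3 <= y.size <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={y.size}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(y)
    return NormalityResult(w_stat=float(w), p_value=float(p))


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal–Wallis H with mid-rank tie correction and chi-square p-value.

    H = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N).  All-identical values give
    (H=0, p=1) by convention.
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValidationError("values and groups must have equal length")
    labels = np.unique(g)
    if labels.size < 2:
        raise ValidationError("Kruskal-Wallis requires at least 2 groups")
    n = y.size
    if np.ptp(y) == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(y)  # mid-ranks for ties
    h = 0.0
    for lab in labels:
        r = ranks[g == lab]
        h += r.size * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(y, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)
    if tie <= 0:
        return 0.0, 1.0
    h /= tie
    p = float(sps.chi2.sf(h, labels.size - 1))
    return float(h), max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# MM-regression robust R^2 for the one-way layout
# ---------------------------------------------------------------------------


def _rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho, normalized to max 1."""
    v = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - v**2) ** 3


def _weight(u: np.ndarray, c: float) -> np.ndarray:
    """Bisquare IRLS weight w(u) = (1 - (u/c)^2)^2 on |u| <= c, else 0."""
    v = u / c
    w = (1.0 - v**2) ** 2
    w[np.abs(v) >= 1.0] = 0.0
    return w


def _m_scale(resid: np.ndarray, c: float = _C0, b: float = 0.5, tol: float = 1e-10) -> float:
    """Solve (1/n) sum rho_c(r/s) = b for s (the bisquare M-scale)."""
    r = np.asarray(resid, float)
    if np.all(r == 0):
        return 0.0
    s = np.median(np.abs(r)) / 0.6745
    if s == 0:
        s = np.abs(r[r != 0]).mean()
    for _ in range(200):
        m = _rho(r / s, c).mean()
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


def _irls_group_means(
    y: np.ndarray, idx: list[np.ndarray], start: np.ndarray, scale: float, c: float,
    max_iter: int = 100, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for the group-means model at fixed scale; returns (coefs, weights)."""
    mu = start.copy()
    for _ in range(max_iter):
        resid = y.copy()
        for j, ix in enumerate(idx):
            resid[ix] -= mu[j]
        w = _weight(resid / scale, c)
        new_mu = mu.copy()
        for j, ix in enumerate(idx):
            wj = w[ix]
            if wj.sum() > 0:
                new_mu[j] = np.average(y[ix], weights=wj)
            # else: every point in the group fully downweighted; keep estimate
        if np.max(np.abs(new_mu - mu)) <= tol * (1 + np.max(np.abs(mu))):
            mu = new_mu
            break
        mu = new_mu
    resid = y.copy()
    for j, ix in enumerate(idx):
        resid[ix] -= mu[j]
    w = _weight(resid / scale, c) if scale > 0 else np.ones_like(y)
    return mu, w


def robust_r2(values: Sequence[float], groups: Sequence) -> float:
    """Robust R² of the one-way group-means model, by MM estimation.

    The fit is an S-estimate (bisquare M-scale, 50% breakdown, initialized
    at group medians and refined by IRLS) followed by an efficient M-step
    (bisquare, 95% Gaussian efficiency) at the fixed S-scale.  The returned
    statistic is the weighted robust R²

        R² = 1 - sum w_i r_i² / sum w_i (y_i - ŷ_w0)²,

    with w_i the final IRLS weights and ŷ_w0 the w-weighted grand mean
    (the weighted intercept-only fit), clipped to [0, 1].  With no
    downweighting it reduces to the classical one-way R².
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValidationError("values and groups must have equal length")
    labels = np.unique(g)
    if labels.size < 2:
        raise ValidationError("robust R^2 requires at least 2 groups")
    if np.ptp(y) == 0:
        raise DegenerateInputError("robust R^2 is undefined for a constant response")
    idx = [np.flatnonzero(g == lab) for lab in labels]

    # S-stage: group medians -> refine means and scale jointly.
    mu = np.array([np.median(y[ix]) for ix in idx])
    resid = y.copy()
    for j, ix in enumerate(idx):
        resid[ix] -= mu[j]
    scale = _m_scale(resid, c=_C0)
    if scale == 0:  # perfect fit at the medians
        return 1.0
    for _ in range(20):
        mu, _ = _irls_group_means(y, idx, mu, scale, _C0, max_iter=1)
        resid = y.copy()
        for j, ix in enumerate(idx):
            resid[ix] -= mu[j]
        new_scale = _m_scale(resid, c=_C0)
        if abs(new_scale - scale) <= 1e-9 * scale:
            scale = new_scale
            break
        scale = new_scale

    # Efficient M-step at fixed S-scale.
    mu, w = _irls_group_means(y, idx, mu, scale, _C1)
    resid = y.copy()
    for j, ix in enumerate(idx):
        resid[ix] -= mu[j]
    if w.sum() == 0:
        return 0.0
    y_w0 = np.average(y, weights=w)
    denom = float((w * (y - y_w0) ** 2).sum())
    if denom == 0:
        return 1.0
    r2 = 1.0 - float((w * resid**2).sum()) / denom
    return float(np.clip(r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Contribution table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContributionRow:
    theme: str
    variable: str
    robust_r2: float
    h_stat: float
    p_value: float
    normal_flag: bool
    n_groups: int
    p_bh: float | None = None


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def contribution_table(
    table: IndicatorTable,
    assignments: Mapping[str, Mapping[str, int]],
    bh: bool = False,
) -> list[ContributionRow]:
    """One row per variable: robust R², Kruskal–Wallis H/p, normality flag.

    ``table`` must hold screened, *unstandardized* values; ``assignments``
    maps theme -> country -> risk-ordered cluster label.  Rows are sorted by
    robust R² descending within each theme.  ``bh=True`` adds a
    Benjamini–Hochberg adjusted p column (computed across all variables).
    """
    rows: list[ContributionRow] = []
    for spec in table.themes:
        theme_assign = assignments[spec.name]
        countries = [c for c in table.countries if c in theme_assign]
        if not countries:
            raise ValidationError(f"no assigned countries for theme {spec.name!r}")
        g = np.array([theme_assign[c] for c in countries])
        theme_rows = []
        for var in spec.variables:
            y = table.values.loc[countries, var].to_numpy(float)
            h, p = kruskal_wallis(y, g)
            r2 = robust_r2(y, g)
            try:
                normal = shapiro_wilk(y).p_value >= 0.05
            except DegenerateInputError:
                normal = False
            theme_rows.append(
                ContributionRow(
                    theme=spec.name, variable=var, robust_r2=r2, h_stat=h,
                    p_value=p, normal_flag=normal, n_groups=int(np.unique(g).size),
                )
            )
        theme_rows.sort(key=lambda r: -r.robust_r2)
        rows.extend(theme_rows)
    if bh:
        adj = _benjamini_hochberg(np.array([r.p_value for r in rows]))
        rows = [
            ContributionRow(**{**r.__dict__, "p_bh": float(a)})
            for r, a in zip(rows, adj)
        ]
    return rows
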