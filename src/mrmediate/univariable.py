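"""Univariable two-sample MR estimators: Wald ratio, IVW, Egger, median, mode.

Each estimator consumes harmonized per-variant effect estimates for an
exposure (``bx``, ``sx``) and an outcome (``by``, ``sy``) and returns an
:class:`MRResults`.  The per-variant causal estimate is the Wald ratio
``by/bx`` with first-order delta-method SE ``sy/|bx|`` (exposure-side
uncertainty is ignored, which is accurate for the strongly instrumented
designs this package targets, per-variant F of order 30-600).

IVW is the inverse-variance-weighted average of Wald ratios, algebraically
the zero-intercept weighted least-squares slope of ``by`` on ``bx`` with
weights ``1/sy^2``.  The default variance model is multiplicative random
effects: the fixed-effect SE is inflated by ``sqrt(max(1, Q/df))`` where Q is
Cochran's heterogeneity statistic, so the SE is never deflated below the
fixed-effect one.  MR-Egger adds an intercept (average directional
pleiotropy) after orienting all variants to a non-negative exposure effect.
The weighted median and weighted mode are robust to subsets of invalid
instruments; their SEs come from a seeded parametric bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedDataset

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MRResults:
    """One MR estimator's fitted result.

    ``theta`` is on the outcome's analysis scale per exposure unit (log-odds
    for binary outcomes).  The CI is the normal approximation theta +/- z*se.
    ``Q`` (with ``Q_df``) is Cochran's heterogeneity statistic where defined;
    ``intercept*`` fields are populated by MR-Egger only.
    """

    method: str
    theta: float
    se: float
    n_variants: int
    Q: float = float("nan")
    Q_df: float = float("nan")
    scale: float = 1.0
    intercept: float = float("nan")
    intercept_se: float = float("nan")

    @property
    def ci_low(self) -> float:
        return self.theta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z_95 * self.se

    @property
    def pval(self) -> float:
        if self.se == 0:
            return 0.0 if self.theta != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.theta) / self.se))

    @property
    def intercept_pval(self) -> float:
        if not np.isfinite(self.intercept_se):
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.intercept) / self.intercept_se))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        lines = [
            f"Method:      {self.method}",
            f"Variants:    {self.n_variants}",
            f"Estimate:    {self.theta:.6g} (se {self.se:.6g})",
            f"95% CI:      [{self.ci_low:.6g}, {self.ci_high:.6g}]",
            f"P-value:     {self.pval:.3g}",
        ]
        if np.isfinite(self.Q):
            lines.append(f"Cochran Q:   {self.Q:.4g} on {self.Q_df:g} df")
        if np.isfinite(self.intercept_se):
            lines.append(
                f"Intercept:   {self.intercept:.6g} (se {self.intercept_se:.6g},"
                f" p {self.intercept_pval:.3g})"
            )
        return "\n".join(lines)


def _as_arrays(bx, sx, by, sy):
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
    if not (bx.shape == sx.shape == by.shape == sy.shape):
        raise ValueError("bx, sx, by, sy must have identical shapes")
    if (sy <= 0).any() or (sx < 0).any():
        raise ValueError("standard errors must be positive")
    return bx, sx, by, sy


def wald_ratio(beta_x, se_x, beta_y, se_y, second_order: bool = False) -> MRResults:
    """Per-variant causal estimate ``beta_y/beta_x``.

    SE is first-order ``se_y/|beta_x|`` by default; ``second_order`` adds the
    exposure-side term ``beta_y^2 se_x^2 / beta_x^4`` under the delta method.
    """
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0; pre-filter instruments")
    theta = beta_y / beta_x
    var = (se_y / beta_x) ** 2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return MRResults(method="wald_ratio", theta=float(theta), se=float(np.sqrt(var)), n_variants=1)


def ivw(bx, sx, by, sy, variance_model: str = "random") -> MRResults:
    """Inverse-variance-weighted estimate across all instruments.

    With a single variant this collapses exactly to the Wald ratio (with the
    heterogeneity statistic reported as missing).
    """
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    L = bx.size
    if L == 0:
        raise ValueError("no instruments")
    if (bx == 0).any():
        raise ValueError("beta_x = 0 instrument present; pre-filter instruments")
    if L == 1:
        r = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return MRResults(method="ivw", theta=r.theta, se=r.se, n_variants=1)

    w = bx**2 / sy**2  # inverse variance of each Wald ratio (first order)
    theta_i = by / bx
    theta = float(np.sum(w * theta_i) / np.sum(w))
    Q = float(np.sum(w * (theta_i - theta) ** 2))
    df = L - 1
    scale = _overdispersion(variance_model, Q, df)
    se = float(np.sqrt(1.0 / np.sum(w)) * scale)
    return MRResults(method="ivw", theta=theta, se=se, n_variants=L, Q=Q, Q_df=df, scale=scale)


def _overdispersion(variance_model: str, Q: float, df: int) -> float:
    if variance_model == "fixed":
        return 1.0
    if variance_model == "random":
        return float(np.sqrt(max(1.0, Q / df))) if df > 0 else 1.0
    raise ValueError(f"unknown variance model {variance_model!r}")


def egger(bx, sx, by, sy, variance_model: str = "random") -> MRResults:
    """MR-Egger regression: WLS of ``by`` on ``bx`` with an intercept.

    Variants are first oriented so every exposure effect is non-negative
    (both betas negated where needed), making the fit invariant to the
    arbitrary allele orientation.  The slope is the causal estimate; the
    intercept estimates average directional pleiotropy.
    """
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    L = bx.size
    if L < 3:
        raise ValueError("insufficient instruments for MR-Egger (need >= 3)")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), x])
    A = (X * w[:, None]).T @ X
    c = (X * w[:, None]).T @ y
    coef = np.linalg.solve(A, c)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    df = L - 2
    scale = _overdispersion(variance_model, Q, df)
    cov = np.linalg.inv(A) * scale**2
    return MRResults(
        method="egger",
        theta=float(coef[1]),
        se=float(np.sqrt(cov[1, 1])),
        n_variants=L,
        Q=Q,
        Q_df=df,
        scale=scale,
        intercept=float(coef[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
    )


def _weighted_median_point(theta_i: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_i, kind="mergesort")
    t = theta_i[order]
    ww = w[order]
    W = ww.sum()
    p = (np.cumsum(ww) - 0.5 * ww) / W
    return float(np.interp(0.5, p, t))


def _weighted_median_batch(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, L) ratio/weight arrays."""
    order = np.argsort(theta, axis=1, kind="mergesort")
    t = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    W = ww.sum(axis=1, keepdims=True)
    p = (np.cumsum(ww, axis=1) - 0.5 * ww) / W
    out = np.empty(theta.shape[0])
    for b in range(theta.shape[0]):
        out[b] = np.interp(0.5, p[b], t[b])
    return out


def _check_n_boot(n_boot: int) -> None:
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unreliable bootstrap SEs", stacklevel=3)


def weighted_median(bx, sx, by, sy, n_boot: int = 1000, seed: int = 0) -> MRResults:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Wald ratios are ordered and the estimate interpolates them at the 50th
    percentile of the normalized cumulative inverse-variance weights;
    consistent when valid instruments carry at least half the weight.
    """
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    if bx.size < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    _check_n_boot(n_boot)
    w = bx**2 / sy**2
    theta = _weighted_median_point(by / bx, w)

    rng = np.random.default_rng(seed)
    bxb = bx + sx * rng.standard_normal((n_boot, bx.size))
    byb = by + sy * rng.standard_normal((n_boot, bx.size))
    wb = bxb**2 / sy**2
    reps = _weighted_median_batch(byb / bxb, wb)
    se = float(np.std(reps, ddof=1))
    return MRResults(method="weighted_median", theta=theta, se=se, n_variants=bx.size)


def _mode_bandwidth(theta_i: np.ndarray, w: np.ndarray, factor: float) -> float:
    mad = np.median(np.abs(theta_i - np.median(theta_i)))
    s = 1.4826 * mad
    if s == 0.0:
        s = float(np.std(theta_i, ddof=0))  # MAD degenerate (majority tie)
    return factor * s


def _mode_point(theta_i: np.ndarray, w: np.ndarray, h: float, grid_size: int = 1024) -> float:
    if h == 0.0:
        return float(theta_i[0])  # all ratios identical
    grid = np.linspace(theta_i.min() - 3 * h, theta_i.max() + 3 * h, grid_size)
    dens = w @ np.exp(-0.5 * ((grid[None, :] - theta_i[:, None]) / h) ** 2)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    bx, sx, by, sy,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 1024,
) -> MRResults:
    """Weighted-mode MR estimate: argmax of a weighted Gaussian-kernel density
    over the Wald ratios.

    Bandwidth is ``bandwidth_factor`` times a MAD-based robust scale of the
    ratios (falling back to the SD when the MAD degenerates); consistent when
    the largest homogeneous cluster of instruments is valid.  SE by the same
    parametric bootstrap as the weighted median.
    """
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    L = bx.size
    if L < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    _check_n_boot(n_boot)
    theta_i = by / bx
    w = bx**2 / sy**2
    h = _mode_bandwidth(theta_i, w, bandwidth_factor)
    theta = _mode_point(theta_i, w, h, grid_size)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    chunk = max(1, 2_000_000 // (L * grid_size) or 1)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        bxb = bx + sx * rng.standard_normal((b, L))
        byb = by + sy * rng.standard_normal((b, L))
        tb = byb / bxb
        wb = bxb**2 / sy**2
        for i in range(b):
            hb = _mode_bandwidth(tb[i], wb[i], bandwidth_factor)
            reps[done + i] = _mode_point(tb[i], wb[i], hb, grid_size)
        done += b
    se = float(np.std(reps, ddof=1))
    return MRResults(method="weighted_mode", theta=theta, se=se, n_variants=L)


_METHODS = {
    "ivw": ivw,
    "egger": egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
}


class UnivariableMR:
    """Univariable two-sample MR model over a harmonized dataset.

    ``target`` selects the dependent trait: ``"outcome"`` (default) or a
    mediator name, so the same object estimates exposure->outcome and
    exposure->mediator associations.
    """

    def __init__(self, data: HarmonizedDataset, target: str = "outcome"):
        self.data = data
        self.target = target
        self.bx = data.exposure_beta
        self.sx = data.exposure_se
        if target == "outcome":
            self.by, self.sy = data.outcome_beta, data.outcome_se
        else:
            self.by, self.sy = data.mediator(target)

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        try:
            fn = _METHODS[method]
        except KeyError:
            raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
        return fn(self.bx, self.sx, self.by, self.sy, **kwargs)

    def fit_all(self, n_boot: int = 1000, seed: int = 0, variance_model: str = "random"):
        """IVW plus the three pleiotropy-robust sensitivity estimators."""
        return {
            "ivw": self.fit("ivw", variance_model=variance_model),
            "egger": self.fit("egger", variance_model=variance_model),
            "weighted_median": self.fit("weighted_median", n_boot=n_boot, seed=seed),
            "weighted_mode": self.fit("weighted_mode", n_boot=n_boot, seed=seed + 1),
        }
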