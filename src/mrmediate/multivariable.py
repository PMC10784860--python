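"""Multivariable MR: direct effects conditional on one or more mediators.

The direct effect of the exposure, holding the mediators fixed, is the
exposure coefficient from a zero-intercept weighted least-squares regression
of the variant-outcome effects on the L x (K+1) matrix of variant-exposure
and variant-mediator effects, with weights 1/se_outcome^2.  SEs come from
the WLS covariance with the same multiplicative overdispersion scaling used
for univariable IVW, ``sqrt(max(1, Q / (L - K - 1)))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedDataset
from .univariable import Z_95, _overdispersion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MVMRResults:
    """Fitted multivariable MR model.

    ``exposure_names[0]`` is always the exposure of interest; its coefficient
    is the direct effect reported downstream.  ``min_f`` holds the per-trait
    minimum marginal F statistic among the instruments (descriptive
    instrument-strength note, not a formal conditional-F diagnostic).
    """

    exposure_names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    n_variants: int
    Q: float
    Q_df: int
    scale: float
    min_f: tuple[float, ...] = ()

    @property
    def direct_effect(self) -> float:
        return float(self.params[0])

    @property
    def direct_se(self) -> float:
        return float(self.bse[0])

    def conf_int(self) -> np.ndarray:
        return np.column_stack([self.params - Z_95 * self.bse, self.params + Z_95 * self.bse])

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.params) / self.bse)

    def summary(self) -> str:
        ci = self.conf_int()
        p = self.pvalues
        rows = [
            f"Multivariable MR ({self.n_variants} variants, Q={self.Q:.4g} on {self.Q_df} df)",
            f"{'trait':<20}{'estimate':>12}{'se':>12}{'ci_low':>12}{'ci_high':>12}{'pval':>12}",
        ]
        for i, name in enumerate(self.exposure_names):
            rows.append(
                f"{name:<20}{self.params[i]:>12.5g}{self.bse[i]:>12.5g}"
                f"{ci[i, 0]:>12.5g}{ci[i, 1]:>12.5g}{p[i]:>12.3g}"
            )
        return "\n".join(rows)


def mvmr_fit(
    X: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    exposure_names: Sequence[str] | None = None,
    variance_model: str = "random",
    min_f: Sequence[float] = (),
) -> MVMRResults:
    """Core weighted-normal-equations solve for multivariable MR."""
    X = np.asarray(X, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    L, M = X.shape
    if L <= M:
        raise ValueError(f"need more variants ({L}) than exposures ({M})")
    if np.linalg.matrix_rank(X) < M:
        raise ValueError("collinear exposures: variant-effect matrix is rank deficient")
    w = 1.0 / sy**2
    Xw = X * w[:, None]
    A = Xw.T @ X
    coef = np.linalg.solve(A, Xw.T @ by)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    df = L - M
    scale = _overdispersion(variance_model, Q, df)
    cov = np.linalg.inv(A) * scale**2
    names = tuple(exposure_names) if exposure_names else tuple(f"x{i}" for i in range(M))
    return MVMRResults(
        exposure_names=names,
        params=coef,
        bse=np.sqrt(np.diag(cov)),
        n_variants=L,
        Q=Q,
        Q_df=df,
        scale=scale,
        min_f=tuple(min_f),
    )


class MultivariableMR:
    """Multivariable MR model over a harmonized dataset.

    ``mediator_set`` selects which mediators enter jointly with the exposure
    (default: all mediators in the dataset).
    """

    def __init__(self, data: HarmonizedDataset, mediator_set: Sequence[str] | None = None):
        self.data = data
        self.mediator_set = tuple(mediator_set if mediator_set is not None else data.mediator_names)
        unknown = set(self.mediator_set) - set(data.mediator_names)
        if unknown:
            raise KeyError(f"mediator(s) not in dataset: {sorted(unknown)}")

    def design_matrix(self) -> np.ndarray:
        cols = [self.data.exposure_beta]
        for m in self.mediator_set:
            cols.append(self.data.mediator(m)[0])
        return np.column_stack(cols)

    def fit(self, variance_model: str = "random") -> MVMRResults:
        X = self.design_matrix()
        ses = [self.data.exposure_se] + [self.data.mediator(m)[1] for m in self.mediator_set]
        min_f = tuple(float(np.min((X[:, i] / ses[i]) ** 2)) for i in range(X.shape[1]))
        return mvmr_fit(
            X,
            self.data.outcome_beta,
            self.data.outcome_se,
            exposure_names=("exposure", *self.mediator_set),
            variance_model=variance_model,
            min_f=min_f,
        )


def mvmr(
    data: HarmonizedDataset,
    mediator_set: Sequence[str] | None = None,
    variance_model: str = "random",
) -> MVMRResults:
    """Direct effect of the exposure conditional on ``mediator_set``."""
    return MultivariableMR(data, mediator_set).fit(variance_model=variance_model)
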