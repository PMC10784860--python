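"""Proportion-mediated analysis combining total and direct MR estimates.

The proportion of an exposure-outcome association explained by a mediator
set is the difference-method statistic

    PM = 1 - theta_direct / theta_total

with the total effect from univariable IVW and the direct effect from
multivariable MR, both on the analysis scale (log-odds for binary outcomes).
PM is deliberately not clamped to [0, 1]: negative values (a mediator set
that amplifies rather than attenuates) and values above 1 are meaningful and
occur in practice.  Uncertainty comes from a seeded bootstrap: per replicate
the total and direct effects are re-fitted and the replicate PMs give the SE
and percentile CI.  The default resampling unit is the variant (instruments
drawn with replacement), which stays calibrated when instruments are
heterogeneous — e.g. mediator-specific genetic effects make per-variant
outcome associations overdispersed relative to their nominal SEs, and a
parametric resample from those SEs then understates the uncertainty.  The
parametric scheme (every harmonized beta redrawn from a normal centred at
its estimate with its SE) remains available as ``mode="parametric"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .multivariable import MultivariableMR, MVMRResults
from .sumstats import (
    HarmonizedDataset,
    SummaryStats,
    harmonize,
    instrument_diagnostics,
    read_summary_stats,
    select_instruments,
)
from .univariable import MRResults, UnivariableMR, ivw

logger = logging.getLogger(__name__)


def proportion_mediated(theta_total: float, theta_direct: float, floor: float = 1e-6) -> float:
    """PM = 1 - direct/total; NaN (with a warning) for a near-null total."""
    if abs(theta_total) < floor:
        warnings.warn(
            f"|theta_total| = {abs(theta_total):.3g} below floor {floor:g}; "
            "proportion mediated undefined", stacklevel=2,
        )
        return float("nan")
    return 1.0 - theta_direct / theta_total


@dataclass(frozen=True)
class MediationResults:
    """Total effect, direct effect and proportion mediated for one mediator set."""

    outcome: str
    mediator_set: tuple[str, ...]
    total: MRResults
    direct: MVMRResults
    pm: float
    pm_se: float
    pm_ci: tuple[float, float]
    n_boot: int
    seed: int
    n_dropped: int = 0
    unstable: bool = False

    @property
    def theta_total(self) -> float:
        return self.total.theta

    @property
    def theta_direct(self) -> float:
        return self.direct.direct_effect

    def summary(self) -> str:
        lines = [
            f"Outcome:            {self.outcome}",
            f"Mediators:          {' + '.join(self.mediator_set) or '(none)'}",
            f"Total effect:       {self.theta_total:.6g} (se {self.total.se:.6g})",
            f"Direct effect:      {self.theta_direct:.6g} (se {self.direct.direct_se:.6g})",
            f"Proportion mediated: {self.pm:.4g} (se {self.pm_se:.4g}, "
            f"95% CI [{self.pm_ci[0]:.4g}, {self.pm_ci[1]:.4g}])",
            f"Bootstrap:          {self.n_boot} replicates, {self.n_dropped} dropped"
            + (" [UNSTABLE: >10% of replicates near-null total]" if self.unstable else ""),
        ]
        return "\n".join(lines)


def _batch_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise zero-intercept WLS slope for (B, L) arrays."""
    return np.sum(w * bx * by, axis=-1) / np.sum(w * bx * bx, axis=-1)


def _batch_mvmr(X: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted normal-equations solve; X is (B, L, M), returns (B, M)."""
    Xw = X * w[..., None]
    A = np.einsum("blm,bln->bmn", Xw, X)
    c = np.einsum("blm,bl->bm", Xw, by)
    return np.linalg.solve(A, c[..., None])[..., 0]


class MRMediation:
    """Mediation model for one harmonized dataset and one mediator set.

    ``fit`` computes the point estimates from the original data (IVW total,
    MVMR direct, PM) and bootstrap uncertainty for PM.
    """

    def __init__(self, data: HarmonizedDataset, mediator_set: Sequence[str] | None = None,
                 outcome_label: str = "outcome"):
        if data.n_mediators == 0:
            raise ValueError("mediation requires at least one mediator in the dataset")
        self.data = data
        self.mediator_set = tuple(mediator_set if mediator_set is not None else data.mediator_names)
        self.outcome_label = outcome_label

    def fit(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        floor: float = 1e-6,
        mode: str = "variant",
        variance_model: str = "random",
    ) -> MediationResults:
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        d = self.data
        total = UnivariableMR(d).fit("ivw", variance_model=variance_model)
        mv = MultivariableMR(d, self.mediator_set)
        direct = mv.fit(variance_model=variance_model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm_point = proportion_mediated(total.theta, direct.direct_effect, floor)
        if not np.isfinite(pm_point):
            warnings.warn("total effect below floor; PM point estimate undefined")

        bx, sx = d.exposure_beta, d.exposure_se
        by, sy = d.outcome_beta, d.outcome_se
        BM = np.column_stack([d.mediator(m)[0] for m in self.mediator_set])
        SM = np.column_stack([d.mediator(m)[1] for m in self.mediator_set])
        L = bx.size

        rng = np.random.default_rng(seed)
        if mode == "parametric":
            bx_b = bx + sx * rng.standard_normal((n_boot, L))
            by_b = by + sy * rng.standard_normal((n_boot, L))
            BM_b = BM + SM * rng.standard_normal((n_boot, L, BM.shape[1]))
            w_b = np.broadcast_to(1.0 / sy**2, (n_boot, L))
        elif mode == "variant":
            idx = rng.integers(0, L, size=(n_boot, L))
            bx_b, by_b = bx[idx], by[idx]
            BM_b = BM[idx]
            w_b = 1.0 / sy[idx] ** 2
        else:
            raise ValueError(f"unknown bootstrap mode {mode!r}")

        total_b = _batch_ivw(bx_b, by_b, w_b)
        X_b = np.concatenate([bx_b[..., None], BM_b], axis=2)
        direct_b = _batch_mvmr(X_b, by_b, w_b)[:, 0]

        ok = np.abs(total_b) >= floor
        n_dropped = int(n_boot - ok.sum())
        pm_b = 1.0 - direct_b[ok] / total_b[ok]
        if pm_b.size < 2:
            pm_se, ci = float("nan"), (float("nan"), float("nan"))
        else:
            pm_se = float(np.std(pm_b, ddof=1))
            ci = tuple(np.percentile(pm_b, [2.5, 97.5]).tolist())
        unstable = n_dropped > 0.1 * n_boot
        if unstable:
            logger.warning(
                "%d/%d bootstrap replicates dropped (near-null total); CI unstable",
                n_dropped, n_boot,
            )
        return MediationResults(
            outcome=self.outcome_label,
            mediator_set=self.mediator_set,
            total=total,
            direct=direct,
            pm=pm_point,
            pm_se=pm_se,
            pm_ci=ci,
            n_boot=n_boot,
            seed=seed,
            n_dropped=n_dropped,
            unstable=unstable,
        )


def bootstrap_mediation(
    data: HarmonizedDataset,
    mediator_set: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    floor: float = 1e-6,
    mode: str = "variant",
    variance_model: str = "random",
) -> MediationResults:
    """Functional form of :meth:`MRMediation.fit`."""
    return MRMediation(data, mediator_set).fit(
        n_boot=n_boot, seed=seed, floor=floor, mode=mode, variance_model=variance_model
    )


# ---------------------------------------------------------------------------
# the full analysis suite
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "outcome", "analysis", "mediator_set", "method", "n_variants",
    "estimate", "se", "ci_low", "ci_high", "pval",
    "Q", "Q_df", "egger_intercept", "egger_intercept_se",
    "odds_ratio", "or_ci_low", "or_ci_high",
    "pm", "pm_se", "pm_ci_low", "pm_ci_high", "status",
]


def _row(outcome, analysis, mediator_set, res: MRResults | None, *,
         binary=False, status="ok", **extra):
    row = dict.fromkeys(_RESULT_COLUMNS, np.nan)
    row.update(outcome=outcome, analysis=analysis,
               mediator_set="+".join(mediator_set) if mediator_set else "", status=status)
    if res is not None:
        row.update(
            method=res.method, n_variants=res.n_variants, estimate=res.theta,
            se=res.se, ci_low=res.ci_low, ci_high=res.ci_high, pval=res.pval,
            Q=res.Q, Q_df=res.Q_df,
            egger_intercept=res.intercept, egger_intercept_se=res.intercept_se,
        )
        if binary:
            row.update(
                odds_ratio=np.exp(res.theta),
                or_ci_low=np.exp(res.ci_low),
                or_ci_high=np.exp(res.ci_high),
            )
    return row


class MediationSuiteResults:
    """Master results of a full run: one table plus the fitted objects."""

    def __init__(self, table: pd.DataFrame, mediation: Mapping, diagnostics,
                 reports: Mapping[str, pd.DataFrame]):
        self.table = table
        self.mediation = dict(mediation)       # (outcome, mediator_set) -> MediationResults
        self.diagnostics = diagnostics         # exposure InstrumentDiagnostics
        self.reports = dict(reports)           # outcome -> harmonization flag table

    def forest_text(self, outcome: str) -> str:
        """Plain-text forest-style summary for one outcome."""
        sub = self.table[(self.table["outcome"] == outcome) & (self.table["status"] == "ok")]
        lines = [f"=== {outcome} ===",
                 f"{'analysis':<24}{'mediators':<22}{'estimate':>10}{'ci':>24}"]
        for _, r in sub.iterrows():
            if not np.isfinite(r["estimate"]):
                continue
            ci = f"[{r['ci_low']:.3g}, {r['ci_high']:.3g}]"
            label = r["mediator_set"] or "-"
            lines.append(f"{r['analysis']:<24}{label:<22}{r['estimate']:>10.3g}{ci:>24}")
            if r["analysis"] == "proportion_mediated":
                lines[-1] += f"  PM={r['pm']:.2%}"
        return "\n".join(lines)


def run_mediation_suite(config: AnalysisConfig | Mapping | str) -> MediationSuiteResults:
    """Execute the full pipeline described by ``config``.

    Stages: read -> instrument selection -> harmonization -> univariable
    total effects (plus sensitivity estimators), exposure->mediator and
    mediator->outcome associations -> multivariable direct effects -> PM with
    bootstrap CIs.  Mediator sets are each single mediator plus all mediators
    combined.  A failure in any row is recorded in its ``status`` and the
    suite continues.
    """
    if isinstance(config, (str,)) or hasattr(config, "__fspath__"):
        cfg = AnalysisConfig.from_yaml(config)
    elif isinstance(config, AnalysisConfig):
        cfg = config
    else:
        cfg = AnalysisConfig.from_dict(config)
    cfg.check_paths()

    exposure = read_summary_stats(cfg.exposure.path, cfg.exposure.column_map,
                                  name="exposure", trait_type=cfg.exposure.trait_type)
    mediators = {
        m.name: read_summary_stats(m.path, m.column_map, name=m.name, trait_type=m.trait_type)
        for m in cfg.mediators
    }
    outcomes = {
        o.name: read_summary_stats(o.path, o.column_map, name=o.name, trait_type=o.trait_type)
        for o in cfg.outcomes
    }
    ld = None
    if cfg.ld_path is not None:
        ld = pd.read_csv(cfg.ld_path, sep="\t", index_col=0)

    exp_instruments = select_instruments(exposure, cfg.p_threshold, ld, cfg.r2_threshold)
    med_instruments = {}
    for name, tab in mediators.items():
        try:
            med_instruments[name] = select_instruments(tab, cfg.p_threshold, ld, cfg.r2_threshold)
        except ValueError:
            logger.warning("no instruments for mediator %s at threshold", name)
            med_instruments[name] = []

    rows: list[dict] = []
    mediation_results: dict = {}
    reports: dict[str, pd.DataFrame] = {}
    diagnostics = None
    hkw = dict(policy=cfg.palindromic_policy, eaf_window=cfg.eaf_window)
    sets = cfg.resolved_mediator_sets()

    # exposure -> mediator associations (outcome-independent)
    for name, tab in mediators.items():
        try:
            h = harmonize(exposure, tab, instruments=exp_instruments, **hkw)
            model = UnivariableMR(h)
            rows.append(_row("", "exposure_to_mediator", (name,),
                             model.fit("ivw", variance_model=cfg.variance_model),
                             binary=tab.trait_type == "binary"))
            if cfg.sensitivity:
                for meth, res in _sensitivity(model, cfg).items():
                    rows.append(_row("", "exposure_to_mediator", (name,), res,
                                     binary=tab.trait_type == "binary"))
        except Exception as exc:  # recorded, suite continues
            rows.append(_row("", "exposure_to_mediator", (name,), None, status=str(exc)))

    for oname, otab in outcomes.items():
        binary = otab.trait_type == "binary"
        # total effect
        try:
            h_tot = harmonize(exposure, otab, instruments=exp_instruments, **hkw)
            if diagnostics is None:
                diagnostics = instrument_diagnostics(h_tot)
            reports[oname] = h_tot.flags
            model = UnivariableMR(h_tot)
            rows.append(_row(oname, "total", (),
                             model.fit("ivw", variance_model=cfg.variance_model), binary=binary))
            if cfg.sensitivity:
                for meth, res in _sensitivity(model, cfg).items():
                    rows.append(_row(oname, "total", (), res, binary=binary))
        except Exception as exc:
            rows.append(_row(oname, "total", (), None, status=str(exc)))

        # mediator -> outcome associations (mediator's own instruments)
        for mname, mtab in mediators.items():
            try:
                if not med_instruments[mname]:
                    raise ValueError("no instruments for mediator")
                h_mo = harmonize(mtab, otab, instruments=med_instruments[mname], **hkw)
                rows.append(_row(oname, "mediator_to_outcome", (mname,),
                                 UnivariableMR(h_mo).fit("ivw", variance_model=cfg.variance_model),
                                 binary=binary))
            except Exception as exc:
                rows.append(_row(oname, "mediator_to_outcome", (mname,), None, status=str(exc)))

        # direct effects and proportion mediated per mediator set
        for si, mset in enumerate(sets):
            try:
                instruments = _mvmr_instruments(cfg, exposure, mediators, mset,
                                                exp_instruments, med_instruments, ld)
                h_mv = harmonize(exposure, otab, {m: mediators[m] for m in mset},
                                 instruments=instruments, **hkw)
                med = MRMediation(h_mv, mset, outcome_label=oname).fit(
                    n_boot=cfg.n_boot, seed=cfg.seed + 7919 * si,
                    floor=cfg.pm_floor, variance_model=cfg.variance_model,
                )
                mediation_results[(oname, mset)] = med
                rows.append(_row(oname, "direct", mset,
                                 MRResults(method="mvmr_ivw", theta=med.theta_direct,
                                           se=med.direct.direct_se,
                                           n_variants=med.direct.n_variants,
                                           Q=med.direct.Q, Q_df=med.direct.Q_df),
                                 binary=binary))
                pm_row = _row(oname, "proportion_mediated", mset, None,
                              status="unstable" if med.unstable else "ok")
                pm_row.update(method="bootstrap", n_variants=med.direct.n_variants,
                              estimate=med.pm, se=med.pm_se,
                              ci_low=med.pm_ci[0], ci_high=med.pm_ci[1],
                              pm=med.pm, pm_se=med.pm_se,
                              pm_ci_low=med.pm_ci[0], pm_ci_high=med.pm_ci[1])
                rows.append(pm_row)
            except Exception as exc:
                rows.append(_row(oname, "direct", mset, None, status=str(exc)))
                rows.append(_row(oname, "proportion_mediated", mset, None, status=str(exc)))

    table = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    return MediationSuiteResults(table, mediation_results, diagnostics, reports)


def _sensitivity(model: UnivariableMR, cfg: AnalysisConfig) -> dict[str, MRResults]:
    out = {}
    for meth, kwargs in (
        ("egger", {"variance_model": cfg.variance_model}),
        ("weighted_median", {"n_boot": cfg.sensitivity_n_boot, "seed": cfg.seed}),
        ("weighted_mode", {"n_boot": cfg.sensitivity_n_boot, "seed": cfg.seed + 1,
                           "bandwidth_factor": cfg.bandwidth_factor}),
    ):
        try:
            out[meth] = model.fit(meth, **kwargs)
        except Exception as exc:
            logger.warning("sensitivity estimator %s failed: %s", meth, exc)
    return out


def _mvmr_instruments(cfg, exposure, mediators, mset, exp_instruments, med_instruments, ld):
    """Instrument set for MVMR: exposure-only, or the pruned per-trait union."""
    if cfg.mvmr_instruments == "exposure":
        return list(exp_instruments)
    union = set(exp_instruments)
    for m in mset:
        union |= set(med_instruments[m])
    # prune the union as a single set, ranking by the best p-value across traits
    frames = [exposure.df[["variant_id", "pval"]]]
    frames += [mediators[m].df[["variant_id", "pval"]] for m in mset]
    allp = pd.concat(frames).groupby("variant_id")["pval"].min()
    allp = allp[allp.index.isin(union)]
    pooled = SummaryStats(pd.DataFrame({
        "variant_id": allp.index,
        "effect_allele": "A", "other_allele": "G",   # placeholders; ranking only
        "beta": 1.0, "se": 1.0, "pval": allp.to_numpy(),
    }), name="union")
    return select_instruments(pooled, p_threshold=np.inf, ld=ld, r2_threshold=cfg.r2_threshold)
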