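"""Synthetic two-sample GWAS summary statistics with known mediation structure.

The generator encodes a linear structural model for one exposure, K mediators
and one outcome:

    exposure  X  = sum_i gamma_i G_i + e_x
    mediator  M_k = alpha_k X + sum_i delta_ik G_i + e_k
    outcome   Y  = theta_direct X + sum_k beta_k M_k + sum_i p_i G_i + e_y

so the marginal (per-allele) variant effects are

    variant -> exposure : gamma_i
    variant -> mediator : gamma_i alpha_k + delta_ik
    variant -> outcome  : gamma_i theta_total + sum_k delta_ik beta_k + p_i

with theta_total = theta_direct + sum_k alpha_k beta_k.  Summary statistics
are produced directly on this scale: each trait's estimated effect is the
true marginal effect plus independent Normal(0, SE) noise, with the SE in
closed form from the trait's GWAS sample size and allele frequency.  Binary
traits are simulated on the log-odds scale, matching how case-control GWAS
report effects.  Independent noise draws per trait emulate the two-sample
(non-overlapping cohorts) design.

The per-mediator variant effects ``delta_ik`` are genuine mediator-specific
genetics (e.g. BMI loci that do not act through the exposure).  They are on
by default because without them the variant->mediator effects are exactly
proportional to the variant->exposure effects and the multivariable
regression that separates direct from mediated paths is unidentified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: ordered allele pairs that read the same on both strands (undecidable strand)
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NON_PALINDROMIC_PAIRS = tuple(
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and b != COMPLEMENT[a]
)

#: reference exposure GWAS size used to convert instrument F statistics into
#: per-allele effects (the scale of a ~3-million-person education GWAS)
DEFAULT_REFERENCE_N = 3_037_499


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueModel:
    """Ground-truth structural parameters of one synthetic study.

    All vectors are per-variant (length ``n_variants``); ``alpha``/``beta_med``
    are per-mediator (length K).  ``gamma`` is in exposure-SD units per
    effect-allele copy; the effect allele is by construction the
    exposure-increasing allele, so ``gamma >= 0``.
    """

    gamma: np.ndarray
    eaf: np.ndarray
    alpha: np.ndarray
    beta_med: np.ndarray
    delta: np.ndarray            # (n_variants, K) mediator-specific effects
    theta_direct: float
    pleio: np.ndarray            # per-variant direct variant->outcome effects
    pleio_mean: float
    pleio_sd: float
    outcome_type: str            # "binary" (log-odds scale) or "continuous"
    case_fraction: float | None
    mediator_names: tuple[str, ...]
    mediator_types: tuple[str, ...]
    mediator_case_fractions: tuple[float | None, ...]
    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    ld_blocks: tuple[int, float] | None
    seed: int

    @property
    def n_variants(self) -> int:
        return int(self.gamma.size)

    @property
    def n_mediators(self) -> int:
        return int(self.alpha.size)

    @property
    def theta_total(self) -> float:
        """Total exposure->outcome effect: direct plus all mediated paths."""
        return float(self.theta_direct + self.alpha @ self.beta_med)

    @property
    def proportion_mediated(self) -> float:
        """True proportion mediated, 1 - direct/total (NaN for a null total)."""
        total = self.theta_total
        if total == 0.0:
            return float("nan")
        return 1.0 - self.theta_direct / total

    def marginal_effects(self, trait: str) -> np.ndarray:
        """True per-allele marginal effect of every variant on ``trait``."""
        if trait == "exposure":
            return self.gamma.copy()
        if trait == "outcome":
            return (
                self.gamma * self.theta_total
                + self.delta @ self.beta_med
                + self.pleio
            )
        if trait in self.mediator_names:
            k = self.mediator_names.index(trait)
            return self.gamma * self.alpha[k] + self.delta[:, k]
        raise KeyError(f"unknown trait {trait!r}")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return ("exposure", *self.mediator_names, "outcome")

    def expected_f(self, n: int, sigma: float = 1.0) -> np.ndarray:
        """Noncentral expectation of the per-variant exposure F statistic."""
        return n * self.gamma**2 * 2 * self.eaf * (1 - self.eaf) / sigma**2 + 1

    def variance_explained(self) -> float:
        """Analytic exposure variance explained by all variants jointly."""
        return float(np.sum(2 * self.eaf * (1 - self.eaf) * self.gamma**2))

    def to_json(self, path: str | Path) -> None:
        """Write the ground truth as a structured text sidecar."""
        payload = {
            "n_variants": self.n_variants,
            "seed": self.seed,
            "theta_direct": self.theta_direct,
            "theta_total": self.theta_total,
            "proportion_mediated": self.proportion_mediated,
            "alpha": self.alpha.tolist(),
            "beta_med": self.beta_med.tolist(),
            "mediator_names": list(self.mediator_names),
            "pleio_mean": self.pleio_mean,
            "pleio_sd": self.pleio_sd,
            "outcome_type": self.outcome_type,
            "case_fraction": self.case_fraction,
            "variance_explained": self.variance_explained(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def build_true_model(config: Mapping[str, Any]) -> TrueModel:
    """Draw the structural parameters of a synthetic study from ``config``.

    Deterministic for a fixed ``config['seed']``.  Recognised keys (all have
    defaults except ``seed`` which defaults to 0):

    ``n_variants``, ``seed``, ``eaf_range``,
    ``gamma`` -- either ``{"kind": "instrument_f", "f_min", "f_mean",
    "reference_n"}`` (per-variant F at the reference GWAS size drawn as
    ``f_min + Exponential(f_mean - f_min)``) or ``{"kind": "normal", "sd"}``,
    ``mediators`` -- list of ``{"name", "alpha", "beta", "type",
    "case_fraction", "delta_sd"}``,
    ``theta_direct``, ``pleio_mean``, ``pleio_sd``,
    ``outcome_type``, ``case_fraction``, ``ld_blocks`` (``[block_size, rho]``),
    ``palindromic_fraction``, ``outcome_seed``, ``mediation`` (bool flag:
    require at least one mediator).
    """
    cfg = dict(config)
    n_variants = int(cfg.get("n_variants", 500))
    seed = int(cfg.get("seed", 0))
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")

    mediators = list(cfg.get("mediators", []))
    if cfg.get("mediation", False) and not mediators:
        raise ValueError("mediation requested but no mediators configured")

    outcome_type = str(cfg.get("outcome_type", "binary"))
    if outcome_type not in ("binary", "continuous"):
        raise ValueError(f"outcome_type must be binary/continuous, got {outcome_type!r}")
    case_fraction = cfg.get("case_fraction", 0.0358 if outcome_type == "binary" else None)
    if outcome_type == "binary":
        case_fraction = float(case_fraction)
        if not 0.0 < case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
    else:
        case_fraction = None

    lo, hi = cfg.get("eaf_range", (0.05, 0.95))
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("eaf_range must lie strictly inside (0, 1)")

    # Independent streams so that variant-level structure is shared between
    # studies that differ only in their outcome configuration.
    rng_var = np.random.default_rng([seed, 1])
    rng_med = np.random.default_rng([seed, 2])
    rng_out = np.random.default_rng([seed, 3, int(cfg.get("outcome_seed", 0))])

    eaf = rng_var.uniform(lo, hi, n_variants)

    gamma_cfg = dict(cfg.get("gamma", {}))
    kind = gamma_cfg.get("kind", "instrument_f")
    if kind == "instrument_f":
        f_min = float(gamma_cfg.get("f_min", 28.0))
        f_mean = float(gamma_cfg.get("f_mean", 57.0))
        ref_n = float(gamma_cfg.get("reference_n", DEFAULT_REFERENCE_N))
        if not (f_mean > f_min > 1.0):
            raise ValueError("instrument_f requires f_mean > f_min > 1")
        f_target = f_min + rng_var.exponential(f_mean - f_min, n_variants)
        gamma = np.sqrt((f_target - 1.0) / (ref_n * 2 * eaf * (1 - eaf)))
    elif kind == "normal":
        gamma = np.abs(rng_var.normal(0.0, float(gamma_cfg["sd"]), n_variants))
    else:
        raise ValueError(f"unknown gamma kind {kind!r}")

    pal_frac = float(cfg.get("palindromic_fraction", 0.15))
    is_pal = rng_var.random(n_variants) < pal_frac
    pal_idx = rng_var.integers(0, len(PALINDROMIC_PAIRS), n_variants)
    npal_idx = rng_var.integers(0, len(_NON_PALINDROMIC_PAIRS), n_variants)
    pal_arr = np.array(PALINDROMIC_PAIRS)
    npal_arr = np.array(_NON_PALINDROMIC_PAIRS)
    pairs = np.where(is_pal[:, None], pal_arr[pal_idx], npal_arr[npal_idx])
    effect_allele, other_allele = pairs[:, 0].copy(), pairs[:, 1].copy()

    K = len(mediators)
    alpha = np.array([float(m.get("alpha", 0.0)) for m in mediators])
    beta_med = np.array([float(m.get("beta", 0.0)) for m in mediators])
    med_names = tuple(str(m.get("name", f"mediator_{k + 1}")) for k, m in enumerate(mediators))
    if len(set(med_names)) != K:
        raise ValueError("mediator names must be unique")
    med_types, med_cfs = [], []
    for m in mediators:
        mtype = str(m.get("type", "continuous"))
        if mtype not in ("binary", "continuous"):
            raise ValueError(f"mediator type must be binary/continuous, got {mtype!r}")
        mcf = m.get("case_fraction")
        if mtype == "binary":
            mcf = float(mcf)
            if not 0.0 < mcf < 1.0:
                raise ValueError("mediator case_fraction must lie in (0, 1)")
        else:
            mcf = None
        med_types.append(mtype)
        med_cfs.append(mcf)
    delta = np.zeros((n_variants, K))
    for k, m in enumerate(mediators):
        delta_sd = float(m.get("delta_sd", 0.01))
        if delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        if delta_sd > 0:
            delta[:, k] = rng_med.normal(0.0, delta_sd, n_variants)

    pleio_mean = float(cfg.get("pleio_mean", 0.0))
    pleio_sd = float(cfg.get("pleio_sd", 0.0))
    if pleio_sd < 0:
        raise ValueError("pleio_sd must be >= 0")
    if pleio_mean == 0.0 and pleio_sd == 0.0:
        pleio = np.zeros(n_variants)
    else:
        pleio = rng_out.normal(pleio_mean, pleio_sd, n_variants)
    invalid_frac = float(cfg.get("invalid_fraction", 1.0))
    if not 0.0 <= invalid_frac <= 1.0:
        raise ValueError("invalid_fraction must lie in [0, 1]")
    if invalid_frac < 1.0:
        # pleiotropy confined to a random subset of "invalid" instruments
        mask = rng_out.random(n_variants) < invalid_frac
        pleio = np.where(mask, pleio, 0.0)

    ld_blocks = cfg.get("ld_blocks")
    if ld_blocks is not None:
        block, rho = int(ld_blocks[0]), float(ld_blocks[1])
        if abs(rho) >= 1.0:
            raise ValueError("|rho| must be < 1")
        if block < 1:
            raise ValueError("ld block size must be >= 1")
        ld_blocks = (block, rho)

    width = len(str(n_variants))
    variant_id = np.array([f"rs{i + 1:0{width}d}" for i in range(n_variants)])
    chrom = (np.arange(n_variants) % 22 + 1).astype(np.int64)
    pos = (10_000 + 5_000 * np.arange(n_variants)).astype(np.int64)

    model = TrueModel(
        gamma=gamma, eaf=eaf, alpha=alpha, beta_med=beta_med, delta=delta,
        theta_direct=float(cfg.get("theta_direct", 0.0)),
        pleio=pleio, pleio_mean=pleio_mean, pleio_sd=pleio_sd,
        outcome_type=outcome_type, case_fraction=case_fraction,
        mediator_names=med_names, mediator_types=tuple(med_types),
        mediator_case_fractions=tuple(med_cfs),
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        ld_blocks=ld_blocks, seed=seed,
    )
    if not np.isfinite(model.theta_total):
        raise ValueError("implied theta_total is not finite")
    return model


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """Per-trait GWAS sample sizes, residual SDs and noise seeds.

    ``n`` maps trait name ("exposure", mediator names, "outcome") to the GWAS
    sample size; ``sigma`` gives the trait SD for continuous traits (default
    1, i.e. traits analysed in SD units).  Every trait uses an independent
    noise stream, emulating non-overlapping samples; ``trait_seeds`` can pin
    individual traits to their own seed.  ``swap_rate``/``strand_flip_rate``
    corrupt the written allele representation (per-variant independent
    events) to exercise harmonization; corruption draws are seeded separately
    so the same study can be produced clean and corrupted.
    """

    n: Mapping[str, int]
    sigma: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    trait_seeds: Mapping[str, int] = field(default_factory=dict)
    swap_rate: float = 0.0
    strand_flip_rate: float = 0.0
    corruption_seed: int | None = None

    def __post_init__(self) -> None:
        for name, n in self.n.items():
            if int(n) < 100:
                raise ValueError(f"sample size for {name!r} must be >= 100")
        for rate in (self.swap_rate, self.strand_flip_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")

    def n_for(self, trait: str) -> int:
        return int(self.n[trait])

    def sigma_for(self, trait: str) -> float:
        return float(self.sigma.get(trait, 1.0))


def _closed_form_se(
    n: int, eaf: np.ndarray, trait_type: str,
    sigma: float, case_fraction: float | None,
) -> np.ndarray:
    het = 2.0 * n * eaf * (1.0 - eaf)
    if trait_type == "continuous":
        return sigma / np.sqrt(het)
    cf = float(case_fraction)
    return 1.0 / np.sqrt(het * cf * (1.0 - cf))


def generate_summary_stats(
    model: TrueModel,
    design: SampleDesign,
    traits: Sequence[str] | None = None,
):
    """Simulate one GWAS summary-statistics table per trait.

    Returns a dict mapping trait name to :class:`mrmediate.sumstats.SummaryStats`.
    Estimated effects are the true marginal effects plus Normal(0, SE) noise
    with an independent stream per trait; SEs come from the closed forms
    documented in the module docstring; p-values are two-sided normal.
    """
    from .sumstats import SummaryStats  # local import to avoid a cycle

    trait_order = model.trait_names
    if traits is None:
        traits = trait_order
    missing = set(traits) - set(trait_order)
    if missing:
        raise KeyError(f"unknown traits {sorted(missing)}")
    for t in traits:
        if t not in design.n:
            raise ValueError(f"design provides no sample size for trait {t!r}")

    out = {}
    for trait in traits:
        idx = trait_order.index(trait)
        if trait == "exposure":
            ttype, cf = "continuous", None
        elif trait == "outcome":
            ttype, cf = model.outcome_type, model.case_fraction
        else:
            k = model.mediator_names.index(trait)
            ttype, cf = model.mediator_types[k], model.mediator_case_fractions[k]

        n = design.n_for(trait)
        se = _closed_form_se(n, model.eaf, ttype, design.sigma_for(trait), cf)
        rng = np.random.default_rng([design.trait_seeds.get(trait, design.seed), 101, idx])
        beta = model.marginal_effects(trait) + rng.normal(0.0, 1.0, model.n_variants) * se
        z = np.abs(beta / se)
        pval = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)

        ea = model.effect_allele.copy()
        oa = model.other_allele.copy()
        eaf = model.eaf.copy()
        b = beta.copy()
        if design.swap_rate > 0.0 or design.strand_flip_rate > 0.0:
            cseed = design.seed + 1 if design.corruption_seed is None else design.corruption_seed
            rng_c = np.random.default_rng([cseed, 202, idx])
            flip_strand = rng_c.random(model.n_variants) < design.strand_flip_rate
            swap = rng_c.random(model.n_variants) < design.swap_rate
            comp = np.vectorize(COMPLEMENT.get)
            ea = np.where(flip_strand, comp(ea), ea)
            oa = np.where(flip_strand, comp(oa), oa)
            ea, oa = np.where(swap, oa, ea), np.where(swap, ea, oa)
            b = np.where(swap, -b, b)
            eaf = np.where(swap, 1.0 - eaf, eaf)

        df = pd.DataFrame({
            "variant_id": model.variant_id,
            "chrom": model.chrom,
            "pos": model.pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": b,
            "se": se,
            "pval": pval,
            "n": np.full(model.n_variants, n, dtype=np.int64),
        })
        out[trait] = SummaryStats(df, name=trait, trait_type=ttype)
    return out


def generate_reference_ld(model: TrueModel) -> pd.DataFrame:
    """Block-diagonal reference correlation matrix for the model's variants.

    Within a block of ``block_size`` consecutive variants the correlation
    between variants ``j`` positions apart is ``rho**j``; blocks are
    independent; the diagonal is exactly 1.  Symmetric positive semidefinite
    by construction (AR(1) within blocks).
    """
    if model.ld_blocks is None:
        raise ValueError("model has no ld_blocks defined")
    block, rho = model.ld_blocks
    n = model.n_variants
    mat = np.eye(n)
    if block > 1 and rho != 0.0:
        for start in range(0, n, block):
            stop = min(start + block, n)
            j = np.arange(stop - start)
            mat[start:stop, start:stop] = rho ** np.abs(j[:, None] - j[None, :])
    ids = model.variant_id
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# individual-level validation mode
# ---------------------------------------------------------------------------

def simulate_individual_level(
    model: TrueModel,
    design: SampleDesign,
    trait: str,
    seed: int = 0,
    max_variants: int | None = None,
):
    """Small-n individual-level simulation validating the closed-form SEs.

    Draws genotypes ``G ~ Binomial(2, eaf)``, builds traits from the
    structural equations, and regresses the trait on each variant one at a
    time (the GWAS marginal model).  Binary traits are generated from a
    logistic model and fitted per variant by logistic regression.  Returns
    ``(beta_hat, se_hat)`` arrays.  Intended for tens of variants and
    moderate n; the summary-level mode is the workhorse.
    """
    rng = np.random.default_rng(seed)
    L = model.n_variants if max_variants is None else min(max_variants, model.n_variants)
    n = design.n_for(trait)
    G = rng.binomial(2, model.eaf[:L], size=(n, L)).astype(float)

    gvar = np.sum(2 * model.eaf[:L] * (1 - model.eaf[:L]) * model.gamma[:L] ** 2)
    ex_sd = np.sqrt(max(1e-12, design.sigma_for("exposure") ** 2 - gvar))
    x = G @ model.gamma[:L] + rng.normal(0.0, ex_sd, n)

    if trait == "exposure":
        y, ttype, cf = x, "continuous", None
    elif trait in model.mediator_names:
        k = model.mediator_names.index(trait)
        lin = model.alpha[k] * x + G @ model.delta[:L, k]
        ttype = model.mediator_types[k]
        cf = model.mediator_case_fractions[k]
        if ttype == "continuous":
            y = lin + rng.normal(0.0, design.sigma_for(trait), n)
        else:
            eta = np.log(cf / (1 - cf)) + lin - lin.mean()
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    elif trait == "outcome":
        meds = np.column_stack([
            model.alpha[k] * x + G @ model.delta[:L, k]
            + (rng.normal(0.0, design.sigma_for(m), n)
               if model.mediator_types[k] == "continuous" else 0.0)
            for k, m in enumerate(model.mediator_names)
        ]) if model.n_mediators else np.zeros((n, 0))
        lin = model.theta_direct * x + meds @ model.beta_med + G @ model.pleio[:L]
        ttype, cf = model.outcome_type, model.case_fraction
        if ttype == "continuous":
            y = lin + rng.normal(0.0, design.sigma_for(trait), n)
        else:
            eta = np.log(cf / (1 - cf)) + lin - lin.mean()
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        raise KeyError(f"unknown trait {trait!r}")

    beta_hat = np.empty(L)
    se_hat = np.empty(L)
    if ttype == "continuous":
        gc = G - G.mean(axis=0)
        yc = y - y.mean()
        ss = np.sum(gc * gc, axis=0)
        beta_hat = gc.T @ yc / ss
        resid_var = np.array([
            np.sum((yc - beta_hat[j] * gc[:, j]) ** 2) / (n - 2) for j in range(L)
        ])
        se_hat = np.sqrt(resid_var / ss)
    else:
        import statsmodels.api as sm  # heavy; only for the validation mode
        for j in range(L):
            res = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            beta_hat[j] = res.params[1]
            se_hat[j] = res.bse[1]
    return beta_hat, se_hat


# ---------------------------------------------------------------------------
# writing a study to disk
# ---------------------------------------------------------------------------

def write_study(
    model: TrueModel,
    design: SampleDesign,
    out_dir: str | Path,
    tables=None,
) -> dict[str, Path]:
    """Write all trait tables, the LD matrix and the ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if tables is None:
        tables = generate_summary_stats(model, design)
    paths: dict[str, Path] = {}
    for trait, table in tables.items():
        p = out_dir / f"{trait}.tsv"
        table.to_file(p)
        paths[trait] = p
    if model.ld_blocks is not None:
        ld = generate_reference_ld(model)
        p = out_dir / "ld.tsv"
        ld.to_csv(p, sep="\t", index_label="variant_id", float_format="%.10g")
        paths["ld"] = p
    p = out_dir / "truth.json"
    model.to_json(p)
    paths["truth"] = p
    return paths
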