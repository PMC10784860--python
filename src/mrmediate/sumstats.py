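"""Reading, validating, harmonizing and instrument-selecting GWAS summary stats.

Harmonization orients every trait's effect estimates to the exposure's effect
allele so that a positive beta always refers to the same allele in every
table.  Swapped allele orders negate the effect and mirror the frequency;
strand complements are resolved by complementing the allele pair; palindromic
(A/T or G/C) variants, whose strand cannot be resolved from the alleles, are
oriented from the effect-allele frequency or dropped, per policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import COMPLEMENT

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "pval", "n")

#: lower-case synonyms accepted for the canonical column names
COLUMN_SYNONYMS: Mapping[str, str] = {
    "snp": "variant_id", "rsid": "variant_id", "markername": "variant_id",
    "id": "variant_id", "variant": "variant_id",
    "chr": "chrom", "chromosome": "chrom",
    "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "a1": "effect_allele", "ea": "effect_allele", "allele1": "effect_allele",
    "a2": "other_allele", "oa": "other_allele", "nea": "other_allele",
    "allele2": "other_allele", "allele0": "other_allele",
    "freq": "eaf", "eaf": "eaf", "af": "eaf", "a1freq": "eaf",
    "effect_allele_frequency": "eaf", "maf": "eaf",
    "b": "beta", "effect": "beta", "beta": "beta",
    "se": "se", "stderr": "se", "standard_error": "se",
    "p": "pval", "pvalue": "pval", "p_value": "pval", "pval": "pval",
    "n": "n", "samplesize": "n", "n_total": "n",
}

_VALID_ALLELES = frozenset("ACGT")

# harmonization provenance flags
UNCHANGED = "unchanged"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_SIGN_FLIPPED = "strand_sign_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISSING = "dropped_missing"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass
class SummaryStats:
    """One trait's per-variant GWAS association records.

    Thin wrapper around a validated :class:`pandas.DataFrame` with the
    canonical columns ``variant_id, chrom, pos, effect_allele, other_allele,
    eaf, beta, se, pval, n`` (coordinates, eaf, pval and n may be absent).
    """

    df: pd.DataFrame
    name: str = "trait"
    trait_type: str | None = None  # "binary" | "continuous" | None (unknown)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary stats for {self.name!r} missing column(s): {missing}")
        if self.df["variant_id"].duplicated().any():
            dup = self.df["variant_id"][self.df["variant_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id in {self.name!r}: {dup!r}")
        if (self.df["se"] <= 0).any():
            raise ValueError(f"non-positive se in {self.name!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_median(self) -> float:
        return float(self.df["n"].median()) if "n" in self.df.columns else float("nan")

    def to_file(self, path: str | Path) -> None:
        """Write as a tab-delimited text file with a header row."""
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    name: str | None = None,
    trait_type: str | None = None,
) -> SummaryStats:
    """Read and validate a tab-delimited summary-statistics file.

    ``column_map`` maps file column names to canonical names and takes
    precedence over the built-in synonyms.  Rows with missing beta/se,
    non-positive se, invalid or non-biallelic allele codes, or identical
    alleles are dropped with a logged count; a missing required column and
    duplicate variant ids are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    rename = {}
    for col in df.columns:
        if column_map and col in column_map:
            rename[col] = column_map[col]
        elif col.lower() in COLUMN_SYNONYMS:
            rename[col] = COLUMN_SYNONYMS[col.lower()]
    df = df.rename(columns=rename)
    df = df.loc[:, ~df.columns.duplicated()]

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")

    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("beta", "se", "eaf", "pval"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n0 = len(df)
    keep = df["beta"].notna() & df["se"].notna()
    if (dropped := n0 - int(keep.sum())):
        logger.warning("%s: dropped %d row(s) with missing beta/se", path, dropped)
    df = df[keep]

    bad_se = df["se"] <= 0
    if bad_se.any():
        logger.warning("%s: dropped %d row(s) with se <= 0", path, int(bad_se.sum()))
        df = df[~bad_se]

    biallelic = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    if (~biallelic).any():
        logger.warning(
            "%s: dropped %d row(s) with non-biallelic/invalid allele codes",
            path, int((~biallelic).sum()),
        )
        df = df[biallelic]

    if "eaf" in df.columns:
        bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0, 1, inclusive="neither")
        if bad_eaf.any():
            logger.warning("%s: %d eaf value(s) outside (0,1) set to missing", path, int(bad_eaf.sum()))
            df.loc[bad_eaf, "eaf"] = np.nan

    if "pval" not in df.columns:
        df["pval"] = np.clip(2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"])), 1e-300, 1.0)

    if df["variant_id"].duplicated().any():
        dup = df["variant_id"][df["variant_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate variant_id {dup!r}")

    return SummaryStats(df.reset_index(drop=True), name=name or path.stem, trait_type=trait_type)


# ---------------------------------------------------------------------------
# instrument selection (greedy LD pruning)
# ---------------------------------------------------------------------------

def select_instruments(
    exposure: SummaryStats,
    p_threshold: float = 5e-8,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.01,
) -> list[str]:
    """Select approximately independent genome-wide-significant instruments.

    Candidates with ``pval < p_threshold`` are ranked by ascending p-value
    (ties broken by variant_id); the best remaining candidate is kept and
    every candidate with squared correlation >= ``r2_threshold`` against any
    kept variant is discarded.  ``ld`` holds correlations (r, not r^2) with
    variant ids on both axes; pairs absent from it are treated as independent
    with a logged warning.
    """
    df = exposure.df
    cand = df[df["pval"] < p_threshold]
    if cand.empty:
        raise ValueError(f"no instruments at threshold p < {p_threshold:g}")
    order = cand.sort_values(["pval", "variant_id"], kind="mergesort")["variant_id"].tolist()
    if ld is None:
        logger.info("no LD matrix supplied; all candidates treated as independent")
        return order

    missing = [v for v in order if v not in ld.index]
    if missing:
        logger.warning(
            "%d candidate variant(s) missing from LD matrix; treated as independent",
            len(missing),
        )
    present = [v for v in order if v in ld.index]
    sub = ld.loc[present, present].to_numpy() ** 2
    pos = {v: i for i, v in enumerate(present)}

    kept: list[str] = []
    kept_idx: list[int] = []
    alive = set(order)
    for v in order:
        if v not in alive:
            continue
        kept.append(v)
        alive.discard(v)
        if v in pos:
            kept_idx.append(pos[v])
            i = pos[v]
            for u in list(alive):
                j = pos.get(u)
                if j is not None and sub[i, j] >= r2_threshold:
                    alive.discard(u)
    return kept


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedDataset:
    """Variant-aligned effect/SE matrices oriented to the exposure effect allele.

    ``mediator_beta``/``mediator_se`` are (L, K) arrays in the order of
    ``mediator_names``; ``flags`` records the per-variant, per-trait
    harmonization action for every instrument considered (including dropped
    ones).  ``n`` maps trait name to its (median) GWAS sample size when known.
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf: np.ndarray
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    mediator_names: tuple[str, ...] = ()
    mediator_beta: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    mediator_se: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    outcome_type: str | None = None
    mediator_types: tuple[str | None, ...] = ()
    flags: pd.DataFrame | None = None
    n: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return int(self.variant_id.size)

    @property
    def n_mediators(self) -> int:
        return len(self.mediator_names)

    def mediator(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        k = self.mediator_names.index(name)
        return self.mediator_beta[:, k], self.mediator_se[:, k]

    def subset(self, variant_ids: Sequence[str]) -> "HarmonizedDataset":
        idx = pd.Index(self.variant_id).get_indexer(list(variant_ids))
        if (idx < 0).any():
            raise KeyError("variant(s) not present in harmonized dataset")
        return replace(
            self,
            variant_id=self.variant_id[idx],
            effect_allele=self.effect_allele[idx],
            other_allele=self.other_allele[idx],
            eaf=self.eaf[idx],
            exposure_beta=self.exposure_beta[idx],
            exposure_se=self.exposure_se[idx],
            outcome_beta=self.outcome_beta[idx],
            outcome_se=self.outcome_se[idx],
            mediator_beta=self.mediator_beta[idx] if self.n_mediators else self.mediator_beta,
            mediator_se=self.mediator_se[idx] if self.n_mediators else self.mediator_se,
            flags=self.flags,
        )

    def to_tables(self) -> dict[str, SummaryStats]:
        """Re-emit per-trait tables in the harmonized orientation."""
        out = {}

        def table(beta, se, name, ttype):
            df = pd.DataFrame({
                "variant_id": self.variant_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "eaf": self.eaf,
                "beta": beta,
                "se": se,
                "pval": np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0),
            })
            if name in self.n and np.isfinite(self.n[name]):
                df["n"] = self.n[name]
            return SummaryStats(df, name=name, trait_type=ttype)

        out["exposure"] = table(self.exposure_beta, self.exposure_se, "exposure", "continuous")
        for k, m in enumerate(self.mediator_names):
            mtype = self.mediator_types[k] if self.mediator_types else None
            out[m] = table(self.mediator_beta[:, k], self.mediator_se[:, k], m, mtype)
        out["outcome"] = table(self.outcome_beta, self.outcome_se, "outcome", self.outcome_type)
        return out

    def harmonization_report(self) -> pd.DataFrame:
        """Per-variant flag table (one column per non-exposure trait)."""
        if self.flags is None:
            raise ValueError("no flags recorded")
        return self.flags


def _align_one(
    exp: pd.DataFrame,
    trait: SummaryStats,
    policy: str,
    eaf_window: tuple[float, float],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Align one trait table to the exposure orientation.

    Returns the aligned frame (indexed like ``exp``; beta/se/eaf NaN where
    dropped) and the per-variant flag array.
    """
    t = trait.df.set_index("variant_id")
    if not t.index.is_unique:
        raise ValueError(f"duplicate variant_id in {trait.name!r}")
    t = t.reindex(exp["variant_id"])

    ea = exp["effect_allele"].to_numpy()
    oa = exp["other_allele"].to_numpy()
    cea = pd.Series(ea).map(COMPLEMENT).to_numpy()
    coa = pd.Series(oa).map(COMPLEMENT).to_numpy()
    ta = t["effect_allele"].to_numpy(dtype=object)
    to = t["other_allele"].to_numpy(dtype=object)

    present = t["beta"].notna().to_numpy() & t["se"].notna().to_numpy()
    palindromic = oa == cea  # exposure pair reads the same on both strands

    same = (ta == ea) & (to == oa)
    swapped = (ta == oa) & (to == ea)
    strand = (ta == cea) & (to == coa)
    strand_swap = (ta == coa) & (to == cea)
    pair_ok = same | swapped | strand | strand_swap

    flip = np.zeros(len(exp), dtype=bool)
    keep = np.zeros(len(exp), dtype=bool)
    flags = np.full(len(exp), DROPPED_MISSING, dtype=object)

    # non-palindromic variants: allele letters identify the orientation
    np_mask = present & ~palindromic
    flags[np_mask & ~pair_ok] = DROPPED_INCOMPATIBLE
    for cond, do_flip, flag in (
        (same, False, UNCHANGED),
        (swapped, True, SIGN_FLIPPED),
        (strand, False, STRAND_FLIPPED),
        (strand_swap, True, STRAND_SIGN_FLIPPED),
    ):
        m = np_mask & cond
        keep[m] = True
        flip[m] = do_flip
        flags[m] = flag

    # palindromic variants: letters are ambiguous, orientation from eaf
    p_mask = present & palindromic
    flags[p_mask & ~pair_ok] = DROPPED_INCOMPATIBLE
    p_mask &= pair_ok
    if policy == "drop-all":
        flags[p_mask] = DROPPED_PALINDROMIC
    else:
        f = exp["eaf"].to_numpy() if "eaf" in exp.columns else np.full(len(exp), np.nan)
        g = t["eaf"].to_numpy() if "eaf" in t.columns else np.full(len(exp), np.nan)
        lo, hi = eaf_window
        informative = (
            ~np.isnan(f) & ~np.isnan(g)
            & ((f < lo) | (f > hi)) & ((g < lo) | (g > hi))
        )
        same_side = (f < 0.5) == (g < 0.5)
        if policy == "infer":
            m_keep = p_mask & informative & same_side
            m_flip = p_mask & informative & ~same_side
        elif policy == "same-side":
            m_keep = p_mask & informative & same_side
            m_flip = np.zeros(len(exp), dtype=bool)
        else:
            raise ValueError(f"unknown palindromic policy {policy!r}")
        keep[m_keep] = True
        flags[m_keep] = UNCHANGED
        keep[m_flip] = True
        flip[m_flip] = True
        flags[m_flip] = SIGN_FLIPPED
        flags[p_mask & ~(m_keep | m_flip)] = DROPPED_PALINDROMIC

    n_incomp = int((flags == DROPPED_INCOMPATIBLE).sum())
    if n_incomp:
        logger.warning("%s: dropped %d variant(s) with incompatible allele pairs", trait.name, n_incomp)

    beta = np.where(flip, -t["beta"].to_numpy(), t["beta"].to_numpy())
    g_out = t["eaf"].to_numpy() if "eaf" in t.columns else np.full(len(exp), np.nan)
    g_out = np.where(flip, 1.0 - g_out, g_out)
    aligned = pd.DataFrame({
        "beta": np.where(keep, beta, np.nan),
        "se": np.where(keep, t["se"].to_numpy(), np.nan),
        "eaf": np.where(keep, g_out, np.nan),
    }, index=exp.index)
    return aligned, flags


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    mediators: Mapping[str, SummaryStats] | None = None,
    instruments: Sequence[str] | None = None,
    policy: str = "infer",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedDataset:
    """Orient all traits to the exposure's effect allele over the instrument set.

    ``policy`` governs palindromic variants: ``"infer"`` (default) keeps them
    when both effect-allele frequencies are outside ``eaf_window`` and flips
    the orientation when the frequencies fall on opposite sides of 0.5;
    ``"same-side"`` keeps only frequency-concordant ones; ``"drop-all"``
    discards every palindromic variant.  Variants missing from any trait or
    with incompatible allele pairs are dropped (never silently retained).
    """
    mediators = dict(mediators or {})
    exp = exposure.df
    if instruments is not None:
        exp = exp.set_index("variant_id", drop=False).reindex(instruments)
        if exp["beta"].isna().any():
            missing = [v for v in instruments if v not in set(exposure.df["variant_id"])]
            raise KeyError(f"instrument(s) absent from exposure table: {missing[:5]}")
        exp = exp.reset_index(drop=True)

    keep = np.ones(len(exp), dtype=bool)
    aligned: dict[str, pd.DataFrame] = {}
    flag_cols: dict[str, np.ndarray] = {}
    for name, tab in list(mediators.items()) + [("outcome", outcome)]:
        a, flags = _align_one(exp, tab, policy, eaf_window)
        aligned[name] = a
        flag_cols[name] = flags
        keep &= a["beta"].notna().to_numpy()

    flags_df = pd.DataFrame({"variant_id": exp["variant_id"].to_numpy(), **flag_cols})
    flags_df["retained"] = keep

    exp_k = exp[keep]
    med_names = tuple(mediators.keys())
    K = len(med_names)
    L = int(keep.sum())
    med_beta = np.zeros((L, K))
    med_se = np.zeros((L, K))
    for k, m in enumerate(med_names):
        med_beta[:, k] = aligned[m]["beta"].to_numpy()[keep]
        med_se[:, k] = aligned[m]["se"].to_numpy()[keep]

    n_map = {"exposure": exposure.n_median, "outcome": outcome.n_median}
    for m, tab in mediators.items():
        n_map[m] = tab.n_median

    return HarmonizedDataset(
        variant_id=exp_k["variant_id"].to_numpy(),
        effect_allele=exp_k["effect_allele"].to_numpy(),
        other_allele=exp_k["other_allele"].to_numpy(),
        eaf=exp_k["eaf"].to_numpy() if "eaf" in exp_k.columns else np.full(L, np.nan),
        exposure_beta=exp_k["beta"].to_numpy(),
        exposure_se=exp_k["se"].to_numpy(),
        outcome_beta=aligned["outcome"]["beta"].to_numpy()[keep],
        outcome_se=aligned["outcome"]["se"].to_numpy()[keep],
        mediator_names=med_names,
        mediator_beta=med_beta,
        mediator_se=med_se,
        outcome_type=outcome.trait_type,
        mediator_types=tuple(mediators[m].trait_type for m in med_names),
        flags=flags_df,
        n=n_map,
    )


# ---------------------------------------------------------------------------
# instrument-strength diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-variant instrument strength for the exposure.

    F is the squared exposure z statistic; r^2 assumes the exposure is
    standardized to unit variance, so per-variant r^2 = 2 eaf (1-eaf) beta^2
    and the total is the sum over the (LD-pruned) instruments.
    """

    f_stat: np.ndarray
    r2: np.ndarray
    total_r2: float
    median_f: float
    min_f: float
    max_f: float

    def summary(self) -> str:
        return (
            f"instruments: {self.f_stat.size}\n"
            f"variance explained (r2): {self.total_r2:.4f}\n"
            f"median F: {self.median_f:.1f} (range {self.min_f:.1f}-{self.max_f:.1f})"
        )


def instrument_diagnostics(harmonized: HarmonizedDataset) -> InstrumentDiagnostics:
    """F statistics and variance explained for the harmonized instrument set."""
    if harmonized.n_variants == 0:
        raise ValueError("empty harmonized dataset")
    f = (harmonized.exposure_beta / harmonized.exposure_se) ** 2
    r2 = 2.0 * harmonized.eaf * (1.0 - harmonized.eaf) * harmonized.exposure_beta**2
    return InstrumentDiagnostics(
        f_stat=f,
        r2=r2,
        total_r2=float(np.nansum(r2)),
        median_f=float(np.median(f)),
        min_f=float(np.min(f)),
        max_f=float(np.max(f)),
    )
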