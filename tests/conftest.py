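"""Shared fixtures and study factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import mrmediate as mm

# Strongly instrumented regime (upper end of a realistic per-variant F range):
# first-order MR theory ignores exposure-side noise, whose bias is O(1/mean F),
# so recovery checks use instruments where that term is below Monte-Carlo
# resolution.  The default generator profile (F ~ 28 + Exp(29)) emulates a
# median-strength panel instead and is exercised in the diagnostics tests.
STRONG_GAMMA = dict(kind="instrument_f", f_min=100.0, f_mean=300.0)

#: GWAS sample sizes of the order used by large consortium studies
BIG_N = {"exposure": 3_037_499, "outcome": 200_000}


def make_mediation_study(
    seed: int,
    n_variants: int = 500,
    theta_direct: float = 0.5,
    alpha: float = 0.4,
    beta: float = 0.5,
    delta_sd: float = 0.02,
    outcome_type: str = "continuous",
    design_seed: int | None = None,
    **model_kw,
):
    """One-mediator synthetic study; returns (model, tables)."""
    cfg = dict(
        n_variants=n_variants,
        seed=seed,
        theta_direct=theta_direct,
        gamma=model_kw.pop("gamma", STRONG_GAMMA),
        mediators=[dict(name="m1", alpha=alpha, beta=beta, delta_sd=delta_sd)],
        outcome_type=outcome_type,
        **model_kw,
    )
    model = mm.build_true_model(cfg)
    design = mm.SampleDesign(
        n={"exposure": 3_037_499, "m1": 800_000, "outcome": 200_000},
        seed=seed + 50_000 if design_seed is None else design_seed,
    )
    return model, mm.generate_summary_stats(model, design)


def harmonize_all(model, tables):
    """Harmonize over the generator's full known instrument panel."""
    mediators = {m: tables[m] for m in model.mediator_names}
    return mm.harmonize(tables["exposure"], tables["outcome"], mediators,
                        instruments=list(model.variant_id))


@pytest.fixture(scope="session")
def mediation_study():
    model, tables = make_mediation_study(seed=42, n_variants=400)
    return model, tables, harmonize_all(model, tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
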