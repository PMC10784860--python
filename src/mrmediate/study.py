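"""A full synthetic study: one exposure, K mediators, several outcomes.

The default configuration emulates the statistical structure of a large
educational-attainment MR mediation analysis: a continuous exposure measured
in SD units instrumented by thousands of variants (per-variant F between
~28 and several hundred, jointly explaining ~7.5% of exposure variance at a
reference GWAS of ~3 million people), five cardiometabolic mediators (one
binary on the log-odds scale, four continuous in SD units), five binary
pregnancy outcomes reported as log-odds ratios from case-control GWAS of
140k-230k women, and one continuous outcome (offspring birth weight in
grams).  Every exposure-outcome pair uses non-overlapping samples.

Outcome blocks state the true total effect on the analysis scale and either
the true proportion mediated (with an optional per-mediator contribution
pattern) or explicit mediator->outcome coefficients; the generator solves
for the structural coefficients so those targets hold exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .simulate import SampleDesign, TrueModel, build_true_model, generate_summary_stats

logger = logging.getLogger(__name__)


def default_study_config(n_variants: int = 4000, seed: int = 7, design_seed: int = 11) -> dict:
    """Demo study emulating a large education -> pregnancy-outcomes design."""
    return {
        "n_variants": n_variants,
        "seed": seed,
        "design_seed": design_seed,
        "exposure": {"n": 3_037_499, "sigma": 1.0},
        "gamma": {"kind": "instrument_f", "f_min": 28.0, "f_mean": 57.0,
                  "reference_n": 3_037_499},
        # delta_sd sets each mediator's own per-variant genetics; values are
        # scaled so each mediator GWAS yields genome-wide-significant hits of
        # its own (log-odds effects for the binary trait are larger per allele)
        "mediators": [
            {"name": "t2d", "alpha": -0.60, "type": "binary",
             "case_fraction": 74_124 / 898_130, "n": 898_130, "delta_sd": 0.08},
            {"name": "bmi", "alpha": -0.30, "type": "continuous", "n": 806_834,
             "delta_sd": 0.015},
            {"name": "smoking", "alpha": -0.25, "type": "continuous", "n": 462_690,
             "delta_sd": 0.012},
            {"name": "hdl", "alpha": 0.21, "type": "continuous", "n": 1_244_580,
             "delta_sd": 0.02},
            {"name": "sbp", "alpha": -0.15, "type": "continuous", "n": 340_159,
             "delta_sd": 0.015},
        ],
        "outcomes": [
            {"name": "ectopic_pregnancy", "type": "binary", "n": 141_014,
             "case_fraction": 5_052 / 141_014, "total_effect": float(np.log(0.53)),
             "pm": 0.45, "pattern": [0.10, 0.15, 0.50, 0.15, 0.10]},
            {"name": "hyperemesis_gravidarum", "type": "binary", "n": 165_794,
             "case_fraction": 2_092 / 165_794, "total_effect": float(np.log(0.54)),
             "pm": -0.17, "pattern": [0.2, 0.2, 0.2, 0.2, 0.2]},
            {"name": "gestational_diabetes", "type": "binary", "n": 190_879,
             "case_fraction": 11_279 / 190_879, "total_effect": float(np.log(0.70)),
             "pm": 0.55, "pattern": [0.60, 0.20, 0.0, 0.10, 0.10]},
            {"name": "preeclampsia", "type": "binary", "n": 162_879,
             "case_fraction": 7_219 / 162_879, "total_effect": float(np.log(0.81)),
             "pm": 0.78, "pattern": [0.40, 0.15, 0.0, 0.10, 0.35]},
            {"name": "preterm_birth", "type": "binary", "n": 233_290,
             "case_fraction": 15_419 / 233_290, "total_effect": float(np.log(0.78)),
             "pm": 0.25, "pattern": [0.30, 0.20, 0.10, 0.10, 0.30]},
            # birth weight: mediators act in competing directions with zero net
            # mediation; the smoking coefficient is solved to cancel the rest
            {"name": "birth_weight", "type": "continuous", "n": 270_002,
             "sigma": 500.0, "total_effect": 42.0,
             "beta_med": [9.4, 38.0, "balance", -16.0, -141.0]},
        ],
    }


def _solve_beta_med(alpha: np.ndarray, outcome: Mapping[str, Any]) -> np.ndarray:
    """Mediator->outcome coefficients hitting the outcome's stated targets."""
    K = alpha.size
    total = float(outcome["total_effect"])
    if "beta_med" in outcome:
        raw = list(outcome["beta_med"])
        if len(raw) != K:
            raise ValueError("beta_med must have one entry per mediator")
        balance = [i for i, b in enumerate(raw) if b == "balance"]
        beta = np.array([0.0 if b == "balance" else float(b) for b in raw])
        if balance:
            if len(balance) > 1:
                raise ValueError("at most one 'balance' entry allowed")
            i = balance[0]
            if alpha[i] == 0:
                raise ValueError("cannot balance through a mediator with alpha = 0")
            target = float(outcome.get("pm", 0.0)) * total
            beta[i] = (target - float(alpha @ beta)) / alpha[i]
        return beta
    pm = float(outcome.get("pm", 0.0))
    pattern = np.asarray(outcome.get("pattern", np.ones(K)), dtype=float)
    if pattern.size != K:
        raise ValueError("pattern must have one entry per mediator")
    if pattern.sum() == 0:
        raise ValueError("pattern must have a nonzero sum")
    share = pattern / pattern.sum()
    indirect = pm * total
    beta = np.zeros(K)
    nz = share != 0
    if nz.any():
        if (alpha[nz] == 0).any():
            raise ValueError("pattern assigns mediation through a mediator with alpha = 0")
        beta[nz] = indirect * share[nz] / alpha[nz]
    return beta


@dataclass
class StudySimulation:
    """Generated study: shared exposure/mediator tables, per-outcome models."""

    config: dict
    models: dict[str, TrueModel]
    design: SampleDesign
    tables: dict[str, Any]            # exposure + mediator SummaryStats
    outcome_tables: dict[str, Any]    # outcome name -> SummaryStats

    @property
    def outcome_names(self) -> list[str]:
        return list(self.models.keys())

    def truth(self, outcome: str) -> dict:
        m = self.models[outcome]
        return {
            "theta_total": m.theta_total,
            "theta_direct": m.theta_direct,
            "proportion_mediated": m.proportion_mediated,
            "alpha": m.alpha.tolist(),
            "beta_med": m.beta_med.tolist(),
        }

    def write(self, out_dir: str | Path, analysis_overrides: Mapping[str, Any] | None = None):
        """Write trait files, ground-truth sidecars and a ready-to-run config."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for trait, tab in self.tables.items():
            p = out_dir / f"{trait}.tsv"
            tab.to_file(p)
            paths[trait] = p
        for oname, tab in self.outcome_tables.items():
            p = out_dir / f"outcome_{oname}.tsv"
            tab.to_file(p)
            paths[oname] = p
            self.models[oname].to_json(out_dir / f"truth_{oname}.json")
        truth_all = {o: self.truth(o) for o in self.outcome_names}
        (out_dir / "truth.json").write_text(json.dumps(truth_all, indent=2))

        med_cfgs = self.config["mediators"]
        analysis = {
            "exposure": {"name": "exposure", "path": str(paths["exposure"]),
                         "type": "continuous"},
            "mediators": [
                {"name": m["name"], "path": str(paths[m["name"]]),
                 "type": m.get("type", "continuous")}
                for m in med_cfgs
            ],
            "outcomes": [
                {"name": o["name"], "path": str(paths[o["name"]]),
                 "type": o.get("type", "binary")}
                for o in self.config["outcomes"]
            ],
            "seed": int(self.config.get("seed", 0)),
        }
        analysis.update(dict(analysis_overrides or {}))
        cfg_path = out_dir / "analysis.yaml"
        cfg_path.write_text(yaml.safe_dump(analysis, sort_keys=True))
        paths["analysis"] = cfg_path
        return paths


def simulate_study(config: Mapping[str, Any] | None = None) -> StudySimulation:
    """Generate all summary-statistic tables for a multi-outcome study."""
    cfg = dict(config) if config is not None else default_study_config()
    med_cfgs = list(cfg["mediators"])
    alpha = np.array([float(m["alpha"]) for m in med_cfgs])
    seed = int(cfg.get("seed", 0))
    design_seed = int(cfg.get("design_seed", seed + 1))

    n_map = {"exposure": int(cfg.get("exposure", {}).get("n", 100_000))}
    sigma_map = {"exposure": float(cfg.get("exposure", {}).get("sigma", 1.0))}
    for m in med_cfgs:
        n_map[m["name"]] = int(m.get("n", 100_000))
        sigma_map[m["name"]] = float(m.get("sigma", 1.0))

    models: dict[str, TrueModel] = {}
    outcome_tables = {}
    tables = None
    for i, ocfg in enumerate(cfg["outcomes"]):
        beta = _solve_beta_med(alpha, ocfg)
        total = float(ocfg["total_effect"])
        theta_direct = total - float(alpha @ beta)
        model_cfg = {
            "n_variants": int(cfg.get("n_variants", 500)),
            "seed": seed,
            "outcome_seed": i,
            "gamma": cfg.get("gamma", {}),
            "mediators": [
                {**{k: v for k, v in m.items() if k in
                    ("name", "type", "case_fraction", "delta_sd")},
                 "alpha": float(m["alpha"]), "beta": float(beta[k])}
                for k, m in zip(range(alpha.size), med_cfgs)
            ],
            "theta_direct": theta_direct,
            "pleio_mean": float(ocfg.get("pleio_mean", cfg.get("pleio_mean", 0.0))),
            "pleio_sd": float(ocfg.get("pleio_sd", cfg.get("pleio_sd", 0.0))),
            "outcome_type": ocfg.get("type", "binary"),
            "case_fraction": ocfg.get("case_fraction"),
            "palindromic_fraction": cfg.get("palindromic_fraction", 0.15),
            "ld_blocks": cfg.get("ld_blocks"),
        }
        model = build_true_model(model_cfg)
        oname = str(ocfg["name"])
        models[oname] = model

        design = SampleDesign(
            n={**n_map, "outcome": int(ocfg["n"])},
            sigma={**sigma_map, "outcome": float(ocfg.get("sigma", 1.0))},
            seed=design_seed,
            trait_seeds={"outcome": design_seed + 1000 + i},
            swap_rate=float(cfg.get("swap_rate", 0.0)),
            strand_flip_rate=float(cfg.get("strand_flip_rate", 0.0)),
        )
        if tables is None:
            full = generate_summary_stats(model, design)
            tables = {t: full[t] for t in full if t != "outcome"}
            outcome_tables[oname] = full["outcome"]
        else:
            outcome_tables[oname] = generate_summary_stats(model, design, traits=["outcome"])["outcome"]

    shared_design = SampleDesign(
        n={**n_map, "outcome": max(int(o["n"]) for o in cfg["outcomes"])},
        sigma=sigma_map, seed=design_seed,
    )
    return StudySimulation(config=cfg, models=models, design=shared_design,
                           tables=tables, outcome_tables=outcome_tables)
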