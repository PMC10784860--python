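"""Analysis configuration: trait paths, thresholds and estimator settings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration is missing or malformed; names the field."""


@dataclass(frozen=True)
class TraitSpec:
    """One trait's summary-statistics source."""

    name: str
    path: str
    trait_type: str = "continuous"  # "binary" traits are on the log-odds scale
    column_map: Mapping[str, str] | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], where: str) -> "TraitSpec":
        if "path" not in d or d["path"] in (None, ""):
            raise ConfigError(f"{where}.path is required")
        name = d.get("name") or Path(str(d["path"])).stem
        ttype = d.get("type", d.get("trait_type", "continuous"))
        if ttype not in ("binary", "continuous"):
            raise ConfigError(f"{where}.type must be binary or continuous, got {ttype!r}")
        return cls(name=str(name), path=str(d["path"]), trait_type=str(ttype),
                   column_map=d.get("column_map"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Full plan for an MR mediation run.

    Defaults mirror the conventional two-sample MR pipeline: instruments at
    p < 5e-8 pruned to pairwise r^2 < 0.01, frequency-inferred palindromic
    harmonization, multiplicative random-effects SEs, and 1000 parametric
    bootstrap replicates for the proportion mediated.  ``seed`` is mandatory
    because the bootstrap is stochastic.
    """

    exposure: TraitSpec
    outcomes: tuple[TraitSpec, ...]
    mediators: tuple[TraitSpec, ...] = ()
    seed: int = 0
    ld_path: str | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    palindromic_policy: str = "infer"
    eaf_window: tuple[float, float] = (0.42, 0.58)
    variance_model: str = "random"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    mvmr_instruments: str = "union"   # or "exposure"
    mediator_sets: Any = "auto"       # "auto" = each single mediator + all combined
    sensitivity: bool = True
    sensitivity_n_boot: int = 200     # bootstrap size for median/mode SEs in the suite
    pm_floor: float = 1e-6
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigError("outcomes must list at least one trait")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ConfigError("p_threshold must lie in (0, 1]")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ConfigError("r2_threshold must lie in (0, 1]")
        if self.palindromic_policy not in ("infer", "same-side", "drop-all"):
            raise ConfigError(f"unknown palindromic_policy {self.palindromic_policy!r}")
        if self.variance_model not in ("random", "fixed"):
            raise ConfigError(f"unknown variance_model {self.variance_model!r}")
        if self.mvmr_instruments not in ("union", "exposure"):
            raise ConfigError(f"unknown mvmr_instruments {self.mvmr_instruments!r}")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is required (stochastic bootstrap stages)")
        lo, hi = self.eaf_window
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("eaf_window must satisfy 0 < low < high < 1")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "exposure" not in d:
            raise ConfigError("exposure is required")
        if "outcomes" not in d or not d["outcomes"]:
            raise ConfigError("outcomes is required")
        exposure = TraitSpec.from_dict(d.pop("exposure"), "exposure")
        outcomes = tuple(
            TraitSpec.from_dict(o, f"outcomes[{i}]") for i, o in enumerate(d.pop("outcomes"))
        )
        mediators = tuple(
            TraitSpec.from_dict(m, f"mediators[{i}]") for i, m in enumerate(d.pop("mediators", []))
        )
        if "eaf_window" in d:
            d["eaf_window"] = tuple(d["eaf_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(exposure=exposure, outcomes=outcomes, mediators=mediators, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def check_paths(self) -> None:
        """Verify that every referenced file exists (run-time invariant)."""
        specs = [("exposure", self.exposure)]
        specs += [(f"mediators[{i}]", m) for i, m in enumerate(self.mediators)]
        specs += [(f"outcomes[{i}]", o) for i, o in enumerate(self.outcomes)]
        for where, spec in specs:
            if not Path(spec.path).exists():
                raise ConfigError(f"{where}.path does not exist: {spec.path}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise ConfigError(f"ld_path does not exist: {self.ld_path}")

    def resolved_mediator_sets(self) -> list[tuple[str, ...]]:
        """Each single mediator plus the all-mediators set (or explicit lists)."""
        names = [m.name for m in self.mediators]
        if self.mediator_sets == "auto":
            sets = [(n,) for n in names]
            if len(names) > 1:
                sets.append(tuple(names))
            return sets
        out = []
        for s in self.mediator_sets:
            s = tuple(s)
            unknown = set(s) - set(names)
            if unknown:
                raise ConfigError(f"mediator_sets references unknown mediator(s): {sorted(unknown)}")
            out.append(s)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eaf_window"] = list(self.eaf_window)
        return d
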