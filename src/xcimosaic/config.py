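"""Cohort simulation configuration.

A simulated cohort is parameterized by :class:`SimCohortConfig`: the number of
animals, the size of the progenitor ("founder") pool at which X-chromosome
inactivation (XCI) is committed, the probability that a founder keeps the
reporter-bearing (normal-allele) X active, clone-size overdispersion during
expansion, a per-stage survival model for the two lineages, a one-way
miscounting rate (truly reporter-negative cells recorded positive, emulating
autofluorescence), the ordered developmental stages, and a root seed.

Configurations can be read from a YAML or JSON document whose keys mirror the
dataclass field names (``survival_model`` is a nested mapping with ``s_base``,
``s_positive`` and optional ``competition: {kappa, form}``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError

__all__ = [
    "CompetitionModel",
    "SurvivalSpec",
    "SimCohortConfig",
    "load_config",
    "config_to_dict",
]

DEFAULT_STAGES = ("P6", "P13", "P20", "adult")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CompetitionModel:
    """Competitive elimination penalty on the low-fitness lineage.

    Under the ``linear`` form the effective per-stage survival of the mutant
    (reporter-negative) lineage is ``s_eff = s_base * (1 - kappa * phi_high)``
    clipped to [0, 1], where ``phi_high`` is the current tissue fraction of
    normal-allele cells.  ``kappa = 0`` recovers purely cell-autonomous death.
    """

    kappa: float = 0.0
    form: str = "linear"

    def __post_init__(self) -> None:
        _check_prob("kappa", self.kappa)
        if self.form != "linear":
            raise ConfigurationError(
                f"unknown competition form {self.form!r}; only 'linear' is implemented"
            )

    def effective_survival(self, s_base, phi_high):
        """Per-stage survival after the competitive penalty, clipped to [0, 1]."""
        import numpy as np

        return np.clip(np.asarray(s_base) * (1.0 - self.kappa * np.asarray(phi_high)), 0.0, 1.0)


@dataclass(frozen=True)
class SurvivalSpec:
    """Per-stage survival probabilities of the two XCI lineages.

    ``s_base[t]`` is the survival of the reporter-negative (mutant-X-active)
    lineage over the interval ending at stage ``t``; the entry for the first
    listed stage covers elimination before the first observation and defaults
    to 1 (the first stage then reflects only XCI and clone expansion).  The
    reporter-positive lineage survives with ``s_positive`` (assumed 1
    throughout under the estimation model).  The product of ``s_base`` entries
    up to a stage is the cumulative survival at that stage.
    """

    s_base: tuple[float, ...]
    s_positive: tuple[float, ...] | None = None
    competition: CompetitionModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_base", tuple(float(s) for s in self.s_base))
        for s in self.s_base:
            _check_prob("s_base entries", s)
        if self.s_positive is not None:
            object.__setattr__(
                self, "s_positive", tuple(float(s) for s in self.s_positive)
            )
            for s in self.s_positive:
                _check_prob("s_positive entries", s)
            if len(self.s_positive) != len(self.s_base):
                raise ConfigurationError(
                    "s_positive and s_base must have the same number of stages"
                )

    @property
    def n_stages(self) -> int:
        return len(self.s_base)

    def positive_survival(self) -> tuple[float, ...]:
        if self.s_positive is None:
            return (1.0,) * self.n_stages
        return self.s_positive

    def cumulative(self) -> float:
        """Cumulative reporter-negative survival at the final stage (no competition)."""
        out = 1.0
        for s in self.s_base:
            out *= s
        return out


@dataclass(frozen=True)
class SimCohortConfig:
    """Full parameterization of a simulated XCI-mosaic cohort."""

    n_animals: int = 8
    n_founders: int = 200
    p_inactivate_mutant_x: float = 0.5
    n_cells_per_region: int = 500
    clone_dispersion: float = 1.0
    survival_model: SurvivalSpec | None = None
    miscount_rate_alpha: float = 0.0
    stages: tuple[str, ...] = DEFAULT_STAGES
    regions: tuple[str, ...] = ("cgc",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ConfigurationError("n_animals must be >= 0")
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        if self.n_cells_per_region < 1:
            raise ConfigurationError("n_cells_per_region must be >= 1")
        if self.clone_dispersion < 0:
            raise ConfigurationError("clone_dispersion must be >= 0")
        _check_prob("p_inactivate_mutant_x", self.p_inactivate_mutant_x)
        _check_prob("miscount_rate_alpha", self.miscount_rate_alpha)
        stages = tuple(str(s) for s in self.stages)
        if not stages:
            raise ConfigurationError("stages must be non-empty")
        if len(set(stages)) != len(stages):
            raise ConfigurationError("stage labels must be distinct")
        object.__setattr__(self, "stages", stages)
        regions = tuple(str(r) for r in self.regions)
        if not regions:
            raise ConfigurationError("regions must be non-empty")
        object.__setattr__(self, "regions", regions)
        if self.survival_model is None:
            object.__setattr__(
                self, "survival_model", SurvivalSpec(s_base=(1.0,) * len(stages))
            )
        if self.survival_model.n_stages != len(stages):
            raise ConfigurationError(
                f"survival_model has {self.survival_model.n_stages} stages, "
                f"config lists {len(stages)}"
            )

    def replace(self, **changes) -> "SimCohortConfig":
        return dataclasses.replace(self, **changes)


def _spec_from_dict(d: dict) -> SurvivalSpec:
    comp = d.get("competition")
    competition = None
    if comp is not None:
        competition = CompetitionModel(
            kappa=float(comp.get("kappa", 0.0)), form=comp.get("form", "linear")
        )
    s_positive = d.get("s_positive")
    return SurvivalSpec(
        s_base=tuple(d["s_base"]),
        s_positive=tuple(s_positive) if s_positive is not None else None,
        competition=competition,
    )


def config_from_dict(d: dict) -> SimCohortConfig:
    """Build a :class:`SimCohortConfig` from a plain mapping (YAML/JSON payload)."""
    d = dict(d)
    unknown = set(d) - {f.name for f in dataclasses.fields(SimCohortConfig)}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "survival_model" in d and d["survival_model"] is not None:
        if isinstance(d["survival_model"], dict):
            d["survival_model"] = _spec_from_dict(d["survival_model"])
    for key in ("stages", "regions"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimCohortConfig(**d)


def load_config(path: str | Path) -> SimCohortConfig:
    """Load a cohort configuration from a YAML (``.yaml``/``.yml``) or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return config_from_dict(payload)


def config_to_dict(config: SimCohortConfig) -> dict:
    """Serialize a configuration back to a plain mapping (inverse of loading)."""
    spec = config.survival_model
    sm: dict = {"s_base": list(spec.s_base)}
    if spec.s_positive is not None:
        sm["s_positive"] = list(spec.s_positive)
    if spec.competition is not None:
        sm["competition"] = {"kappa": spec.competition.kappa, "form": spec.competition.form}
    return {
        "n_animals": config.n_animals,
        "n_founders": config.n_founders,
        "p_inactivate_mutant_x": config.p_inactivate_mutant_x,
        "n_cells_per_region": config.n_cells_per_region,
        "clone_dispersion": config.clone_dispersion,
        "survival_model": sm,
        "miscount_rate_alpha": config.miscount_rate_alpha,
        "stages": list(config.stages),
        "regions": list(config.regions),
        "seed": config.seed,
    }
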