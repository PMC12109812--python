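"""Stochastic simulator of XCI-mosaic cell-count cohorts.

Generative model, per animal:

1. **Founder pool.**  ``n_founders`` progenitors commit X-inactivation
   independently; each keeps the reporter-bearing (normal-allele) X active
   with probability ``p_inactivate_mutant_x`` (random XCI gives 0.5).
2. **Clone expansion.**  Each region's tissue is composed of the founders'
   clones with relative sizes drawn from a symmetric Dirichlet with
   concentration ``1 / clone_dispersion`` (``clone_dispersion = 0`` means
   exactly equal clones).  The reporter-positive tissue fraction before any
   elimination is the weight of reporter-positive founders, ``phi``.
3. **Staged elimination.**  The first listed stage reflects only XCI and
   clone expansion.  Between consecutive stages the reporter-negative
   (mutant) lineage survives with the per-stage probability of the
   :class:`~xcimosaic.config.SurvivalSpec`; if a competition model is
   configured the per-stage survival is additionally penalized by
   ``(1 - kappa * phi_high)`` where ``phi_high`` is the tissue fraction of
   normal-allele cells after the previous stage (recomputed every stage).
   Competition is inert in a uniform-genotype tissue (``phi_high = 0``).
4. **Counting.**  At every (region, stage) a fixed number of cells
   ``n_cells_per_region`` is scored; the truly-positive count is binomial in
   the current tissue fraction, and each truly-negative cell is misrecorded
   as positive with probability ``miscount_rate_alpha`` (one-way
   autofluorescence-like bias).

Randomness policy: one root seed per cohort; each animal consumes an
independent deterministic stream derived from ``(seed, animal_index)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CompetitionModel, SimCohortConfig, SurvivalSpec
from .errors import ConfigurationError

__all__ = [
    "simulate_animal",
    "simulate_cohort",
    "simulate_paired_design",
    "expected_gfp_fraction",
    "expected_cumulative_survival",
    "cohort_tissue_fraction",
    "simulate_layer_thickness",
    "COUNT_COLUMNS",
]

COUNT_COLUMNS = ["animal_id", "region", "stage", "n_gfp_pos", "n_gfp_neg"]


def _animal_rng(seed: int, animal_index: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-animal generator derived from the cohort root seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(animal_index), int(stream)))
    return np.random.default_rng(ss)


def _clone_weights(rng: np.random.Generator, n_founders: int, dispersion: float) -> np.ndarray:
    if dispersion == 0.0 or n_founders == 1:
        return np.full(n_founders, 1.0 / n_founders)
    return rng.dirichlet(np.full(n_founders, 1.0 / dispersion))


def _stage_fractions(
    phi: float, spec: SurvivalSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reporter-positive tissue fraction and total surviving tissue
    fraction at every stage, for a tissue with pre-elimination positive
    fraction ``phi``.

    The competitive penalty applies to transitions into stage t >= 1, using
    the positive fraction after the previous stage; the first stage precedes
    any between-stage elimination.
    """
    s_pos = spec.positive_survival()
    comp = spec.competition
    n = spec.n_stages
    frac = np.empty(n)
    tissue = np.empty(n)
    s_neg_cum = 1.0
    s_pos_cum = 1.0
    phi_current = phi
    for t in range(n):
        s_neg_t = spec.s_base[t]
        if comp is not None and t >= 1:
            s_neg_t = float(comp.effective_survival(s_neg_t, phi_current))
        s_neg_cum *= s_neg_t
        s_pos_cum *= s_pos[t]
        denom = phi * s_pos_cum + (1.0 - phi) * s_neg_cum
        if denom > 0.0:
            phi_current = phi * s_pos_cum / denom
        else:  # tissue fully eliminated; positive fraction is vacuous
            phi_current = 1.0 if phi > 0 else 0.0
        frac[t] = phi_current
        tissue[t] = denom
    return frac, tissue


def _simulate_animal_frame(
    config: SimCohortConfig, animal_index: int, rng: np.random.Generator
) -> pd.DataFrame:
    spec = config.survival_model
    n_cells = config.n_cells_per_region
    alpha = config.miscount_rate_alpha
    rows = []
    # one XCI decision per founder per animal, shared across regions
    founder_pos = rng.random(config.n_founders) < config.p_inactivate_mutant_x
    for region in config.regions:
        weights = _clone_weights(rng, config.n_founders, config.clone_dispersion)
        phi = float(weights @ founder_pos)
        frac, _ = _stage_fractions(phi, spec)
        for t, stage in enumerate(config.stages):
            n_pos_true = int(rng.binomial(n_cells, frac[t]))
            n_obs_pos = n_pos_true
            if alpha > 0.0 and n_pos_true < n_cells:
                n_obs_pos += int(rng.binomial(n_cells - n_pos_true, alpha))
            rows.append(
                {
                    "animal_id": f"a{animal_index:03d}",
                    "region": region,
                    "stage": stage,
                    "n_gfp_pos": n_obs_pos,
                    "n_gfp_neg": n_cells - n_obs_pos,
                }
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def simulate_animal(config: SimCohortConfig, animal_index: int) -> pd.DataFrame:
    """Simulate one animal; returns one count record per (region, stage).

    Reproducible: the animal's random stream is a pure function of
    ``(config.seed, animal_index)``.
    """
    if not 0 <= animal_index < config.n_animals:
        raise ConfigurationError(
            f"animal_index {animal_index} out of range for n_animals={config.n_animals}"
        )
    rng = _animal_rng(config.seed, animal_index)
    return _simulate_animal_frame(config, animal_index, rng)


def simulate_cohort(config: SimCohortConfig, cohort: str = "cohort") -> pd.DataFrame:
    """Simulate all animals of a cohort; deterministic per seed.

    Returns a tidy table with columns ``cohort, animal_id, region, stage,
    n_gfp_pos, n_gfp_neg``.
    """
    frames = [
        _simulate_animal_frame(config, i, _animal_rng(config.seed, i))
        for i in range(config.n_animals)
    ]
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=COUNT_COLUMNS)
    table.insert(0, "cohort", cohort)
    return table


def simulate_paired_design(
    uniform_config: SimCohortConfig, mosaic_config: SimCohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the hemizygote-analog (uniform genotype) and mosaic cohorts.

    The uniform cohort must have ``p_inactivate_mutant_x`` of exactly 0 or 1
    (every cell carries the same active X, so any competition penalty is inert
    for an all-mutant tissue); the mosaic cohort must be genuinely mixed.
    """
    if uniform_config.p_inactivate_mutant_x not in (0.0, 1.0):
        raise ConfigurationError(
            "uniform cohort requires p_inactivate_mutant_x of exactly 0 or 1"
        )
    if not 0.0 < mosaic_config.p_inactivate_mutant_x < 1.0:
        raise ConfigurationError("mosaic cohort requires 0 < p_inactivate_mutant_x < 1")
    if uniform_config.stages != mosaic_config.stages:
        raise ConfigurationError("paired cohorts must share the same stage list")
    return (
        simulate_cohort(uniform_config, cohort="uniform"),
        simulate_cohort(mosaic_config, cohort="mosaic"),
    )


def expected_gfp_fraction(config: SimCohortConfig, observed: bool = True) -> np.ndarray:
    """Analytic per-stage expected reporter-positive fraction.

    Uses the deterministic large-founder-pool approximation
    ``phi = p_inactivate_mutant_x``.  With ``observed=True`` the one-way
    miscounting expectation ``f + alpha * (1 - f)`` is applied.
    """
    frac, _ = _stage_fractions(config.p_inactivate_mutant_x, config.survival_model)
    if observed and config.miscount_rate_alpha > 0:
        frac = frac + config.miscount_rate_alpha * (1.0 - frac)
    return frac


def expected_cumulative_survival(config: SimCohortConfig) -> float:
    """Expected cumulative mutant-lineage survival at the final stage,
    including any competition penalty (expected-``phi`` approximation)."""
    spec = config.survival_model
    comp = spec.competition
    frac, _ = _stage_fractions(config.p_inactivate_mutant_x, spec)
    s_cum = 1.0
    phi_current = config.p_inactivate_mutant_x
    for t in range(spec.n_stages):
        s_t = spec.s_base[t]
        if comp is not None and t >= 1:
            s_t = float(comp.effective_survival(s_t, phi_current))
        s_cum *= s_t
        phi_current = frac[t]
    return s_cum


def cohort_tissue_fraction(config: SimCohortConfig, cv: float = 0.0) -> np.ndarray:
    """Per-animal surviving tissue fraction at the final stage.

    Relative to the pre-elimination tissue size: ``phi * S_pos + (1 - phi) *
    S_neg`` averaged over regions, times an optional multiplicative
    between-animal noise factor with coefficient of variation ``cv``.  Layer
    thickness is modeled as proportional to this quantity.
    """
    out = np.empty(config.n_animals)
    for i in range(config.n_animals):
        rng = _animal_rng(config.seed, i)
        founder_pos = rng.random(config.n_founders) < config.p_inactivate_mutant_x
        sizes = []
        for _region in config.regions:
            weights = _clone_weights(rng, config.n_founders, config.clone_dispersion)
            phi = float(weights @ founder_pos)
            _, tissue = _stage_fractions(phi, config.survival_model)
            sizes.append(tissue[-1])
        size = float(np.mean(sizes))
        if cv > 0.0:
            noise_rng = _animal_rng(config.seed, i, stream=1)
            size *= max(float(noise_rng.normal(1.0, cv)), 0.0)
        out[i] = size
    return out


def simulate_layer_thickness(
    config: SimCohortConfig, baseline: float = 118.4, cv: float = 0.075
) -> np.ndarray:
    """Per-animal simulated layer thickness (µm).

    Thickness is taken proportional to the surviving tissue fraction;
    ``baseline`` is the thickness of an intact (no-elimination) layer and
    ``cv`` the between-animal coefficient of variation of the measurement.
    """
    return baseline * cohort_tissue_fraction(config, cv=cv)
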