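"""Uniform-genotype versus mosaic contrast: an estimable competition effect.

A hemizygote-analog cohort is uniformly low-fitness (every cell carries the
mutant-analog X), so its survival reflects the cell-autonomous rate alone; in
a mosaic cohort the same lineage additionally competes with normal-allele
neighbors.  Under the linear penalty ``s_mosaic = s_base * (1 - kappa *
phi_high)`` the competition coefficient is identified by inversion:

    kappa_hat = (1 - s_mosaic / s_base_reference) / phi_high_mean

where ``phi_high_mean`` is the observed reporter-positive fraction of the
mosaic tissue averaged over stages (the pre-elimination 0.5 is unobservable;
for a two-stage design the stage average includes the near-pre-elimination
first-stage fraction).  This is the package's own identification strategy —
the biology asserts a competitive mechanism, not a functional law — and
outputs are labelled accordingly.  ``kappa_hat`` is reported both raw and
clipped to [0, 1]; uncertainty is a paired animal-level percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._bootstrap import _expanded_levels, bootstrap_indices
from .errors import EmptyGroupError, SchemaError, UnidentifiableCompetitionError
from .stats import ComparisonResult, two_sample_compare
from .survival import correct_miscount

__all__ = [
    "PairedCohortResult",
    "CompetitionEstimator",
    "estimate_competition",
    "invert_kappa",
    "compare_layer_thickness",
]


def invert_kappa(s_base_reference: float, s_mosaic: float, phi_high: float) -> float:
    """Linear-form inversion ``(1 - s_mosaic / s_ref) / phi_high`` (unclipped)."""
    if s_base_reference <= 0.0 or s_base_reference > 1.0:
        raise ValueError("s_base_reference must lie in (0, 1]")
    if phi_high <= 0.0:
        raise UnidentifiableCompetitionError(
            "competition is unidentifiable with no normal-allele cells (phi_high = 0)"
        )
    return (1.0 - s_mosaic / s_base_reference) / phi_high


@dataclass
class PairedCohortResult:
    """Outcome of the uniform-vs-mosaic competition contrast."""

    s_uniform: float
    s_mosaic: float
    s_mosaic_sem: float
    kappa_raw: float
    kappa_hat: float
    delta: float
    ci_low: float
    ci_high: float
    phi_high_mean: float
    n_animals: int
    model: str = "linear penalty (package identification strategy)"

    def to_dict(self) -> dict:
        return {
            "s_uniform": self.s_uniform,
            "s_mosaic": self.s_mosaic,
            "s_mosaic_sem": self.s_mosaic_sem,
            "kappa_raw": self.kappa_raw,
            "kappa_hat": self.kappa_hat,
            "delta": self.delta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "phi_high_mean": self.phi_high_mean,
            "n_animals": self.n_animals,
            "model": self.model,
        }


def _per_animal_summaries(
    mosaic: pd.DataFrame, alpha: float, final_stage: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal (survival at final stage, stage-averaged positive fraction)."""
    required = {"animal_id", "stage", "n_gfp_pos", "n_gfp_neg"}
    missing = required - set(mosaic.columns)
    if missing:
        raise SchemaError(f"mosaic count table is missing columns: {sorted(missing)}")
    if len(mosaic) == 0:
        raise EmptyGroupError("mosaic count table is empty")
    stages = list(dict.fromkeys(mosaic["stage"]))
    if final_stage is None:
        final_stage = stages[-1]
    elif final_stage not in stages:
        raise SchemaError(f"final stage {final_stage!r} not present in table")
    pooled = mosaic.groupby(["animal_id", "stage"], sort=False)[
        ["n_gfp_pos", "n_gfp_neg"]
    ].sum()
    frac = pooled["n_gfp_pos"] / (pooled["n_gfp_pos"] + pooled["n_gfp_neg"])
    if alpha > 0.0:
        frac = pd.Series(correct_miscount(frac.to_numpy(), alpha), index=frac.index)
    by_animal = frac.unstack("stage")
    phi = by_animal.mean(axis=1).to_numpy()
    final = by_animal[final_stage].to_numpy()
    if np.any(final <= 0):
        raise UnidentifiableCompetitionError(
            "an animal has no positive cells at the final stage; survival undefined"
        )
    surv = np.minimum(1.0 / final - 1.0, 1.0)
    return surv, phi


class CompetitionEstimator(BaseEstimator):
    """Estimate the competition coefficient from a mosaic count table.

    Parameters
    ----------
    s_base_reference : float
        Cell-autonomous (uniform-cohort) cumulative survival in (0, 1], from
        simulation truth or an external estimate; the uniform cohort's own
        reporter fractions carry no survival information (the tissue is
        single-genotype).
    alpha : float
        Optional one-way miscount correction applied to fractions.
    final_stage : str or None
        Stage whose fraction yields the mosaic survival estimate (default:
        last stage present).
    n_bootstrap, ci_level, random_state
        Paired percentile bootstrap over animals for the CI of ``kappa_raw``.

    Attributes
    ----------
    kappa_, kappa_raw_, delta_, ci_, s_mosaic_, phi_high_mean_, result_
    """

    def __init__(
        self,
        s_base_reference: float = 1.0,
        alpha: float = 0.0,
        final_stage: str | None = None,
        n_bootstrap: int = 2000,
        ci_level: float = 0.95,
        random_state: int = 0,
    ):
        self.s_base_reference = s_base_reference
        self.alpha = alpha
        self.final_stage = final_stage
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "CompetitionEstimator":
        s_ref = float(self.s_base_reference)
        if not (0.0 < s_ref <= 1.0):
            raise ValueError("s_base_reference must lie in (0, 1]")
        surv, phi = _per_animal_summaries(X, self.alpha, self.final_stage)
        n = len(surv)
        s_mosaic = float(np.mean(surv))
        phi_mean = float(np.mean(phi))
        kappa_raw = invert_kappa(s_ref, s_mosaic, phi_mean)
        rng = np.random.default_rng(self.random_state)
        if n > 1:
            idx = bootstrap_indices(n, self.n_bootstrap, rng)
            s_boot = surv[idx].mean(axis=1)
            phi_boot = phi[idx].mean(axis=1)
            with np.errstate(divide="ignore"):
                k_boot = (1.0 - s_boot / s_ref) / phi_boot
            if n > 2:
                lo, hi = _expanded_levels(n, self.ci_level)
            else:
                lo = (1.0 - self.ci_level) / 2.0
                hi = 1.0 - lo
            ci = (float(np.quantile(k_boot, lo)), float(np.quantile(k_boot, hi)))
        else:
            ci = (kappa_raw, kappa_raw)
        self.s_mosaic_ = s_mosaic
        self.s_mosaic_sem_ = (
            float(np.std(surv, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        )
        self.phi_high_mean_ = phi_mean
        self.kappa_raw_ = float(kappa_raw)
        self.kappa_ = float(np.clip(kappa_raw, 0.0, 1.0))
        self.delta_ = s_ref - s_mosaic
        self.ci_ = ci
        self.n_animals_ = n
        self.result_ = PairedCohortResult(
            s_uniform=s_ref,
            s_mosaic=s_mosaic,
            s_mosaic_sem=self.s_mosaic_sem_,
            kappa_raw=self.kappa_raw_,
            kappa_hat=self.kappa_,
            delta=self.delta_,
            ci_low=ci[0],
            ci_high=ci[1],
            phi_high_mean=phi_mean,
            n_animals=n,
        )
        return self


def estimate_competition(
    uniform,
    mosaic: pd.DataFrame,
    s_base_reference: float | None = None,
    **kwargs,
) -> PairedCohortResult:
    """Competition contrast between a uniform and a mosaic cohort.

    ``uniform`` may be a survival scalar (used directly as the cell-autonomous
    reference) or a count table of the uniform cohort, in which case
    ``s_base_reference`` must be supplied separately — a single-genotype
    tissue's reporter fractions cannot identify its own survival.
    """
    if isinstance(uniform, (int, float, np.floating)):
        s_ref = float(uniform)
    else:
        if s_base_reference is None:
            raise ValueError(
                "with a uniform count table, s_base_reference must be given "
                "(simulation truth or an external estimate such as layer thickness)"
            )
        s_ref = float(s_base_reference)
    est = CompetitionEstimator(s_base_reference=s_ref, **kwargs).fit(mosaic)
    return est.result_


def compare_layer_thickness(uniform, mosaic, **kwargs) -> ComparisonResult:
    """Two-sample comparison of layer-thickness measurements.

    Delegates to :func:`xcimosaic.stats.two_sample_compare` (equal-variance
    Student's t by default, Shapiro-Wilk recorded).
    """
    return two_sample_compare(uniform, mosaic, **kwargs)
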