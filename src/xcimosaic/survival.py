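"""Estimation of mutant-lineage survival from reporter-positive fractions.

Model.  Under random XCI the two lineages are produced in equal numbers, the
reporter-positive (normal-allele) lineage is assumed to survive fully, and
the reporter-negative (mutant) lineage survives with probability
``P_survival``.  The observed positive fraction then satisfies

    P_GFP+ = 1 / (1 + P_survival)            (forward model)
    P_survival = 1 / P_GFP+ - 1              (estimator)

Aggregation follows the reported-experiment convention: each animal's counts
are pooled into one fraction, transformed to a survival estimate, and the
group summary is the mean ± SEM across animals.  Per-animal estimates above 1
(positive fraction below 0.5) are capped at 1 and flagged, since the
generative model bounds survival at 1.  Uncertainty is a seeded percentile
bootstrap over animals (default B = 2000), appropriate for the 4–8 animals
per group typical of these experiments.

An optional one-way misclassification correction removes an assumed
false-positive rate ``alpha`` (autofluorescence over-counting) before the
transform: ``p_true = (p_obs - alpha) / (1 - alpha)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._bootstrap import percentile_bootstrap_ci
from .errors import (
    EmptyGroupError,
    InfeasibleCorrectionError,
    SchemaError,
    UndefinedEstimateError,
)

__all__ = [
    "GfpFraction",
    "SurvivalEstimate",
    "forward_gfp_fraction",
    "estimate_survival",
    "correct_miscount",
    "MosaicSurvivalEstimator",
    "aggregate_per_animal",
    "ESTIMATE_COLUMNS",
]

ESTIMATE_COLUMNS = [
    "n_animals",
    "mean_gfp_pct",
    "sem_gfp_pct",
    "p_survival_mean",
    "p_survival_sem",
    "ci_low",
    "ci_high",
    "clipped_n",
]


@dataclass(frozen=True)
class GfpFraction:
    """An observed reporter-positive proportion with its denominator."""

    value: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"GFP fraction must lie in [0, 1], got {self.value!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @classmethod
    def from_counts(cls, n_gfp_pos: int, n_gfp_neg: int) -> "GfpFraction":
        total = n_gfp_pos + n_gfp_neg
        if total < 1:
            raise SchemaError("a count record needs n_gfp_pos + n_gfp_neg >= 1")
        return cls(value=n_gfp_pos / total, n_cells=total)


@dataclass
class SurvivalEstimate:
    """Per-group survival summary: per-animal estimates, mean ± SEM, bootstrap CI."""

    per_animal: np.ndarray
    mean: float
    sem: float
    ci_low: float
    ci_high: float
    n_clipped: int
    method: str = "raw"
    mean_gfp: float = float("nan")
    sem_gfp: float = float("nan")

    @property
    def point(self) -> float:
        return self.mean

    @property
    def clipped(self) -> bool:
        return self.n_clipped > 0

    @property
    def n_animals(self) -> int:
        return len(self.per_animal)


def forward_gfp_fraction(p_survival):
    """Expected positive fraction ``1 / (1 + s)`` for survival ``s`` in [0, 1].

    Exact inverse of :func:`estimate_survival` on (0, 1]; accepts scalars or
    arrays.
    """
    s = np.asarray(p_survival, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("p_survival must lie in [0, 1]")
    out = 1.0 / (1.0 + s)
    return float(out) if np.isscalar(p_survival) or out.ndim == 0 else out


def estimate_survival(p_gfp):
    """Survival estimate ``1 / P_GFP+ - 1`` for a positive fraction in (0, 1].

    Accepts a float, a :class:`GfpFraction`, or an array.  A fraction of zero
    leaves survival undefined (the model assumes the positive lineage
    persists) and raises :class:`UndefinedEstimateError`.  Values above 1
    (fractions below 0.5) are returned as computed; aggregation decides about
    capping.
    """
    if isinstance(p_gfp, GfpFraction):
        p_gfp = p_gfp.value
    p = np.asarray(p_gfp, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("GFP fraction must lie in [0, 1]")
    if np.any(p == 0):
        raise UndefinedEstimateError(
            "GFP-positive fraction of 0 leaves survival undefined (division by zero)"
        )
    out = 1.0 / p - 1.0
    return float(out) if out.ndim == 0 else out


def correct_miscount(p_obs, alpha: float):
    """Remove a one-way false-positive rate: ``(p_obs - alpha) / (1 - alpha)``.

    ``alpha`` is the probability that a truly negative cell is recorded
    positive.  Observed fractions below ``alpha`` are infeasible under the
    assumed misclassification model.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    p = np.asarray(p_obs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("observed fraction must lie in [0, 1]")
    if np.any(p < alpha):
        raise InfeasibleCorrectionError(
            f"observed fraction below the false-positive rate alpha={alpha}"
        )
    out = (p - alpha) / (1.0 - alpha)
    return float(out) if out.ndim == 0 else out


def _estimate_group(
    fractions: np.ndarray,
    animal_ids: Sequence[str],
    alpha: float,
    cap: bool,
    n_bootstrap: int,
    ci_level: float,
    rng: np.random.Generator,
) -> SurvivalEstimate:
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise EmptyGroupError("no animals in group")
    zero = fractions == 0.0
    if np.any(zero):
        bad = ", ".join(str(a) for a, z in zip(animal_ids, zero) if z)
        raise UndefinedEstimateError(
            f"animal(s) with GFP-positive fraction 0 (survival undefined): {bad}"
        )
    method = "raw"
    if alpha > 0.0:
        fractions = correct_miscount(fractions, alpha)
        method = "bias_corrected"
        zero = fractions == 0.0
        if np.any(zero):
            bad = ", ".join(str(a) for a, z in zip(animal_ids, zero) if z)
            raise UndefinedEstimateError(
                f"animal(s) at exactly the false-positive rate after correction: {bad}"
            )
    raw = 1.0 / fractions - 1.0
    n_clipped = int(np.sum(raw > 1.0)) if cap else 0
    per_animal = np.minimum(raw, 1.0) if cap else raw
    n = len(per_animal)
    mean = float(np.mean(per_animal))
    sem = float(np.std(per_animal, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    # CI: resample the untruncated per-animal estimates, then clip the interval
    # into the model space [0, 1] (bounded-parameter bootstrap); resampling the
    # capped values instead truncates the upper tail and undercovers near s = 1
    ci_low, ci_high = percentile_bootstrap_ci(raw, n_bootstrap, ci_level, rng)
    if cap:
        ci_low, ci_high = min(ci_low, 1.0), min(ci_high, 1.0)
    return SurvivalEstimate(
        per_animal=per_animal,
        mean=mean,
        sem=sem,
        ci_low=ci_low,
        ci_high=ci_high,
        n_clipped=n_clipped,
        method=method,
        mean_gfp=float(np.mean(fractions)),
        sem_gfp=float(np.std(fractions, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def _pool_animal_fractions(records: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Pool each animal's counts within a group into one fraction."""
    pooled = records.groupby("animal_id", sort=True)[["n_gfp_pos", "n_gfp_neg"]].sum()
    totals = pooled["n_gfp_pos"] + pooled["n_gfp_neg"]
    if np.any(totals < 1):
        bad = ", ".join(str(a) for a in pooled.index[totals < 1])
        raise SchemaError(f"animal(s) with zero counted cells: {bad}")
    return (pooled["n_gfp_pos"] / totals).to_numpy(), list(pooled.index)


class MosaicSurvivalEstimator(BaseEstimator):
    """Mutant-lineage survival from grouped count tables (sklearn-style).

    Parameters
    ----------
    group_keys : tuple of str
        Columns defining an estimation group; keys absent from the input are
        ignored, so the default works for tables with or without a cohort
        column.
    alpha : float
        One-way false-positive (miscount) rate removed from each animal's
        fraction before the survival transform; 0 disables correction.
    cap : bool
        Cap per-animal estimates at 1 (fractions below 0.5 cannot arise from
        the generative model without noise); the capped count is reported.
    n_bootstrap, ci_level, random_state
        Percentile-bootstrap settings (resampling animals within a group).

    Attributes
    ----------
    estimates_ : pandas.DataFrame
        One row per group, with group keys and the estimate columns.
    groups_ : dict
        Group key tuple -> :class:`SurvivalEstimate` (per-animal detail).
    """

    def __init__(
        self,
        group_keys: tuple = ("cohort", "region", "stage"),
        alpha: float = 0.0,
        cap: bool = True,
        n_bootstrap: int = 2000,
        ci_level: float = 0.95,
        random_state: int = 0,
    ):
        self.group_keys = group_keys
        self.alpha = alpha
        self.cap = cap
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "MosaicSurvivalEstimator":
        """Compute per-group survival estimates from a count table."""
        required = {"animal_id", "n_gfp_pos", "n_gfp_neg"}
        missing = required - set(X.columns)
        if missing:
            raise SchemaError(f"count table is missing columns: {sorted(missing)}")
        if len(X) == 0:
            raise EmptyGroupError("count table is empty")
        keys = [k for k in self.group_keys if k in X.columns]
        root = np.random.SeedSequence(self.random_state)
        groups: dict = {}
        rows = []
        if keys:
            grouped = sorted(X.groupby(keys, sort=True), key=lambda kv: str(kv[0]))
        else:
            grouped = [((), X)]
        children = root.spawn(len(grouped))
        for (key, sub), child in zip(grouped, children):
            if not isinstance(key, tuple):
                key = (key,)
            fractions, animal_ids = _pool_animal_fractions(sub)
            est = _estimate_group(
                fractions,
                animal_ids,
                alpha=self.alpha,
                cap=self.cap,
                n_bootstrap=self.n_bootstrap,
                ci_level=self.ci_level,
                rng=np.random.default_rng(child),
            )
            groups[key] = est
            rows.append(
                dict(zip(keys, key))
                | {
                    "n_animals": est.n_animals,
                    "mean_gfp_pct": 100.0 * est.mean_gfp,
                    "sem_gfp_pct": 100.0 * est.sem_gfp,
                    "p_survival_mean": est.mean,
                    "p_survival_sem": est.sem,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "clipped_n": est.n_clipped,
                }
            )
        self.group_keys_ = tuple(keys)
        self.groups_ = groups
        self.estimates_ = pd.DataFrame(rows, columns=list(keys) + ESTIMATE_COLUMNS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fit on ``X`` and return the per-group estimate table."""
        return self.fit(X).estimates_


def aggregate_per_animal(
    records: pd.DataFrame,
    group_keys: tuple = ("cohort", "region", "stage"),
    alpha: float = 0.0,
    cap: bool = True,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    random_state: int = 0,
):
    """Per-animal-then-average survival estimation over a count table.

    Thin functional wrapper around :class:`MosaicSurvivalEstimator`; returns
    the fitted estimator (``.estimates_`` holds the summary table, ``.groups_``
    the per-animal detail).
    """
    est = MosaicSurvivalEstimator(
        group_keys=group_keys,
        alpha=alpha,
        cap=cap,
        n_bootstrap=n_bootstrap,
        ci_level=ci_level,
        random_state=random_state,
    )
    return est.fit(records)
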