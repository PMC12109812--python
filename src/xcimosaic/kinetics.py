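"""Staged-hazard model of the postnatal reporter-positivity trajectory.

In the mosaic cerebellum the granule-cell reporter-positive fraction starts
near 50% (random XCI) and rises across postnatal stages as the mutant lineage
is eliminated.  With inactivation probability ``p`` and per-stage mutant
survivals ``s_1..s_T`` (entry 1 covering any elimination before the first
observed stage, normally 1), the expected positive fraction at stage t is

    f_t = p / (p + (1 - p) * prod_{k<=t} s_k)

which for p = 0.5 reduces to ``1 / (1 + cumulative survival)``, consistent
with the survival estimator.  Fitting recovers the per-stage survivals from
an observed trajectory by box-constrained weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .errors import SchemaError, UnderdeterminedFitError

__all__ = [
    "StageTrajectory",
    "HazardFit",
    "predict_trajectory",
    "fit_trajectory",
    "StagedHazardEstimator",
    "trajectory_from_counts",
]


@dataclass(frozen=True)
class StageTrajectory:
    """Observed per-stage positive fractions with SEM and animal counts."""

    stages: tuple[str, ...]
    gfp_fraction_mean: tuple[float, ...]
    gfp_fraction_sem: tuple[float, ...]
    n_animals: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.stages)
        for name in ("gfp_fraction_mean", "gfp_fraction_sem", "n_animals"):
            if len(getattr(self, name)) != n:
                raise SchemaError(f"{name} must have one entry per stage")
        for f in self.gfp_fraction_mean:
            if not (0.0 < f <= 1.0):
                raise SchemaError("stage fractions must lie in (0, 1]")
        for s in self.gfp_fraction_sem:
            if s < 0:
                raise SchemaError("SEMs must be non-negative")
        for m in self.n_animals:
            if m < 1:
                raise SchemaError("n_animals must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StageTrajectory":
        required = {"stage", "gfp_fraction_mean", "gfp_fraction_sem", "n_animals"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"trajectory table is missing columns: {sorted(missing)}")
        return cls(
            stages=tuple(str(s) for s in df["stage"]),
            gfp_fraction_mean=tuple(float(v) for v in df["gfp_fraction_mean"]),
            gfp_fraction_sem=tuple(float(v) for v in df["gfp_fraction_sem"]),
            n_animals=tuple(int(v) for v in df["n_animals"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stages,
                "gfp_fraction_mean": self.gfp_fraction_mean,
                "gfp_fraction_sem": self.gfp_fraction_sem,
                "n_animals": self.n_animals,
            }
        )


@dataclass
class HazardFit:
    """Result of a staged-hazard fit."""

    per_stage_survival: np.ndarray
    cumulative_survival: float
    sse: float
    fitted_fractions: np.ndarray
    stages: tuple[str, ...] = ()


def predict_trajectory(per_stage_survival, p: float = 0.5) -> np.ndarray:
    """Expected positive fraction at each stage for given per-stage survivals."""
    s = np.asarray(per_stage_survival, dtype=float)
    if s.size == 0:
        raise UnderdeterminedFitError("need at least one stage")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("per-stage survivals must lie in [0, 1]")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    cum = np.cumprod(s)
    return p / (p + (1.0 - p) * cum)


def _closed_form_start(obs: np.ndarray, p: float) -> np.ndarray:
    """Stagewise inversion of the forward model as an optimizer start.

    The cumulative survival at stage t is ``c_t = p (1 - f_t) / ((1 - p) f_t)``;
    per-stage survivals are the successive ratios, clipped into the box.
    """
    c = p * (1.0 - obs) / ((1.0 - p) * obs)
    s = np.empty_like(c)
    s[0] = c[0]
    prev = np.maximum(c[:-1], 1e-12)
    s[1:] = c[1:] / prev
    return np.clip(s, 0.0, 1.0)


class StagedHazardEstimator(BaseEstimator):
    """Box-constrained weighted least-squares fit of per-stage survivals.

    Parameters
    ----------
    p : float
        Pre-elimination positive fraction (random XCI: 0.5).
    starts : tuple of float
        Constant-vector multi-starts added to the closed-form stagewise start
        to avoid local minima; the fit is deterministic.
    tol : float
        Optimizer function tolerance.

    Attributes
    ----------
    per_stage_survival_ : ndarray
    cumulative_survival_ : float
    sse_ : float
        Weighted sum of squared residuals (weights 1/sem² where sem > 0,
        else 1).
    fit_ : HazardFit
    """

    def __init__(
        self,
        p: float = 0.5,
        starts: tuple = (0.05, 0.25, 0.5, 0.75, 0.95, 1.0),
        tol: float = 1e-14,
    ):
        self.p = p
        self.starts = starts
        self.tol = tol

    def fit(self, X, y=None) -> "StagedHazardEstimator":
        """Fit per-stage survivals to a :class:`StageTrajectory` (or its frame)."""
        traj = X
        if isinstance(traj, pd.DataFrame):
            traj = StageTrajectory.from_frame(traj)
        if not isinstance(traj, StageTrajectory):
            raise TypeError("fit expects a StageTrajectory or its DataFrame form")
        obs = np.asarray(traj.gfp_fraction_mean, dtype=float)
        sem = np.asarray(traj.gfp_fraction_sem, dtype=float)
        n_stages = obs.size
        if n_stages < 2:
            raise UnderdeterminedFitError(
                "staged-hazard fit needs at least 2 stages; per-stage survival is "
                "not identifiable from a single fraction"
            )
        weights = np.where(sem > 0, 1.0 / np.maximum(sem, 1e-12) ** 2, 1.0)
        p = self.p

        def objective(s: np.ndarray) -> float:
            pred = p / (p + (1.0 - p) * np.cumprod(s))
            r = pred - obs
            return float(np.sum(weights * r * r))

        bounds = [(0.0, 1.0)] * n_stages
        candidates = [_closed_form_start(obs, p)]
        candidates += [np.full(n_stages, c) for c in self.starts]
        best = None
        for x0 in candidates:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": self.tol, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        s_hat = np.clip(best.x, 0.0, 1.0)
        self.per_stage_survival_ = s_hat
        self.cumulative_survival_ = float(np.prod(s_hat))
        self.sse_ = float(best.fun)
        self.stages_ = traj.stages
        self.fit_ = HazardFit(
            per_stage_survival=s_hat,
            cumulative_survival=self.cumulative_survival_,
            sse=self.sse_,
            fitted_fractions=predict_trajectory(s_hat, p),
            stages=traj.stages,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted positive-fraction trajectory at the training stages."""
        return self.fit_.fitted_fractions


def fit_trajectory(traj: StageTrajectory, p: float = 0.5, **kwargs) -> HazardFit:
    """Functional wrapper around :class:`StagedHazardEstimator`."""
    return StagedHazardEstimator(p=p, **kwargs).fit(traj).fit_


def trajectory_from_counts(records: pd.DataFrame, region: str | None = None) -> StageTrajectory:
    """Summarize a count table into a per-stage trajectory.

    Each animal's counts are pooled within a stage (optionally restricted to
    one region); the trajectory carries the across-animal mean, SEM and n per
    stage, in first-appearance stage order.
    """
    df = records
    if region is not None:
        df = df[df["region"] == region]
    if len(df) == 0:
        raise SchemaError("no records to summarize")
    stage_order = list(dict.fromkeys(df["stage"]))
    means, sems, ns = [], [], []
    for stage in stage_order:
        sub = df[df["stage"] == stage]
        pooled = sub.groupby("animal_id")[["n_gfp_pos", "n_gfp_neg"]].sum()
        frac = pooled["n_gfp_pos"] / (pooled["n_gfp_pos"] + pooled["n_gfp_neg"])
        means.append(float(frac.mean()))
        sems.append(float(frac.std(ddof=1) / np.sqrt(len(frac))) if len(frac) > 1 else 0.0)
        ns.append(int(len(frac)))
    return StageTrajectory(
        stages=tuple(stage_order),
        gfp_fraction_mean=tuple(means),
        gfp_fraction_sem=tuple(sems),
        n_animals=tuple(ns),
    )
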