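"""Tests for the XCI-mosaic cohort simulator.

The Monte-Carlo expectations are checked against an independent brute-force
reimplementation (plain per-founder/per-cell loops using the stdlib RNG) so
the main vectorized simulator is never its own oracle.
"""

import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xcimosaic import (
    CompetitionModel,
    ConfigurationError,
    SimCohortConfig,
    SurvivalSpec,
    cohort_tissue_fraction,
    expected_cumulative_survival,
    expected_gfp_fraction,
    simulate_animal,
    simulate_cohort,
    simulate_paired_design,
)


def brute_force_mean_fraction(
    p, s_stages, n_founders, n_cells, n_animals, seed, alpha=0.0
):
    """Straight-loop oracle: expected final-stage observed positive fraction.

    Equal clones, no competition; one python-random stream, nothing shared
    with the package's generator.
    """
    rng = random.Random(seed)
    fractions = []
    for _ in range(n_animals):
        pos_founders = sum(1 for _ in range(n_founders) if rng.random() < p)
        phi = pos_founders / n_founders
        s_cum = 1.0
        for s in s_stages:
            s_cum *= s
        denom = phi + (1 - phi) * s_cum
        f = phi / denom if denom > 0 else 0.0
        n_pos = 0
        for _ in range(n_cells):
            is_pos = rng.random() < f
            if not is_pos and rng.random() < alpha:
                is_pos = True
            n_pos += is_pos
        fractions.append(n_pos / n_cells)
    return float(np.mean(fractions)), float(np.std(fractions, ddof=1) / np.sqrt(n_animals))


def adult_fractions(table, n_cells=500, stage="adult"):
    sub = table[table["stage"] == stage]
    return (sub["n_gfp_pos"] / n_cells).to_numpy()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_inactivate_mutant_x": 1.5},
            {"miscount_rate_alpha": -0.1},
            {"n_founders": 0},
            {"stages": ()},
            {"stages": ("P6", "P6")},
            {"clone_dispersion": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimCohortConfig(**kwargs)

    def test_survival_stage_mismatch(self):
        with pytest.raises(ConfigurationError):
            SimCohortConfig(stages=("P6", "adult"), survival_model=SurvivalSpec(s_base=(1.0,)))

    def test_animal_index_out_of_range(self):
        cfg = SimCohortConfig(n_animals=2, stages=("P6",))
        with pytest.raises(ConfigurationError):
            simulate_animal(cfg, 2)


class TestGenerativeExpectations:
    def test_no_elimination_gives_half(self, wt_config):
        table = simulate_cohort(wt_config)
        frac = adult_fractions(table)
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_total_elimination_gives_one(self):
        cfg = SimCohortConfig(
            n_animals=6,
            stages=("P6", "P13", "adult"),
            survival_model=SurvivalSpec(s_base=(1.0, 0.0, 1.0)),
            seed=5,
        )
        table = simulate_cohort(cfg)
        for stage in ("P13", "adult"):  # all post-elimination stages
            assert (table[table["stage"] == stage]["n_gfp_neg"] == 0).all()

    def test_quarter_survival_closed_form(self):
        # cumulative s = 0.25 -> expected fraction 1/(1+0.25) = 0.8
        cfg = SimCohortConfig(
            n_animals=12,
            n_founders=5000,
            clone_dispersion=0.0,
            stages=("P6", "adult"),
            survival_model=SurvivalSpec(s_base=(1.0, 0.25)),
            seed=3,
        )
        frac = adult_fractions(simulate_cohort(cfg))
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.8) < 3 * max(se, 1e-3)

    def test_partial_elimination_matches_brute_force_oracle(self, partial_elimination_config):
        # analytic expectation 1/(1+0.714) = 0.58343; verified independently
        oracle_mean, oracle_se = brute_force_mean_fraction(
            p=0.5, s_stages=(1.0, 0.714), n_founders=200, n_cells=500,
            n_animals=400, seed=99,
        )
        assert abs(oracle_mean - 1 / 1.714) < 3 * oracle_se
        table = simulate_cohort(partial_elimination_config)
        frac = adult_fractions(table)
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 1 / 1.714) < 3 * se

    def test_miscount_shifts_mean_by_alpha(self):
        alpha = 0.1
        cfg = SimCohortConfig(
            n_animals=100, stages=("adult",), miscount_rate_alpha=alpha, seed=21
        )
        frac = adult_fractions(simulate_cohort(cfg))
        expected = 0.5 + alpha * 0.5
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - expected) < 3 * se
        np.testing.assert_allclose(expected_gfp_fraction(cfg), [expected])

    def test_counts_conserve_requested_cells(self, partial_elimination_config):
        table = simulate_cohort(partial_elimination_config)
        totals = table["n_gfp_pos"] + table["n_gfp_neg"]
        assert (totals == partial_elimination_config.n_cells_per_region).all()

    def test_binomial_consistency_large_founder_pool(self):
        # with no elimination and a huge founder pool the counts reduce to
        # Binomial(n_cells, p); chi-square GOF over 200 animal draws
        cfg = SimCohortConfig(
            n_animals=200,
            n_founders=50000,
            clone_dispersion=0.0,
            n_cells_per_region=500,
            stages=("adult",),
            seed=17,
        )
        counts = simulate_cohort(cfg)["n_gfp_pos"].to_numpy()
        edges = sps.binom.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], 500, 0.5)
        observed, _ = np.histogram(counts, bins=np.r_[-0.5, edges[1:-1] + 0.5, 500.5])
        probs = np.diff(sps.binom.cdf(np.r_[-1, edges[1:-1], 500], 500, 0.5))
        chi2 = sps.chisquare(observed, probs / probs.sum() * len(counts))
        assert chi2.pvalue > 0.01

    def test_monotonicity_in_stage_survival(self):
        base = (1.0, 0.8, 0.9)
        lowered = (1.0, 0.5, 0.9)
        cfg = lambda s: SimCohortConfig(
            stages=("P6", "P13", "adult"), survival_model=SurvivalSpec(s_base=s)
        )
        f_base = expected_gfp_fraction(cfg(base))
        f_low = expected_gfp_fraction(cfg(lowered))
        assert f_low[0] == f_base[0]
        assert (f_low[1:] >= f_base[1:]).all()
        assert f_low[1] > f_base[1]


class TestDispersion:
    def _per_animal_sd(self, n_founders, dispersion, seed=31):
        cfg = SimCohortConfig(
            n_animals=400,
            n_founders=n_founders,
            clone_dispersion=dispersion,
            stages=("adult",),
            seed=seed,
        )
        return adult_fractions(simulate_cohort(cfg)).std(ddof=1)

    def test_variance_rises_with_clone_dispersion(self):
        assert self._per_animal_sd(50, 4.0) > self._per_animal_sd(50, 0.0)

    def test_variance_falls_with_founder_pool(self):
        assert self._per_animal_sd(20, 1.0) > self._per_animal_sd(500, 1.0)

    def test_default_dispersion_matches_reported_sem_band(self):
        # between-animal SEM of the positive fraction at n = 8: 1-2 points
        sd = self._per_animal_sd(200, 1.0)
        sem_pct = 100 * sd / np.sqrt(8)
        assert 1.0 <= sem_pct <= 2.0


class TestDeterminismAndStructure:
    def test_same_seed_identical(self, wt_config):
        pd.testing.assert_frame_equal(simulate_cohort(wt_config), simulate_cohort(wt_config))

    def test_animal_records_are_cohort_rows(self, wt_config):
        one = simulate_animal(wt_config, 3)
        cohort = simulate_cohort(wt_config)
        sub = cohort[cohort["animal_id"] == "a003"].drop(columns="cohort").reset_index(drop=True)
        pd.testing.assert_frame_equal(one, sub)

    def test_zero_animals_empty_table(self):
        cfg = SimCohortConfig(n_animals=0, stages=("adult",))
        table = simulate_cohort(cfg)
        assert len(table) == 0
        assert list(table.columns) == ["cohort", "animal_id", "region", "stage", "n_gfp_pos", "n_gfp_neg"]

    def test_seeds_differ_but_means_agree(self, partial_elimination_config):
        big = partial_elimination_config.replace(n_animals=60, seed=1)
        a = adult_fractions(simulate_cohort(big))
        b = adult_fractions(simulate_cohort(big.replace(seed=2)))
        assert not np.array_equal(a, b)
        se = np.hypot(a.std(ddof=1) / np.sqrt(len(a)), b.std(ddof=1) / np.sqrt(len(b)))
        assert abs(a.mean() - b.mean()) < 4 * se


class TestCompetitionMechanics:
    def test_linear_penalty_algebra(self):
        comp = CompetitionModel(kappa=0.5)
        assert comp.effective_survival(0.8, 0.5) == pytest.approx(0.8 * 0.75)
        assert CompetitionModel(kappa=1.0).effective_survival(0.7, 1.0) == pytest.approx(0.0)

    def test_paired_design_requires_matching_stages(self):
        uni = SimCohortConfig(p_inactivate_mutant_x=0.0, stages=("P6", "adult"),
                              survival_model=SurvivalSpec(s_base=(1.0, 0.8)))
        mos = SimCohortConfig(p_inactivate_mutant_x=0.5, stages=("P6", "P13"),
                              survival_model=SurvivalSpec(s_base=(1.0, 0.8)))
        with pytest.raises(ConfigurationError):
            simulate_paired_design(uni, mos)

    def test_paired_design_requires_uniform_p(self):
        cfg = SimCohortConfig(p_inactivate_mutant_x=0.5)
        with pytest.raises(ConfigurationError):
            simulate_paired_design(cfg, cfg)

    def test_penalty_inert_in_uniform_mutant_tissue(self):
        spec = SurvivalSpec(s_base=(1.0, 0.8), competition=CompetitionModel(kappa=0.9))
        uni = SimCohortConfig(p_inactivate_mutant_x=0.0, stages=("P6", "adult"), survival_model=spec)
        assert expected_cumulative_survival(uni) == pytest.approx(0.8)

    def test_expected_mosaic_survival_under_penalty(self):
        # kappa=0.5, cumulative s_base=0.8, phi ~ 0.5 -> 0.8 * (1 - 0.25) = 0.6
        spec = SurvivalSpec(s_base=(1.0, 0.8), competition=CompetitionModel(kappa=0.5))
        mos = SimCohortConfig(p_inactivate_mutant_x=0.5, stages=("P6", "adult"), survival_model=spec)
        assert expected_cumulative_survival(mos) == pytest.approx(0.6)

    def test_kappa_zero_matches_no_competition(self):
        spec0 = SurvivalSpec(s_base=(1.0, 0.8), competition=CompetitionModel(kappa=0.0))
        spec = SurvivalSpec(s_base=(1.0, 0.8))
        kw = dict(p_inactivate_mutant_x=0.5, stages=("P6", "adult"), seed=13)
        a = simulate_cohort(SimCohortConfig(survival_model=spec0, **kw))
        b = simulate_cohort(SimCohortConfig(survival_model=spec, **kw))
        assert np.allclose(
            adult_fractions(a).mean(), adult_fractions(b).mean(), atol=0.02
        )

    def test_tissue_fraction_uniform_vs_mosaic(self):
        # uniform mutant tissue keeps fraction s_base; mosaic keeps phi + (1-phi) s_eff
        spec = SurvivalSpec(s_base=(1.0, 0.8), competition=CompetitionModel(kappa=0.5))
        uni = SimCohortConfig(n_animals=4, p_inactivate_mutant_x=0.0, stages=("P6", "adult"), survival_model=spec)
        frac = cohort_tissue_fraction(uni)
        np.testing.assert_allclose(frac, 0.8)
        mos = SimCohortConfig(n_animals=50, p_inactivate_mutant_x=0.5, stages=("P6", "adult"), survival_model=spec, seed=2)
        assert cohort_tissue_fraction(mos).mean() == pytest.approx(0.5 + 0.5 * 0.6, abs=0.02)
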