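"""End-to-end simulation experiments: generate, fit, diagnose, compare to truth.

These wrap the whole chain — world generation, covariate construction,
absence inference, MCMC fit, diagnostics and the posterior counterfactual —
into single calls used by the analysis drivers, the test suite and the
acceptance script.  All randomness descends from one integer seed through a
``SeedSequence`` so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counterfactual import CounterfactualSummary, percent_difference
from .covariates import build_covariate_table
from .dataset import build_model_table, infer_absences, landuse_habitat_r2
from .design import ModelSpec
from .diagnostics import (
    MoranResult,
    bayes_r2,
    bayes_r2_summary,
    morans_i,
    per_study_moran,
    per_study_moran_summary,
    site_residuals,
)
from .gibbs import PosteriorSamples, fit_model
from .synthetic import (
    LAND_USE_HUMAN,
    LAND_USE_NATURAL,
    Survey,
    TrueParameters,
    World,
    WorldConfig,
    generate_survey,
    generate_world,
    records_from_outcomes,
    simulate_occurrence,
)

__all__ = ["StudyResult", "run_full_study", "moran_null_calibration", "child_seeds"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds below 2^31 derived from one root seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31 - 1)]


@dataclass
class StudyResult:
    """Everything a full synthetic study produces."""

    world: World
    survey: Survey
    model_table: pd.DataFrame          # fitted rows (absences inferred)
    scalers: dict[str, tuple[float, float]]
    params: TrueParameters
    posterior: PosteriorSamples
    r2_marginal: np.ndarray
    r2_conditional: np.ndarray
    moran_overall: MoranResult
    moran_by_study: list[MoranResult]
    counterfactual: CounterfactualSummary
    landuse_r2: float
    true_effects: dict[str, float]     # simulated effects actually realised

    # ---- truth-recovery summaries ---------------------------------------
    def coverage_95(self) -> tuple[int, int]:
        """(# true fixed effects inside their 95% interval, total)."""
        b = self.posterior.beta_flat()
        lo, hi = np.quantile(b, [0.025, 0.975], axis=0)
        truth = self.params.vector(self.posterior.beta_labels)
        inside = int(np.sum((truth >= lo) & (truth <= hi)))
        return inside, truth.size

    def sign_recovery(self, min_magnitude: float = 1e-12) -> tuple[int, int]:
        """Posterior-median sign agreement for true nonzero pressure/niche effects."""
        med = np.median(self.posterior.beta_flat(), axis=0)
        truth = self.params.vector(self.posterior.beta_labels)
        check = [
            j
            for j, lab in enumerate(self.posterior.beta_labels)
            if lab != "intercept" and abs(truth[j]) > min_magnitude
        ]
        agree = int(sum(np.sign(med[j]) == np.sign(truth[j]) for j in check))
        return agree, len(check)

    def summary_dict(self) -> dict[str, float]:
        inside, total = self.coverage_95()
        agree, n_signs = self.sign_recovery()
        moran_frac = per_study_moran_summary(self.moran_by_study)
        return {
            "n_rows": len(self.model_table),
            "prevalence": float(self.model_table["outcome"].mean()),
            "landuse_habitat_r2": self.landuse_r2,
            "coverage_95_count": inside,
            "coverage_95_total": total,
            "sign_recovery_count": agree,
            "sign_recovery_total": n_signs,
            "max_rhat": float(self.posterior.rhat["rhat"].max()),
            "bayes_r2_marginal_median": bayes_r2_summary(self.r2_marginal)["median"],
            "bayes_r2_conditional_median": bayes_r2_summary(self.r2_conditional)["median"],
            "moran_overall_i": self.moran_overall.statistic,
            "moran_overall_p": self.moran_overall.p_value,
            "moran_study_fraction_significant": moran_frac["fraction_significant"],
            "pct_reduction_natural": self.counterfactual.median(LAND_USE_NATURAL),
            "pct_reduction_human": self.counterfactual.median(LAND_USE_HUMAN),
        }


def run_full_study(
    seed: int = 1,
    *,
    n_studies: int = 40,
    sites_per_study: int = 15,
    species_pool: int = 8,
    spec: ModelSpec | None = None,
    params: TrueParameters | None = None,
    config: WorldConfig | None = None,
    n_counterfactual_draws: int = 1000,
    moran_permutations: int = 999,
) -> StudyResult:
    """Simulate a full survey, fit the model and run every downstream analysis."""
    spec = spec or ModelSpec()
    params = params or TrueParameters.default()
    s_world, s_survey, s_sim, s_fit, s_cf, s_moran = child_seeds(seed, 6)

    config = config or WorldConfig(seed=s_world)
    world = generate_world(config, seed=s_world)
    survey = generate_survey(
        world, n_studies, sites_per_study, species_pool, seed=s_survey
    )
    covariates = build_covariate_table(world, survey)
    skeleton, scalers = build_model_table(covariates)
    simulated = simulate_occurrence(skeleton, params, seed=s_sim)

    records = records_from_outcomes(simulated)
    inferred = infer_absences(records, survey.sites)
    model_table = inferred[["study_id", "site_id", "species", "outcome"]].merge(
        skeleton, on=["study_id", "site_id", "species"], how="left", validate="1:1"
    )

    posterior = fit_model(model_table, spec, seed=s_fit)
    r2_m = bayes_r2(posterior, model_table, "marginal")
    r2_c = bayes_r2(posterior, model_table, "conditional")

    resid = site_residuals(posterior, model_table)
    moran_overall = morans_i(
        resid["residual"].to_numpy(),
        resid[["x_km", "y_km"]].to_numpy(),
        n_permutations=moran_permutations,
        seed=s_moran,
        scope="all",
    )
    moran_by_study = per_study_moran(
        resid, n_permutations=moran_permutations, seed=s_moran
    )

    cf = percent_difference(
        posterior, model_table, scalers, n_draws=n_counterfactual_draws, seed=s_cf
    )
    lu_r2 = landuse_habitat_r2(
        covariates.drop_duplicates("site_id")[["site_id", "land_use_class", "natural_habitat"]]
    )
    return StudyResult(
        world, survey, model_table, scalers, params, posterior,
        r2_m, r2_c, moran_overall, moran_by_study, cf, lu_r2,
        {k: v for k, v in params.beta.items()},
    )


def moran_null_calibration(
    n_studies: int = 400,
    sites_per_study: int = 15,
    seed: int = 0,
    *,
    n_permutations: int = 999,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate of the permutation Moran test under a spatially null model.

    Each simulated study has iid Bernoulli(1/2) outcomes at uniform random
    site locations (all effects and random-intercept SDs zero), so residuals
    carry no spatial signal and the test should reject a fraction ~alpha of
    studies.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_studies):
        coords = rng.uniform(0.0, 50.0, size=(sites_per_study, 2))
        resid = rng.integers(0, 2, sites_per_study).astype(float) - 0.5
        if np.all(resid == resid[0]):  # degenerate draw: no variance, resample
            resid[0] = -resid[0]
        results.append(
            morans_i(
                resid, coords, n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)), scope="null",
            )
        )
    summary = per_study_moran_summary(results, alpha=alpha)
    return summary
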