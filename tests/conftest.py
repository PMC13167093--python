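import numpy as np
import pandas as pd
import pytest

from methylvar import (
    SimulationConfig,
    simulate_cohort,
    build_design,
    complete_model_spec,
    fit_laplace,
)
from methylvar.cells import clr_transform, impute_missing_cells
from methylvar.lgm import FitResult, LatentModelSpec


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects × 40 sites with 10% hypervariable sites (sd multiplier 3)."""
    cfg = SimulationConfig(
        n_subjects=30, n_genes=4, sites_per_gene=10, seed=7,
        sd_site=1.5, sd_interaction=0.4, sd_subject=0.5,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_small_cohort(small_cohort):
    """Cell-adjusted complete-model fit of the small cohort."""
    coh = small_cohort
    cell_z = impute_missing_cells(clr_transform(coh.covariates), seed=0)
    spec, y, trials = build_design(
        coh.table, coh.annotation, cell_covariates=cell_z, template=complete_model_spec(True)
    )
    return fit_laplace(spec, y, trials)


def make_interaction_fit(site_ids, subject_ids, means):
    """A minimal FitResult exposing a site × subject interaction term.

    ``means`` is an array of posterior means ordered site-major.
    """
    from methylvar.lgm import PCPrior, RandomTerm

    levels = [f"{s}||{j}" for s in site_ids for j in subject_ids]
    n = len(levels)
    term = RandomTerm(
        name="site_subject",
        index=np.arange(n),
        n_levels=n,
        level_names=levels,
        prior=PCPrior(1.0, 0.05),
    )
    spec = LatentModelSpec(
        likelihood="binomial-logit",
        X=np.ones((n, 1)),
        fixed_names=["intercept"],
        fixed_prior_sd=np.array([3.0]),
        random_terms=[term],
    )
    latent = np.concatenate([[0.0], np.asarray(means, float)])
    return FitResult(
        spec=spec,
        y=np.zeros(n),
        trials=np.full(n, 10.0),
        sigma={"site_subject": 1.0},
        latent_mean=latent,
        latent_sd=np.ones(latent.size),
        log_marginal=0.0,
        n_inner_iterations=0,
        n_outer_evaluations=0,
        final_gradient_norm=0.0,
    )


@pytest.fixture
def bedmethyl_file(tmp_path):
    """3-line modkit-dialect fixture with mod codes m, h, m."""
    lines = [
        # chrom start end code score strand ts te color n_valid frac n_mod + 6 trailing
        "chr1\t100\t101\tm\t10\t+\t100\t101\t255,0,0\t10\t50.00\t5\t5\t0\t0\t0\t0\t0",
        "chr1\t100\t101\th\t10\t+\t100\t101\t255,0,0\t10\t10.00\t1\t9\t0\t0\t0\t0\t0",
        "chr1\t250\t251\tm\t12\t+\t250\t251\t255,0,0\t12\t100.00\t12\t0\t0\t0\t0\t0\t0",
    ]
    path = tmp_path / "subjA.bedmethyl"
    path.write_text("\n".join(lines) + "\n")
    return path
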