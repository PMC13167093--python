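"""Blood cell-composition adjustment of the methylation GLMM.

Whole blood is a mixture; a subject's methylation at a site partly reflects
their cell proportions rather than site-level regulation. The five-part
differential (lymphocytes, monocytes, eosinophils, basophils, neutrophils)
is compositional, so it enters the model through a centered log-ratio (CLR)
transform. Neutrophils — the most abundant, least variable part — are
dropped after the transform and the remaining values are z-scored.
Eosinophils and basophils are computed but excluded from the final model as
weakly identified; lymphocyte and monocyte CLR-z values enter as varying
slopes across genomic sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .lgm import FitResult, ModelTemplate
from .types import CELL_TYPES

RETAINED_CELLS = ["lymphocytes", "monocytes"]
EXCLUDED_CELLS = ["eosinophils", "basophils"]
NON_NEUTROPHIL = RETAINED_CELLS + EXCLUDED_CELLS


def clr_transform(covariates: pd.DataFrame, zero_replace: float = 0.1) -> pd.DataFrame:
    """CLR-transform blood differentials and z-score across subjects.

    CLR_c = ln(x_c / g(x)) with g the geometric mean over all five parts
    (zero percentages replaced by ``zero_replace``% and renormalized).
    Neutrophils are dropped after the transform; the four remaining columns
    are z-scored across observed subjects. Subjects with missing
    differentials get NaN rows. Output columns: subject_id,
    clr_z_<cell> for lymphocytes/monocytes/eosinophils/basophils, imputed.
    """
    vals = covariates[CELL_TYPES].to_numpy(dtype=float)
    present = ~np.isnan(vals).any(axis=1)
    x = vals.copy()
    x[x == 0] = zero_replace
    x = x / x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        logx = np.log(x)
        clr = logx - logx.mean(axis=1, keepdims=True)
    clr_df = pd.DataFrame(clr, columns=CELL_TYPES)
    out = pd.DataFrame({"subject_id": covariates["subject_id"].to_numpy()})
    for cell in NON_NEUTROPHIL:
        col = clr_df[cell].to_numpy()
        obs = col[present]
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"degenerate {cell} CLR column (constant across subjects)")
        z = np.full(len(col), np.nan)
        z[present] = (obs - mu) / sd
        out[f"clr_z_{cell}"] = z
    out["imputed"] = ~present
    return out


def clr_rows_sum_zero(covariates: pd.DataFrame, zero_replace: float = 0.1) -> np.ndarray:
    """Raw 5-part CLR rows (pre-exclusion, pre-z-scoring); rows sum to 0."""
    vals = covariates[CELL_TYPES].to_numpy(dtype=float)
    x = vals.copy()
    x[x == 0] = zero_replace
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def impute_missing_cells(
    cell_covariates: pd.DataFrame,
    sd_impute: float = 0.1,
    seed: int = 0,
    mode: str = "normal",
) -> pd.DataFrame:
    """Fill missing CLR-z rows.

    ``mode="normal"`` draws independent N(0, sd_impute²) per retained cell
    type (on the z-scored scale); ``mode="zero"`` sets them to exactly 0,
    the missing-as-no-contribution companion used to check imputation
    robustness.
    """
    out = cell_covariates.copy()
    missing = out["imputed"].to_numpy(bool)
    if not missing.any():
        return out
    rng = np.random.default_rng(seed)
    z_cols = [c for c in out.columns if c.startswith("clr_z_")]
    for col in z_cols:
        if mode == "normal":
            draws = rng.normal(0.0, sd_impute, size=int(missing.sum()))
        elif mode == "zero":
            draws = np.zeros(int(missing.sum()))
        else:
            raise ValueError(f"unknown imputation mode {mode!r}")
        vals = out[col].to_numpy(float)
        vals[missing] = draws
        out[col] = vals
    return out


def complete_model_spec(use_cells: bool = False) -> ModelTemplate:
    """The final model template: annotation + TE fixed effects, four iid
    random terms (subject, TE taxonomy, site, site × subject), and — with
    ``use_cells`` — per-site varying slopes for lymphocyte and monocyte
    CLR-z with PC(0.1, 0.05) priors. Gene and CpG-island terms are kept out
    of the final model but available via :func:`candidate_catalogue`.
    """
    t = ModelTemplate()
    if use_cells:
        t.cell_types = list(RETAINED_CELLS)
    return t


def candidate_catalogue() -> dict[str, ModelTemplate]:
    """Candidate model variants compared by DIC/WAIC/CPO before settling on
    the complete model: with/without gene and CpG-island terms and without
    the interaction."""
    base = ModelTemplate()
    no_inter = ModelTemplate(random=["subject", "te_taxonomy", "site"])
    with_gene = ModelTemplate(random=["subject", "te_taxonomy", "site", "site_subject", "gene"])
    with_cgi = ModelTemplate(fixed=["annotation", "te_present", "cpg_island"])
    return {
        "complete": base,
        "no_interaction": no_inter,
        "with_gene": with_gene,
        "with_cpg_island": with_cgi,
    }


def cell_specific_sites(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Sites whose varying slope's credible interval excludes zero, per cell type."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for term in fit.spec.random_terms:
        if not term.name.startswith("slope_"):
            continue
        cell = term.name.removeprefix("slope_")
        means = fit.term_means(term.name)
        sds = fit.term_sds(term.name)
        for site_id in means.index:
            m, s = float(means[site_id]), float(sds[site_id])
            lo, hi = m - z * s, m + z * s
            rows.append(
                {
                    "site_id": site_id,
                    "cell_type": cell,
                    "mean": m,
                    "sd": s,
                    "ci_low": lo,
                    "ci_high": hi,
                    "called": bool(lo > 0 or hi < 0),
                }
            )
    if not rows:
        raise ValueError("fit has no cell varying-slope terms")
    return pd.DataFrame(rows)


def _interaction_frame(fit: FitResult) -> pd.DataFrame:
    term = next((t for t in fit.spec.random_terms if t.name == "site_subject"), None)
    if term is None:
        raise ValueError("fit lacks the site × subject interaction term")
    means = fit.term_means("site_subject")
    sds = fit.term_sds("site_subject")
    parts = [lvl.split("||") for lvl in means.index]
    return pd.DataFrame(
        {
            "site_id": [p[0] for p in parts],
            "subject_id": [p[1] for p in parts],
            "mean": means.to_numpy(),
            "sd": sds.to_numpy(),
        }
    )


def adjustment_concordance(fit_adj: FitResult, fit_unadj: FitResult) -> dict:
    """Compare interaction effects with and without cell adjustment.

    Returns Pearson/Spearman correlations of paired interaction posterior
    means, the same for site-level IQR and SD summaries, and the median
    per-site relative change in posterior interaction-effect SD (negative =
    adjustment shrank it).
    """
    a = _interaction_frame(fit_adj).set_index(["site_id", "subject_id"])
    b = _interaction_frame(fit_unadj).set_index(["site_id", "subject_id"])
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("fits cover different site/subject sets")
        b = b.loc[a.index]

    out = {
        "interaction_pearson": float(pearsonr(a["mean"], b["mean"])[0]),
        "interaction_spearman": float(spearmanr(a["mean"], b["mean"])[0]),
    }

    def site_summ(frame):
        g = frame.groupby("site_id")["mean"]
        q1 = g.quantile(0.25)
        q3 = g.quantile(0.75)
        return pd.DataFrame({"iqr": q3 - q1, "sd": g.std(ddof=1)})

    sa, sb = site_summ(a.reset_index()), site_summ(b.reset_index())
    sb = sb.loc[sa.index]
    for col in ("iqr", "sd"):
        out[f"site_{col}_pearson"] = float(pearsonr(sa[col], sb[col])[0])
        out[f"site_{col}_spearman"] = float(spearmanr(sa[col], sb[col])[0])

    # per-site spread of posterior means across subjects, adjusted vs not
    spread_a = a.reset_index().groupby("site_id")["mean"].std(ddof=1)
    spread_b = b.reset_index().groupby("site_id")["mean"].std(ddof=1)
    rel = (spread_a - spread_b.loc[spread_a.index]) / spread_b.loc[spread_a.index]
    out["median_interaction_sd_change"] = float(rel.median())
    return out
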