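"""Synthetic methylation cohorts with known ground truth.

The generator emulates a targeted nanopore panel: a cohort of subjects with
binomial read counts at CpG sites laid out across a set of genes on one
synthetic chromosome. Counts follow the same logit-linear structure the
model assumes —

    η_sj = β0 + β_a(s) + β_TE·TE(s) + u_subj(j) + u_tax(t(s)) + u_site(s)
           + u_int(s,j) + Σ_c γ_{c,s}·x_{c,j}
    n_mod ~ Binomial(n_valid, logit⁻¹(η_sj))

with iid Gaussian random effects. A configurable fraction of sites is
flagged hypervariable: their site × subject interaction sd is multiplied by
``hypervariable_sd_multiplier``. Chromatin states are assigned so that
flagged sites preferentially receive regulatory states, exercising the
enrichment stage. Blood differentials are Dirichlet draws mimicking a
healthy leukocyte distribution; per-site cell slopes are sparse.

All randomness flows from a single seed through named sub-streams so that
changing one component's dimensions does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as mio
from .cells import clr_transform
from .types import CELL_TYPES, MethylationCountTable, validate_covariates

CHROM = "chrS"

DEFAULT_ANNOTATION_EFFECTS = {"CDS": -0.5, "UTR": -0.5, "promoter": -2.0, "intron": 0.0}

TE_TAXONOMIES = ["LINE/L1", "SINE/Alu", "LTR/ERVL", "DNA/hAT"]

DEFAULT_STATES = ["TssA", "TssAFlnk", "Enh", "Tx", "TxWk", "ReprPC", "Quies"]
DEFAULT_STATE_FREQS = [0.05, 0.05, 0.10, 0.10, 0.15, 0.05, 0.50]
REGULATORY_STATES = ("TssA", "TssAFlnk", "Enh", "ReprPC")


@dataclass
class SimulationConfig:
    n_subjects: int = 100
    n_genes: int = 10
    sites_per_gene: int = 30
    seed: int = 0
    intercept: float = 1.2
    annotation_effects: dict = field(default_factory=lambda: dict(DEFAULT_ANNOTATION_EFFECTS))
    te_effect: float = 0.5
    sd_subject: float = 0.5
    sd_taxonomy: float = 0.1
    sd_site: float = 1.63
    sd_interaction: float = 0.323
    cell_slope_sd: dict = field(default_factory=lambda: {"lymphocytes": 0.08, "monocytes": 0.04})
    cell_slope_nonzero_frac: float = 0.1
    dirichlet_alpha: tuple = (30.0, 7.0, 2.5, 0.5, 60.0)
    dirichlet_concentration: float = 50.0
    n_missing_cells: int = 2
    coverage_mean: float = 30.0
    coverage_min: int = 10
    fraction_hypervariable: float = 0.10
    hypervariable_sd_multiplier: float = 3.0
    te_fraction: float = 0.15
    cpg_island_fraction_of_genes: float = 0.5
    regulatory_state_boost: float = 3.0
    chromatin_states: tuple = tuple(DEFAULT_STATES)
    chromatin_freqs: tuple = tuple(DEFAULT_STATE_FREQS)
    promoter_window: int = 2000
    gene_length: int = 8000
    gene_spacing: int = 20000

    def validate(self) -> "SimulationConfig":
        if self.n_subjects <= 0 or self.n_genes <= 0 or self.sites_per_gene <= 0:
            raise ValueError("cohort dimensions must be positive")
        for name in ("sd_subject", "sd_taxonomy", "sd_site", "sd_interaction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.fraction_hypervariable <= 1.0):
            raise ValueError("fraction_hypervariable must be in [0, 1]")
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be ≥ 1")
        if self.coverage_mean < self.coverage_min:
            raise ValueError("coverage_mean must be ≥ coverage_min")
        if abs(sum(self.chromatin_freqs) - 1.0) > 1e-8:
            raise ValueError("chromatin_freqs must sum to 1")
        return self


@dataclass
class GroundTruth:
    subject_effects: pd.Series
    taxonomy_effects: pd.Series
    site_effects: pd.Series
    interaction: pd.DataFrame  # site_id, subject_id, value
    hypervariable: pd.Series  # bool per site_id
    cell_slopes: pd.DataFrame  # site_id, cell_type, value
    cell_composition: pd.DataFrame  # true (pre-masking) percentages
    eta: pd.DataFrame  # site_id, subject_id, eta
    config: SimulationConfig


@dataclass
class SimulatedCohort:
    table: MethylationCountTable
    annotation: pd.DataFrame
    covariates: pd.DataFrame
    chromatin_bed: pd.DataFrame
    truth: GroundTruth
    beds: dict  # gene/cds/utr/te/cpg BED frames + tss table


def _rngs(seed: int, names: list[str]) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _layout(cfg: SimulationConfig, rng) -> dict:
    """Genes, feature intervals, TEs, CpG islands and site positions."""
    genes, cds, utr, te, cpg, tss = [], [], [], [], [], []
    site_rows = []
    for g in range(cfg.n_genes):
        gene = f"G{g:02d}"
        start = 10_000 + g * cfg.gene_spacing
        end = start + cfg.gene_length
        genes.append((CHROM, start, end, gene))
        tss.append((gene, CHROM, start, "+"))
        # 5' UTR, two CDS exons, 3' UTR; the rest of the body is intronic
        utr.append((CHROM, start, start + 300, gene))
        cds.append((CHROM, start + 800, start + 1600, gene))
        cds.append((CHROM, start + 4000, start + 4800, gene))
        utr.append((CHROM, end - 300, end, gene))
        if rng.random() < cfg.cpg_island_fraction_of_genes:
            cpg.append((CHROM, start - 500, start + 700, f"CpG_{gene}"))
        n_te = rng.poisson(cfg.te_fraction * cfg.sites_per_gene / 3) + (
            1 if rng.random() < cfg.te_fraction else 0
        )
        for _ in range(n_te):
            te_start = int(rng.integers(start + 1600, end - 600))
            taxonomy = TE_TAXONOMIES[int(rng.integers(len(TE_TAXONOMIES)))]
            te.append((CHROM, te_start, te_start + 400, taxonomy))
        lo, hi = start - cfg.promoter_window, end
        pos = np.sort(rng.choice(np.arange(lo, hi), size=cfg.sites_per_gene, replace=False))
        for p in pos:
            site_rows.append((f"{CHROM}:{p}:+", CHROM, int(p), "+"))

    def bed(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos", "strand"])
    sites = sites.drop_duplicates("site_id").sort_values("pos", kind="mergesort").reset_index(drop=True)
    return {
        "sites": sites,
        "gene_bed": bed(genes),
        "cds_bed": bed(cds),
        "utr_bed": bed(utr),
        "te_bed": bed(te),
        "cpg_bed": bed(cpg),
        "tss_table": pd.DataFrame(tss, columns=["gene", "chrom", "tss", "strand"]),
    }


def _chromatin_partition(sites: pd.DataFrame, states: pd.Series, span_end: int) -> pd.DataFrame:
    """Non-overlapping state intervals whose boundaries fall midway between sites."""
    pos = sites["pos"].to_numpy()
    mids = ((pos[:-1] + pos[1:]) // 2 + 1).tolist()
    starts = [0] + mids
    ends = mids + [span_end]
    return pd.DataFrame(
        {"chrom": CHROM, "start": starts, "end": ends, "name": states.loc[sites["site_id"]].to_numpy()}
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    cfg = config.validate()
    rngs = _rngs(
        cfg.seed,
        ["layout", "effects", "interaction", "cells", "slopes", "coverage", "counts",
         "chromatin", "flags"],
    )
    lay = _layout(cfg, rngs["layout"])
    sites = lay["sites"]
    n_sites = len(sites)
    subjects = [f"S{j:03d}" for j in range(cfg.n_subjects)]

    annotation = mio.annotate_sites(
        sites, lay["gene_bed"],
        {"CDS": lay["cds_bed"], "UTR": lay["utr_bed"]},
        lay["te_bed"], lay["cpg_bed"], lay["tss_table"],
        promoter_window=cfg.promoter_window,
    )
    ann = annotation.set_index("site_id")

    r = rngs["effects"]
    u_subject = pd.Series(r.normal(0, cfg.sd_subject, cfg.n_subjects), index=subjects)
    u_tax = pd.Series(r.normal(0, cfg.sd_taxonomy, len(TE_TAXONOMIES)), index=TE_TAXONOMIES)
    u_site = pd.Series(r.normal(0, cfg.sd_site, n_sites), index=sites["site_id"])

    n_hyper = int(round(cfg.fraction_hypervariable * n_sites))
    hyper_ids = rngs["flags"].choice(sites["site_id"].to_numpy(), size=n_hyper, replace=False)
    hyper = pd.Series(False, index=sites["site_id"])
    hyper.loc[hyper_ids] = True

    int_sd = np.where(hyper.to_numpy(), cfg.sd_interaction * cfg.hypervariable_sd_multiplier,
                      cfg.sd_interaction)
    u_int = rngs["interaction"].normal(0.0, 1.0, (n_sites, cfg.n_subjects)) * int_sd[:, None]

    # Blood differentials: Dirichlet mimicking a healthy distribution
    alpha = np.asarray(cfg.dirichlet_alpha, float)
    alpha = alpha / alpha.sum() * cfg.dirichlet_concentration
    comp = rngs["cells"].dirichlet(alpha, size=cfg.n_subjects) * 100.0
    cell_df = pd.DataFrame(comp, columns=CELL_TYPES)
    cell_df.insert(0, "subject_id", subjects)
    validate_covariates(cell_df)
    clr_z = clr_transform(cell_df).set_index("subject_id")

    slope_rows = []
    slope_mats = {}
    for cell, sd_c in cfg.cell_slope_sd.items():
        nz = rngs["slopes"].random(n_sites) < cfg.cell_slope_nonzero_frac
        gam = np.where(nz, rngs["slopes"].normal(0, sd_c, n_sites), 0.0)
        slope_mats[cell] = gam
        for sid, v in zip(sites["site_id"], gam):
            slope_rows.append({"site_id": sid, "cell_type": cell, "value": v})

    beta_a = np.array([cfg.annotation_effects[c] for c in ann.loc[sites["site_id"], "category"]])
    te_flag = ann.loc[sites["site_id"], "te_present"].to_numpy(float)
    tax_eff = np.array(
        [u_tax[t] if isinstance(t, str) and t in u_tax.index else 0.0
         for t in ann.loc[sites["site_id"], "te_taxonomy"]]
    )
    eta = (
        cfg.intercept
        + beta_a[:, None]
        + cfg.te_effect * te_flag[:, None]
        + tax_eff[:, None]
        + u_site.to_numpy()[:, None]
        + u_subject.to_numpy()[None, :]
        + u_int
    )
    for cell, gam in slope_mats.items():
        x = clr_z[f"clr_z_{cell}"].to_numpy()
        eta += gam[:, None] * x[None, :]

    extra = max(cfg.coverage_mean - cfg.coverage_min, 0.0)
    n_valid = cfg.coverage_min + rngs["coverage"].poisson(extra, (n_sites, cfg.n_subjects))
    n_mod = rngs["counts"].binomial(n_valid, expit(eta))

    entries = pd.DataFrame(
        {
            "site_id": np.repeat(sites["site_id"].to_numpy(), cfg.n_subjects),
            "subject_id": np.tile(subjects, n_sites),
            "n_mod": n_mod.ravel(),
            "n_valid": n_valid.ravel(),
        }
    )
    table = MethylationCountTable(entries=entries, sites=sites.copy(), subjects=list(subjects))

    # Chromatin states: hypervariable sites preferentially regulatory
    base = np.asarray(cfg.chromatin_freqs, float)
    boost = np.array(
        [cfg.regulatory_state_boost if s in REGULATORY_STATES else 1.0 for s in cfg.chromatin_states]
    )
    p_hyper = base * boost
    p_hyper /= p_hyper.sum()
    rc = rngs["chromatin"]
    labels = []
    for flag in hyper.loc[sites["site_id"]]:
        probs = p_hyper if flag else base
        labels.append(cfg.chromatin_states[int(rc.choice(len(base), p=probs))])
    state_series = pd.Series(labels, index=sites["site_id"], name="chromatin_state")
    span_end = int(sites["pos"].max()) + 1000
    chromatin_bed = _chromatin_partition(sites, state_series, span_end)

    # Mask cell data for a few subjects (whole-row missing)
    covariates = cell_df.copy()
    if cfg.n_missing_cells > 0:
        miss = rngs["cells"].choice(cfg.n_subjects, size=min(cfg.n_missing_cells, cfg.n_subjects),
                                    replace=False)
        covariates.loc[covariates.index[miss], CELL_TYPES] = np.nan

    truth = GroundTruth(
        subject_effects=u_subject,
        taxonomy_effects=u_tax,
        site_effects=u_site,
        interaction=pd.DataFrame(
            {
                "site_id": np.repeat(sites["site_id"].to_numpy(), cfg.n_subjects),
                "subject_id": np.tile(subjects, n_sites),
                "value": u_int.ravel(),
            }
        ),
        hypervariable=hyper,
        cell_slopes=pd.DataFrame(slope_rows),
        cell_composition=cell_df,
        eta=pd.DataFrame(
            {
                "site_id": np.repeat(sites["site_id"].to_numpy(), cfg.n_subjects),
                "subject_id": np.tile(subjects, n_sites),
                "eta": eta.ravel(),
            }
        ),
        config=cfg,
    )
    annotation = annotation.merge(
        state_series.rename("chromatin_state"), left_on="site_id", right_index=True
    )
    return SimulatedCohort(
        table=table,
        annotation=annotation,
        covariates=covariates,
        chromatin_bed=chromatin_bed,
        truth=truth,
        beds={k: lay[k] for k in ("gene_bed", "cds_bed", "utr_bed", "te_bed", "cpg_bed", "tss_table")},
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> Path:
    """Write the cohort as files re-readable by the IO layer.

    One bedMethyl per subject, the annotation BEDs, the chromatin-state BED,
    the covariate CSV, and ground truth as TSV + JSON.
    """
    out = Path(out_dir)
    if not out.exists():
        raise FileNotFoundError(f"output directory does not exist: {out}")
    bm_dir = out / "bedmethyl"
    bm_dir.mkdir(exist_ok=True)
    for subject in cohort.table.subjects:
        mio.write_bedmethyl(cohort.table, subject, bm_dir / f"{subject}.bedmethyl")
    for key, name in [
        ("gene_bed", "genes.bed"), ("cds_bed", "cds.bed"), ("utr_bed", "utr.bed"),
        ("te_bed", "te.bed"), ("cpg_bed", "cpg_islands.bed"),
    ]:
        mio.write_bed(cohort.beds[key], out / name)
    cohort.beds["tss_table"].to_csv(out / "tss.tsv", sep="\t", index=False)
    mio.write_bed(cohort.chromatin_bed, out / "chromatin_states.bed")
    mio.write_covariates(cohort.covariates, out / "covariates.csv")
    mio.write_tsv(cohort.annotation, out / "annotation.tsv")

    t = cohort.truth
    mio.write_tsv(t.interaction.rename(columns={"value": "u_interaction"}), out / "truth_interaction.tsv")
    truth_json = {
        "subject_effects": t.subject_effects.to_dict(),
        "taxonomy_effects": t.taxonomy_effects.to_dict(),
        "site_effects": t.site_effects.to_dict(),
        "hypervariable": {k: bool(v) for k, v in t.hypervariable.items()},
        "cell_slopes": t.cell_slopes.to_dict("records"),
        "config": asdict(t.config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, default=float)
    t.cell_composition.to_csv(out / "truth_cell_composition.csv", index=False)
    return out


def read_cohort(in_dir) -> tuple[MethylationCountTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back (table, annotation, covariates, chromatin_bed) written by write_cohort."""
    d = Path(in_dir)
    paths = {p.stem: p for p in sorted((d / "bedmethyl").glob("*.bedmethyl"))}
    if not paths:
        raise FileNotFoundError(f"no bedMethyl files under {d / 'bedmethyl'}")
    table = mio.read_cohort_bedmethyls(paths)
    annotation = mio.read_tsv(d / "annotation.tsv")
    # round-trip hygiene: NaN taxonomy back to None-like and bools to bool
    annotation["te_present"] = annotation["te_present"].astype(bool)
    annotation["cpg_island"] = annotation["cpg_island"].astype(bool)
    covariates = mio.read_covariates(d / "covariates.csv")
    chromatin = mio.read_bed(d / "chromatin_states.bed")
    return table, annotation, covariates, chromatin
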