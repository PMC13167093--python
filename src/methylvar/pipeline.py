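"""End-to-end orchestration: simulate → assemble → filter → fit → adjust → hypervar.

Each stage reads its inputs from disk artifacts and writes tidy TSV/JSON
outputs plus a manifest (config hash, seeds, wall times), so any stage can
be rerun from the directory alone. Defaults mirror the analysis the package
implements: Hrel filtering at the 50th percentile, the complete model with
cell-composition varying slopes, and hypervariable selection at IQR 0.25.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cells import (
    adjustment_concordance,
    cell_specific_sites,
    clr_transform,
    complete_model_spec,
    impute_missing_cells,
)
from .filtering import compute_site_metrics, concordance_report, filter_by_percentile
from .hypervar import (
    call_stability,
    gene_proportions,
    interaction_summaries,
    select_hypervariable,
    state_assignment,
    threshold_scan,
)
from .lgm import build_design, fit_laplace, information_criteria
from .simulate import SimulationConfig, simulate_cohort, write_cohort, read_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "methylvar_run"
    seed: int = 0
    # stage toggles
    do_simulate: bool = True
    do_assemble: bool = True
    do_filter: bool = True
    do_fit: bool = True
    do_hypervar: bool = True
    # simulate
    simulation: dict = field(default_factory=dict)
    # assemble
    n_top_subjects: int | None = None  # default: all simulated subjects
    min_cov: int = 10
    min_subjects_frac: float = 0.9
    # filter
    filter_metric: str = "hrel"
    filter_percentile: float = 50.0
    # fit
    use_cells: bool = True
    impute_sd: float = 0.1
    ic_samples: int = 1000
    # hypervar
    iqr_threshold: float = 0.25
    scan: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _fit_on(table, annotation, cell_z, use_cells, seed, ic_samples):
    template = complete_model_spec(use_cells=use_cells)
    spec, y, trials = build_design(table, annotation, cell_covariates=cell_z, template=template)
    fit = fit_laplace(spec, y, trials)
    return information_criteria(fit, n_samples=ic_samples, seed=seed)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    A failed stage writes a FAILED marker naming the stage and re-raises;
    artifacts of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            def wrapped(*a, **k):
                t0 = time.time()
                try:
                    result = fn(*a, **k)
                except Exception as exc:
                    (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest()
                    raise
                manifest["stages"][name] = {
                    "status": "ok",
                    "wall_seconds": round(time.time() - t0, 3),
                }
                _write_manifest()
                return result

            return wrapped

        return deco

    def _write_manifest():
        manifest["total_wall_seconds"] = round(time.time() - t_start, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    cohort_dir = out / "cohort"

    @stage("simulate")
    def _simulate():
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(cfg)
        cohort_dir.mkdir(exist_ok=True)
        write_cohort(cohort, cohort_dir)
        return cohort

    if config.do_simulate:
        _simulate()
    if not (config.do_assemble or config.do_filter or config.do_fit or config.do_hypervar):
        return out

    table, annotation, covariates, chromatin = read_cohort(cohort_dir)

    @stage("assemble")
    def _assemble(table):
        n_top = config.n_top_subjects or table.n_subjects
        min_subj = int(np.ceil(config.min_subjects_frac * n_top))
        assembled = mio.assemble_dataset(
            table, n_top_subjects=n_top, min_cov=config.min_cov, min_subjects=min_subj
        )
        mio.write_tsv(assembled.entries, out / "assembled_counts.tsv")
        return assembled

    if config.do_assemble:
        table = _assemble(table)

    @stage("filter")
    def _filter(table):
        metrics = compute_site_metrics(table)
        mio.write_tsv(metrics, out / "metrics.tsv")
        spearman, jacc = concordance_report(metrics)
        mio.write_tsv(spearman, out / "metric_spearman.tsv")
        mio.write_tsv(jacc, out / "concordance.tsv")
        kept, cut = filter_by_percentile(metrics, config.filter_metric, config.filter_percentile)
        logger.info(
            "filter: %s > %.4g at percentile %.0f keeps %d/%d sites",
            config.filter_metric, cut, config.filter_percentile, len(kept), table.n_sites,
        )
        return table.subset(site_ids=kept)

    full_table = table  # pre-filter set, the enrichment background default
    if config.do_filter:
        table = _filter(table)

    fits = {}

    @stage("fit")
    def _fit(table):
        cell_z = impute_missing_cells(
            clr_transform(covariates), sd_impute=config.impute_sd, seed=config.seed
        )
        fit_unadj = _fit_on(table, annotation, None, False, config.seed, config.ic_samples)
        fits["unadjusted"] = fit_unadj
        _dump_fit(fit_unadj, out / "fit_unadjusted")
        if config.use_cells:
            fit_adj = _fit_on(table, annotation, cell_z, True, config.seed, config.ic_samples)
            fits["adjusted"] = fit_adj
            _dump_fit(fit_adj, out / "fit_adjusted")
            conc = adjustment_concordance(fit_adj, fit_unadj)
            with open(out / "adjustment_concordance.json", "w") as fh:
                json.dump(conc, fh, indent=1)
            mio.write_tsv(cell_specific_sites(fit_adj), out / "cell_specific_sites.tsv")
        return fits

    if config.do_fit:
        _fit(table)

    @stage("hypervar")
    def _hypervar():
        fit = fits.get("adjusted") or fits["unadjusted"]
        summaries = interaction_summaries(fit)
        mio.write_tsv(summaries, out / "interaction_summaries.tsv")
        assigned, freqs = state_assignment(full_table.sites, chromatin)
        selected = select_hypervariable(summaries, config.iqr_threshold)
        mio.write_tsv(selected, out / "hypervariable_sites.tsv")
        site_info = full_table.sites.set_index("site_id")
        bed_rows = []
        for row in selected.itertuples(index=False):
            s = site_info.loc[row.site_id]
            bed_rows.append(
                {
                    "chrom": s["chrom"], "start": int(s["pos"]), "end": int(s["pos"]) + 1,
                    "name": row.site_id, "score": round(float(row.iqr), 4), "strand": s["strand"],
                }
            )
        mio.write_bed(pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
                      out / "hypervariable_sites.bed")
        if config.scan:
            scan = threshold_scan(summaries, assigned, freqs)
            mio.write_tsv(scan, out / "enrichment.tsv")
            mio.write_tsv(call_stability(scan), out / "enrichment_stability.tsv")
        else:
            from .hypervar import enrichment_test

            sel_states = assigned.loc[
                [s for s in selected["site_id"] if assigned.get(s) != "Unannotated"]
            ]
            tab = enrichment_test(sel_states.value_counts(), freqs, len(sel_states))
            mio.write_tsv(tab, out / "enrichment.tsv")
        mio.write_tsv(gene_proportions(summaries, annotation, config.iqr_threshold),
                      out / "gene_proportions.tsv")

    if config.do_hypervar:
        _hypervar()
    return out


def _dump_fit(fit, fit_dir: Path) -> None:
    fit_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    slices = fit.spec.term_slices()
    p = fit.spec.X.shape[1]
    for i, name in enumerate(fit.spec.fixed_names):
        rows.append({"term": "fixed", "level": name,
                     "mean": fit.latent_mean[i], "sd": fit.latent_sd[i]})
    for term in fit.spec.random_terms:
        sl = slices[term.name]
        for lvl, m, s in zip(term.level_names, fit.latent_mean[sl], fit.latent_sd[sl]):
            rows.append({"term": term.name, "level": lvl, "mean": m, "sd": s})
    mio.write_tsv(pd.DataFrame(rows), fit_dir / "estimates.tsv")
    meta = {
        "sigma": fit.sigma,
        "log_marginal": fit.log_marginal,
        "dic": fit.dic,
        "waic": fit.waic,
        "cpo_sum": fit.cpo_sum,
        "p_dic": fit.p_dic,
        "p_waic": fit.p_waic,
        "n_inner_iterations": fit.n_inner_iterations,
        "n_outer_evaluations": fit.n_outer_evaluations,
        "final_gradient_norm": fit.final_gradient_norm,
    }
    with open(fit_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
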