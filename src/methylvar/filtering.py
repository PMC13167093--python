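"""Per-site variability metrics and percentile filtering.

Sites with little across-subject spread in methylation fraction carry no
information about inter-individual variability and are filtered out before
model fitting. The primary metric is normalized Shannon entropy (Hrel) of
the binned across-subject fraction distribution — 0 when all subjects fall
in one bin, 1 under uniform occupancy — computed with 10 bins to match a
10× minimum coverage resolution. IQR and SD are computed alongside for
concordance diagnostics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import MethylationCountTable

logger = logging.getLogger(__name__)

METRIC_NAMES = ("hrel", "iqr", "sd")


def compute_hrel(fractions, n_bins: int = 10) -> float:
    """Normalized Shannon entropy of binned methylation fractions.

    Bins are equal-width on [0, 1], left-closed, with 1.0 assigned to the top
    bin. With occupancy proportions p_k over non-empty bins,
    Hrel = −Σ p_k ln p_k / ln(n_bins).
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 2:
        raise ValueError("Hrel needs at least 2 fractions")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    idx = np.minimum((f * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / f.size
    return float(-(p * np.log(p)).sum() / np.log(n_bins))


def compute_site_metrics(table: MethylationCountTable, min_valid: int = 1, n_bins: int = 10) -> pd.DataFrame:
    """Hrel / IQR / SD per site over subject methylation fractions.

    Subjects with n_valid < ``min_valid`` are excluded per site. Sites with
    fewer than two usable subjects get NaN metrics and usable=False, and are
    excluded from downstream filtering. Quartiles use linear interpolation
    (type-7); SD is the sample SD (n−1 denominator).
    """
    e = table.entries[table.entries["n_valid"] >= max(min_valid, 1)]
    rows = []
    for site_id, grp in e.groupby("site_id", sort=False):
        f = (grp["n_mod"] / grp["n_valid"]).to_numpy()
        if f.size < 2:
            rows.append((site_id, np.nan, np.nan, np.nan, f.size, False))
            continue
        q1, q3 = np.percentile(f, [25, 75], method="linear")
        rows.append(
            (site_id, compute_hrel(f, n_bins), float(q3 - q1), float(np.std(f, ddof=1)), f.size, True)
        )
    metrics = pd.DataFrame(rows, columns=["site_id", "hrel", "iqr", "sd", "n_subjects_used", "usable"])
    order = {s: i for i, s in enumerate(table.sites["site_id"])}
    metrics = metrics.sort_values("site_id", key=lambda s: s.map(order), kind="mergesort")
    n_bad = int((~metrics["usable"]).sum())
    if n_bad:
        logger.warning("%d sites have <2 usable subjects; metrics undefined", n_bad)
    return metrics.reset_index(drop=True)


def filter_by_percentile(metrics: pd.DataFrame, metric_name: str, percentile: float) -> tuple[set, float]:
    """Retain sites whose metric is strictly greater than the empirical percentile.

    Returns (retained site_id set, cut value). The percentile uses linear
    interpolation; ties at the cut are dropped, so an all-tied metric vector
    retains nothing (warned).
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    usable = metrics[metrics["usable"]] if "usable" in metrics.columns else metrics
    vals = usable[metric_name].to_numpy(dtype=float)
    cut = float(np.percentile(vals, percentile, method="linear"))
    kept = set(usable.loc[usable[metric_name] > cut, "site_id"])
    if not kept:
        logger.warning("percentile filter on %s at %.1f retained no sites (cut=%.4g)", metric_name, percentile, cut)
    return kept, cut


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def concordance_report(metrics: pd.DataFrame, percentile_grid=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman ρ between metrics + Jaccard of retained sets per threshold.

    Returns (spearman table, jaccard table) in tidy form; the Jaccard table is
    keyed by (percentile, pair).
    """
    if percentile_grid is None:
        percentile_grid = list(range(10, 100, 10))
    usable = metrics[metrics["usable"]] if "usable" in metrics.columns else metrics
    if len(usable) < 2:
        raise ValueError("concordance needs at least 2 usable sites")
    pairs = [("hrel", "iqr"), ("hrel", "sd"), ("iqr", "sd")]
    srows = []
    for a, b in pairs:
        rho, _ = spearmanr(usable[a], usable[b])
        srows.append({"metric_a": a, "metric_b": b, "spearman_rho": float(rho)})
    spearman_df = pd.DataFrame(srows)

    jrows = []
    for q in percentile_grid:
        kept = {m: filter_by_percentile(usable, m, q)[0] for m in METRIC_NAMES}
        for a, b in pairs:
            jrows.append(
                {"percentile": q, "metric_a": a, "metric_b": b, "jaccard": jaccard(kept[a], kept[b])}
            )
    return spearman_df, pd.DataFrame(jrows)
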