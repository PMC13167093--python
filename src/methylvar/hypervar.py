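"""Hypervariable-site selection and chromatin-state enrichment.

The hypervariability statistic is the IQR, across subjects, of the
posterior means of the site × subject interaction effects: a site where
subjects' deviations spread widely is inter-individually variable. Sites
above an IQR threshold (default 0.25 on the logit scale) are intersected
with a chromatin-state segmentation, and per-state counts are tested for
enrichment with a Poisson model whose offset is the expected count under
the state frequencies of the full analyzed set:

    o_k ~ Poisson(e_k · exp(δ_k)),   e_k = n_selected · f_k,
    δ_k ~ N(0, prior_sd²)

The δ posterior is computed by 1-D quadrature (the engine's Laplace path is
an independent cross-check in the tests). A state is called enriched if the
95% credible interval of δ lies above 0, depleted if below.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cells import _interaction_frame
from .lgm import FitResult


def interaction_summaries(fit: FitResult) -> pd.DataFrame:
    """Per-site mean / SD / IQR / range of posterior interaction means across subjects.

    Quartiles use linear interpolation (type-7), matching the site metrics.
    """
    frame = _interaction_frame(fit)
    rows = []
    for site_id, grp in frame.groupby("site_id", sort=False):
        m = grp["mean"].to_numpy()
        q1, q3 = np.percentile(m, [25, 75], method="linear")
        rows.append(
            {
                "site_id": site_id,
                "mean": float(m.mean()),
                "sd": float(np.std(m, ddof=1)) if m.size > 1 else 0.0,
                "iqr": float(q3 - q1),
                "range": float(m.max() - m.min()),
                "n_subjects": int(m.size),
            }
        )
    return pd.DataFrame(rows)


def select_hypervariable(summaries: pd.DataFrame, iqr_threshold: float = 0.25) -> pd.DataFrame:
    """Sites with interaction IQR above the threshold, ranked descending."""
    if iqr_threshold < 0:
        raise ValueError("iqr_threshold must be non-negative")
    sel = summaries[summaries["iqr"] > iqr_threshold]
    return sel.sort_values("iqr", ascending=False, kind="mergesort").reset_index(drop=True)


def state_assignment(sites: pd.DataFrame, chromatin_bed: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Assign each site the chromatin state of its containing interval.

    Intervals are half-open [start, end) and must partition each chromosome
    (overlaps are an error). Sites in uncovered gaps get "Unannotated" and
    are excluded from the frequency denominator. Returns (state per site_id,
    full-set state frequencies).
    """
    states = {}
    for chrom, grp in chromatin_bed.groupby("chrom"):
        grp = grp.sort_values("start", kind="mergesort")
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping chromatin-state intervals on {chrom}")
        names = grp["name"].to_numpy()
        sub = sites[sites["chrom"].astype(str) == str(chrom)]
        pos = sub["pos"].to_numpy(int)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        for sid, i, ok in zip(sub["site_id"], idx, inside):
            states[sid] = names[i] if ok else "Unannotated"
    assigned = pd.Series(
        [states.get(s, "Unannotated") for s in sites["site_id"]],
        index=sites["site_id"],
        name="chromatin_state",
    )
    covered = assigned[assigned != "Unannotated"]
    if len(covered) == 0:
        raise ValueError("no sites covered by chromatin-state intervals")
    freqs = covered.value_counts(normalize=True).sort_index()
    return assigned, freqs


def _log_ratio_posterior(o: float, e: float, prior_sd: float):
    """Grid quadrature over the δ posterior: mean, sd, and a quantile function."""

    def neg_logpost(d):
        return -(o * d - e * np.exp(d) - 0.5 * d**2 / prior_sd**2)

    res = minimize_scalar(neg_logpost, bounds=(-40.0, 40.0), method="bounded",
                          options={"xatol": 1e-10})
    mode = float(res.x)
    curv = e * np.exp(mode) + 1.0 / prior_sd**2  # −d²logpost/dδ² at mode
    scale = 1.0 / np.sqrt(curv)
    grid = np.linspace(mode - 12 * scale, mode + 12 * scale, 8001)
    logp = -np.vectorize(neg_logpost)(grid)
    logp -= logp.max()
    p = np.exp(logp)
    Z = np.trapezoid(p, grid)
    p /= Z
    mean = float(np.trapezoid(grid * p, grid))
    var = float(np.trapezoid((grid - mean) ** 2 * p, grid))
    cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]

    def quantile(q):
        return float(np.interp(q, cdf, grid))

    return mean, float(np.sqrt(var)), quantile


def enrichment_test(
    observed_by_state: pd.Series,
    frequencies: pd.Series,
    n_selected: int,
    prior_sd: float = 10.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-state Poisson enrichment with expected counts as an offset.

    ``frequencies`` must sum to 1 over the tested states. States with
    f_k = 0 but a positive observed count are impossible under the model
    and raise. Low-information states (expected count < 1) are flagged but
    still reported.
    """
    freqs = frequencies.astype(float)
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("state frequencies must sum to 1")
    if n_selected <= 0:
        raise ValueError("n_selected must be positive")
    bad = [k for k in freqs.index if freqs[k] == 0 and observed_by_state.get(k, 0) > 0]
    if bad:
        raise ValueError(f"states observed but with zero background frequency: {bad}")
    lo_q, hi_q = (1 - level) / 2.0, 1 - (1 - level) / 2.0
    rows = []
    for state in freqs.index:
        f = float(freqs[state])
        if f == 0:
            continue
        o = float(observed_by_state.get(state, 0))
        e = n_selected * f
        mean, sd, quantile = _log_ratio_posterior(o, e, prior_sd)
        ci_low, ci_high = quantile(lo_q), quantile(hi_q)
        call = "enriched" if ci_low > 0 else ("depleted" if ci_high < 0 else "ns")
        rows.append(
            {
                "state": state,
                "observed": int(o),
                "expected": e,
                "log_ratio": mean,
                "sd": sd,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "call": call,
                "low_information": e < 1.0,
            }
        )
    return pd.DataFrame(rows)


def threshold_scan(
    summaries: pd.DataFrame,
    assignment: pd.Series,
    frequencies: pd.Series,
    grid=None,
    prior_sd: float = 10.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Enrichment table over a grid of IQR thresholds (default 0.10–0.35 by 0.01).

    Rows where the selection is empty are flagged (``empty_selection``)
    rather than raised. A per-(threshold, state) tidy table is returned; the
    stability of each state's call along the grid can be read off directly.
    """
    if grid is None:
        grid = np.round(np.arange(0.10, 0.35 + 1e-9, 0.01), 2)
    rows = []
    for thr in grid:
        sel = select_hypervariable(summaries, float(thr))
        sel_states = assignment.loc[[s for s in sel["site_id"] if assignment.get(s, "Unannotated") != "Unannotated"]]
        n_sel = len(sel_states)
        if n_sel == 0:
            for state in frequencies.index:
                rows.append(
                    {
                        "threshold": float(thr),
                        "state": state,
                        "observed": 0,
                        "expected": 0.0,
                        "log_ratio": np.nan,
                        "sd": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "call": "empty",
                        "low_information": True,
                        "n_selected": 0,
                        "empty_selection": True,
                    }
                )
            continue
        obs = sel_states.value_counts()
        table = enrichment_test(obs, frequencies, n_sel, prior_sd=prior_sd, level=level)
        table["threshold"] = float(thr)
        table["n_selected"] = n_sel
        table["empty_selection"] = False
        rows.extend(table.to_dict("records"))
    out = pd.DataFrame(rows)
    cols = ["threshold", "state", "observed", "expected", "log_ratio", "sd",
            "ci_low", "ci_high", "call", "low_information", "n_selected", "empty_selection"]
    return out[cols]


def call_stability(scan: pd.DataFrame) -> pd.DataFrame:
    """Per state, the longest grid suffix over which the call is constant."""
    rows = []
    for state, grp in scan.groupby("state"):
        grp = grp.sort_values("threshold")
        calls = grp["call"].tolist()
        last = calls[-1]
        run = 0
        for c in reversed(calls):
            if c == last:
                run += 1
            else:
                break
        rows.append({"state": state, "stable_call": last, "stable_suffix_len": run,
                     "stable_from_threshold": float(grp["threshold"].iloc[len(calls) - run])})
    return pd.DataFrame(rows)


def gene_proportions(summaries: pd.DataFrame, annotations: pd.DataFrame, iqr_threshold: float = 0.25) -> pd.DataFrame:
    """Descriptive per-gene proportion of hypervariable sites."""
    ann = annotations.set_index("site_id")
    sel = set(select_hypervariable(summaries, iqr_threshold)["site_id"])
    ann_used = ann.loc[[s for s in summaries["site_id"] if s in ann.index]]
    rows = []
    for gene, grp in ann_used.groupby("gene"):
        n = len(grp)
        k = sum(1 for s in grp.index if s in sel)
        rows.append({"gene": gene, "n_sites": n, "n_hypervariable": k, "proportion": k / n})
    return pd.DataFrame(rows).sort_values("proportion", ascending=False).reset_index(drop=True)
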