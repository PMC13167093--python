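"""Interaction summaries, hypervariable selection, chromatin-state enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import spearmanr

from methylvar import (
    interaction_summaries,
    select_hypervariable,
    state_assignment,
    enrichment_test,
    threshold_scan,
)
from methylvar.hypervar import call_stability, gene_proportions
from .conftest import make_interaction_fit


class TestInteractionSummaries:
    def test_constant_means_have_zero_spread(self):
        fit = make_interaction_fit(["s1"], ["a", "b", "c", "d"], [0.3, 0.3, 0.3, 0.3])
        s = interaction_summaries(fit).iloc[0]
        assert s["iqr"] == 0.0 and s["range"] == 0.0 and s["sd"] == 0.0

    def test_range_is_max_minus_min(self):
        fit = make_interaction_fit(["s1"], ["a", "b", "c"], [-1.0, 0.0, 1.0])
        assert interaction_summaries(fit).iloc[0]["range"] == 2.0

    def test_type7_quartiles_on_four_values(self):
        # {0.1, 0.2, 0.4, 0.8}: q1 = 0.175, q3 = 0.5 → IQR 0.325
        fit = make_interaction_fit(["s1"], list("abcd"), [0.1, 0.2, 0.4, 0.8])
        assert interaction_summaries(fit).iloc[0]["iqr"] == pytest.approx(0.325, abs=1e-12)

    def test_range_bounds_iqr(self, fitted_small_cohort):
        s = interaction_summaries(fitted_small_cohort)
        assert (s["range"] >= s["iqr"]).all()
        assert (s["iqr"] >= 0).all()

    def test_missing_term_is_an_error(self):
        from methylvar.lgm import LatentModelSpec, FitResult

        spec = LatentModelSpec(
            likelihood="binomial-logit", X=np.ones((1, 1)),
            fixed_names=["intercept"], fixed_prior_sd=np.array([3.0]),
        )
        fit = FitResult(spec=spec, y=np.zeros(1), trials=np.ones(1), sigma={},
                        latent_mean=np.zeros(1), latent_sd=np.ones(1), log_marginal=0.0,
                        n_inner_iterations=0, n_outer_evaluations=0, final_gradient_norm=0.0)
        with pytest.raises(ValueError, match="interaction"):
            interaction_summaries(fit)


class TestSelectHypervariable:
    def _summaries(self):
        return pd.DataFrame(
            {"site_id": list("abcde"), "iqr": [0.1, 0.3, 0.2, 0.5, 0.25],
             "mean": 0.0, "sd": 0.0, "range": 1.0, "n_subjects": 10}
        )

    def test_threshold_above_max_gives_empty_set(self):
        assert len(select_hypervariable(self._summaries(), 0.9)) == 0

    def test_threshold_zero_keeps_all_ranked(self):
        out = select_hypervariable(self._summaries(), 0.0)
        assert out["site_id"].tolist() == ["d", "b", "e", "c", "a"]

    def test_strictly_greater_than_threshold(self):
        out = select_hypervariable(self._summaries(), 0.25)
        assert set(out["site_id"]) == {"b", "d"}


class TestStateAssignment:
    def _sites(self, positions):
        return pd.DataFrame(
            {"site_id": [f"s{p}" for p in positions], "chrom": "chr1",
             "pos": positions, "strand": "+"}
        )

    def test_single_state_covers_everything(self):
        bed = pd.DataFrame([("chr1", 0, 1000, "Quies")],
                           columns=["chrom", "start", "end", "name"])
        assigned, freqs = state_assignment(self._sites([10, 500, 999]), bed)
        assert (assigned == "Quies").all()
        assert freqs["Quies"] == 1.0

    def test_half_open_boundary_convention(self):
        bed = pd.DataFrame([("chr1", 0, 100, "TssA"), ("chr1", 100, 200, "Enh")],
                           columns=["chrom", "start", "end", "name"])
        assigned, _ = state_assignment(self._sites([99, 100]), bed)
        assert assigned["s99"] == "TssA"
        assert assigned["s100"] == "Enh"  # boundary belongs to the right interval

    def test_frequencies_by_enumeration(self):
        bed = pd.DataFrame([("chr1", 0, 700, "Enh"), ("chr1", 700, 1000, "Quies")],
                           columns=["chrom", "start", "end", "name"])
        positions = list(range(50, 1000, 100))  # 7 in Enh, 3 in Quies
        _, freqs = state_assignment(self._sites(positions), bed)
        assert freqs["Enh"] == pytest.approx(0.7)
        assert freqs["Quies"] == pytest.approx(0.3)

    def test_gap_sites_unannotated(self):
        bed = pd.DataFrame([("chr1", 0, 100, "TssA")],
                           columns=["chrom", "start", "end", "name"])
        assigned, freqs = state_assignment(self._sites([50, 500]), bed)
        assert assigned["s500"] == "Unannotated"
        assert "Unannotated" not in freqs.index

    def test_overlapping_intervals_rejected(self):
        bed = pd.DataFrame([("chr1", 0, 100, "TssA"), ("chr1", 50, 200, "Enh")],
                           columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError, match="overlap"):
            state_assignment(self._sites([10]), bed)


def quad_oracle(o, e, prior_sd):
    """Independent moments of the log enrichment ratio via scipy.integrate.quad."""
    from scipy.optimize import minimize_scalar

    def logpost(d):
        return o * d - e * np.exp(d) - 0.5 * d**2 / prior_sd**2

    mode = minimize_scalar(lambda d: -logpost(d), bounds=(-40, 40), method="bounded").x
    peak = logpost(mode)
    scale = 1.0 / np.sqrt(e * np.exp(mode) + 1.0 / prior_sd**2)
    half = max(20.0, 15.0 * scale)
    lo, hi = mode - half, mode + half

    def unnorm(d):
        return np.exp(logpost(d) - peak)

    z, _ = integrate.quad(unnorm, lo, hi, limit=400)
    mean, _ = integrate.quad(lambda d: d * unnorm(d), lo, hi, limit=400)
    mean /= z
    var, _ = integrate.quad(lambda d: (d - mean) ** 2 * unnorm(d), lo, hi, limit=400)
    return mean, np.sqrt(var / z)


class TestEnrichmentTest:
    def test_observed_equals_expected_is_ns(self):
        freqs = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        obs = pd.Series({"A": 50, "B": 30, "C": 20})
        out = enrichment_test(obs, freqs, 100).set_index("state")
        assert (out["call"] == "ns").all()
        assert out["log_ratio"].abs().max() < 0.05

    def test_two_fold_enrichment_recovers_ln2(self):
        freqs = pd.Series({"A": 0.5, "B": 0.5})
        obs = pd.Series({"A": 200, "B": 100})
        out = enrichment_test(obs, freqs, 150).set_index("state")
        # state A: e = 75, o = 200 → δ ≈ ln(200/75); large counts, prior negligible
        assert out.loc["A", "log_ratio"] == pytest.approx(np.log(200 / 75), abs=0.02)
        assert out.loc["A", "call"] == "enriched"

    @pytest.mark.parametrize("o,e", [(200, 100), (0, 5), (3, 10), (12, 4)])
    def test_matches_independent_quadrature(self, o, e):
        freqs = pd.Series({"X": e / (e + 7.0), "Y": 7.0 / (e + 7.0)})
        n_sel = e + 7.0
        obs = pd.Series({"X": o, "Y": 7})
        out = enrichment_test(obs, freqs, int(n_sel), prior_sd=10.0).set_index("state")
        mean, sd = quad_oracle(o, e, 10.0)
        assert out.loc["X", "log_ratio"] == pytest.approx(mean, abs=1e-2)
        assert out.loc["X", "sd"] == pytest.approx(sd, abs=1e-2)

    def test_zero_observed_can_be_depleted(self):
        freqs = pd.Series({"A": 0.5, "B": 0.5})
        obs = pd.Series({"A": 0, "B": 10})
        out = enrichment_test(obs, freqs, 10).set_index("state")
        mean, sd = quad_oracle(0, 5.0, 10.0)
        assert out.loc["A", "log_ratio"] == pytest.approx(mean, abs=2e-2)

    def test_flat_prior_approaches_mle(self):
        freqs = pd.Series({"A": 0.4, "B": 0.6})
        obs = pd.Series({"A": 80, "B": 120})
        out = enrichment_test(obs, freqs, 100, prior_sd=100.0).set_index("state")
        assert out.loc["A", "log_ratio"] == pytest.approx(np.log(80 / 40), abs=1e-2)
        assert out.loc["B", "log_ratio"] == pytest.approx(np.log(120 / 60), abs=1e-2)

    def test_expected_counts_sum_to_n_selected(self):
        freqs = pd.Series({"A": 0.25, "B": 0.35, "C": 0.4})
        obs = pd.Series({"A": 10, "B": 10, "C": 10})
        out = enrichment_test(obs, freqs, 30)
        assert out["expected"].sum() == pytest.approx(30.0)

    def test_impossible_state_rejected(self):
        freqs = pd.Series({"A": 1.0, "B": 0.0})
        obs = pd.Series({"A": 5, "B": 2})
        with pytest.raises(ValueError, match="zero background"):
            enrichment_test(obs, freqs, 7)

    def test_laplace_engine_cross_check(self):
        """Poisson-with-offset fit through the LGM engine agrees with quadrature."""
        from methylvar.lgm import LatentModelSpec, fit_laplace

        obs = np.array([200.0, 100.0, 30.0, 5.0])
        expected = np.array([100.0, 120.0, 25.0, 8.0])
        spec = LatentModelSpec(
            likelihood="poisson-log",
            X=np.eye(4),
            fixed_names=[f"state{i}" for i in range(4)],
            fixed_prior_sd=np.full(4, 10.0),
            offset=np.log(expected),
        )
        fit = fit_laplace(spec, obs)
        for i, (o, e) in enumerate(zip(obs, expected)):
            mean, _ = quad_oracle(o, e, 10.0)
            assert fit.latent_mean[i] == pytest.approx(mean, abs=1e-2)


class TestThresholdScan:
    def _setup(self):
        rng = np.random.default_rng(9)
        n = 60
        site_ids = [f"s{i}" for i in range(n)]
        iqr = np.concatenate([rng.uniform(0.0, 0.2, 40), rng.uniform(0.2, 0.6, 20)])
        summaries = pd.DataFrame(
            {"site_id": site_ids, "iqr": iqr, "mean": 0.0, "sd": 0.0,
             "range": 1.0, "n_subjects": 10}
        )
        states = ["Enh" if i >= 40 and i % 2 == 0 else "Quies" for i in range(n)]
        assignment = pd.Series(states, index=site_ids)
        freqs = assignment.value_counts(normalize=True).sort_index()
        return summaries, assignment, freqs

    def test_single_threshold_equals_direct_call(self):
        summaries, assignment, freqs = self._setup()
        scan = threshold_scan(summaries, assignment, freqs, grid=[0.25])
        sel = select_hypervariable(summaries, 0.25)
        obs = assignment.loc[sel["site_id"]].value_counts()
        direct = enrichment_test(obs, freqs, len(sel)).set_index("state")
        got = scan.set_index("state")
        for state in direct.index:
            assert got.loc[state, "log_ratio"] == pytest.approx(direct.loc[state, "log_ratio"])

    def test_selection_count_monotone_in_threshold(self):
        summaries, assignment, freqs = self._setup()
        scan = threshold_scan(summaries, assignment, freqs)
        n_sel = scan.groupby("threshold")["n_selected"].first()
        assert (np.diff(n_sel.to_numpy()) <= 0).all()

    def test_empty_selection_flagged_not_raised(self):
        summaries, assignment, freqs = self._setup()
        scan = threshold_scan(summaries, assignment, freqs, grid=[0.99])
        assert scan["empty_selection"].all()

    def test_stability_summary_shape(self):
        summaries, assignment, freqs = self._setup()
        scan = threshold_scan(summaries, assignment, freqs, grid=[0.1, 0.2, 0.3])
        stab = call_stability(scan)
        assert set(stab["state"]) == set(freqs.index)
        assert (stab["stable_suffix_len"] >= 1).all()


def test_coverage_unrelated_to_interaction_iqr(fitted_small_cohort, small_cohort):
    """Selection is not driven by sequencing depth when depth is independent of signal."""
    summ = interaction_summaries(fitted_small_cohort).set_index("site_id")
    cov = small_cohort.table.entries.groupby("site_id")["n_valid"].mean()
    rho = spearmanr(summ["iqr"], cov.loc[summ.index])[0]
    assert abs(rho) < 0.25


def test_gene_proportions_counts(small_cohort, fitted_small_cohort):
    summ = interaction_summaries(fitted_small_cohort)
    gp = gene_proportions(summ, small_cohort.annotation, iqr_threshold=0.25)
    assert gp["n_sites"].sum() == len(summ)
    assert ((gp["proportion"] >= 0) & (gp["proportion"] <= 1)).all()
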