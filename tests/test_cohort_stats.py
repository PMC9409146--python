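import itertools

import numpy as np
import pandas as pd
import pytest

import cryptoseek as cs
from cryptoseek.cohort_stats import (
    StatConfig,
    _exact_ranksum_p,
    _logistic_row,
    conditional_logit_binary,
)
from cryptoseek.twopass_assign import QuantMatrix

from _bruteforce import enumerated_ranksum_p


def make_qm(rows: dict, samples):
    counts = pd.DataFrame(rows, index=samples).T.astype(np.int64)
    counts.index.name = "orf_id"
    meta = pd.DataFrame(
        {"total_psm": counts.sum(axis=1), "n_samples_detected": (counts > 0).sum(axis=1)},
        index=counts.index,
    )
    return QuantMatrix(counts=counts, row_meta=meta)


def design_for(samples, n_case):
    return [
        cs.CohortDesign(s, "case" if i < n_case else "control", 3)
        for i, s in enumerate(samples)
    ]


class TestFoldChange:
    SAMPLES = ["c1", "c2", "k1", "k2"]

    def test_fc_arithmetic_and_flag(self):
        qm = make_qm({"a": [40, 20, 15, 5], "b": [20, 10, 12, 8]}, self.SAMPLES)
        fc = cs.fold_change_table(qm, design_for(self.SAMPLES, 2))
        assert fc.loc["a", "fc"] == pytest.approx(3.0)
        assert bool(fc.loc["a", "fc_gt2"])
        assert fc.loc["b", "fc"] == pytest.approx(1.5)
        assert not bool(fc.loc["b", "fc_gt2"])

    def test_case_exclusive_sentinel(self):
        qm = make_qm({"a": [9, 0, 0, 0]}, self.SAMPLES)
        fc = cs.fold_change_table(qm, design_for(self.SAMPLES, 2))
        assert fc.loc["a", "status"] == "case_exclusive"
        assert bool(fc.loc["a", "case_exclusive"])
        assert np.isnan(fc.loc["a", "fc"])

    def test_both_groups_zero_not_evaluable(self):
        qm = make_qm({"a": [0, 0, 0, 0]}, self.SAMPLES)
        fc = cs.fold_change_table(qm, design_for(self.SAMPLES, 2))
        assert fc.loc["a", "status"] == "not_evaluable"

    def test_pseudocount_gives_finite_fc(self):
        qm = make_qm({"a": [9, 1, 0, 0]}, self.SAMPLES)
        fc = cs.fold_change_table(qm, design_for(self.SAMPLES, 2), StatConfig(pseudocount=0.5))
        assert fc.loc["a", "fc"] == pytest.approx(10.0)


def loglik_2x2(beta0, beta1, a, b, c, d):
    """Binomial log-likelihood of logit P(case) = beta0 + beta1*detected."""
    p1 = 1 / (1 + np.exp(-(beta0 + beta1)))  # detected
    p0 = 1 / (1 + np.exp(-beta0))            # not detected
    return a * np.log(p1) + b * np.log(1 - p1) + c * np.log(p0) + d * np.log(1 - p0)


class TestLogisticOddsRatio:
    @pytest.mark.parametrize("table", [(8, 2, 4, 16), (5, 3, 7, 9), (12, 8, 3, 17), (2, 1, 9, 11)])
    def test_mle_equals_cross_product_ratio(self, table):
        a, b, c, d = table
        row = _logistic_row(a, b, c, d, StatConfig())
        assert row["or_hat"] == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_brute_force_likelihood_grid_confirms_mle(self):
        a, b, c, d = 8, 2, 4, 16
        beta1_hat = np.log(a * d / (b * c))
        grid = np.linspace(beta1_hat - 2, beta1_hat + 2, 161)
        best = max(
            grid,
            key=lambda b1: max(
                loglik_2x2(b0, b1, a, c, b, d) for b0 in np.linspace(-4, 4, 161)
            ),
        )
        assert best == pytest.approx(beta1_hat, abs=0.05)

    def test_zero_cell_haldane_correction(self):
        row = _logistic_row(5, 0, 2, 10, StatConfig())
        assert np.isfinite(row["or_hat"]) and row["or_hat"] > 1
        assert "separation_corrected" in row["flags"]
        expected = (5.5 * 10.5) / (0.5 * 2.5)
        assert row["or_hat"] == pytest.approx(expected)

    def test_degenerate_predictor_not_estimable(self):
        samples = [f"s{i}" for i in range(6)]
        qm = make_qm({"all": [3, 4, 5, 2, 6, 1], "none": [0, 0, 0, 0, 0, 0]}, samples)
        out = cs.odds_ratio(qm, design_for(samples, 3), method="logistic")
        assert out["flags"].tolist() == ["not_estimable"] * 2
        assert out["or_hat"].isna().all()


def matched_design(n_strata):
    design = []
    for i in range(n_strata):
        design.append(cs.CohortDesign(f"ca{i}", "case", 4, f"S{i}", "pre_diagnostic"))
        design.append(cs.CohortDesign(f"co{i}", "control", 12, f"S{i}", "pre_diagnostic"))
    return design


class TestConditionalOddsRatio:
    @pytest.mark.parametrize("n10,n01,n_conc", [(6, 2, 4), (5, 5, 2), (3, 9, 0), (1, 7, 5)])
    def test_mle_equals_discordant_ratio_one_to_one(self, n10, n01, n_conc):
        design = matched_design(n10 + n01 + n_conc)
        det = {}
        for i in range(n10 + n01 + n_conc):
            if i < n10:
                det[f"ca{i}"], det[f"co{i}"] = 1, 0
            elif i < n10 + n01:
                det[f"ca{i}"], det[f"co{i}"] = 0, 1
            else:
                det[f"ca{i}"], det[f"co{i}"] = 1, 1
        qm = make_qm({"x": [det[d.sample_id] * 7 for d in design]}, [d.sample_id for d in design])
        out = cs.odds_ratio(qm, design, method="conditional")
        assert out.loc["x", "or_hat"] == pytest.approx(n10 / n01, abs=1e-6)

    def test_matches_statsmodels_on_general_strata(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(17)
        for _ in range(5):
            y, x, strata, groups = [], [], [], []
            idx = 0
            for s in range(10):
                n = int(rng.integers(3, 6))
                m = int(rng.integers(1, n))
                ys = [1] * m + [0] * (n - m)
                xs = list((rng.random(n) < 0.5).astype(float))
                strata.append(list(range(idx, idx + n)))
                idx += n
                y += ys
                x += xs
                groups += [f"S{s}"] * n
            y, x = np.array(y), np.array(x)
            try:
                beta, se = conditional_logit_binary(y, x, strata)
            except FloatingPointError:
                continue
            fit = ConditionalLogit(y, x[:, None], groups=np.array(groups)).fit(disp=0)
            assert beta == pytest.approx(float(fit.params[0]), abs=1e-4)
            assert se == pytest.approx(float(fit.bse[0]), rel=1e-3)

    def test_separation_corrected_to_finite_estimate(self):
        design = matched_design(4)
        qm = make_qm({"x": [5, 0] * 4}, [d.sample_id for d in design])
        out = cs.odds_ratio(qm, design, method="conditional")
        assert np.isfinite(out.loc["x", "or_hat"])
        assert out.loc["x", "flags"] == "separation_corrected"
        assert out.loc["x", "or_hat"] == pytest.approx(4.5 / 0.5)

    def test_requires_stratum_ids(self):
        samples = ["a", "b"]
        qm = make_qm({"x": [3, 0]}, samples)
        with pytest.raises(ValueError, match="stratum"):
            cs.odds_ratio(qm, design_for(samples, 1), method="conditional")


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        assert _exact_ranksum_p(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0])) == 1.0

    def test_complete_separation_three_vs_three(self):
        assert _exact_ranksum_p(np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0])) == pytest.approx(0.1)

    def test_single_swap_increases_p(self):
        sep = _exact_ranksum_p(np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        swap = _exact_ranksum_p(np.array([3.0, 5.0, 6.0]), np.array([1.0, 2.0, 4.0]))
        assert swap > sep

    def test_exact_matches_full_enumeration_small_groups(self, rng):
        for n1 in range(1, 8):
            for n2 in range(1, 9 - n1):
                for _ in range(3):
                    case = rng.integers(0, 5, size=n1).astype(float)  # ties likely
                    ctrl = rng.integers(0, 5, size=n2).astype(float)
                    assert _exact_ranksum_p(case, ctrl) == pytest.approx(
                        enumerated_ranksum_p(case, ctrl)
                    )

    def test_large_n_uses_tie_corrected_normal_approximation(self):
        samples = [f"s{i}" for i in range(30)]
        rng = np.random.default_rng(5)
        qm = make_qm({"x": rng.integers(0, 20, 30)}, samples)
        p = cs.wilcoxon_pvalues(qm, design_for(samples, 15))
        assert 0 < p["x"] <= 1


class TestClassifyAndOverlap:
    def _stats(self, rows):
        return pd.DataFrame(rows).set_index("orf_id")

    def test_or_hit_rule(self):
        stats = self._stats(
            [
                {"orf_id": "a", "or_hat": 2.5, "p_one_sided": 0.03, "or_hit": True},
                {"orf_id": "b", "or_hat": 2.5, "p_one_sided": 0.2, "or_hit": False},
            ]
        )
        hits = cs.classify_hits(stats, cohort="pre_diagnostic")
        assert list(hits.index) == ["a"]

    def test_newly_diagnosed_rule_is_union(self):
        stats = self._stats(
            [
                {"orf_id": "a", "case_exclusive": True, "fc_gt2": False},
                {"orf_id": "b", "case_exclusive": False, "fc_gt2": True},
                {"orf_id": "c", "case_exclusive": False, "fc_gt2": False},
            ]
        )
        hits = cs.classify_hits(stats, cohort="newly_diagnosed")
        assert sorted(hits.index) == ["a", "b"]

    def test_threshold_monotonicity(self):
        samples = ["c1", "c2", "c3", "k1", "k2", "k3"]
        rng = np.random.default_rng(9)
        qm = make_qm({f"r{i}": rng.integers(0, 12, 6) for i in range(30)}, samples)
        design = design_for(samples, 3)
        loose = cs.classify_hits(
            cs.fold_change_table(qm, design, StatConfig(fc_threshold=1.5)),
            StatConfig(fc_threshold=1.5),
        )
        tight = cs.classify_hits(
            cs.fold_change_table(qm, design, StatConfig(fc_threshold=3.0)),
            StatConfig(fc_threshold=3.0),
        )
        assert set(tight.index) <= set(loose.index)

    def test_overlap_counts_and_ids(self):
        rep = cs.overlap_report({"nd": {"A", "B", "C"}, "pre": {"B", "C", "D"}})
        row = rep[rep["sets"] == "nd&pre"].iloc[0]
        assert row["count"] == 2 and row["ids"] == "B;C"


class TestPlantedOddsRatioRecovery:
    def test_detection_contrast_recovered_within_simulation_ci(self):
        """The cohort generator's planted detection odds ratio is recovered
        by the conditional-logistic fit, pooling over seeded replicates."""
        from cryptoseek.orf_enumerator import CryptoDbEntry
        from cryptoseek.synthetic_fixtures import _planted_aa

        planted = 3.0
        log_ors = []
        for seed in range(8):
            design = cs.make_design(40, 40, cohort="pre_diagnostic", matched=True, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            entries = [
                CryptoDbEntry(
                    orf_id=f"p{i}", transcript_id=f"t{i}", frame=0, nt_start=0,
                    nt_end=3 * 61, aa_sequence=_planted_aa(rng, 60), codon_count=60,
                    biotype="lincRNA")
                for i in range(10)
            ]
            effects = {e.orf_id: ("odds_ratio", planted) for e in entries}
            psms, _ = cs.simulate_psm_cohort(entries, design, effects, seed=seed)
            assigned, p2o, _ = cs.assign_and_filter(psms, entries, cs.FilterConfig())
            qm, _ = cs.quantify_and_select(
                assigned, p2o, design, cs.FilterConfig(psm_min=1, min_samples=1)
            )
            out = cs.odds_ratio(qm, design, method="conditional")
            ok = out["flags"] == ""
            log_ors.extend(np.log(out.loc[ok, "or_hat"]))
        mean = np.mean(log_ors)
        sem = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert abs(mean - np.log(planted)) < 3 * sem + 0.05
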