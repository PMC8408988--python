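"""Differential expression, Cox screening, lasso reduction, PS/HRDPS."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import hrdimmune as h
from hrdimmune.expression import (
    HrdSignature,
    SignatureFactor,
    call_hrdps_positive,
    cox_screen,
    differential_expression,
    evaluate_signature_as_hrd_predictor,
    lasso_reduce,
    prognostic_score,
)


def nb_counts(rng, mean, n, dispersion=0.1):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean[:, None]), size=(len(mean), n))


class TestDifferentialExpression:
    def test_null_cohort_is_calibrated(self):
        # homogeneous cohort with arbitrary labels: ~5% of genes at nominal
        # p < 0.05, essentially none at FDR 0.05
        rng = np.random.default_rng(0)
        fracs, deg_counts = [], []
        for _ in range(10):
            mean = np.exp(rng.normal(4, 1, 400))
            counts = pd.DataFrame(
                nb_counts(rng, mean, 30),
                index=[f"g{i}" for i in range(400)],
                columns=[f"s{i}" for i in range(30)],
            )
            labels = pd.Series([True] * 15 + [False] * 15, index=counts.columns)
            de = differential_expression(counts, labels)
            fracs.append((de["p"] < 0.05).mean())
            deg_counts.append(int(de["deg"].sum()))
        assert 0.02 <= np.mean(fracs) <= 0.10
        assert np.mean(deg_counts) <= 2

    def test_planted_fourfold_shift_recovered_with_direction(self):
        rng = np.random.default_rng(1)
        n_genes, n_planted, n_per_group = 400, 50, 20
        mean = np.exp(rng.normal(4, 1, n_genes))
        g1 = nb_counts(rng, mean * np.where(np.arange(n_genes) < n_planted, 4.0, 1.0),
                       n_per_group)
        g2 = nb_counts(rng, mean, n_per_group)
        counts = pd.DataFrame(
            np.hstack([g1, g2]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(2 * n_per_group)],
        )
        labels = pd.Series([True] * n_per_group + [False] * n_per_group,
                           index=counts.columns)
        de = differential_expression(counts, labels)
        planted = de.iloc[:n_planted]
        assert planted["deg"].mean() >= 0.8
        assert (planted.loc[planted["deg"], "log2fc"] > 0).all()

    def test_all_zero_gene_excluded_not_nan(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            nb_counts(rng, np.full(20, 50.0), 10),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(10)],
        )
        counts.loc["g0"] = 0
        labels = pd.Series([True] * 5 + [False] * 5, index=counts.columns)
        de = differential_expression(counts, labels)
        assert "g0" not in de.index
        assert not de.isna().any().any()

    def test_non_integer_counts_rejected(self):
        counts = pd.DataFrame(np.random.default_rng(3).normal(5, 1, (10, 6)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(6)])
        labels = pd.Series([True] * 3 + [False] * 3, index=counts.columns)
        with pytest.raises(ValueError, match="integer"):
            differential_expression(counts, labels)

    def test_bh_fdr_is_monotone_step_up(self):
        rng = np.random.default_rng(4)
        mean = np.exp(rng.normal(4, 1, 200))
        counts = pd.DataFrame(nb_counts(rng, mean, 20),
                              index=[f"g{i}" for i in range(200)],
                              columns=[f"s{i}" for i in range(20)])
        labels = pd.Series([True] * 10 + [False] * 10, index=counts.columns)
        de = differential_expression(counts, labels).sort_values("p")
        assert (np.diff(de["fdr"].to_numpy()) >= -1e-12).all()
        assert de["fdr"].between(0, 1).all()


def survival_frame(rng, n, loghr=0.0, x=None):
    x = rng.normal(0, 1, n) if x is None else x
    lam = 0.02 * np.exp(loghr * x)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / 0.01, n)
    idx = [f"s{i}" for i in range(n)]
    times = pd.Series(np.minimum(t, c), index=idx)
    events = pd.Series((t <= c).astype(int), index=idx)
    expr = pd.DataFrame({"gene": x}, index=idx).T
    expr.columns = idx
    return expr, times, events


class TestCoxScreen:
    def test_null_gene_hr_near_one(self):
        rng = np.random.default_rng(5)
        inside = 0
        for _ in range(20):
            expr, times, events = survival_frame(rng, 500)
            res = cox_screen(expr, times, events)
            inside += 0.85 <= res.loc["gene", "hr"] <= 1.18
        assert inside >= 18

    def test_planted_loghr_recovered(self):
        rng = np.random.default_rng(6)
        hrs = []
        for _ in range(10):
            expr, times, events = survival_frame(rng, 500, loghr=-0.7)
            res = cox_screen(expr, times, events)
            hrs.append(res.loc["gene", "hr"])
        assert 0.40 <= np.mean(hrs) <= 0.62

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        expr, times, events = survival_frame(rng, 100)
        expr.loc["flatgene"] = 1.0
        with pytest.warns(UserWarning, match="dropped"):
            res = cox_screen(expr, times, events)
        assert "flatgene" not in res.index and "gene" in res.index

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(8)
        expr, times, events = survival_frame(rng, 30)
        events[:] = 0
        with pytest.raises(ValueError, match="events"):
            cox_screen(expr, times, events)


class TestLassoReduce:
    def _cohort(self, rng, n=300, n_noise=200, effect=1.2):
        hrd = rng.random(n) < 0.5
        informative = {
            f"inf{i:02d}": rng.normal(0, 1, n) + effect * hrd * (1 if i % 3 else -1)
            for i in range(15)
        }
        noise = {f"noise{i:03d}": rng.normal(0, 1, n) for i in range(n_noise)}
        expr = pd.DataFrame({**informative, **noise},
                            index=[f"s{i}" for i in range(n)]).T
        labels = pd.Series(hrd, index=expr.columns)
        # univariate table and fold changes consistent with the construction
        uni = pd.DataFrame(
            {"hr": [0.7 if i % 3 else 1.4 for i in range(15)]
                   + [1.2 if rng.random() < 0.5 else 0.8 for _ in range(n_noise)]},
            index=list(informative) + list(noise),
        )
        lfc = pd.Series(
            [1.5 if i % 3 else -1.5 for i in range(15)]
            + [rng.choice([-1.0, 1.0]) for _ in range(n_noise)],
            index=uni.index,
        )
        return expr, labels, uni, lfc

    def test_support_recovery(self):
        rng = np.random.default_rng(9)
        recovered, false_pos = [], []
        for _ in range(5):
            expr, labels, uni, lfc = self._cohort(rng)
            sig = lasso_reduce(expr, labels, uni, lfc, seed=0)
            genes = set(sig.genes)
            recovered.append(len([g for g in genes if g.startswith("inf")]))
            false_pos.append(len([g for g in genes if g.startswith("noise")]))
        assert np.median(recovered) >= 12
        assert np.median(false_pos) <= 5

    def test_duplicate_gene_retained_once(self):
        rng = np.random.default_rng(10)
        expr, labels, uni, lfc = self._cohort(rng, n=150, n_noise=20)
        expr.loc["inf_copy"] = expr.loc["inf00"]
        uni.loc["inf_copy"] = uni.loc["inf00"]
        lfc.loc["inf_copy"] = lfc.loc["inf00"]
        sig = lasso_reduce(expr, labels, uni, lfc, seed=0)
        assert not ({"inf00", "inf_copy"} <= set(sig.genes))

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(11)
        expr, labels, uni, lfc = self._cohort(rng, n=150, n_noise=30)
        s1 = lasso_reduce(expr, labels, uni, lfc, seed=4)
        s2 = lasso_reduce(expr, labels, uni, lfc, seed=4)
        assert s1.genes == s2.genes

    def test_inconsistent_direction_excluded(self):
        rng = np.random.default_rng(12)
        expr, labels, uni, lfc = self._cohort(rng, n=150, n_noise=10)
        # flip one informative gene's HR so direction and hazard disagree
        uni.loc["inf01", "hr"] = 0.5  # up-direction gene needs HR < 1; make a down gene bad
        lfc.loc["inf01"] = -2.0
        with pytest.warns(UserWarning, match="inconsistent"):
            sig = lasso_reduce(expr, labels, uni, lfc, seed=0)
        assert "inf01" not in sig.genes


class TestPrognosticScore:
    def test_hand_computed_example(self):
        sig = HrdSignature(
            [SignatureFactor("up1", "up", 0.5), SignatureFactor("dn1", "down", 2.0)]
        )
        expr = pd.DataFrame({"s1": [2.0, 1.0]}, index=["up1", "dn1"])
        ps = prognostic_score(expr, sig)
        assert ps.loc["s1", "ps_up"] == pytest.approx(4.0)
        assert ps.loc["s1", "ps_down"] == pytest.approx(0.5)
        assert ps.loc["s1", "hrdps"] == pytest.approx(3.5)

    def test_empty_down_list_means_hrdps_equals_ps_up(self):
        sig = HrdSignature([SignatureFactor("up1", "up", 0.8)])
        expr = pd.DataFrame({"s1": [3.0], "s2": [1.0]}, index=["up1"])
        ps = prognostic_score(expr, sig)
        assert (ps["hrdps"] == ps["ps_up"]).all()

    def test_homogeneity_and_identity(self):
        rng = np.random.default_rng(13)
        sig = HrdSignature(
            [SignatureFactor(f"u{i}", "up", 0.5 + 0.1 * i) for i in range(3)]
            + [SignatureFactor(f"d{i}", "down", 1.5 + 0.2 * i) for i in range(4)]
        )
        expr = pd.DataFrame(
            rng.normal(5, 2, (7, 10)),
            index=[f.gene for f in sig.factors],
            columns=[f"s{i}" for i in range(10)],
        )
        ps = prognostic_score(expr, sig)
        np.testing.assert_allclose(ps["hrdps"], ps["ps_up"] - ps["ps_down"], rtol=1e-12)
        doubled = prognostic_score(2 * expr, sig)
        np.testing.assert_allclose(doubled["hrdps"], 2 * ps["hrdps"], rtol=1e-12)

    def test_missing_genes_listed_in_error(self):
        sig = HrdSignature([SignatureFactor("absent", "up", 0.5)])
        expr = pd.DataFrame({"s1": [1.0]}, index=["other"])
        with pytest.raises(KeyError, match="absent"):
            prognostic_score(expr, sig)

    def test_invalid_hazard_ratio_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            HrdSignature([SignatureFactor("g", "up", -1.0)])
        with pytest.raises(ValueError, match="HR < 1"):
            HrdSignature([SignatureFactor("g", "up", 1.2)])

    def test_signature_serialisation_round_trip(self, tmp_path):
        sig = HrdSignature(
            [SignatureFactor("a", "up", 0.4), SignatureFactor("b", "down", 2.5)]
        )
        assert HrdSignature.from_json(sig.to_json()).to_frame().equals(sig.to_frame())
        sig.to_tsv(tmp_path / "sig.tsv")
        assert HrdSignature.from_tsv(tmp_path / "sig.tsv").to_frame().equals(sig.to_frame())


class TestHrdpsPositivity:
    def test_median_split_is_strict(self):
        flags = call_hrdps_positive(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert flags.tolist() == [False, False, True, True]

    def test_all_equal_none_positive(self):
        assert call_hrdps_positive(pd.Series([2.0] * 6)).sum() == 0

    def test_quantile_rule_matches_is_positivity(self):
        rng = np.random.default_rng(14)
        scores = pd.Series(rng.normal(size=40))
        pd.testing.assert_series_equal(
            call_hrdps_positive(scores, rule=0.75),
            h.call_is_positive(scores).rename("hrdps_positive"),
        )


class TestSignatureAsPredictor:
    def _sig_and_expr(self, rng, n, sigma):
        labels = pd.Series(rng.random(n) < 0.5, index=[f"s{i}" for i in range(n)])
        sig = HrdSignature([SignatureFactor("g1", "up", 0.5)])
        expr = pd.DataFrame(
            {"g1": labels.astype(float) + rng.normal(0, sigma, n)},
            index=labels.index,
        ).T
        return sig, expr, labels

    def test_perfect_separation_gives_auc_one(self):
        rng = np.random.default_rng(15)
        sig, expr, labels = self._sig_and_expr(rng, 100, sigma=1e-6)
        _, _, auc = evaluate_signature_as_hrd_predictor(expr, sig, labels)
        assert auc == pytest.approx(1.0)

    def test_independent_labels_give_chance_auc(self):
        rng = np.random.default_rng(16)
        sig, expr, labels = self._sig_and_expr(rng, 200, sigma=1.0)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        _, _, auc = evaluate_signature_as_hrd_predictor(expr, sig, perm)
        assert 0.42 <= auc <= 0.58

    def test_binormal_closed_form(self):
        # score = label + N(0, sigma): AUC -> Phi(1 / (sigma * sqrt(2)))
        rng = np.random.default_rng(17)
        sigma = 1.0
        sig, expr, labels = self._sig_and_expr(rng, 3000, sigma=sigma)
        _, _, auc = evaluate_signature_as_hrd_predictor(expr, sig, labels)
        assert auc == pytest.approx(norm.cdf(1 / (sigma * np.sqrt(2))), abs=0.05)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(18)
        sig, expr, labels = self._sig_and_expr(rng, 50, sigma=1.0)
        labels[:] = True
        with pytest.raises(ValueError, match="both classes"):
            evaluate_signature_as_hrd_predictor(expr, sig, labels)


class TestEndToEndDerivation:
    def test_derived_signature_predicts_deficiency(self):
        """Full derivation chain (DE screen -> Cox screen -> lasso) on
        cohorts with the planted expression shift yields a deficiency
        predictor with AUC >= 0.85 (median over replicates)."""
        aucs = []
        for rep in range(5):
            config = h.CohortConfig(n_samples=250, n_genes=300, seed=7000 + rep)
            bundle, truth = h.generate_cohort(config)
            labels = truth.samples["hrd"].map(
                {True: "HR-deficient", False: "HR-proficient"}
            )
            de = differential_expression(bundle.expression_counts, labels)
            degs = de.index[de["deg"]].tolist()
            uni = cox_screen(
                bundle.expression_log,
                bundle.clinical["ffi_months"],
                bundle.clinical["ffi_event"],
                degs,
            )
            sig = lasso_reduce(
                bundle.expression_log.loc[degs], labels, uni, de["log2fc"], seed=0
            )
            _, _, auc = evaluate_signature_as_hrd_predictor(
                bundle.expression_log, sig, labels
            )
            aucs.append(auc)
        assert np.median(aucs) >= 0.85
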