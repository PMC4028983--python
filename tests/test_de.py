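import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from conftest import naive_bh
from stagesig import de
from stagesig.io import ExpressionMatrix, FeatureMap


def _random_log_expr(seed, n_feat=200, n1=8, n2=6):
    rng = np.random.default_rng(seed)
    x = rng.normal(5, 1, (n_feat, n1 + n2))
    labels = ["early"] * n1 + ["late"] * n2
    df = pd.DataFrame(x, index=[f"f{i}" for i in range(n_feat)])
    return df, labels


class TestLogTransform:
    def test_arithmetic(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.99]], index=["f"], columns=["a", "b"]), "gene")
        out = de.log_transform(expr, pseudocount=0.01)
        assert out.loc["f", "a"] == pytest.approx(np.log2(0.01))
        assert out.loc["f", "b"] == pytest.approx(0.0)

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 50, 100)
        out = de.log_transform(pd.DataFrame(v[None, :]))
        assert np.array_equal(np.argsort(v), np.argsort(out.to_numpy()[0]))

    def test_bad_pseudocount(self):
        with pytest.raises(ValueError):
            de.log_transform(pd.DataFrame([[1.0]]), pseudocount=0.0)


class TestModeratedT:
    def test_prior_df_zero_equals_ordinary_pooled_t(self):
        log_expr, labels = _random_log_expr(0)
        res = de.moderated_t(log_expr, labels, early="early", late="late",
                             prior_df=0)
        t_ref, p_ref = stats.ttest_ind(
            log_expr.loc[:, np.array(labels) == "late"],
            log_expr.loc[:, np.array(labels) == "early"], axis=1)
        assert np.abs(res["t_mod"].to_numpy() - t_ref).max() < 1e-10
        assert np.abs(res["p"].to_numpy() - p_ref).max() < 1e-10

    def test_identical_variances_give_infinite_prior(self):
        # every feature shares the same residual variance -> moments see no
        # spread -> d0 = inf and s2_post = s0^2 = s2
        base = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.tile(base, (50, 1)) + np.arange(50)[:, None]
        log_expr = pd.DataFrame(np.hstack([x, x + 0.5]))
        labels = ["a"] * 4 + ["b"] * 4
        res = de.moderated_t(log_expr, labels)
        assert np.isinf(res.attrs["prior_df"])
        assert res.attrs["prior_var"] == pytest.approx(res["s2"].iloc[0], rel=1e-9)

    def test_null_type_i_rate(self):
        rng = np.random.default_rng(42)
        log_expr = pd.DataFrame(rng.normal(0, 1, (2000, 40)))
        labels = ["a"] * 20 + ["b"] * 20
        res = de.moderated_t(log_expr, labels)
        frac = float((res["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_group_relabeling_flips_sign_only(self):
        log_expr, labels = _random_log_expr(7)
        fwd = de.moderated_t(log_expr, labels, early="early", late="late")
        rev = de.moderated_t(log_expr, labels, early="late", late="early")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_prior_estimation_recovers_planted_hyperparameters(self):
        # variances drawn from the scaled inverse-chi2 the moderation assumes
        rng = np.random.default_rng(3)
        d0_true, s0_true, d = 8.0, 0.7, 12
        n_feat = 5000
        s2_true = d0_true * s0_true / rng.chisquare(d0_true, n_feat)
        s2_obs = s2_true * rng.chisquare(d, n_feat) / d
        d0_hat, s0_hat = de.estimate_prior(s2_obs, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.25)
        assert s0_hat == pytest.approx(s0_true, rel=0.1)

    def test_small_group_rejected(self):
        log_expr, _ = _random_log_expr(0, n1=1, n2=5)
        with pytest.raises(ValueError, match=">=2"):
            de.moderated_t(log_expr, ["a"] + ["b"] * 5)


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            assert np.allclose(de.bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_never_decreases_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 100)
        adj = de.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])


def _de_frame(rows):
    df = pd.DataFrame(rows, columns=["log2fc", "t_mod", "p", "fdr"])
    df["level"] = "gene"
    df.index = [f"g{i}" for i in range(len(rows))]
    return df


class TestSelection:
    def test_strongly_significant_feature_selected_up(self):
        # the headline calcium-signaling gene: log2FC 2.14 at FDR 1.8e-10
        df = _de_frame([[2.14, 10.0, 1e-12, 1.8e-10]])
        sigs = de.select_signatures(df)
        assert sigs.feature_ids == ["g0"]
        assert sigs.table["direction"].iloc[0] == 1

    def test_fold_change_below_two_rejected(self):
        df = _de_frame([[0.99, 8.0, 1e-11, 1e-9]])
        assert len(de.select_signatures(df)) == 0

    def test_stricter_thresholds_give_subset(self):
        rng = np.random.default_rng(0)
        df = _de_frame([[rng.normal(0, 2), 0.0, p, p * 2]
                        for p in rng.uniform(0, 0.01, 100)])
        loose = set(de.select_signatures(df, fc_min=2, fdr_max=0.01).feature_ids)
        strict = set(de.select_signatures(df, fc_min=4, fdr_max=0.001).feature_ids)
        assert strict <= loose


class TestCombineAndSwitches:
    def _sigs(self, features, directions, level):
        df = pd.DataFrame({
            "log2fc": [2.0 * d for d in directions],
            "t_mod": 9.0, "p": 1e-9, "fdr": 1e-7,
            "level": level, "direction": directions,
        }, index=features)
        return de.SignatureSet(df, level=level)

    def setup_method(self):
        self.fmap = FeatureMap(pd.Series(
            ["gA", "gA", "gB", "gC", "gC"],
            index=["a1", "a2", "b1", "c1", "c2"]))

    def test_gene_priority_rule(self):
        gene_sigs = self._sigs(["gA"], [1], "gene")
        iso_sigs = self._sigs(["a1", "b1"], [1, -1], "isoform")
        combined = de.combine_signatures(gene_sigs, iso_sigs, self.fmap)
        assert set(combined.feature_ids) == {"gA", "b1"}
        assert combined.table.loc["gA", "provenance"] == "both"
        assert combined.table.loc["b1", "provenance"] == "isoform_only"

    def test_isoform_of_nonsignificant_gene_kept(self):
        combined = de.combine_signatures(
            self._sigs([], [], "gene"), self._sigs(["c1"], [1], "isoform"), self.fmap)
        assert combined.feature_ids == ["c1"]
        assert (combined.table["provenance"] == "isoform_only").all()

    def test_unmapped_isoform_is_error(self):
        with pytest.raises(ValueError, match="zz9"):
            de.combine_signatures(
                self._sigs(["gA"], [1], "gene"),
                self._sigs(["zz9"], [1], "isoform"), self.fmap)

    def test_combined_size_set_arithmetic(self, small_cohort):
        cohort = small_cohort
        disc = cohort.clinical.stage_subset(["I", "IV"])
        labels = disc.stages().to_numpy()
        gene_res = de.moderated_t(
            de.log_transform(cohort.gene.subset_samples(disc.sample_ids)),
            labels, early="I", late="IV", level="gene")
        iso_res = de.moderated_t(
            de.log_transform(cohort.isoform.subset_samples(disc.sample_ids)),
            labels, early="I", late="IV", level="isoform")
        g = de.select_signatures(gene_res)
        i = de.select_signatures(iso_res)
        combined = de.combine_signatures(g, i, cohort.feature_map)
        iso_genes = cohort.feature_map.genes_for(i.feature_ids)
        n_iso_kept = int((~iso_genes.isin(set(g.feature_ids))).sum())
        assert len(combined) == len(g) + n_iso_kept

    def test_switch_directions(self):
        iso_sigs = self._sigs(["a1", "a2", "c1", "c2"], [1, -1, 1, 1], "isoform")
        assert de.detect_switches(iso_sigs, self.fmap) == ["gA"]

    def test_planted_switches_recovered_exactly(self, small_cohort):
        cohort = small_cohort
        disc = cohort.clinical.stage_subset(["I", "IV"])
        iso_res = de.moderated_t(
            de.log_transform(cohort.isoform.subset_samples(disc.sample_ids)),
            disc.stages().to_numpy(), early="I", late="IV", level="isoform")
        switches = de.detect_switches(
            de.select_signatures(iso_res), cohort.feature_map)
        assert switches == cohort.truth.switch_genes


class TestOverlap:
    def setup_method(self):
        self.fmap = FeatureMap(pd.Series(
            ["gA", "gB", "gC"], index=["a1", "b1", "c1"]))

    def _sigs(self, features, level):
        df = pd.DataFrame(
            {"log2fc": 2.0, "t_mod": 9.0, "p": 1e-9, "fdr": 1e-7,
             "level": level, "direction": 1}, index=features)
        return de.SignatureSet(df, level=level)

    def test_disjoint(self):
        counts = de.signature_overlap(
            self._sigs(["gZ"], "gene"), self._sigs(["a1"], "isoform"), self.fmap)
        assert counts["n_both"] == 0

    def test_identical(self):
        counts = de.signature_overlap(
            self._sigs(["gA", "gB"], "gene"),
            self._sigs(["a1", "b1"], "isoform"), self.fmap)
        assert counts["n_both"] == 2
        assert counts["pct_gene_with_sig_isoform"] == pytest.approx(100.0)
        assert counts["pct_isoform_genes_not_gene_sig"] == pytest.approx(0.0)

    def test_matches_brute_force_sets(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        isos = [f"i{i}" for i in range(60)]
        fmap = FeatureMap(pd.Series(rng.choice(genes, 60), index=isos))
        gene_sel = list(rng.choice(genes, 10, replace=False))
        iso_sel = list(rng.choice(isos, 15, replace=False))
        counts = de.signature_overlap(
            self._sigs(gene_sel, "gene"), self._sigs(iso_sel, "isoform"), fmap)
        iso_genes = {fmap.gene_of(i) for i in iso_sel}
        assert counts["n_both"] == len(set(gene_sel) & iso_genes)
        assert counts["n_isoform_only"] == len(iso_genes - set(gene_sel))


def test_planted_gene_signatures_recovered(small_cohort):
    cohort = small_cohort
    disc = cohort.clinical.stage_subset(["I", "IV"])
    res = de.moderated_t(
        de.log_transform(cohort.gene.subset_samples(disc.sample_ids)),
        disc.stages().to_numpy(), early="I", late="IV", level="gene")
    sigs = set(de.select_signatures(res).feature_ids)
    planted = set(cohort.truth.planted("gene_de", "gene"))
    assert len(sigs & planted) >= 0.9 * len(planted)
    null = set(cohort.truth.null_features("gene"))
    assert not sigs & null
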