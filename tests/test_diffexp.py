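"""Two-group fits, empirical-Bayes moderation and B-statistic selection."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mirscape.diffexp import (
    collapse_probes,
    estimate_variance_prior,
    fit_groups,
    moderate,
    rank_by_logfc,
    run_diffexp,
    select_de,
)
from mirscape.io import ExpressionMatrix
from mirscape.synthetic import SimConfig, simulate_expression


def make_matrix(ctrl: np.ndarray, trt: np.ndarray, genes=None) -> ExpressionMatrix:
    ctrl, trt = np.atleast_2d(ctrl), np.atleast_2d(trt)
    n = ctrl.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    cols = [f"c{j}" for j in range(ctrl.shape[1])] + [f"t{j}" for j in range(trt.shape[1])]
    values = pd.DataFrame(np.hstack([ctrl, trt]), index=genes, columns=cols)
    groups = pd.Series(
        ["control"] * ctrl.shape[1] + ["treatment"] * trt.shape[1],
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionMatrix(values=values, groups=groups)


class TestFitGroups:
    def test_downregulated_gene_has_positive_logfc(self):
        fit = fit_groups(make_matrix([[4, 5, 6]], [[1, 2, 3]]))
        assert fit["logFC"].iloc[0] == pytest.approx(3.0)
        assert fit["df"].iloc[0] == 4

    def test_identical_groups(self):
        fit = fit_groups(make_matrix([[1, 2, 3]], [[1, 2, 3]]))
        assert fit["logFC"].iloc[0] == pytest.approx(0.0)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)  # pooled of two var-1 groups

    def test_zero_variance_gene_retained(self):
        fit = fit_groups(make_matrix([[1, 1, 1]], [[1, 1, 1]]))
        assert fit["logFC"].iloc[0] == 0.0
        assert fit["s2"].iloc[0] == 0.0

    def test_label_swap_negates_logfc_and_reverses_ranking(self, small_bundle):
        mat = small_bundle.expr_treatment
        swapped = ExpressionMatrix(
            values=mat.values.copy(),
            groups=mat.groups.map(
                {"control": "treatment", "treatment": "control"}
            ),
        )
        f1, f2 = fit_groups(mat), fit_groups(swapped)
        np.testing.assert_allclose(f1["logFC"], -f2["logFC"], atol=1e-12)
        # rank order reverses exactly when there are no logFC ties
        assert f1["logFC"].duplicated().sum() == 0
        assert rank_by_logfc(f1) == rank_by_logfc(f2)[::-1]


class TestModeration:
    def test_d0_zero_recovers_ordinary_t(self, small_bundle):
        fit = fit_groups(small_bundle.expr_treatment)
        de = moderate(fit, d0_override=0.0, s0_sq_override=1.0)
        n1, n2, df = 3, 3, 4
        u = 1 / n1 + 1 / n2
        t_ord = fit["logFC"] / np.sqrt(fit["s2"] * u)
        np.testing.assert_allclose(de["t_mod"], t_ord, rtol=1e-12)

    def test_d0_infinite_uses_prior_scale_only(self, small_bundle):
        fit = fit_groups(small_bundle.expr_treatment)
        s0_sq = 0.07
        de = moderate(fit, d0_override=np.inf, s0_sq_override=s0_sq)
        u = 1 / 3 + 1 / 3
        np.testing.assert_allclose(
            de["t_mod"], fit["logFC"] / np.sqrt(s0_sq * u), rtol=1e-12
        )

    def test_equal_variances_pass_through(self):
        rng = np.random.default_rng(0)
        n = 200
        ctrl = rng.normal(5, 0.0, (n, 3)) + rng.normal(0, 1, (n, 1))
        # all genes share the same within-group variance pattern
        base = rng.normal(0, 0.5, (1, 6))
        values = np.tile(base, (n, 1)) + rng.normal(0, 1e-9, (n, 6))
        mat = make_matrix(values[:, :3], values[:, 3:])
        de = moderate(fit_groups(mat))
        # d0 -> inf fallback: posterior variance identical for all genes
        assert np.isinf(de.attrs["d0"])
        assert np.allclose(de["s2_post"], de["s2_post"].iloc[0])

    def test_hyperparameter_recovery_from_hierarchical_model(self):
        # sigma2 ~ s0^2 * d0 / chi2_d0, s2 | sigma2 ~ sigma2 * chi2_df / df
        d0_true, s0_true, df, n = 4.0, 0.05, 4, 5000
        rng = np.random.default_rng(123)
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        d0_hat, s0_hat = estimate_variance_prior(s2, df)
        assert abs(d0_hat - d0_true) / d0_true < 0.2
        assert abs(s0_hat - s0_true) / s0_true < 0.2

    def test_needs_ensemble(self):
        fit = fit_groups(make_matrix(np.ones((5, 3)), np.ones((5, 3))))
        with pytest.raises(ValueError, match="50 genes"):
            moderate(fit)


class TestSelection:
    def test_all_below_cut_gives_empty_sets(self, small_bundle):
        de = run_diffexp(small_bundle.expr_treatment)
        up, down = select_de(de, b_cut=de["B"].max() + 1)
        assert up == set() and down == set()

    def test_sign_convention_routes_positive_logfc_to_downregulated(self):
        de = pd.DataFrame(
            {"B": [6.0, 6.0, 1.0], "logFC": [2.0, -2.0, 3.0]},
            index=["down_gene", "up_gene", "weak"],
        )
        up, down = select_de(de, b_cut=5.0)
        assert down == {"down_gene"} and up == {"up_gene"}

    def test_planted_recall_beats_permutation_baseline(self, study10k):
        de = run_diffexp(study10k.expr_treatment)
        _, down = select_de(de, b_cut=5.0)
        targets = set(study10k.truth.index[study10k.truth["is_target"]])
        recall = len(down & targets) / len(targets)
        rng = np.random.default_rng(0)
        genes = np.array(de.index)
        perm_recalls = [
            len(set(rng.choice(genes, size=len(down), replace=False)) & targets)
            / len(targets)
            for _ in range(20)
        ]
        assert recall > max(perm_recalls)
        assert recall > 0.2  # a meaningful fraction of planted genes


class TestCollapseProbes:
    def test_keeps_largest_absolute_logfc_per_gene(self):
        fit = pd.DataFrame(
            {"logFC": [0.5, -2.0, 1.0, 0.1]},
            index=["p1", "p2", "p3", "p4"],
        )
        mapping = pd.Series(
            {"p1": "gA", "p2": "gA", "p3": "gB", "p4": "gB"}
        )
        out = collapse_probes(fit, mapping)
        assert out.loc["gA", "logFC"] == -2.0
        assert out.loc["gB", "logFC"] == 1.0

    def test_unmapped_probe_rejected(self):
        fit = pd.DataFrame({"logFC": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="p1"):
            collapse_probes(fit, pd.Series(dtype=object))


class TestRanking:
    def test_descending_logfc(self):
        de = pd.DataFrame({"logFC": [2.0, 0.0, -1.0]}, index=["a", "b", "c"])
        assert rank_by_logfc(de) == ["a", "b", "c"]

    def test_ties_break_lexicographically(self):
        de = pd.DataFrame({"logFC": [1.0, 1.0, 2.0]}, index=["zz", "aa", "mm"])
        assert rank_by_logfc(de) == ["mm", "aa", "zz"]


def test_null_run_rarely_reaches_extreme_adjusted_p(study10k):
    """Global-null expression: adjusted p < 1e-4 in at most 0.1% of genes."""
    truth = study10k.truth
    cfg = SimConfig(n_genes=len(truth), seed=0)
    fracs = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        _, null_run = simulate_expression(cfg, truth, rng)
        de = run_diffexp(null_run)
        fracs.append((de["p_adj"] < 1e-4).mean())
    assert np.mean(fracs) <= 0.001


def test_moderation_matches_limma_oracle(small_bundle, tmp_path):
    """Independent cross-check: Bioconductor limma on the same matrix."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    mat = small_bundle.expr_treatment
    expr_path = tmp_path / "expr.tsv"
    mat.values.to_csv(expr_path, sep="\t")
    groups = ",".join(f'"{g}"' for g in mat.groups)
    rcode = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        x <- read.delim("{expr_path}", row.names=1)
        groups <- c({groups})
        design <- model.matrix(~0+factor(groups, levels=c("treatment","control")))
        colnames(design) <- c("treatment","control")
        fit <- lmFit(as.matrix(x), design)
        fit <- contrasts.fit(fit, makeContrasts(control-treatment, levels=design))
        fit <- eBayes(fit)
        out <- data.frame(logFC=fit$coefficients[,1], t=fit$t[,1],
                          B=fit$lods[,1], p=fit$p.value[,1])
        write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t", quote=FALSE)
        """
    )
    (tmp_path / "cmp.R").write_text(rcode)
    subprocess.run(["Rscript", str(tmp_path / "cmp.R")], check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
    de = moderate(fit_groups(mat))
    np.testing.assert_allclose(de["logFC"], ref["logFC"], atol=1e-10)
    np.testing.assert_allclose(de["t_mod"], ref["t"], atol=1e-8)
    np.testing.assert_allclose(de["p"], ref["p"], atol=1e-10)
    np.testing.assert_allclose(de["B"], ref["B"], atol=1e-6)
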