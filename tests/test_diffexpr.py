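"""Probe collapsing, the moderated t, and DE list set logic."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet import (
    ExpressionMatrix,
    collapse_probes,
    combine_de,
    ensure_log2,
    intersect_de,
    moderated_t_test,
    screen_de,
)
from cernet.diffexpr import DERecord, ModeratedFit

from conftest import two_group_matrix


def _fit_from_values(log2fc, p, t=None):
    """Wrap raw per-feature statistics into a ModeratedFit for screening."""
    idx = [f"g{i}" for i in range(len(log2fc))]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "var": 1.0,
            "var_post": 1.0,
            "t": t if t is not None else log2fc,
            "p": p,
        },
        index=idx,
    )
    return ModeratedFit(table, 4.0, 2.0, 1.0, 3, 3)


class TestCollapseProbes:
    def test_one_probe_per_gene_rekeys(self, rng):
        em = two_group_matrix(rng.normal(size=(4, 6)), 3, 3,
                              feature_ids=["p1", "p2", "p3", "p4"])
        ann = {"p1": "gB", "p2": "gA", "p3": "gD", "p4": "gC"}
        out = collapse_probes(em, ann)
        assert list(out.feature_ids) == ["gA", "gB", "gC", "gD"]
        np.testing.assert_allclose(
            out.values.loc["gA"].to_numpy(), em.values.loc["p2"].to_numpy()
        )

    def test_two_probes_average(self):
        em = two_group_matrix([[2.0, 2, 2, 2], [4.0, 4, 4, 4]], 2, 2,
                              feature_ids=["p1", "p2"])
        out = collapse_probes(em, {"p1": "g", "p2": "g"})
        assert (out.values.loc["g"] == 3.0).all()

    def test_matches_groupby_oracle(self, rng):
        probes = [f"p{i}" for i in range(50)]
        genes = [f"g{i % 10}" for i in range(50)]
        vals = rng.normal(size=(50, 8))
        em = two_group_matrix(vals, 4, 4, feature_ids=probes)
        out = collapse_probes(em, dict(zip(probes, genes)))
        for g in sorted(set(genes)):
            rows = [i for i, gg in enumerate(genes) if gg == g]
            np.testing.assert_allclose(
                out.values.loc[g].to_numpy(), vals[rows].mean(axis=0)
            )

    def test_unmapped_probes_dropped_and_empty_overlap_errors(self, rng):
        em = two_group_matrix(rng.normal(size=(3, 4)), 2, 2,
                              feature_ids=["p1", "p2", "p3"])
        out = collapse_probes(em, {"p1": "g1"})
        assert list(out.feature_ids) == ["g1"]
        with pytest.raises(ValueError, match="no probe"):
            collapse_probes(em, {"x": "g1"})

    def test_balanced_design_preserves_sample_means(self, rng):
        """With all probes mapped and equal probe counts per gene, the
        per-sample mean over genes equals the mean over probes."""
        probes = [f"p{i}" for i in range(40)]
        genes = [f"g{i % 8}" for i in range(40)]  # 5 probes per gene
        vals = rng.normal(size=(40, 6))
        em = two_group_matrix(vals, 3, 3, feature_ids=probes)
        out = collapse_probes(em, dict(zip(probes, genes)))
        np.testing.assert_allclose(
            out.values.mean(axis=0).to_numpy(), vals.mean(axis=0), atol=1e-12
        )


class TestEnsureLog2:
    def test_log_scale_unchanged(self, rng):
        em = two_group_matrix(rng.uniform(2, 14, size=(5, 4)), 2, 2)
        out = ensure_log2(em)
        pd.testing.assert_frame_equal(out.values, em.values)

    def test_all_zero_linear_matrix_stays_zero(self):
        em = two_group_matrix(np.zeros((3, 4)), 2, 2)
        out = ensure_log2(em)
        assert (out.values == 0).all().all()

    def test_linear_matrix_transformed(self):
        em = two_group_matrix(np.full((2, 4), 1e6), 2, 2)
        out = ensure_log2(em)
        np.testing.assert_allclose(
            out.values.to_numpy(), np.log2(1e6 + 1), rtol=1e-12
        )

    def test_negative_linear_matrix_errors(self):
        em = two_group_matrix([[100.0, 100, 100, -1]], 2, 2)
        with pytest.raises(ValueError, match="negative"):
            ensure_log2(em)


class TestModeratedT:
    def test_equal_group_means_give_null_statistics(self):
        em = two_group_matrix([[1.0, 2, 3, 3, 2, 1],
                               [5.0, 6, 7, 7, 6, 5]], 3, 3)
        fit = moderated_t_test(em)
        assert fit.table["log2fc"].abs().max() < 1e-12
        np.testing.assert_allclose(fit.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.table["p"], 1.0, atol=1e-12)

    def test_prior_df_zero_equals_classical_t(self, rng):
        """Forcing d0 = 0 reproduces the pooled two-sample t exactly."""
        for _ in range(100):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            vals = rng.normal(size=(20, n1 + n2))
            em = two_group_matrix(vals, n1, n2)
            fit = moderated_t_test(em, prior_df=0)
            t_ref, p_ref = stats.ttest_ind(
                vals[:, :n1], vals[:, n1:], axis=1, equal_var=True
            )
            np.testing.assert_allclose(fit.table["t"], t_ref, atol=1e-12)
            np.testing.assert_allclose(fit.table["p"], p_ref, atol=1e-12)

    def test_infinite_prior_df_is_z_statistic(self, rng):
        vals = rng.normal(size=(50, 8))
        em = two_group_matrix(vals, 4, 4)
        fit = moderated_t_test(em, prior_df=np.inf, prior_var=1.0)
        lfc = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
        z = lfc / np.sqrt(1.0 * (0.25 + 0.25))
        np.testing.assert_allclose(fit.table["t"], z, atol=1e-12)
        np.testing.assert_allclose(
            fit.table["p"], 2 * stats.norm.sf(np.abs(z)), atol=1e-12
        )

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same matrix
        reproduces the prior (d0, s0^2), moderated t and p to ~1e-10."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        sd = np.sqrt(0.25 * rng.chisquare(6, 200) / 6)
        vals = rng.normal(8, 1, 200)[:, None] + rng.normal(
            size=(200, 8)
        ) * sd[:, None]
        vals[:30, :4] += 1.5
        em = two_group_matrix(vals, 4, 4)
        expr = tmp_path / "expr.tsv"
        em.values.to_csv(expr, sep="\t")
        script = tmp_path / "run.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{expr}', row.names=1))\n"
            "design <- cbind(Intercept=1, Case=c(rep(1,4), rep(0,4)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(t=fit$t[,'Case'], p=fit$p.value[,'Case'],"
            " d0=fit$df.prior, s02=fit$s2.prior)\n"
            f"write.table(out, '{tmp_path / 'ref.tsv'}', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        fit = moderated_t_test(em)
        np.testing.assert_allclose(fit.prior_df, ref["d0"].iloc[0], rtol=1e-8)
        np.testing.assert_allclose(fit.prior_var, ref["s02"].iloc[0], rtol=1e-8)
        np.testing.assert_allclose(fit.table["t"], ref["t"], atol=1e-10)
        np.testing.assert_allclose(fit.table["p"], ref["p"], atol=1e-10)

    def test_zero_variance_everywhere_falls_back(self):
        em = two_group_matrix([[1.0, 1, 2, 2], [3.0, 3, 3, 3]], 2, 2)
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            fit = moderated_t_test(em)
        assert fit.fallback_unmoderated
        # no spread, nonzero difference: overwhelming evidence
        assert fit.table.loc["g0", "p"] == 0.0
        # no spread, no difference: no evidence
        assert fit.table.loc["g1", "p"] == 1.0

    def test_requires_two_samples_per_group(self, rng):
        em = two_group_matrix(rng.normal(size=(3, 3)), 1, 2)
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(em)


class TestScreen:
    def test_planted_de_features_recovered(self):
        """Recovery property: at effect size 2.0, noise SD 0.5 and 10 vs 10
        samples with 20% DE prevalence, the screen finds >=95% of planted
        features with <=5% false discoveries, pooled over 20 simulations."""
        from cernet import SimulationConfig, generate_cohort

        tp = fp = planted = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_lnc=10, n_mir=10, n_mrna=500, frac_de=0.2, n_triples=0,
                effect_size=2.0, noise_sd=0.5, n_case=10, n_control=10,
                seed=seed,
            )
            mats, truth = generate_cohort(cfg)
            got = {
                r.feature
                for r in screen_de(moderated_t_test(mats["mRNA"]), "mRNA")
            }
            true_de = set(truth.de_by_class("mRNA"))
            tp += len(got & true_de)
            fp += len(got - true_de)
            planted += len(true_de)
        assert tp / planted >= 0.95
        assert fp / (tp + fp) <= 0.05

    def test_basic_retention_and_direction(self):
        fit = _fit_from_values([1.0, -1.0, 0.1], [0.01, 0.01, 0.001])
        recs = screen_de(fit, "mRNA")
        assert [(r.feature, r.direction) for r in recs] == [
            ("g0", "up"), ("g1", "down")
        ]

    def test_boundaries_are_strict(self):
        fit = _fit_from_values([0.585, 0.6, 0.6], [0.001, 0.05, 0.049])
        recs = screen_de(fit, "mRNA")
        assert [r.feature for r in recs] == ["g2"]

    def test_fold_change_formulation_is_equivalent(self, rng):
        """|log2FC| > 0.585 retains the same features as a brute-force
        fold-change recomputation with FC beyond 1.5x either way.

        2^0.585 = 1.50004; draws are taken at two-decimal precision so no
        value can land inside that 4e-5-wide rounding window.
        """
        lfc = np.round(rng.uniform(-3, 3, 5000), 2)
        p = rng.uniform(0, 0.1, 5000)
        recs = screen_de(_fit_from_values(lfc, p), "mRNA")
        fc = 2.0**lfc
        oracle = {
            f"g{i}"
            for i in range(5000)
            if (fc[i] > 1.5 or fc[i] < 1 / 1.5) and p[i] < 0.05
        }
        assert {r.feature for r in recs} == oracle

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-4, 4, allow_nan=False),
                st.floats(0.0001, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=40,
        ),
        p1=st.floats(0.001, 0.2),
        p2=st.floats(0.001, 0.2),
        l1=st.floats(0.1, 2),
        l2=st.floats(0.1, 2),
    )
    def test_screen_is_monotone_in_thresholds(self, data, p1, p2, l1, l2):
        """A stricter threshold pair never admits a new feature."""
        lfc, p = zip(*data)
        fit = _fit_from_values(list(lfc), list(p))
        loose = {
            r.feature
            for r in screen_de(fit, "mRNA", max(p1, p2), min(l1, l2))
        }
        strict = {
            r.feature
            for r in screen_de(fit, "mRNA", min(p1, p2), max(l1, l2))
        }
        assert strict <= loose


def _rec(f, d, p=0.01, cls="lncRNA"):
    return DERecord(f, cls, 1.0 if d == "up" else -1.0, p, d)


class TestCombineIntersect:
    def test_disjoint_sets_concatenate(self):
        a = [_rec("f1", "up"), _rec("f2", "down")]
        b = [_rec("f3", "up")]
        combined, conflicts = combine_de(a, b)
        assert [r.feature for r in combined] == ["f1", "f2", "f3"]
        assert conflicts == []

    def test_idempotent_on_identical_sets(self):
        a = [_rec("f1", "up"), _rec("f2", "down")]
        combined, _ = combine_de(a, list(a))
        assert combined == sorted(a, key=lambda r: r.feature)

    def test_conflicts_excluded_and_reported(self):
        a = [_rec("f1", "up", 0.01)]
        b = [_rec("f1", "down", 0.02), _rec("f2", "up")]
        combined, conflicts = combine_de(a, b)
        assert [r.feature for r in combined] == ["f2"]
        assert conflicts == [("f1", "down/up")]

    def test_smaller_p_wins(self):
        a = [_rec("f1", "up", 0.04)]
        b = [_rec("f1", "up", 0.002)]
        combined, _ = combine_de(a, b)
        assert combined[0].p == 0.002

    def test_mixed_classes_rejected(self):
        with pytest.raises(ValueError, match="mixed feature classes"):
            combine_de([_rec("f1", "up")], [_rec("f2", "up", cls="mRNA")])

    def test_random_sets_match_dictionary_oracle(self, rng):
        for _ in range(30):
            sets = []
            for _ in range(3):
                feats = rng.choice(40, size=rng.integers(5, 20), replace=False)
                sets.append(
                    [
                        _rec(
                            f"f{f}",
                            "up" if rng.random() < 0.5 else "down",
                            float(rng.uniform(0.001, 0.05)),
                        )
                        for f in feats
                    ]
                )
            combined, conflicts = combine_de(*sets)
            # brute-force dictionary oracle
            dirs, best = {}, {}
            for s in sets:
                for r in s:
                    dirs.setdefault(r.feature, set()).add(r.direction)
                    if r.feature not in best or r.p < best[r.feature].p:
                        best[r.feature] = r
            confl = {f for f, d in dirs.items() if len(d) > 1}
            assert {r.feature for r in combined} == set(best) - confl
            assert {f for f, _ in conflicts} == confl
            for r in combined:
                assert r.p == best[r.feature].p

    def test_intersect_identity_disjoint_and_oracle(self, rng):
        a = [_rec("f1", "up"), _rec("f2", "down")]
        assert intersect_de(a, a) == sorted(a, key=lambda r: r.feature)
        assert intersect_de(a, [_rec("f9", "up")]) == []
        mismatched = [_rec("f1", "down"), _rec("f2", "down")]
        assert [r.feature for r in intersect_de(a, mismatched)] == ["f2"]
        for _ in range(20):
            fa = rng.choice(30, size=15, replace=False)
            fb = rng.choice(30, size=15, replace=False)
            da = {f: "up" if rng.random() < 0.5 else "down" for f in fa}
            db = {f: "up" if rng.random() < 0.5 else "down" for f in fb}
            a = [_rec(f"f{f}", d) for f, d in da.items()]
            b = [_rec(f"f{f}", d) for f, d in db.items()]
            expect = sorted(
                f"f{f}" for f in set(fa) & set(fb) if da[f] == db[f]
            )
            assert [r.feature for r in intersect_de(a, b)] == expect
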