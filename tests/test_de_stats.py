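import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cocultureq.de_stats import (
    DEConfig,
    bh_adjust,
    call_deps,
    impute_perseus,
    moderated_ttest,
    prepare_matrix,
    run_de,
)
from cocultureq.lfqratio import QuantMatrix
from cocultureq.quant_io import ExperimentalDesign


def make_design(n_per=3, conditions=("c1", "c2")):
    rows = [
        (f"{c}_{i}", c, i) for c in conditions for i in range(1, n_per + 1)
    ]
    return ExperimentalDesign(
        df=pd.DataFrame(rows, columns=["label", "condition", "replicate"])
    )


def make_qm(values: np.ndarray, design: ExperimentalDesign, kind="log2"):
    df = pd.DataFrame(values, columns=design.labels)
    idx = df.index
    return QuantMatrix(
        values=df,
        strain=pd.Series("strainA", index=idx),
        accession=pd.Series([f"P{i}" for i in idx], index=idx),
        value_kind=kind,
    )


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Quadratic oracle: adj_i = min over p_(j) >= p_i of m*p_(j)/rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(pos, m)
        ]
        adj[order[pos]] = min(1.0, min(candidates))
    return adj


class TestPrepareMatrix:
    def _raw(self, arr, design):
        return make_qm(arr, design, kind="raw_lfq")

    def test_log2_transform(self):
        design = make_design(2)
        qm = self._raw(np.full((1, 4), 0.25), design)
        out = prepare_matrix(qm, design)
        assert (out.values.to_numpy() == -2.0).all()

    def test_consistency_rule_keeps_one_full_condition(self):
        design = make_design(2)
        arr = np.array(
            [
                [1.0, 2.0, np.nan, np.nan],  # (2, 0): kept
                [1.0, np.nan, 2.0, np.nan],  # (1, 1): dropped
            ]
        )
        out = prepare_matrix(self._raw(arr, design), design)
        assert len(out.values) == 1

    def test_single_sample_condition_is_error(self):
        design = ExperimentalDesign(
            df=pd.DataFrame(
                {
                    "label": ["a1", "a2", "b1"],
                    "condition": ["c1", "c1", "c2"],
                    "replicate": [1, 2, 1],
                }
            )
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            prepare_matrix(self._raw(np.ones((2, 3)), design), design)

    def test_design_sample_mismatch_is_error(self):
        design = make_design(2)
        qm = self._raw(np.ones((2, 4)), design)
        bad = make_design(3)
        with pytest.raises(ValueError, match="absent"):
            prepare_matrix(qm, bad)


class TestImputePerseus:
    def test_downshift_and_width_moments(self):
        rng = np.random.default_rng(42)
        design = make_design(1, conditions=("c",))
        n_obs, n_missing = 5000, 100_000
        observed = rng.normal(25, 2, size=n_obs)
        col = np.concatenate([observed, np.full(n_missing, np.nan)])
        qm = make_qm(col[:, None], design)
        out = impute_perseus(qm, seed=99)
        imputed = out.values.iloc[n_obs:, 0].to_numpy()
        mu, sd = observed.mean(), observed.std(ddof=1)
        downshift = (mu - imputed.mean()) / sd
        assert downshift == pytest.approx(1.8, abs=0.02)
        assert imputed.std(ddof=1) / sd == pytest.approx(0.3, abs=0.01)

    def test_observed_cells_untouched_and_seed_determinism(self):
        rng = np.random.default_rng(0)
        design = make_design(3)
        arr = rng.normal(25, 2, size=(50, 6))
        arr[rng.random(arr.shape) < 0.2] = np.nan
        qm = make_qm(arr, design)
        out1 = impute_perseus(qm, seed=5)
        out2 = impute_perseus(qm, seed=5)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        mask = ~np.isnan(arr)
        np.testing.assert_array_equal(
            out1.values.to_numpy()[mask], arr[mask]
        )
        out3 = impute_perseus(qm, seed=6)
        assert not out3.values.equals(out1.values)

    def test_sparse_column_falls_back_to_matrix_stats(self):
        design = make_design(2)
        arr = np.array(
            [
                [25.0, 24.0, np.nan, 26.0],
                [24.5, 23.0, np.nan, 24.0],
                [26.0, 22.0, 1.0, 25.0],
            ]
        )
        qm = make_qm(arr, design)
        with pytest.warns(UserWarning, match="matrix-wide"):
            impute_perseus(qm, seed=1)


class TestModeratedTTest:
    def test_zero_prior_df_reproduces_ordinary_pooled_t(self, rng):
        design = make_design(3)
        arr = rng.normal(20, 1, size=(200, 6))
        qm = make_qm(arr, design)
        res = moderated_ttest(qm, design, ("c1", "c2"), prior_df=0)
        t_ref, p_ref = stats.ttest_ind(
            arr[:, 3:], arr[:, :3], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res.table["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(res.table["p_value"], p_ref, rtol=1e-12)

    def test_posterior_variance_between_prior_and_sample(self, rng):
        design = make_design(3)
        sds = rng.lognormal(0, 0.5, size=300)
        arr = rng.normal(0, sds[:, None], size=(300, 6))
        qm = make_qm(arr, design)
        res = moderated_ttest(qm, design, ("c1", "c2"))
        s2 = res.table["s2"].to_numpy()
        s2_post = res.table["s2_posterior"].to_numpy()
        lo = np.minimum(s2, res.s2_prior)
        hi = np.maximum(s2, res.s2_prior)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(7)
        design = make_design(3)
        arr = rng.normal(25, 1, size=(5000, 6))
        qm = make_qm(arr, design)
        res = moderated_ttest(qm, design, ("c1", "c2"))
        frac = (res.table["p_value"] <= 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Cross-check t, p and hyperparameters against limma via Rscript."""
        import subprocess

        rng = np.random.default_rng(3)
        design = make_design(3)
        sds = rng.lognormal(-1, 0.6, size=120)
        arr = rng.normal(0, sds[:, None], size=(120, 6))
        arr[:10, 3:] += 1.0
        qm = make_qm(arr, design)
        res = moderated_ttest(qm, design, ("c1", "c2"))

        mat_path = tmp_path / "mat.csv"
        out_path = tmp_path / "limma.csv"
        pd.DataFrame(arr, columns=design.labels).to_csv(mat_path, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{mat_path}"))
            design <- cbind(Intercept=1, c2=rep(c(0,1), each=3))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(lfc=fit$coefficients[,2], t=fit$t[,2],
                              p=fit$p.value[,2], df_prior=fit$df.prior,
                              s2_prior=fit$s2.prior)
            write.csv(out, "{out_path}", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_path)
        np.testing.assert_allclose(res.table["log2_fc"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-5)
        np.testing.assert_allclose(res.table["p_value"], ref["p"], rtol=1e-5)
        assert res.df_prior == pytest.approx(ref["df_prior"].iloc[0], rel=1e-3)
        assert res.s2_prior == pytest.approx(ref["s2_prior"].iloc[0], rel=1e-3)

    def test_all_zero_variance_is_error(self):
        design = make_design(3)
        qm = make_qm(np.ones((5, 6)), design)
        with pytest.raises(ValueError, match="degenerate"):
            moderated_ttest(qm, design, ("c1", "c2"))


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "p,expected", [([0.3], [0.3]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])]
    )
    def test_degenerate_inputs(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_against_brute_force_and_statsmodels(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 50)))
            adj = bh_adjust(p)
            np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)
        p = rng.random(500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(
        p=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_permutation_equivariance(self, p, seed):
        p = np.array(p)
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCallDeps:
    def _result(self, lfc, adj_p):
        from cocultureq.de_stats import DEResult

        n = len(lfc)
        table = pd.DataFrame(
            {
                "accession": [f"P{i}" for i in range(n)],
                "strain": "s",
                "log2_fc": lfc,
                "t": 1.0,
                "p_value": adj_p,  # single test: BH leaves p unchanged per rank
            }
        )
        return DEResult(table=table, contrast=("c1", "c2"))

    def test_double_cutoff_and_direction(self):
        res = call_deps(self._result([1.5, 0.5, -2.0], [0.001, 0.001, 0.001]))
        t = res.table
        assert t["significant"].tolist() == [True, False, True]
        assert t["direction"].tolist() == ["up", "ns", "down"]

    def test_boundary_values_are_inclusive(self):
        res = call_deps(self._result([1.0], [0.05]))
        assert res.table["significant"].iloc[0]

    def test_volcano_table_columns(self):
        res = call_deps(self._result([1.0, 2.0], [0.01, 0.2]))
        v = res.volcano_table()
        assert set(v.columns) >= {
            "accession", "log2_fc", "neg_log10_p", "adj_p_value", "significant",
        }


class TestRunDe:
    def test_scale_invariance_without_missingness(self, rng):
        design = make_design(3)
        arr = 2.0 ** rng.normal(25, 2, size=(100, 6))
        cfg = DEConfig(imputation="none")
        r1 = run_de(make_qm(arr, design, "raw_lfq"), design, ("c1", "c2"), cfg)
        r2 = run_de(make_qm(arr * 7.3, design, "raw_lfq"), design, ("c1", "c2"), cfg)
        np.testing.assert_allclose(r1.table["log2_fc"], r2.table["log2_fc"], atol=1e-9)
        np.testing.assert_allclose(r1.table["t"], r2.table["t"], rtol=1e-7)
        np.testing.assert_allclose(r1.table["p_value"], r2.table["p_value"], rtol=1e-7)

    def test_complete_data_is_seed_independent(self, rng):
        design = make_design(3)
        arr = 2.0 ** rng.normal(25, 2, size=(50, 6))
        r1 = run_de(make_qm(arr, design, "raw_lfq"), design, ("c1", "c2"),
                    DEConfig(seed=1))
        r2 = run_de(make_qm(arr, design, "raw_lfq"), design, ("c1", "c2"),
                    DEConfig(seed=99))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_planted_effect_recovery(self):
        rng = np.random.default_rng(11)
        design = make_design(3)
        n, n_de = 1000, 50
        base = rng.uniform(20, 33, size=n)
        arr = base[:, None] + rng.normal(0, 0.3, size=(n, 6))
        signs = rng.choice([-1.0, 1.0], size=n_de)
        arr[:n_de, 3:] += 2.0 * signs[:, None]
        qm = make_qm(2.0 ** arr, design, kind="raw_lfq")
        res = run_de(qm, design, ("c1", "c2"), DEConfig(seed=0))
        called = res.table["significant"].to_numpy()
        recall = called[:n_de].mean()
        fdp = called[n_de:].sum() / max(1, called.sum())
        assert recall >= 0.9
        assert fdp <= 0.1
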