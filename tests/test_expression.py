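import subprocess

import numpy as np
import pandas as pd
import pytest

import crossmode as cm
from crossmode.categories import InheritanceCategory as C


class TestCountMatrixIO:
    def test_read_matches_toy_file(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t3\ng2\t5\t0\n")
        mat = cm.read_counts(path)
        assert mat.shape == (2, 2)
        assert mat.counts.loc["g1", "s2"] == 3
        assert mat.library_sizes.tolist() == [6, 3]

    def test_write_read_round_trip(self, toy_matrix, tmp_path):
        path = tmp_path / "c.tsv"
        cm.write_counts(toy_matrix, path)
        assert cm.read_counts(path) == toy_matrix

    def test_negative_count_names_gene_and_sample(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t3\ng2\t-5\t0\n")
        with pytest.raises(cm.FormatError, match="g2.*s1"):
            cm.read_counts(path)

    def test_non_integer_and_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts1\ng1\t1.5\n")
        with pytest.raises(cm.FormatError, match="non-integer"):
            cm.read_counts(path)
        path.write_text("gene_id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(cm.FormatError, match="duplicate gene"):
            cm.read_counts(path)
        path.write_text("gene_id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(cm.FormatError, match="duplicate sample"):
            cm.read_counts(path)


class TestCpm:
    def test_arithmetic_identity(self):
        mat = cm.CountMatrix(pd.DataFrame({"s1": [1, 3]}, index=["a", "b"]))
        assert cm.cpm(mat)["s1"].tolist() == [250000.0, 750000.0]

    def test_columns_sum_to_one_million(self, toy_matrix):
        sums = cm.cpm(toy_matrix).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_factors_with_bad_geometric_mean_rejected(self, toy_matrix):
        factors = pd.Series(2.0, index=toy_matrix.sample_ids)
        with pytest.raises(cm.ConfigError, match="geometric mean"):
            cm.cpm(toy_matrix, factors)


class TestLowExpressionFilter:
    def test_all_zero_gene_removed(self, toy_matrix):
        kept = cm.filter_low_expression(toy_matrix, 0.5, 1)
        assert "g3" in toy_matrix.gene_ids  # g3 has tiny counts
        assert set(kept.gene_ids) <= set(toy_matrix.gene_ids)
        zero = cm.CountMatrix(
            pd.DataFrame({"s1": [0, 5], "s2": [0, 5]}, index=["dead", "live"])
        )
        assert cm.filter_low_expression(zero, 0.5, 1).gene_ids.tolist() == ["live"]

    def test_threshold_zero_keeps_any_expressed_gene(self, toy_matrix):
        kept = cm.filter_low_expression(toy_matrix, 0.0, 1)
        assert len(kept.gene_ids) == 5

    def test_survivor_set_matches_brute_force(self, toy_matrix):
        threshold, min_samples = 0.5, 2
        # brute force: evaluate CPM per cell directly from the definition
        libs = toy_matrix.counts.sum(axis=0)
        survivors = [
            g
            for g in toy_matrix.gene_ids
            if sum(
                toy_matrix.counts.loc[g, s] / libs[s] * 1e6 >= threshold
                for s in toy_matrix.sample_ids
            )
            >= min_samples
        ]
        kept = cm.filter_low_expression(toy_matrix, threshold, min_samples)
        assert kept.gene_ids.tolist() == survivors

    def test_idempotent(self, toy_matrix):
        once = cm.filter_low_expression(toy_matrix, 30.0, 2)
        twice = cm.filter_low_expression(once, 30.0, 2)
        assert once == twice

    def test_min_samples_exceeding_sample_count_rejected(self, toy_matrix):
        with pytest.raises(cm.ConfigError):
            cm.filter_low_expression(toy_matrix, 0.5, 99)


def _tmm_reference(counts, ref_idx, m_trim=0.3, a_trim=0.05):
    """Step-by-step trimmed weighted-mean reference implementation."""
    from scipy.stats import rankdata

    libs = counts.sum(axis=0)
    log_f = []
    for j in range(counts.shape[1]):
        y, r = counts[:, j].astype(float), counts[:, ref_idx].astype(float)
        keep = (y > 0) & (r > 0)
        y, r = y[keep], r[keep]
        py, pr = y / libs[j], r / libs[ref_idx]
        m, a = np.log2(py / pr), 0.5 * np.log2(py * pr)
        w = (libs[j] - y) / (libs[j] * y) + (libs[ref_idx] - r) / (libs[ref_idx] * r)
        if np.max(np.abs(m)) < 1e-6:
            log_f.append(0.0)
            continue
        n = m.size
        lo_m, lo_a = np.floor(n * m_trim) + 1, np.floor(n * a_trim) + 1
        keep2 = (
            (rankdata(m) >= lo_m)
            & (rankdata(m) <= n + 1 - lo_m)
            & (rankdata(a) >= lo_a)
            & (rankdata(a) <= n + 1 - lo_a)
        )
        log_f.append(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))
    log_f = np.array(log_f)
    return 2.0 ** (log_f - log_f.mean())


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 200, 3, 47, 99])
        mat = cm.CountMatrix(
            pd.DataFrame({f"s{i}": col for i in range(4)}, index=list("abcde"))
        )
        assert np.allclose(cm.tmm_factors(mat), 1.0)

    def test_invariant_to_global_library_scaling(self):
        rng = np.random.default_rng(0)
        col = rng.negative_binomial(5, 0.01, size=300) + 1
        base = np.tile(col[:, None], (1, 4))
        scaled = base.copy()
        scaled[:, 2] *= 5  # composition unchanged, library depth x5
        genes = [f"g{i}" for i in range(300)]
        mat = cm.CountMatrix(pd.DataFrame(scaled, index=genes))
        factors = cm.tmm_factors(mat)
        assert np.allclose(factors, 1.0, atol=1e-6)
        # downstream CPM of the scaled sample matches the unscaled one
        cpms = cm.cpm(mat, factors)
        unscaled = cm.cpm(cm.CountMatrix(pd.DataFrame(base, index=genes)))
        assert np.allclose(cpms.iloc[:, 2], unscaled.iloc[:, 2], rtol=1e-9)

    def test_matches_step_by_step_reference(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(5, 0.02, size=(200, 4))
        counts[rng.random(size=counts.shape) < 0.1] = 0
        counts = counts * rng.integers(1, 4, size=(1, 4))
        mat = cm.CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(200)]))
        libs = counts.sum(axis=0)
        f75 = np.quantile(counts / libs, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        expected = _tmm_reference(counts, ref_idx)
        assert np.allclose(cm.tmm_factors(mat), expected, rtol=1e-12)

    def test_matches_edger_cross_check(self, tmp_path):
        # independent oracle: edgeR's calcNormFactors on the same matrix
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(5, 0.02, size=(200, 4))
        counts[rng.random(size=counts.shape) < 0.1] = 0
        counts = counts * rng.integers(1, 4, size=(1, 4))
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(200)], columns=list("ABCD"))
        path = tmp_path / "c.tsv"
        df.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.10f", calcNormFactors(x, method="TMM")), sep="\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
        edger = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(cm.tmm_factors(cm.CountMatrix(df)), edger, atol=1e-8)

    def test_disjoint_support_sample_rejected(self):
        mat = cm.CountMatrix(
            pd.DataFrame({"s1": [5, 5, 0, 0], "s2": [0, 0, 7, 7]}, index=list("abcd"))
        )
        with pytest.raises(cm.AnalysisError):
            cm.tmm_factors(mat, reference="s1")


class TestLogCpm:
    def test_finite_at_zero_counts(self, toy_matrix):
        vals = cm.log_cpm(toy_matrix)
        assert np.isfinite(vals.to_numpy()).all()

    def test_invariant_to_count_and_library_doubling(self, toy_matrix):
        doubled = cm.CountMatrix(toy_matrix.counts * 2)
        assert np.allclose(cm.log_cpm(toy_matrix), cm.log_cpm(doubled))

    def test_matches_hand_calculation(self):
        mat = cm.CountMatrix(
            pd.DataFrame({"s1": [3, 7]}, index=["a", "b"]),
            library_sizes=pd.Series({"s1": 1_000_000}),
        )
        # one-million library: the prior is exactly 0.5 counts
        expected = np.log2((np.array([3, 7]) + 0.5) / (1e6 + 1.0) * 1e6)
        assert np.allclose(cm.log_cpm(mat)["s1"], expected)

    def test_non_positive_prior_rejected(self, toy_matrix):
        with pytest.raises(cm.ConfigError):
            cm.log_cpm(toy_matrix, prior_count=0.0)


class TestBatchCenter:
    @staticmethod
    def design_for(samples, batches, groups):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "tissue": "liver",
                "group": groups,
                "sex": "M",
                "replicate": 1,
                "batch": batches,
            }
        )

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(2)
        logmat = pd.DataFrame(rng.normal(size=(10, 4)), columns=[f"s{i}" for i in range(4)])
        design = self.design_for(logmat.columns, ["b1"] * 4, [1, 1, 4, 4])
        assert np.allclose(cm.batch_center(logmat, design, preserve=("group",)), logmat)

    def test_balanced_additive_shift_removed_exactly(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 8))
        effect = np.repeat([1.0, 0.0], 4)  # group 1 higher than group 4
        shift = np.tile([0.0, 2.5], 4)  # batch alternates within groups
        logmat = pd.DataFrame(
            base + np.outer(np.ones(20), effect) + np.outer(np.ones(20), shift),
            columns=[f"s{i}" for i in range(8)],
        )
        design = self.design_for(
            logmat.columns, ["b1", "b2"] * 4, [1, 1, 1, 1, 4, 4, 4, 4]
        )
        centered = cm.batch_center(logmat, design, preserve=("group",))
        expected = pd.DataFrame(
            base + np.outer(np.ones(20), effect), columns=logmat.columns
        )
        # batch shift removed up to a constant; group contrasts preserved
        contrast = centered.iloc[:, :4].mean(axis=1) - centered.iloc[:, 4:].mean(axis=1)
        expected_contrast = expected.iloc[:, :4].mean(axis=1) - expected.iloc[:, 4:].mean(axis=1)
        assert np.allclose(contrast, expected_contrast, atol=1e-9)
        within_batch_var = centered.T.groupby(design.set_index("sample_id")["batch"]).mean()
        assert np.allclose(within_batch_var.iloc[0], within_batch_var.iloc[1], atol=1e-9)

    def test_unbalanced_case_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        logmat = pd.DataFrame(rng.normal(size=(15, 6)), columns=[f"s{i}" for i in range(6)])
        design = self.design_for(
            logmat.columns, ["b1", "b1", "b1", "b1", "b2", "b2"], [1, 1, 4, 4, 1, 4]
        )
        centered = cm.batch_center(logmat, design, preserve=("group",))
        # oracle: explicit least squares with intercept + group dummy +
        # sum-coded batch, subtracting the fitted batch component
        g = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        b = np.array([1, 1, 1, 1, -1, -1], dtype=float)
        x = np.column_stack([np.ones(6), g, b])
        beta = np.linalg.solve(x.T @ x, x.T @ logmat.to_numpy().T)
        expected = logmat.to_numpy() - np.outer(beta[2], b)
        assert np.allclose(centered.to_numpy(), expected, atol=1e-9)

    def test_confounded_batch_warns_and_noops(self):
        rng = np.random.default_rng(6)
        logmat = pd.DataFrame(rng.normal(size=(5, 4)), columns=[f"s{i}" for i in range(4)])
        design = self.design_for(logmat.columns, ["b1", "b1", "b2", "b2"], [1, 1, 4, 4])
        with pytest.warns(UserWarning, match="confounded"):
            centered = cm.batch_center(logmat, design, preserve=("group",))
        assert np.allclose(centered, logmat)


class TestGroupMeansAndTopExpressed:
    def test_single_sample_cells_return_their_values(self):
        design = cm.make_design(tissues=["liver"], sexes=["M"], replicates=1)
        rng = np.random.default_rng(7)
        logmat = pd.DataFrame(
            rng.normal(size=(6, 4)), columns=design["sample_id"], index=[f"g{i}" for i in range(6)]
        )
        prof = cm.group_means(logmat, design)
        for g in (1, 2, 3, 4):
            sample = design.loc[design["group"] == g, "sample_id"].iloc[0]
            assert np.allclose(prof[f"m{g}"], logmat[sample])

    def test_replicated_identical_samples_give_common_value(self, liver_design):
        logmat = pd.DataFrame(
            np.tile([[1.0], [2.0]], (1, 24)), columns=liver_design["sample_id"], index=["a", "b"]
        )
        prof = cm.group_means(logmat, liver_design)
        assert np.allclose(prof[["m1", "m2", "m3", "m4"]], [[1, 1, 1, 1], [2, 2, 2, 2]])

    def test_hand_averaged_toy_values(self):
        design = cm.make_design(tissues=["liver"], sexes=["M"], replicates=2)
        cols = design["sample_id"]
        vals = np.arange(8, dtype=float)[np.newaxis, :]
        logmat = pd.DataFrame(vals, columns=cols, index=["g"])
        prof = cm.group_means(logmat, design)
        assert prof.loc[0, ["m1", "m2", "m3", "m4"]].tolist() == [0.5, 2.5, 4.5, 6.5]

    def test_empty_cell_reported(self, liver_design):
        design = liver_design[liver_design["group"] != 3]
        logmat = pd.DataFrame(
            np.zeros((2, len(design))), columns=design["sample_id"], index=["a", "b"]
        )
        with pytest.raises(cm.AnalysisError, match="group=3"):
            cm.group_means(logmat, design)

    def test_top_expressed_ranking_and_tissue_specific_flag(self):
        design = cm.make_design(tissues=["liver", "lung"], sexes=["M"], replicates=1)
        rng = np.random.default_rng(8)
        logmat = pd.DataFrame(
            rng.uniform(0, 5, size=(30, len(design))),
            columns=design["sample_id"],
            index=[f"g{i:02d}" for i in range(30)],
        )
        logmat.loc["g05", design.loc[design["tissue"] == "liver", "sample_id"]] = 12.0
        rankings, specific = cm.top_expressed(logmat, design, n=10)
        assert rankings["liver"].iloc[0]["gene_id"] == "g05"
        # sort oracle: descending mean, gene id as tie-break
        liver_means = logmat[design.loc[design["tissue"] == "liver", "sample_id"]].mean(axis=1)
        oracle = sorted(liver_means.index, key=lambda g: (-liver_means[g], g))[:10]
        assert rankings["liver"]["gene_id"].tolist() == oracle
        assert specific["gene_id"].tolist() == ["g05"]
        assert specific["tissue"].tolist() == ["liver"]

    def test_top_expressed_n_larger_than_gene_count_gives_full_ranking(self):
        design = cm.make_design(tissues=["liver"], sexes=["M"], replicates=1)
        logmat = pd.DataFrame(
            np.ones((3, 4)), columns=design["sample_id"], index=["a", "b", "c"]
        )
        rankings, _ = cm.top_expressed(logmat, design, n=99)
        assert len(rankings["liver"]) == 3


class TestMds:
    def test_identical_samples_coincide(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=600)
        logmat = pd.DataFrame(
            {"s1": col, "s2": col, "s3": col + rng.normal(size=600)},
        )
        coords = cm.mds_coordinates(logmat, k=2)
        assert np.allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-9)

    def test_euclidean_embeddable_distances_reproduced(self):
        # 3 points in the plane; with top >= n_genes the pairwise distance
        # equals Euclidean distance / sqrt(n_genes), which classical
        # scaling must reproduce exactly
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        logmat = pd.DataFrame(pts.T, columns=["a", "b", "c"])
        coords = cm.mds_coordinates(logmat, k=2, top=2).to_numpy()
        got = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        want = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2) / np.sqrt(2)
        assert np.allclose(got, want, atol=1e-9)

    def test_degenerate_input_warns_and_returns_zeros(self):
        logmat = pd.DataFrame(np.ones((50, 4)), columns=list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            coords = cm.mds_coordinates(logmat, k=2)
        assert np.allclose(coords, 0.0)

    def test_separates_tissues_on_synthetic_study_data(self):
        from sklearn.metrics import silhouette_score

        design = cm.make_design(tissues=["brain", "liver", "lung"], replicates=2)
        cfg = cm.SimulationConfig(n_genes=300, seed=17)
        truth = cm.assign_gene_truth(cfg)
        mat = cm.filter_low_expression(cm.simulate_counts(design, truth, cfg))
        coords = cm.mds_coordinates(cm.log_cpm(mat, cm.tmm_factors(mat)))
        labels = design.set_index("sample_id").loc[coords.index, "tissue"]
        assert silhouette_score(coords.to_numpy(), labels) > 0
        # between-tissue distances exceed within-tissue distances
        d = np.linalg.norm(
            coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :], axis=2
        )
        same = (labels.to_numpy()[:, None] == labels.to_numpy()[None, :]) & ~np.eye(
            len(labels), dtype=bool
        )
        diff = ~(labels.to_numpy()[:, None] == labels.to_numpy()[None, :])
        assert d[diff].mean() > d[same].mean()
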