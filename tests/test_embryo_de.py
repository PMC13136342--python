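import numpy as np
import pandas as pd
import pytest

from tdrprof.embryo_de import (
    ExpressionMatrix,
    de_test,
    filter_expressed,
    group_cdf_analysis,
    resolve_groups,
    tpm_normalize,
)


def _counts_matrix(values, genes=None, n_a=3, n_b=3):
    genes = genes or [f"g{i}" for i in range(len(values))]
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    condition = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ExpressionMatrix(values=df, condition=condition, unit="counts")


class TestTpmNormalize:
    def test_equal_counts_equal_lengths_split_evenly(self):
        mat = _counts_matrix([[10] * 6, [10] * 6])
        tpm = tpm_normalize(mat, {"g0": 1000, "g1": 1000})
        assert np.allclose(tpm.values.to_numpy(), 5e5)

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(20, 6))
        lengths = dict(zip([f"g{i}" for i in range(20)], rng.integers(300, 3000, 20)))
        t1 = tpm_normalize(_counts_matrix(base), lengths)
        t2 = tpm_normalize(_counts_matrix(base * 3), lengths)
        assert np.allclose(t1.values.to_numpy(), t2.values.to_numpy())

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(1)
        mat = _counts_matrix(rng.integers(0, 100, size=(50, 6)))
        tpm = tpm_normalize(mat, {f"g{i}": 1000 + i for i in range(50)})
        assert np.allclose(tpm.values.sum(axis=0), 1e6)

    def test_missing_length_is_an_error(self):
        with pytest.raises(ValueError, match="without a length"):
            tpm_normalize(_counts_matrix([[1] * 6, [1] * 6]), {"g0": 100})


class TestMatrixInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _counts_matrix([[-1] * 6])

    def test_tpm_unit_enforces_column_sums(self):
        df = pd.DataFrame([[5.0] * 4], index=["g0"], columns=list("abcd"))
        with pytest.raises(ValueError, match="sum to 1e6"):
            ExpressionMatrix(
                values=df, condition=dict.fromkeys("abcd", "A"), unit="TPM"
            )

    def test_unlabeled_sample_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="without condition"):
            ExpressionMatrix(values=df, condition={"s1": "A"}, unit="counts")


class TestFilterExpressed:
    def _tpm(self, seed=0, n_genes=40):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n_genes, 6))
        counts[0] = 0  # an all-zero gene
        return tpm_normalize(
            _counts_matrix(counts), {f"g{i}": 1000 for i in range(n_genes)}
        )

    def test_all_zero_gene_removed(self):
        out = filter_expressed(self._tpm(), min_mean_tpm=1.0)
        assert "g0" not in out.values.index
        assert "expression_filter" in out.meta

    def test_threshold_zero_keeps_everything_detected(self):
        tpm = self._tpm()
        out = filter_expressed(tpm, min_mean_tpm=0.0)
        assert len(out.values) == len(tpm.values)

    def test_monotone_in_threshold(self):
        tpm = self._tpm(seed=3)
        kept = [
            len(filter_expressed(tpm, min_mean_tpm=thr).values)
            for thr in (0.0, 1.0, 100.0, 10000.0)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_everything_filtered_is_an_error(self):
        with pytest.raises(ValueError, match="every gene"):
            filter_expressed(self._tpm(), min_mean_tpm=1e9)


class TestDeTest:
    def _tpm_from(self, a_block, b_block, genes=None):
        values = np.hstack([a_block, b_block])
        mat = _counts_matrix(values, genes=genes, n_a=a_block.shape[1], n_b=b_block.shape[1])
        lengths = {g: 1000 for g in mat.values.index}
        return tpm_normalize(mat, lengths)

    def test_pure_fold_change_without_pseudocount(self):
        # two genes so TPM normalization keeps a free ratio: g0 at 100 vs 400
        a = np.array([[100.0] * 3, [900.0] * 3])
        b = np.array([[400.0] * 3, [600.0] * 3])
        tpm = self._tpm_from(a, b)
        de = de_test(tpm, "A", "B", pseudocount=0.0)
        assert de.loc["g0", "log2fc"] == pytest.approx(2.0)

    def test_identical_groups_not_called(self):
        rng = np.random.default_rng(2)
        block = rng.uniform(50, 150, size=(30, 4))
        tpm = self._tpm_from(block, block.copy())
        de = de_test(tpm, "A", "B")
        assert (de["log2fc"] == 0).all()
        assert (de["call"] == "ns").all()

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(10, 1000, size=(25, 5))
        b = a * rng.uniform(0.2, 5.0, size=(25, 1))
        tpm = self._tpm_from(a, b)
        fwd = de_test(tpm, "A", "B")
        rev = de_test(tpm, "B", "A")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        flipped = rev["call"].map({"up": "down", "down": "up", "ns": "ns"})
        assert (fwd["call"] == flipped).all()

    def test_single_shifted_gene_is_the_only_call(self):
        rng = np.random.default_rng(6)
        n, reps = 60, 10
        base = rng.uniform(100, 500, size=(n, 1))
        noise = lambda: rng.normal(1.0, 0.05, size=(n, reps))  # CV 5%
        a = base * noise()
        b = base * noise()
        b[7] *= 4.0  # one gene shifted 4-fold
        tpm = self._tpm_from(a, b)
        de = de_test(tpm, "A", "B")
        assert de.loc["g7", "call"] == "up"
        assert (de["call"] != "ns").sum() == 1

    def test_fewer_than_two_replicates_rejected(self):
        a = np.full((5, 1), 100.0)
        b = np.full((5, 3), 100.0)
        tpm = self._tpm_from(a, b)
        with pytest.raises(ValueError, match="2 replicates"):
            de_test(tpm, "A", "B")


class TestResolveGroups:
    def test_stem_matching_semantics(self):
        names = ["hsp-16.2", "hsp-70", "hsph-1", "rpl-3", "rps-0", "fbxb-55"]
        groups = {g.name: g.members for g in resolve_groups(
            names,
            prefix_rules={"hsp": "hsp", "ribosomal": "rpl"},
        )}
        assert groups["hsp"] == ["hsp-16.2", "hsp-70"]  # hsph-1 excluded
        assert groups["ribosomal"] == ["rpl-3"]

    def test_explicit_list_intersected_with_expressed(self):
        groups = resolve_groups(
            ["his-1", "his-2", "other-1"],
            explicit_lists={"histone": ["his-1", "his-2", "his-99"]},
        )
        assert groups[0].members == ["his-1", "his-2"]

    def test_empty_rules_give_empty_output(self):
        assert resolve_groups(["a-1"], prefix_rules={}, explicit_lists={}) == []


class TestGroupCdf:
    def _de_frame(self, fc_by_gene):
        return pd.DataFrame(
            {"log2fc": pd.Series(fc_by_gene)}, index=list(fc_by_gene)
        ).rename_axis("gene_id")

    def test_matched_distribution_gives_small_d(self):
        rng = np.random.default_rng(8)
        fc = {f"g{i}": v for i, v in enumerate(rng.normal(0, 0.3, 400))}
        from tdrprof.embryo_de import GeneGroup

        report = group_cdf_analysis(
            self._de_frame(fc), [GeneGroup("null", [f"g{i}" for i in range(40)])]
        )
        assert report.loc[0, "ks_p"] > 0.01

    def test_shifted_group_detected_with_direction(self):
        rng = np.random.default_rng(9)
        fc = {f"g{i}": v for i, v in enumerate(rng.normal(0, 0.3, 400))}
        for i in range(30):
            fc[f"g{i}"] -= 1.0
        from tdrprof.embryo_de import GeneGroup

        report = group_cdf_analysis(
            self._de_frame(fc), [GeneGroup("down", [f"g{i}" for i in range(30)])]
        )
        row = report.iloc[0]
        assert row["median_shift"] < -0.5
        assert row["ks_p"] < 1e-6
        assert row["direction"] == "down"

    def test_group_of_all_genes_is_an_error(self):
        from tdrprof.embryo_de import GeneGroup

        frame = self._de_frame({"g0": 0.1, "g1": -0.2, "g2": 0.0})
        with pytest.raises(ValueError, match="no background"):
            group_cdf_analysis(frame, [GeneGroup("all", ["g0", "g1", "g2"])])

    def test_tiny_group_skipped_with_warning(self):
        from tdrprof.embryo_de import GeneGroup

        frame = self._de_frame({"g0": 0.1, "g1": -0.2, "g2": 0.0})
        with pytest.warns(UserWarning, match="skipped"):
            report = group_cdf_analysis(frame, [GeneGroup("tiny", ["g0"])])
        assert report.empty
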