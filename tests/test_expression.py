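import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from txresponse.expression import (
    AnnotatedCounts,
    ValidationError,
    paired_log2fc,
    read_counts,
    remove_batch,
    tmm_normalize,
)

from conftest import make_annotation, plain_matrix


class TestReadCounts:
    def _write(self, tmp_path, counts_text, ann_text):
        c = tmp_path / "counts.tsv"
        a = tmp_path / "ann.tsv"
        c.write_text(textwrap.dedent(counts_text))
        a.write_text(textwrap.dedent(ann_text))
        return c, a

    def test_parses_small_matrix_with_full_annotation(self, tmp_path):
        c, a = self._write(
            tmp_path,
            "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n",
            "sample_id\tpatient_id\ttherapy\ttimepoint\tresponse\tbatch\n"
            "s1\tp1\tICI\tPT\tR\tb1\ns2\tp1\tICI\tOT\tR\tb1\n",
        )
        data = read_counts(c, a)
        assert data.counts.shape == (3, 2)
        assert list(data.sample_ids) == ["s1", "s2"]

    def test_missing_annotation_names_the_sample(self, tmp_path):
        c, a = self._write(
            tmp_path,
            "gene_id\ts1\ts2\ng1\t1\t2\n",
            "sample_id\tpatient_id\ttherapy\ttimepoint\tresponse\tbatch\n"
            "s1\tp1\tICI\tPT\tR\tb1\n",
        )
        with pytest.raises(ValidationError, match="s2"):
            read_counts(c, a)

    def test_negative_count_names_gene_and_sample(self, tmp_path):
        c, a = self._write(
            tmp_path,
            "gene_id\ts1\ng1\t5\ng2\t-1\n",
            "sample_id\tpatient_id\ttherapy\ttimepoint\tresponse\tbatch\n"
            "s1\tp1\tICI\tPT\tR\tb1\n",
        )
        with pytest.raises(ValidationError, match="g2.*s1"):
            read_counts(c, a)

    def test_duplicate_gene_ids_rejected(self):
        ann = make_annotation([("s1", "p", "ICI", "PT", "R", "b"),
                               ("s2", "p", "ICI", "OT", "R", "b")])
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g1"], columns=ann.index)
        with pytest.raises(ValidationError, match="duplicate gene"):
            AnnotatedCounts(counts=counts, annotation=ann)


def _two_sample_counts(col_a, col_b):
    ann = make_annotation([("A", "p1", "ICI", "PT", "R", "b"),
                           ("B", "p1", "ICI", "OT", "R", "b")])
    counts = pd.DataFrame({"A": col_a, "B": col_b},
                          index=[f"g{i}" for i in range(len(col_a))])
    return AnnotatedCounts(counts=counts, annotation=ann)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 51)
        norm = tmm_normalize(_two_sample_counts(col, col.copy()))
        assert np.allclose(norm.tmm_factors, 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        col = np.arange(1, 51)
        norm = tmm_normalize(_two_sample_counts(col, 2 * col))
        assert np.allclose(norm.tmm_factors, 1.0)

    def test_factor_matches_brute_force_trimmed_mean_formula(self):
        # one gene carries half of sample B's reads
        rng = np.random.default_rng(0)
        a = rng.integers(5, 500, size=50)
        b = rng.integers(5, 500, size=50)
        b[0] = b[1:].sum()
        data = _two_sample_counts(a, b)
        norm = tmm_normalize(data, reference="A")

        # independent re-implementation, straight from the formula
        na, nb = a.sum(), b.sum()
        m = np.log2((b / nb) / (a / na))
        av = 0.5 * np.log2((b / nb) * (a / na))
        v = (nb - b) / (nb * b) + (na - a) / (na * a)
        n = len(m)
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        keep = (
            (rankdata(m) >= lo_m) & (rankdata(m) <= n + 1 - lo_m)
            & (rankdata(av) >= lo_a) & (rankdata(av) <= n + 1 - lo_a)
        )
        f_b = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected = np.array([1.0, f_b])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(norm.tmm_factors.to_numpy(), expected, atol=1e-12)

    def test_matches_edger_reference_implementation(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(200, 4)),
            index=[f"g{i}" for i in range(200)], columns=list("ABCD"),
        )
        counts.iloc[0, 1] = counts["B"].sum()
        ann = make_annotation([(s, f"p{s}", "ICI", "PT", "R", "b") for s in "ABCD"])
        norm = tmm_normalize(AnnotatedCounts(counts=counts, annotation=ann))
        counts.to_csv(tmp_path / "c.tsv", sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{tmp_path / "c.tsv"}", row.names=1));'
            'cat(sprintf("%.12f ", calcNormFactors(x, method="TMM")))'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True, timeout=120)
        expected = np.array([float(t) for t in res.stdout.split()])
        assert np.allclose(norm.tmm_factors.to_numpy(), expected, atol=1e-8)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            tmm_normalize(_two_sample_counts(np.arange(1, 11), np.zeros(10, dtype=int)))

    def test_single_sample_rejected(self):
        ann = make_annotation([("A", "p1", "ICI", "PT", "R", "b")])
        counts = pd.DataFrame({"A": [1, 2, 3]}, index=["g0", "g1", "g2"])
        with pytest.raises(ValidationError, match="2 samples"):
            tmm_normalize(AnnotatedCounts(counts=counts, annotation=ann))

    def test_geometric_mean_of_factors_is_one(self, small_cohort):
        norm = tmm_normalize(small_cohort)
        assert np.isclose(np.exp(np.mean(np.log(norm.tmm_factors))), 1.0, atol=1e-9)

    @pytest.mark.parametrize("weighted,tol", [(False, 1e-9), (True, 0.02)])
    def test_depth_scaling_leaves_factor_stable(self, weighted, tol):
        # unweighted: exact; weighted: the inverse-variance weights shift by 1/k
        rng = np.random.default_rng(7)
        a = rng.integers(10, 1000, size=100)
        b = rng.integers(10, 1000, size=100)
        f1 = tmm_normalize(_two_sample_counts(a, b), weighted=weighted,
                           reference="A").tmm_factors["B"]
        f2 = tmm_normalize(_two_sample_counts(a, 3 * b), weighted=weighted,
                           reference="A").tmm_factors["B"]
        assert abs(np.log2(f1) - np.log2(f2)) < tol

    def test_log_cpm_formula(self):
        data = _two_sample_counts(np.array([100, 900]), np.array([300, 700]))
        norm = tmm_normalize(data, prior=1.0)
        expected = np.log2(
            1e6 * 100 / (1000 * norm.tmm_factors["A"]) + 1.0
        )
        assert np.isclose(norm.values.loc["g0", "A"], expected)


class TestRemoveBatch:
    def _norm(self, values):
        return plain_matrix(values)

    def test_additive_shift_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(20, 8))
        values = base.copy()
        values[:, 4:] += 3.0  # batch 2 = batch 1 + 3
        batch = ["b1"] * 4 + ["b2"] * 4
        group = ["g1", "g1", "g2", "g2"] * 2
        out = remove_batch(self._norm(values), batch, group).values.to_numpy()
        assert np.allclose(out[:, :4].mean(axis=1), out[:, 4:].mean(axis=1), atol=1e-9)

    def test_single_batch_is_identity(self):
        values = np.random.default_rng(1).normal(size=(5, 4))
        out = remove_batch(self._norm(values), ["b"] * 4, ["x", "x", "y", "y"])
        assert np.allclose(out.values.to_numpy(), values)

    def test_least_squares_oracle_on_planted_offsets(self):
        rng = np.random.default_rng(5)
        n_genes, n = 30, 12
        batch = np.array(["b1", "b2", "b3"] * 4)
        group = np.array(["g1"] * 6 + ["g2"] * 6)
        offsets = {"b1": 0.7, "b2": -1.1, "b3": 0.4}
        values = rng.normal(size=(n_genes, n))
        before = values.copy()
        for j in range(n):
            values[:, j] += offsets[batch[j]]
        out = remove_batch(self._norm(values), batch, group).values.to_numpy()
        # residual batch-mean differences vanish
        means = {b: out[:, batch == b].mean(axis=1) for b in offsets}
        assert np.allclose(means["b1"], means["b2"], atol=1e-8)
        assert np.allclose(means["b2"], means["b3"], atol=1e-8)
        # preserved-group contrast unchanged relative to the clean matrix
        for g in ("g1", "g2"):
            assert np.allclose(
                out[:, group == g].mean(axis=1),
                before[:, group == g].mean(axis=1)
                + np.mean([offsets[b] for b in batch[group == g]]),
                atol=1e-8,
            )

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(10, 8))
        values[:, ::2] += 2.0
        batch = ["b1", "b2"] * 4
        group = ["g1"] * 4 + ["g2"] * 4
        once = remove_batch(self._norm(values), batch, group)
        twice = remove_batch(once, batch, group)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9)

    def test_confounded_batch_rejected(self):
        values = np.zeros((3, 4))
        with pytest.raises(ValidationError, match="confounded"):
            remove_batch(self._norm(values), ["b1", "b1", "b2", "b2"],
                         ["g1", "g1", "g2", "g2"])


class TestPairedLog2FC:
    def _cohort(self, values, specs):
        ann = make_annotation(specs)
        counts = pd.DataFrame(
            np.ones((values.shape[0], len(ann)), dtype=int),
            index=[f"g{i}" for i in range(values.shape[0])], columns=ann.index,
        )
        data = AnnotatedCounts(counts=counts, annotation=ann)
        matrix = plain_matrix(values, samples=list(ann.index))
        return matrix, data

    def test_single_pair_subtraction(self):
        matrix, data = self._cohort(
            np.array([[3.0, 5.0]]),
            [("s_pt", "p1", "ICI", "PT", "R", "b"), ("s_ot", "p1", "ICI", "OT", "R", "b")],
        )
        fc = paired_log2fc(matrix, data)
        assert fc.log2fc.loc["g0", "s_ot"] == pytest.approx(2.0)

    def test_multiple_pt_samples_averaged(self):
        matrix, data = self._cohort(
            np.array([[3.0, 5.0, 6.0]]),
            [
                ("pt1", "p1", "ICI", "PT", "R", "b"),
                ("pt2", "p1", "ICI", "PT", "R", "b"),
                ("ot", "p1", "ICI", "OT", "R", "b"),
            ],
        )
        fc = paired_log2fc(matrix, data)
        assert fc.log2fc.loc["g0", "ot"] == pytest.approx(2.0)

    def test_full_cohort_matches_hand_computation(self):
        # 4 patients, 2 genes, values set by hand
        specs, cols = [], []
        values = {
            "p1": {"PT": [1.0, 2.0], "OT": [3.0, 1.0]},
            "p2": {"PT": [0.0, 0.0], "OT": [2.0, -1.0]},
            "p3": {"PT": [5.0, 5.0], "OT": [5.0, 8.0]},
            "p4": {"PT": [2.0, 4.0], "OT": [0.0, 4.0]},
        }
        for k, (p, tps) in enumerate(values.items()):
            therapy = "ICI" if k < 2 else "MAPKi"
            response = "R" if k % 2 == 0 else "NR"
            for tp, v in tps.items():
                specs.append((f"{p}_{tp}", p, therapy, tp, response, "b"))
                cols.append(v)
        matrix, data = self._cohort(np.array(cols).T, specs)
        fc = paired_log2fc(matrix, data)
        expected = {
            "p1_OT": [2.0, -1.0], "p2_OT": [2.0, -1.0],
            "p3_OT": [0.0, 3.0], "p4_OT": [-2.0, 0.0],
        }
        for col, vals in expected.items():
            assert np.allclose(fc.log2fc[col], vals)
        assert fc.pairs.loc["p1_OT", "response"] == "R"
        assert fc.pairs.loc["p4_OT", "therapy"] == "MAPKi"

    def test_identical_pt_ot_gives_zero(self, small_cohort):
        values = np.tile(np.arange(5.0)[:, None], (1, len(small_cohort.sample_ids)))
        matrix = plain_matrix(values, samples=list(small_cohort.sample_ids))
        fc = paired_log2fc(matrix, small_cohort)
        assert np.allclose(fc.log2fc.to_numpy(), 0.0)

    def test_ot_without_pt_skipped_with_warning(self, caplog):
        matrix, data = self._cohort(
            np.array([[3.0, 5.0, 4.0]]),
            [
                ("s_pt", "p1", "ICI", "PT", "R", "b"),
                ("s_ot", "p1", "ICI", "OT", "R", "b"),
                ("lone_ot", "p2", "ICI", "OT", "R", "b"),
            ],
        )
        with caplog.at_level("WARNING"):
            fc = paired_log2fc(matrix, data)
        assert list(fc.log2fc.columns) == ["s_ot"]
        assert "lone_ot" in caplog.text
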