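"""Normalisation and the NB Wald test: algebraic oracles and planted effects."""

import numpy as np
import pandas as pd
import pytest

from lncnet.diffexpr import (
    DEOptions,
    filter_de,
    nb_wald_test,
    normalized_counts,
    rpkm,
    size_factors,
)
from lncnet.io import CountMatrix
from lncnet.synthdata import table2_fixture


def make_cm(counts, groups=None, biotype=None, lengths=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"G{i+1}" for i in range(counts.shape[0])]
    counts.columns = [f"S{j+1}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    if groups is None:
        groups = ["patient"] * (n // 2) + ["control"] * (n - n // 2)
    return CountMatrix(
        counts=counts.astype(np.int64),
        group=pd.Series(groups, index=counts.columns),
        biotype=pd.Series(biotype or ["mRNA"] * len(counts), index=counts.index),
        gene_length_bp=pd.Series(lengths or [1000] * len(counts), index=counts.index),
    )


class TestSizeFactors:
    def test_doubled_sample(self):
        # sample 2 = 2 x sample 1: median-of-ratios gives (1/sqrt2, sqrt2)
        cm = make_cm([[10, 20], [5, 10], [100, 200]])
        sf = size_factors(cm)
        assert sf.tolist() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_identical_samples_unit_factors(self):
        cm = make_cm([[7, 7, 7, 7], [3, 3, 3, 3]])
        assert size_factors(cm).tolist() == pytest.approx([1.0] * 4)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 200, size=(50, 4))
        scaled = base.copy()
        scaled[:, 2] *= 3
        a = size_factors(make_cm(base))
        b = size_factors(make_cm(scaled))
        # ratios between samples are preserved up to the global rescale
        np.testing.assert_allclose(
            (b / a).to_numpy() / (b / a).iloc[0], [1, 1, 3, 1], rtol=1e-12
        )

    def test_fallback_to_library_size(self, caplog):
        # every gene has a zero somewhere -> median-of-ratios undefined
        cm = make_cm([[0, 5], [4, 0]])
        with caplog.at_level("WARNING"):
            sf = size_factors(cm)
        assert any("library-size" in m for m in caplog.messages)
        np.testing.assert_allclose(np.exp(np.mean(np.log(sf))), 1.0)


class TestRPKM:
    def test_formula(self):
        cm = make_cm([[10, 10], [999_990, 999_990]], lengths=[1000, 10_000])
        # library size 1e6, length 1 kb -> RPKM = count
        assert rpkm(cm).loc["G1", "S1"] == pytest.approx(10.0)

    def test_zero_count_zero_rpkm(self):
        cm = make_cm([[0, 1], [10, 10]])
        assert rpkm(cm).loc["G1", "S1"] == 0.0

    def test_double_length_halves_rpkm(self):
        a = rpkm(make_cm([[10, 10], [5, 5]], lengths=[1000, 1000]))
        b = rpkm(make_cm([[10, 10], [5, 5]], lengths=[2000, 1000]))
        assert b.loc["G1", "S1"] == pytest.approx(a.loc["G1", "S1"] / 2)


class TestNBWald:
    def test_flat_gene_is_null(self):
        cm = make_cm([[50] * 10, [10, 20, 30, 12, 25, 11, 19, 31, 13, 24]])
        res = nb_wald_test(cm, sf=pd.Series(1.0, index=cm.sample_ids))
        assert res.loc["G1", "log2fc"] == 0.0
        assert res.loc["G1", "p"] == pytest.approx(1.0)

    def test_all_zero_gene_excluded_from_family(self):
        cm = make_cm([[0] * 10, [50] * 10, [10, 20, 30, 12, 25, 11, 19, 31, 13, 24]])
        res = nb_wald_test(cm)
        assert np.isnan(res.loc["G1", "p"]) and np.isnan(res.loc["G1", "adj_p"])
        assert not res.loc["G1", "significant"]
        # BH family excludes the zero gene: m = 2, smallest adj_p = min(p)*2/1 bound
        assert res.loc[["G2", "G3"], "adj_p"].notna().all()

    def test_group_swap_negates_log2fc(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 500, size=(30, 10))
        cm = make_cm(counts)
        swapped = make_cm(counts, groups=["control"] * 5 + ["patient"] * 5)
        a = nb_wald_test(cm)
        b = nb_wald_test(swapped)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)

    def test_planted_effect_power(self):
        # 200 replicate genes with true log2fc = 3 at base mean 100,
        # dispersion 0.1, 5 vs 5: detection sensitivity must reach 0.8
        rng = np.random.default_rng(42)
        n_rep, disp, base = 200, 0.1, 100.0
        mu = np.tile(base * 2.0 ** (3.0 * np.r_[np.ones(5), np.zeros(5)]), (n_rep, 1))
        size = 1.0 / disp
        planted = rng.negative_binomial(size, size / (size + mu))
        nulls = rng.negative_binomial(size, size / (size + np.full((300, 10), base)))
        cm = make_cm(np.vstack([planted, nulls]))
        res = nb_wald_test(cm)
        sensitivity = res.iloc[:n_rep]["significant"].mean()
        assert sensitivity >= 0.8

    def test_null_false_positive_fraction(self):
        # 1000 pure-NB null genes: fraction flagged at adj_p < 0.05 stays <= 0.10
        rng = np.random.default_rng(7)
        base = rng.lognormal(np.log(100), 1.0, size=1000)
        disp = np.maximum(rng.gamma(2.0, 0.05, size=1000), 0.01)
        size = 1.0 / disp[:, None]
        mu = np.broadcast_to(base[:, None], (1000, 10))
        counts = rng.negative_binomial(size, size / (size + mu))
        res = nb_wald_test(make_cm(counts))
        assert res["significant"].mean() <= 0.10

    def test_separate_vs_joint_bh_families(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 300, size=(40, 10))
        cm = make_cm(counts, biotype=["mRNA"] * 20 + ["lncRNA"] * 20)
        sep = nb_wald_test(cm, options=DEOptions(bh_family="separate"))
        joint = nb_wald_test(cm, options=DEOptions(bh_family="joint"))
        # same raw p-values, different adjustment families
        np.testing.assert_allclose(sep["p"], joint["p"])
        assert not np.allclose(sep["adj_p"], joint["adj_p"])

    def test_small_group_rejected(self):
        cm = make_cm([[1, 2, 3], [4, 5, 6]], groups=["patient", "control", "control"])
        with pytest.raises(ValueError, match="2 samples"):
            nb_wald_test(cm)


class TestFilterDE:
    def test_published_panel_survives_filter(self):
        # the six validation pairs: every |log2FC| > 1 and all downregulated
        tab = table2_fixture()
        res = pd.DataFrame(
            {
                "log2fc": tab["log2fc"].to_numpy(),
                "adj_p": 0.0,  # all reported as differentially expressed
            },
            index=tab["mrna_id"],
        )
        res["significant"] = (res["log2fc"].abs() > 1.0) & (res["adj_p"] < 0.05)
        res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
        up, down = filter_de(res)
        assert len(up) == 0 and len(down) == 6
        assert set(down) == set(tab["mrna_id"])

    def test_boundary_log2fc_excluded(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, 1.0001], "adj_p": [0.0, 0.0]}, index=["A", "B"]
        )
        res["significant"] = (res["log2fc"].abs() > 1.0) & (res["adj_p"] < 0.05)
        res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
        up, down = filter_de(res)
        assert up == ["B"]

    def test_empty_input(self):
        assert filter_de(pd.DataFrame()) == ([], [])


class TestAgainstDESeq2Style:
    def test_sign_and_call_agreement_with_pydeseq2(self):
        """Independent cross-check: strong planted effects get the same sign
        and significance call as a DESeq2-style analysis."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(10)
        n_de, n_null = 10, 60
        base = rng.lognormal(np.log(200), 0.5, size=n_de + n_null)
        lfc = np.r_[np.full(n_de, 3.0), np.zeros(n_null)]
        mu = base[:, None] * 2.0 ** (lfc[:, None] * np.r_[np.ones(5), np.zeros(5)])
        size = 10.0  # dispersion 0.1
        counts = rng.negative_binomial(size, size / (size + mu))
        cm = make_cm(counts)
        ours = nb_wald_test(cm)

        meta = pd.DataFrame({"condition": cm.group.to_numpy()}, index=cm.sample_ids)
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "patient", "control"], quiet=True)
        st.summary()
        ref = st.results_df

        planted = ours.index[:n_de]
        assert (np.sign(ours.loc[planted, "log2fc"]) == 1).all()
        assert (np.sign(ref.loc[planted, "log2FoldChange"]) == 1).all()
        # both pipelines call every strong planted gene significant
        assert ours.loc[planted, "significant"].all()
        assert (ref.loc[planted, "padj"] < 0.05).all()
        # fold-change estimates broadly agree on the planted genes
        np.testing.assert_allclose(
            ours.loc[planted, "log2fc"], ref.loc[planted, "log2FoldChange"], atol=0.75
        )


class TestNormalizedCounts:
    def test_division_by_size_factor(self):
        cm = make_cm([[10, 20], [30, 40]])
        q = normalized_counts(cm, pd.Series([2.0, 0.5], index=cm.sample_ids))
        assert q.loc["G1"].tolist() == [5.0, 40.0]
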