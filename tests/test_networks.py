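"""Coexpression and the cis/trans/ceRNA layers, plus the seed-match scanner."""

import numpy as np
import pandas as pd
import pytest

from lncnet.io import GeneAnnotation, GeneSetCollection
from lncnet.networks import (
    CoexpressionPair,
    ce_network,
    cis_network,
    coexpression_pairs,
    genomic_distance,
    seed_match_scan,
    trans_network,
)


def expr_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


def annotation(entries) -> GeneAnnotation:
    t = pd.DataFrame(
        entries, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    ).set_index("gene_id")
    return GeneAnnotation(table=t)


def pair(lnc, mrna, r=0.99, p=1e-6, n=10):
    return CoexpressionPair(lnc_id=lnc, mrna_id=mrna, r=r, p=p, n=n)


class TestCoexpression:
    def test_exact_linear_pair_retained(self):
        x = np.arange(1.0, 11.0)
        expr = expr_frame({"L1": x, "M1": 2 * x, "M2": np.r_[x[1:], 0.0]})
        got = coexpression_pairs(expr, ["L1"], ["M1", "M2"])
        assert [(p.lnc_id, p.mrna_id) for p in got] == [("L1", "M1")]
        assert got[0].r == pytest.approx(1.0)

    def test_both_thresholds_required(self):
        # n = 4: r = 0.95 gives p ~ 0.05 > 0.01, so the pair must be dropped
        # even though r clears the correlation threshold
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.2, 2.8, 4.4])
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.9
        got = coexpression_pairs(expr_frame({"L1": x, "M1": y}), ["L1"], ["M1"])
        assert got == []

    def test_constant_row_skipped_with_warning(self, caplog):
        x = np.arange(10.0)
        expr = expr_frame({"L1": np.full(10, 3.0), "M1": x})
        with caplog.at_level("WARNING"):
            got = coexpression_pairs(expr, ["L1"], ["M1"])
        assert got == []
        assert any("constant" in m for m in caplog.messages)

    def test_null_pairs_rarely_retained(self):
        # 1000 independent pairs at n = 10: the p < 0.01 threshold keeps the
        # retained fraction near or below 1%
        rng = np.random.default_rng(123)
        n_pairs = 1000
        lnc = {f"L{i}": rng.normal(size=10) for i in range(n_pairs)}
        mrna = {f"M{i}": rng.normal(size=10) for i in range(n_pairs)}
        expr = expr_frame({**lnc, **mrna})
        kept = 0
        for i in range(n_pairs):
            kept += bool(
                coexpression_pairs(expr, [f"L{i}"], [f"M{i}"])
            )
        se = np.sqrt(0.01 * 0.99 / n_pairs)
        assert kept / n_pairs <= 0.01 + 3 * se


class TestGenomicDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 1000), ("chr1", 500, 1500), 0),  # overlap
            (("chr1", 0, 1000), ("chr1", 51_000, 52_000), 50_000),  # gap
            (("chr1", 51_000, 52_000), ("chr1", 0, 1000), 50_000),  # symmetric
            (("chr1", 0, 1000), ("chr1", 1000, 2000), 0),  # abutting
            (("chr1", 0, 1000), ("chr2", 0, 1000), None),  # incomparable
        ],
    )
    def test_gap_arithmetic(self, a, b, expected):
        assert genomic_distance(a, b) == expected


class TestCisNetwork:
    ANN = annotation(
        [
            ("L1", "chr1", 0, 1000, "+", "lncRNA"),
            ("M_near", "chr1", 90_000, 91_000, "+", "mRNA"),  # gap 89 kb
            ("M_far", "chr1", 151_000, 152_000, "+", "mRNA"),  # gap 150 kb
            ("M_other", "chr2", 0, 1000, "+", "mRNA"),
            ("M_edge", "chr1", 101_000, 102_000, "+", "mRNA"),  # gap exactly 100 kb
        ]
    )

    def test_window_rule(self):
        pairs = [pair("L1", m) for m in ("M_near", "M_far", "M_other", "M_edge")]
        got = cis_network(pairs, self.ANN, window_bp=100_000)
        assert {(c.lnc_id, c.mrna_id, c.distance_bp) for c in got} == {
            ("L1", "M_near", 89_000),
            ("L1", "M_edge", 100_000),  # inclusive boundary
        }

    def test_missing_annotation_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            got = cis_network([pair("L1", "M_unknown")], self.ANN)
        assert got == []
        assert any("no annotation" in m for m in caplog.messages)


class TestTransNetwork:
    def test_toy_overlap_significant(self):
        # N=20, K=8, n=5, k=5: p = C(8,5)/C(20,5) = 56/15504
        universe = {f"M{i}" for i in range(20)}
        targets = {f"M{i}" for i in range(8)}
        pairs = [pair("L1", f"M{i}") for i in range(5)]
        gsc = GeneSetCollection(sets={"TF_A": targets})
        got = trans_network(pairs, gsc, universe)
        assert len(got) == 1
        t = got[0]
        assert (t.N, t.K, t.n, t.k) == (20, 8, 5, 5)
        assert t.p == pytest.approx(56 / 15504, rel=1e-12)
        assert set(t.mrna_ids) == {f"M{i}" for i in range(5)}

    def test_zero_overlap_never_retained(self):
        universe = {f"M{i}" for i in range(20)}
        gsc = GeneSetCollection(sets={"TF_A": {f"M{i}" for i in range(10, 18)}})
        pairs = [pair("L1", f"M{i}") for i in range(5)]
        got = trans_network(pairs, gsc, universe)
        assert got == []

    def test_empty_category_skipped(self):
        universe = {"M1", "M2"}
        gsc = GeneSetCollection(sets={"TF_A": {"X1", "X2"}})  # disjoint from universe
        got = trans_network([pair("L1", "M1")], gsc, universe)
        assert got == []

    def test_empty_universe_rejected(self):
        gsc = GeneSetCollection(sets={"TF_A": {"M1"}})
        with pytest.raises(ValueError, match="universe"):
            trans_network([pair("L1", "M1")], gsc, set())


class TestCeNetwork:
    MT = pd.DataFrame(
        {
            "mirna_id": ["miR-X", "miR-X", "miR-Y"],
            "gene_id": ["L1", "M1", "M1"],
            "gene_class": ["lncRNA", "mRNA", "mRNA"],
        }
    )

    def test_shared_mirna_triple(self):
        got = ce_network([pair("L1", "M1", r=0.95)], self.MT)
        assert [(t.lnc_id, t.mirna_id, t.mrna_id) for t in got] == [("L1", "miR-X", "M1")]

    def test_negative_pair_excluded_by_default(self):
        assert ce_network([pair("L1", "M1", r=-0.95)], self.MT) == []

    def test_negative_pair_included_when_sign_rule_lifted(self):
        got = ce_network([pair("L1", "M1", r=-0.95)], self.MT, positive_only=False)
        assert len(got) == 1

    def test_no_shared_mirna_no_triple(self):
        assert ce_network([pair("L2", "M1", r=0.95)], self.MT) == []


def brute_force_sites(mirna, target):
    """Naive oracle: literal substring search for each site string with the
    strongest-class precedence at a shared core position."""
    m = mirna.upper().replace("U", "T")
    t = target.upper().replace("U", "T")
    comp = str.maketrans("ACGT", "TGCA")
    core = m[1:7].translate(comp)[::-1]
    m8 = m[7].translate(comp)
    found = []
    for i in range(len(t) - 5):
        if t[i : i + 6] != core:
            continue
        has_m8 = i > 0 and t[i - 1] == m8
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            found.append(("8mer", i - 1, i + 7))
        elif has_m8:
            found.append(("7mer-m8", i - 1, i + 6))
        elif has_a1:
            found.append(("7mer-A1", i, i + 7))
        else:
            found.append(("6mer", i, i + 6))
    return found


class TestSeedMatchScan:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # let-7 family sequence

    def test_constructed_8mer(self):
        # reverse complement of positions 2-8, followed by A opposite position 1
        comp = str.maketrans("ACGT", "TGCA")
        m = self.MIRNA.replace("U", "T")
        site = m[1:8].translate(comp)[::-1] + "A"
        target = "CCCC" + site + "CCCC"
        got = seed_match_scan(self.MIRNA, target)
        assert [(s.kind, s.start, s.end) for s in got] == [("8mer", 4, 12)]

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(99)
        target = "".join(rng.choice(list("ACGT"), size=1000))
        got = [(s.kind, s.start, s.end) for s in seed_match_scan(self.MIRNA, target)]
        assert got == brute_force_sites(self.MIRNA, target)

    def test_u_t_equivalence_and_case(self):
        comp = str.maketrans("ACGT", "TGCA")
        m = self.MIRNA.replace("U", "T")
        site = m[1:7].translate(comp)[::-1]
        upper = seed_match_scan(self.MIRNA, "gg" + site + "gg")
        as_rna = seed_match_scan(self.MIRNA, ("gg" + site + "gg").replace("T", "u"))
        assert upper == as_rna and len(upper) == 1

    def test_empty_target(self):
        assert seed_match_scan(self.MIRNA, "") == []

    def test_alphabet_violation(self):
        with pytest.raises(ValueError, match="characters"):
            seed_match_scan(self.MIRNA, "ACGTNNN")

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            seed_match_scan("ACGUACG", "ACGT")
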