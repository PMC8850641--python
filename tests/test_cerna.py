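"""Correlation filters, sponge test, triad assembly, network export."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.cerna import (
    CeRNANetwork,
    ConstantVectorError,
    build_cerna_network,
    coexpressed_pairs,
    export_network,
    negative_pairs,
    parse_sif,
    pearson,
    spearman,
    sponge_test,
    sponge_universe,
)
from cernet.models import CorrelationPair


def spearman_oracle_no_ties(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free vectors."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n**2 - 1))


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    return cov / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())


class TestSpearman:
    def test_anti_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 7, 3, 1]) == pytest.approx(-1.0)

    def test_hand_case(self):
        # d^2 sum = 2, n = 3 -> 1 - 12/24 = 0.5
        assert spearman([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.permutation(10).astype(float)
            y = rng.permutation(10).astype(float)
            assert spearman(x, y) == pytest.approx(spearman_oracle_no_ties(x, y))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base)
        assert spearman(x, 3 * y + 7) == pytest.approx(base)
        assert spearman(x**3, np.exp(y)) == pytest.approx(base)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantVectorError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestPearson:
    def test_affine_identity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)

    def test_reflection(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_closed_form_case(self):
        x, y = [1, 2, 3, 4], [1, 2, 4, 3]
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y))
        assert pearson(x, y) == pytest.approx(0.8)

    def test_random_vs_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pearson(x, y) == pytest.approx(pearson_oracle(x, y))


def _expr(rows, features, samples=6):
    cols = [f"s{i}" for i in range(samples)]
    return pd.DataFrame(np.asarray(rows, float), index=features, columns=cols)


class TestNegativePairs:
    def test_boundary_strict(self):
        x = np.arange(6.0)
        # construct y with spearman exactly -0.7 impossible at n=6; use a
        # threshold equal to an achievable value instead
        y = np.array([5.0, 4, 3, 2, 0, 1])  # one adjacent swap: rho = -0.943
        rho = spearman(x, y)
        mirna = _expr([x], ["m"])
        target = _expr([y], ["t"])
        assert negative_pairs(mirna, target, [("m", "t")], rho_threshold=rho) == []
        kept = negative_pairs(mirna, target, [("m", "t")], rho_threshold=rho + 1e-9)
        assert [(p.id_a, p.id_b) for p in kept] == [("m", "t")]

    def test_missing_feature_named(self):
        e = _expr([np.arange(6.0)], ["m"])
        with pytest.raises(KeyError, match="ghost"):
            negative_pairs(e, e.rename(index={"m": "x"}), [("m", "ghost")])

    def test_constant_vector_skipped(self, caplog):
        mirna = _expr([[1, 1, 1, 1, 1, 1]], ["m"])
        target = _expr([np.arange(6.0)], ["t"])
        assert negative_pairs(mirna, target, [("m", "t")]) == []

    def test_mismatched_samples(self):
        a = _expr([np.arange(6.0)], ["m"])
        b = _expr([np.arange(4.0)], ["t"], samples=4)
        with pytest.raises(ValueError, match="sample columns"):
            negative_pairs(a, b, [("m", "t")])

    def test_independent_pair_retained_at_null_rate(self):
        # a decoy pair (sites but independent expression) survives the
        # Spearman filter with probability equal to the exact permutation
        # null tail P(rho < -0.7 | n = 6)
        from itertools import permutations

        n = 6
        null_tail = np.mean(
            [
                spearman_oracle_no_ties(np.arange(n), np.array(p)) < -0.7
                for p in permutations(range(n))
            ]
        )
        rng = np.random.default_rng(47)
        draws = 4000
        r = 1 / 0.02
        mu = 200.0
        x = rng.negative_binomial(r, r / (r + mu), size=(draws, n)).astype(float)
        y = rng.negative_binomial(r, r / (r + mu), size=(draws, n)).astype(float)
        retained = sum(spearman(x[i], y[i]) < -0.7 for i in range(draws))
        rate = retained / draws
        se = np.sqrt(null_tail * (1 - null_tail) / draws)
        assert abs(rate - null_tail) < 4 * se, (rate, null_tail)


class TestCoexpressedPairs:
    def test_boundary_strict(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        lnc = _expr([x], ["L"])
        mrna = _expr([2 * x], ["G"])
        r = pearson(x, 2 * x)  # exactly 1.0
        assert coexpressed_pairs(lnc, mrna, r_threshold=r) == []
        kept = coexpressed_pairs(lnc, mrna, r_threshold=0.9)
        assert [(p.id_a, p.id_b) for p in kept] == [("L", "G")]

    def test_counts_match_bruteforce_20x20(self):
        rng = np.random.default_rng(31)
        lnc = _expr(rng.normal(size=(20, 6)), [f"L{i}" for i in range(20)])
        mrna = _expr(rng.normal(size=(20, 6)), [f"G{i}" for i in range(20)])
        kept = coexpressed_pairs(lnc, mrna, r_threshold=0.5)
        brute = sum(
            1
            for i in range(20)
            for j in range(20)
            if pearson_oracle(lnc.iloc[i], mrna.iloc[j]) > 0.5
        )
        assert len(kept) == brute


class TestSpongeTest:
    def test_k_zero(self):
        assert sponge_test({"a"}, {"b"}, 10) == 1.0

    def test_degenerate_certainty(self):
        u = {f"m{i}" for i in range(5)}
        assert sponge_test(u, u, 5) == pytest.approx(1.0)

    def test_example_n20(self):
        lnc = {f"m{i}" for i in range(5)}
        mrna = {f"m{i}" for i in range(2, 8)}  # overlap m2,m3,m4 -> k=3
        expected = sum(
            math.comb(5, j) * math.comb(15, 6 - j) for j in range(3, 6)
        ) / math.comb(20, 6)
        assert sponge_test(lnc, mrna, 20) == pytest.approx(expected, abs=1e-14)

    def test_universe_too_small(self):
        with pytest.raises(ValueError, match="universe"):
            sponge_test({"a", "b", "c"}, {"a"}, 2)


def _neg(mir, target, rho=-0.9):
    return CorrelationPair(mir, target, "spearman", rho, 6)


def _co(lnc, mrna, r=0.95):
    return CorrelationPair(lnc, mrna, "pearson", r, 6)


class TestBuildNetwork:
    def test_no_shared_mirna_excluded(self):
        net = build_cerna_network(
            [_neg("m1", "L")], [_neg("m2", "G")], [_co("L", "G")], universe=set("abcdefghijklmnopqrst")
        )
        assert net.triads == []

    def test_shared_mirna_triad_emitted(self):
        universe = {f"m{i}" for i in range(25)}
        neg_l = [_neg(f"m{i}", "L") for i in range(3)]
        neg_g = [_neg(f"m{i}", "G") for i in range(3)]
        net = build_cerna_network(neg_l, neg_g, [_co("L", "G")], universe=universe)
        assert len(net.triads) == 1
        t = net.triads[0]
        assert t.shared_mirna_ids == ("m0", "m1", "m2")
        assert (t.k, t.K, t.n, t.N) == (3, 3, 3, 25)
        expected = sum(
            math.comb(3, j) * math.comb(22, 3 - j) for j in range(3, 4)
        ) / math.comb(25, 3)
        assert t.p_value == pytest.approx(expected)
        assert ("L", "lncRNA-miRNA", "m0") in net.edges
        assert ("m0", "miRNA-mRNA", "G") in net.edges

    def test_p_threshold_strict(self):
        universe = {"m0", "m1"}
        neg_l = [_neg("m0", "L")]
        neg_g = [_neg("m0", "G")]
        # k=K=n=1, N=2 -> p = 0.5
        net = build_cerna_network(neg_l, neg_g, [_co("L", "G")], universe=universe, p_threshold=0.5)
        assert net.triads == []
        net = build_cerna_network(neg_l, neg_g, [_co("L", "G")], universe=universe, p_threshold=0.51)
        assert len(net.triads) == 1

    def test_default_universe(self):
        pairs = [_neg("m0", "L"), _neg("m1", "G"), _neg("m0", "G")]
        assert sponge_universe(pairs) == {"m0", "m1"}

    def test_empty_universe_error(self):
        with pytest.raises(ValueError, match="universe"):
            build_cerna_network([], [], [_co("L", "G")], universe=set())


class TestExportNetwork:
    def _network(self):
        universe = {f"m{i}" for i in range(25)}
        neg_l = [_neg(f"m{i}", "L") for i in range(3)]
        neg_g = [_neg(f"m{i}", "G") for i in range(3)]
        return build_cerna_network(neg_l, neg_g, [_co("L", "G")], universe=universe)

    def test_sif_round_trip(self, tmp_path):
        net = self._network()
        attrs = {"L": {"type": "lncRNA", "de": "up"}, "G": {"type": "mRNA", "de": "up"}}
        paths = export_network(net.triads, net.edges, attrs, tmp_path)
        assert parse_sif(paths["sif"]) == net.edges

    def test_sif_lines_exact(self, tmp_path):
        triads = self._network().triads
        edges = [("L1", "lncRNA-miRNA", "M1"), ("M1", "miRNA-mRNA", "G1")]
        paths = export_network(triads, edges, {}, tmp_path)
        lines = paths["sif"].read_text().splitlines()
        assert lines == ["L1\tlncRNA-miRNA\tM1", "M1\tmiRNA-mRNA\tG1"]

    def test_node_table_rows(self, tmp_path):
        net = self._network()
        paths = export_network(net.triads, net.edges, {}, tmp_path)
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        expected = {e[0] for e in net.edges} | {e[2] for e in net.edges}
        assert len(nodes) == len(expected)

    def test_empty_network_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            export_network([], [], {}, tmp_path)

    def test_triad_table_columns(self, tmp_path):
        net = self._network()
        paths = export_network(net.triads, net.edges, {}, tmp_path)
        df = pd.read_csv(paths["triads"], sep="\t")
        assert list(df.columns) == [
            "lncrna_id", "mrna_id", "shared_mirnas", "k", "K", "n", "N", "p_value",
        ]
        assert len(df) == 1


def test_network_dataclass_defaults():
    net = CeRNANetwork()
    assert net.triads == [] and net.edges == []
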