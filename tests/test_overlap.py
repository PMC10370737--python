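"""Overlap statistics: hypergeometric law, Jaccard, diseasome graph."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comolink import (
    SignificantGeneSet,
    build_diseasome,
    hypergeom_overlap,
    jaccard,
    shared_gene_overlap,
)
from comolink.overlap import decimal_from_log, read_graph, write_graph


def exact_log_pmf(k, N, M, s):
    """Big-integer oracle: log of C(M,k)C(N-M,s-k)/C(N,s)."""
    num = math.comb(M, k) * math.comb(N - M, s - k)
    if num == 0:
        return -math.inf
    return math.log(num) - math.log(math.comb(N, s))


class TestSharedGeneOverlap:
    def test_disjoint_sets(self):
        a = SignificantGeneSet("a", frozenset({"X"}), frozenset({"Y"}))
        b = SignificantGeneSet("b", frozenset({"Z"}), frozenset({"W"}))
        assert shared_gene_overlap(a, b).n_shared == 0

    def test_direction_stratification(self):
        a = SignificantGeneSet("a", frozenset({"X", "Y"}), frozenset({"Z"}))
        b = SignificantGeneSet("b", frozenset({"Y"}), frozenset({"Z", "W"}))
        s = shared_gene_overlap(a, b)
        assert s.shared_up == {"Y"}
        assert s.shared_down == {"Z"}
        assert s.discordant == frozenset()
        assert s.n_shared == 2

    def test_discordant_counts_toward_total(self):
        a = SignificantGeneSet("a", frozenset({"X"}), frozenset())
        b = SignificantGeneSet("b", frozenset(), frozenset({"X"}))
        s = shared_gene_overlap(a, b)
        assert s.discordant == {"X"} and s.n_shared == 1


class TestHypergeom:
    def test_matches_exact_combinatorics_on_sample(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            N = int(rng.integers(1, 61))
            M = int(rng.integers(0, N + 1))
            s = int(rng.integers(0, N + 1))
            lo, hi = max(0, M + s - N), min(M, s)
            k = int(rng.integers(lo, hi + 1))
            r = hypergeom_overlap(N, M, s, k)
            assert r.log_pmf == pytest.approx(exact_log_pmf(k, N, M, s), abs=1e-10)

    def test_simple_exact_value(self):
        r = hypergeom_overlap(10, 4, 5, 2)
        assert r.pmf == pytest.approx(120 / 252, rel=1e-12)

    def test_draw_everything_degenerate(self):
        r = hypergeom_overlap(12, 7, 12, 7)
        assert r.pmf == pytest.approx(1.0)
        assert hypergeom_overlap(12, 7, 12, 6).pmf == 0.0

    def test_moments_closed_form(self):
        r = hypergeom_overlap(55528, 1517, 2368, 162)
        assert r.mean == pytest.approx(2368 * 1517 / 55528, rel=1e-12)
        N, M, s = 55528, 1517, 2368
        assert r.variance == pytest.approx(
            s * M * (N - M) * (N - s) / (N**2 * (N - 1)), rel=1e-12
        )

    def test_pmf_sums_to_one_across_scales(self):
        for N, M, s in [(2, 1, 1), (17, 9, 5), (100, 40, 30), (557, 200, 300),
                        (2000, 900, 700), (2000, 1999, 1999)]:
            lo, hi = max(0, M + s - N), min(M, s)
            total = sum(hypergeom_overlap(N, M, s, k).pmf for k in range(lo, hi + 1))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_tails_and_pmf_are_consistent(self):
        r = hypergeom_overlap(500, 120, 90, 30)
        assert math.exp(r.upper_tail) + math.exp(r.lower_tail) - r.pmf == pytest.approx(
            1.0, abs=1e-9
        )

    def test_role_symmetry_of_the_two_diseases(self):
        a = hypergeom_overlap(1000, 300, 200, 80)
        b = hypergeom_overlap(1000, 200, 300, 80)
        assert a.log_pmf == pytest.approx(b.log_pmf, rel=1e-12)
        assert a.upper_tail == pytest.approx(b.upper_tail, rel=1e-12)

    def test_out_of_support_conventions(self):
        below = hypergeom_overlap(20, 15, 10, 2)  # support starts at 5
        assert below.log_pmf == -math.inf
        assert below.upper_tail == 0.0 and below.lower_tail == -math.inf
        above = hypergeom_overlap(20, 5, 10, 7)  # support ends at 5
        assert above.log_pmf == -math.inf
        assert above.upper_tail == -math.inf and above.lower_tail == 0.0

    def test_survives_extreme_underflow(self):
        """Probabilities far below 1e-600 keep a finite, correct log."""
        r = hypergeom_overlap(2500, 1250, 1250, 0)
        expected = -math.log(math.comb(2500, 1250))  # ~ -1e3 * ln10
        assert r.log_pmf == pytest.approx(expected, rel=1e-12)
        assert r.log_pmf / math.log(10) < -600
        assert r.pmf_decimal.endswith(f"e{math.floor(r.log_pmf / math.log(10))}")

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 11, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 4, 5, -1)
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 4.5, 5, 2)

    def test_decimal_rendering(self):
        assert decimal_from_log(math.log(0.0123)) == "1.23e-2"
        assert decimal_from_log(-math.inf) == "0"


class TestJaccard:
    def test_published_pathway_similarities(self):
        assert round(jaccard(278, 301, 134).J, 2) == 0.30
        assert jaccard(278, 287, 65).J == pytest.approx(65 / 500)
        assert round(jaccard(278, 287, 65).J, 2) == 0.13

    def test_identical_sets(self):
        assert jaccard(7, 7, 7).J == 1.0

    def test_exact_rational(self):
        assert jaccard(3, 4, 2).J == float(Fraction(2, 5))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_symmetric_and_bounded(self, a, b, c):
        c = min(c, a, b)
        if a + b - c == 0:
            return
        ja, jb = jaccard(a, b, c), jaccard(b, a, c)
        assert ja.J == jb.J
        assert 0.0 <= ja.J <= 1.0
        assert (ja.J == 1.0) == (a == b == c)

    def test_undefined_for_all_zero(self):
        with pytest.raises(ValueError):
            jaccard(0, 0, 0)

    def test_overlap_exceeding_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard(3, 5, 4)


class TestDiseasome:
    def _sets(self):
        a = SignificantGeneSet("obe", frozenset({"S1", "S2", "U"}), frozenset({"D"}))
        b = SignificantGeneSet("scz", frozenset({"S1"}), frozenset({"D", "S2"}))
        c = SignificantGeneSet("mdd", frozenset({"S1", "X"}), frozenset())
        return a, b, c

    def test_disjoint_pair_yields_no_gene_nodes(self):
        a = SignificantGeneSet("a", frozenset({"X"}), frozenset())
        b = SignificantGeneSet("b", frozenset({"Y"}), frozenset())
        g = build_diseasome([a, b], restrict_to_shared=True)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_shared_gene_degree_and_regulation(self):
        a, b, c = self._sets()
        g = build_diseasome([a, b, c], restrict_to_shared=True)
        assert g.degree("S1") == 3 and g.nodes["S1"]["regulation"] == "up"
        assert g.nodes["D"]["regulation"] == "down"
        assert g.nodes["S2"]["regulation"] == "discordant"
        assert "U" not in g and "X" not in g

    def test_set_algebra_matches_hand_count(self):
        a, b, c = self._sets()
        g = build_diseasome([a, b, c], restrict_to_shared=True)
        # shared genes: S1 (3 diseases), S2 (2), D (2) -> 3 disease + 3 gene nodes
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 3 + 2 + 2
        assert nx.is_bipartite(g)

    def test_unrestricted_keeps_singletons(self):
        a, b, _ = self._sets()
        g = build_diseasome([a, b], restrict_to_shared=False)
        assert "U" in g and g.degree("U") == 1

    def test_needs_two_diseases(self):
        a, _, _ = self._sets()
        with pytest.raises(ValueError):
            build_diseasome([a])


class TestGraphRoundTrip:
    def test_graphml_preserves_attributes(self, tmp_path):
        a, b, c = TestDiseasome()._sets()
        g = build_diseasome([a, b, c])
        path = tmp_path / "d.graphml"
        write_graph(g, path, "graphml")
        back = read_graph(path, "graphml")
        assert nx.is_isomorphic(
            g, back,
            node_match=lambda x, y: x.get("type") == y.get("type")
            and x.get("regulation") == y.get("regulation"),
        )
        assert set(back.nodes) == set(g.nodes)

    def test_sif_line_per_edge(self, tmp_path):
        a = SignificantGeneSet("a", frozenset({"G"}), frozenset())
        b = SignificantGeneSet("b", frozenset({"G"}), frozenset())
        path = tmp_path / "d.sif"
        write_graph(build_diseasome([a, b]), path, "sif")
        lines = path.read_text().splitlines()
        assert lines == ["a\tassociates\tG", "b\tassociates\tG"]
        back = read_graph(path, "sif")
        assert back.number_of_edges() == 2

    def test_empty_graph_round_trip(self, tmp_path):
        g = nx.Graph()
        for fmt in ("graphml", "sif"):
            p = tmp_path / f"empty.{fmt}"
            write_graph(g, p, fmt)
            assert read_graph(p, fmt).number_of_nodes() == 0
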