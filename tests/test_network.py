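import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shippath.network import (
    SegmentCountMatrix,
    build_transmission,
    count_segments,
    decompose_route,
    degree_centrality,
)

from conftest import voyage


def brute_force_pairs(calls):
    """Independent enumerator: all (earlier, later) position pairs, deduped."""
    return {
        (calls[a], calls[b])
        for a, b in itertools.combinations(range(len(calls)), 2)
        if calls[a] != calls[b]
    }


class TestDecomposeRoute:
    def test_four_port_route_yields_all_six_segments(self):
        assert decompose_route(voyage("ABCD")) == {
            ("A", "B"), ("B", "C"), ("C", "D"), ("A", "C"), ("B", "D"), ("A", "D"),
        }

    def test_minimal_route(self):
        assert decompose_route(voyage("AB")) == {("A", "B")}

    def test_revisit_dedupes_and_excludes_self_pairs(self):
        assert decompose_route(voyage("ABAC")) == {
            ("A", "B"), ("A", "C"), ("B", "A"), ("B", "C"),
        }

    def test_short_route_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert decompose_route(voyage("A")) == set()

    @given(st.lists(st.sampled_from("ABCDEF"), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumerator(self, calls):
        assert decompose_route(voyage(calls)) == brute_force_pairs(calls)

    @given(st.permutations(list("ABCDEF")))
    @settings(max_examples=50, deadline=None)
    def test_duplicate_free_route_has_l_choose_2_segments(self, calls):
        L = len(calls)
        assert len(decompose_route(voyage(calls))) == L * (L - 1) // 2


class TestCountSegments:
    def test_replicated_voyages_count_vessels(self):
        routes = [voyage("ABC", vid=f"V{k}") for k in range(3)]
        m = count_segments(routes)
        for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert m.counts[m.index[pair[0]], m.index[pair[1]]] == 3
        assert m.counts.sum() == 9

    def test_directionality_preserved(self):
        m = count_segments([voyage("AB", vid="V1"), voyage("BA", vid="V2")])
        assert m.counts[m.index["A"], m.index["B"]] == 1
        assert m.counts[m.index["B"], m.index["A"]] == 1

    def test_total_matches_brute_force_over_random_routes(self):
        rng = np.random.default_rng(42)
        ports = list("ABCDEFGH")
        routes = []
        for k in range(200):
            length = int(rng.integers(2, 9))
            calls = [ports[i] for i in rng.integers(0, len(ports), size=length)]
            calls = [c for i, c in enumerate(calls) if i == 0 or c != calls[i - 1]]
            if len(calls) < 2:
                calls = ["A", "B"]
            routes.append(voyage(calls, vid=f"V{k}"))
        m = count_segments(routes)
        expected = sum(len(brute_force_pairs(r.calls)) for r in routes)
        assert m.counts.sum() == expected

    def test_position_pair_mode_counts_multiplicities(self):
        m = count_segments([voyage("ABAB")], dedupe=False)
        # positions: A1B2A3B4 -> AB pairs (1,2),(1,4),(3,4); BA pair (2,3)
        assert m.counts[m.index["A"], m.index["B"]] == 3
        assert m.counts[m.index["B"], m.index["A"]] == 1

    def test_empty_routes_rejected(self):
        with pytest.raises(ValueError):
            count_segments([])


class TestBuildTransmission:
    def test_single_segment_arithmetic(self):
        m = count_segments([voyage("XY", vid=f"V{k}") for k in range(5)])
        P = build_transmission(m, cap=0.9)
        assert P.lam == pytest.approx(0.18)
        assert P.rates[P.index["X"], P.index["Y"]] == pytest.approx(0.9)
        assert P.absorption[P.index["X"]] == pytest.approx(0.1)
        assert P.absorption[P.index["Y"]] == pytest.approx(1.0)

    def test_max_row_sum_equals_cap(self, small_model):
        P = small_model.transmission
        assert P.row_sums().max() == pytest.approx(0.9, abs=1e-12)

    def test_doubling_cap_doubles_every_rate(self, small_model):
        lo = build_transmission(small_model.segment_counts, cap=0.45)
        hi = build_transmission(small_model.segment_counts, cap=0.9)
        assert np.allclose(hi.rates, 2 * lo.rates)

    def test_conservation_and_support(self, small_model):
        P = small_model.transmission
        assert np.all(np.abs(P.row_sums() + P.absorption - 1.0) <= 1e-12)
        assert np.array_equal(P.rates > 0, small_model.segment_counts.counts > 0)
        assert np.all(np.diag(P.rates) == 0)

    def test_all_zero_counts_rejected(self):
        m = SegmentCountMatrix(ports=["A", "B"], counts=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="no network"):
            build_transmission(m)

    def test_invalid_cap_rejected(self, small_model):
        for cap in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                build_transmission(small_model.segment_counts, cap=cap)


class TestDegreeCentrality:
    def test_interior_calls_count_twice(self):
        assert degree_centrality([voyage("ABC")]) == {"A": 1, "B": 2, "C": 1}

    def test_two_opposite_voyages(self):
        deg = degree_centrality([voyage("AB", vid="V1"), voyage("BA", vid="V2")])
        assert deg == {"A": 2, "B": 2}

    def test_total_is_twice_total_legs(self, small_network):
        _, _, routes, _ = small_network
        deg = degree_centrality(routes)
        assert sum(deg.values()) == sum(2 * (len(r.calls) - 1) for r in routes)
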