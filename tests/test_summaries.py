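import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shippath import PathwayModel
from shippath.network import degree_centrality
from shippath.simulate import ArrivalRateTable, SimulationConfig, estimate_arrival_rates
from shippath.summaries import (
    RankingTable,
    combine_rates,
    rank_countries,
    rank_domestic_ports,
    rank_foreign_ports,
)
from shippath.synthetic import generate_known_answer_case

rates_lists = st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=12)


class TestCombineRates:
    def test_two_rate_hand_value(self):
        # 1 - 0.755 * 0.773
        assert combine_rates([0.245, 0.227]) == pytest.approx(0.416385, abs=1e-9)

    def test_identity_and_empty(self):
        assert combine_rates([0.37]) == pytest.approx(0.37)
        assert combine_rates([]) == 0.0

    def test_out_of_range_rejected(self):
        for bad in ([1.2], [-0.1], [0.5, np.nan]):
            with pytest.raises(ValueError):
                combine_rates(bad)

    @given(rates_lists)
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, rates):
        c = combine_rates(rates)
        if rates:
            assert max(rates) - 1e-12 <= c <= min(1.0, sum(rates)) + 1e-12

    @given(rates_lists, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant(self, rates, rnd):
        shuffled = list(rates)
        rnd.shuffle(shuffled)
        assert combine_rates(shuffled) == pytest.approx(combine_rates(rates), abs=1e-12)

    @given(rates_lists.filter(len), st.integers(0, 11), st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_every_argument(self, rates, idx, new):
        idx = idx % len(rates)
        bumped = list(rates)
        bumped[idx] = max(bumped[idx], new)
        assert combine_rates(bumped) >= combine_rates(rates) - 1e-12

    def test_small_rate_limit_is_additive(self):
        rates = [1e-7, 2e-7, 3e-7]
        assert combine_rates(rates) == pytest.approx(sum(rates), rel=1e-5)


def table_from(origins, destinations, phi, K=1000):
    J = (np.asarray(phi) * K).astype(int)
    return ArrivalRateTable(origins=origins, destinations=destinations, J=J, K=K)


class TestRankings:
    def test_single_cell_ranking(self, small_registry):
        tab = table_from(["A"], ["D"], [[0.3]], K=10)
        rt = rank_domestic_ports(tab, small_registry)
        df = rt.to_frame()
        assert df.iloc[0].tolist() == [1, "D", "domestic_port", 0.3, 1.0]

    def test_two_source_port_outranks_single_stronger_source(self):
        from shippath.io import PortRecord

        registry = [
            PortRecord("O1", "", "AA"),
            PortRecord("O2", "", "AA"),
            PortRecord("D1", "", "AUS", is_domestic=True),
            PortRecord("D2", "", "AUS", is_domestic=True),
        ]
        tab = table_from(["O1", "O2"], ["D1", "D2"], [[0.5, 0.4], [0.0, 0.2]], K=10)
        rt = rank_domestic_ports(tab, registry)
        df = rt.to_frame().set_index("entity_id")
        assert df.loc["D2", "phi"] == pytest.approx(1 - 0.6 * 0.8)  # 0.52
        assert df.loc["D2", "rank"] == 1 and df.loc["D1", "rank"] == 2

    def test_origin_permutation_invariance(self, small_registry):
        tab1 = table_from(["A", "C"], ["D"], [[0.4], [0.1]])
        tab2 = table_from(["C", "A"], ["D"], [[0.1], [0.4]])
        rt1 = rank_domestic_ports(tab1, small_registry)
        rt2 = rank_domestic_ports(tab2, small_registry)
        assert rt1.to_frame().equals(rt2.to_frame())

    def test_unreachable_origin_ranks_last(self, small_registry):
        tab = table_from(["A", "C"], ["D"], [[0.4], [0.0]])
        rt = rank_foreign_ports(tab, small_registry)
        df = rt.to_frame().set_index("entity_id")
        assert df.loc["C", "phi"] == 0.0
        assert df.loc["C", "rank"] == len(df)

    def test_country_pooling(self, small_registry):
        fp = RankingTable("foreign_port", {"A": 0.537, "C": 0.211, "B": 0.0})
        rc = rank_countries(fp, small_registry)
        df = rc.to_frame().set_index("entity_id")
        # A and C share country AA: 1 - 0.463 * 0.789
        assert df.loc["AA", "phi"] == pytest.approx(1 - 0.463 * 0.789, abs=1e-12)
        assert df.loc["BB", "phi"] == 0.0

    def test_relative_phi_mean_is_one(self, small_model):
        res = small_model.fit(K=2000, seed=1)
        for rt in (res.domestic_ports, res.foreign_ports, res.countries):
            assert rt.to_frame()["relative_phi"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_ranks_invariant_under_common_scaling(self, small_registry):
        phi = np.array([[0.4, 0.1], [0.25, 0.3]])
        registry = small_registry
        t1 = table_from(["A", "C"], ["D", "B"], phi, K=100)
        t2 = table_from(["A", "C"], ["D", "B"], phi / 2, K=100)
        r1 = rank_foreign_ports(t1, registry).to_frame()
        r2 = rank_foreign_ports(t2, registry).to_frame()
        assert list(r1["entity_id"]) == list(r2["entity_id"])

    def test_tie_break_is_lexicographic(self, small_registry):
        tab = table_from(["A", "C"], ["D"], [[0.2], [0.2]])
        df = rank_foreign_ports(tab, small_registry).to_frame()
        assert list(df["entity_id"]) == ["A", "C"]
        # rank statistics use average ranks for ties
        ranks = rank_foreign_ports(tab, small_registry).ranks()
        assert ranks["A"] == ranks["C"] == 1.5

    def test_no_domestic_ports_rejected(self):
        from shippath.io import PortRecord

        registry = [PortRecord("A", "", "AA"), PortRecord("B", "", "BB")]
        tab = table_from(["A"], ["B"], [[0.1]])
        with pytest.raises(ValueError, match="domestic"):
            rank_domestic_ports(tab, registry)


class TestCorridorInversion:
    def test_pathway_rank_beats_degree_rank_on_corridor(self):
        """A low-degree port on the corridor into the entry port outranks
        a high-degree hub whose traffic never leads there."""
        case = generate_known_answer_case("corridor6")
        model = PathwayModel(case.routes, case.registry, case.pest_range, cap=case.cap)
        deg = degree_centrality(case.routes)
        assert deg == case.facts["degree_centrality"]
        table = estimate_arrival_rates(
            model.transmission, model.origins, SimulationConfig(K=20_000, seed=8)
        )
        rt = rank_foreign_ports(table, case.registry)
        assert deg["COR"] < deg["HUB"]
        assert rt.rank_of("COR") < rt.rank_of("HUB")
        assert rt.rank_of("COR") == 1
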