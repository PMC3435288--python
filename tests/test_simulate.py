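import numpy as np
import pytest

from shippath import PathwayModel
from shippath.network import TransmissionMatrix
from shippath.simulate import SimulationConfig, estimate_arrival_rates, simulate_walk
from shippath.synthetic import generate_known_answer_case


def model_for(case_id):
    case = generate_known_answer_case(case_id)
    return PathwayModel(case.routes, case.registry, case.pest_range, cap=case.cap)


def binom_bound(p, n):
    return 4 * np.sqrt(p * (1 - p) / n)


class TestSimulateWalk:
    def test_two_port_walk_frequency(self):
        P = model_for("twoport").transmission
        rng = np.random.default_rng(0)
        n = 20_000
        hits = sum(simulate_walk(P, "X", rng) == ["Y"] for _ in range(n))
        assert abs(hits / n - 0.9) <= binom_bound(0.9, n)

    def test_absorbing_row_yields_empty_walk(self):
        P = model_for("twoport").transmission
        rng = np.random.default_rng(0)
        assert simulate_walk(P, "Y", rng) == []  # Y has no outgoing paths

    def test_cycle_respects_max_steps(self):
        P = model_for("cycle2").transmission
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert len(simulate_walk(P, "X", rng, max_steps=5)) <= 5

    def test_unknown_origin_rejected(self):
        P = model_for("twoport").transmission
        with pytest.raises(KeyError):
            simulate_walk(P, "NOPE", np.random.default_rng(0))


class TestEstimateArrivalRates:
    def test_chain_rates_match_closed_form(self):
        P = model_for("chain3").transmission
        K = 100_000
        table = estimate_arrival_rates(P, ["X"], SimulationConfig(K=K, seed=11))
        assert abs(table.phi_for("X", "Y") - 0.5) <= binom_bound(0.5, K)
        assert abs(table.phi_for("X", "Z") - 0.25) <= binom_bound(0.25, K)

    def test_origin_with_full_absorption_never_arrives(self):
        rates = np.zeros((2, 2))
        rates[1, 0] = 0.5
        P = TransmissionMatrix(
            ports=["X", "Y"], rates=rates, absorption=np.array([1.0, 0.5]), lam=0.5, cap=0.5
        )
        table = estimate_arrival_rates(P, ["X"], SimulationConfig(K=5000, seed=2))
        assert table.J.sum() == 0

    def test_unreachable_pairs_are_exactly_zero(self):
        P = model_for("corridor6").transmission
        table = estimate_arrival_rates(
            P, ["HUB", "REM"], SimulationConfig(K=20_000, seed=3)
        )
        assert table.phi_for("HUB", "DST") == 0.0
        assert table.phi_for("REM", "DST") == 0.0

    def test_same_seed_is_bit_identical_and_origin_order_free(self):
        P = model_for("corridor6").transmission
        cfg = SimulationConfig(K=5000, seed=9)
        a = estimate_arrival_rates(P, ["SRCA", "COR", "SRCB"], cfg)
        b = estimate_arrival_rates(P, ["SRCB", "SRCA", "COR"], cfg)
        assert a.origins == b.origins
        assert np.array_equal(a.J, b.J)

    def test_origin_never_counts_itself(self):
        P = model_for("cycle2").transmission
        table = estimate_arrival_rates(P, ["X"], SimulationConfig(K=5000, seed=4))
        assert table.phi_for("X", "X") == 0.0

    def test_raw_visit_mode_dominates_first_visit(self):
        P = model_for("cycle2").transmission
        fv = estimate_arrival_rates(P, ["X"], SimulationConfig(K=20_000, seed=5))
        rv = estimate_arrival_rates(
            P, ["X"], SimulationConfig(K=20_000, seed=5, count_mode="visits")
        )
        assert np.all(rv.J >= fv.J)

    def test_variance_scales_inversely_with_k(self):
        P = model_for("twoport").transmission
        reps = 80
        var = {}
        for K in (250, 500):
            phis = [
                estimate_arrival_rates(P, ["X"], SimulationConfig(K=K, seed=s)).phi_for("X", "Y")
                for s in range(reps)
            ]
            var[K] = np.var(phis)
        ratio = var[250] / var[500]
        assert 1.2 < ratio < 3.4  # expected 2, with chi-squared sampling slack

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(K=0)
        with pytest.raises(ValueError):
            SimulationConfig(count_mode="bogus")
        P = model_for("twoport").transmission
        with pytest.raises(ValueError):
            estimate_arrival_rates(P, [], SimulationConfig(K=10))
        with pytest.raises(KeyError):
            estimate_arrival_rates(P, ["NOPE"], SimulationConfig(K=10))

    def test_table_long_form_round_trip(self, tmp_path):
        P = model_for("chain3").transmission
        table = estimate_arrival_rates(P, ["X", "Y"], SimulationConfig(K=1000, seed=6))
        df = table.to_frame()
        assert set(df.columns) == {"origin", "destination", "J", "K", "phi"}
        assert len(df) == 2 * P.n_ports
        assert np.allclose(df["J"] / df["K"], df["phi"])
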