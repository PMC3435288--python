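"""Model/Results interface over the pathway pipeline.

:class:`PathwayModel` holds the data side — routes, port registry, pest
range — and the derived network objects (segment counts, transmission
matrix, degree centrality). :meth:`PathwayModel.fit` runs the Monte-Carlo
pathway simulation and returns a :class:`PathwayResults` carrying the
arrival-rate estimates, the three rankings, Monte-Carlo standard errors,
and a text summary; sensitivity experiments and file export hang off the
results object.

Example
-------
>>> from shippath import PathwayModel
>>> from shippath.synthetic import generate_known_answer_case
>>> case = generate_known_answer_case("corridor6")
>>> model = PathwayModel(case.routes, case.registry, case.pest_range, cap=case.cap)
>>> res = model.fit(K=10_000, seed=1)
>>> res.domestic_ports.rank_of("DST")
1
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PestRange,
    PortRecord,
    VoyageRoute,
    read_pest_range,
    read_ports,
    read_routes,
    _registry_index,
)
from .network import (
    SegmentCountMatrix,
    TransmissionMatrix,
    build_transmission,
    count_segments,
    degree_centrality,
)
from .oracle import VisitProbabilityMatrix, visit_probability_matrix
from .sensitivity import PerturbationConfig, RankStabilityResult, run_sensitivity
from .simulate import ArrivalRateTable, SimulationConfig, estimate_arrival_rates
from .summaries import (
    RankingTable,
    rank_countries,
    rank_domestic_ports,
    rank_foreign_ports,
)

__all__ = ["PathwayModel", "PathwayResults"]

logger = logging.getLogger(__name__)


class PathwayModel:
    """First-order Markov pathway model of organism arrival on a shipping
    network.

    Parameters
    ----------
    routes
        Voyage call sequences (earliest call first, destination last).
    registry
        Port records; domestic flags mark the destination-country ports
        of entry.
    pest_range
        Countries where the organism is established. Origins are the
        non-domestic registry ports in these countries that appear on at
        least one route.
    cap
        Row-sum cap fixing the traffic-to-rate scaling coefficient
        lam = cap / max_i sum_j m_ij.
    dedupe_segments
        Count each voyage at most once per segment (vessel counts). The
        alternative counts every qualifying position pair.
    """

    def __init__(
        self,
        routes: list[VoyageRoute],
        registry: list[PortRecord],
        pest_range: PestRange,
        cap: float = 0.9,
        dedupe_segments: bool = True,
        period_label: str = "",
    ) -> None:
        self.routes = routes
        self.registry = registry
        self.registry_index = _registry_index(registry)
        self.pest_range = pest_range
        self.cap = cap
        self.dedupe_segments = dedupe_segments
        self.period_label = period_label
        self._counts: SegmentCountMatrix | None = None
        self._transmission: TransmissionMatrix | None = None

    @classmethod
    def from_csv(
        cls,
        routes_path: str | Path,
        ports_path: str | Path,
        pest_range_path: str | Path,
        **kwargs,
    ) -> "PathwayModel":
        """Build a model from the routes/ports/pest-range CSV dialects."""
        registry = read_ports(ports_path)
        routes = read_routes(routes_path, registry)
        pest_range, _ = read_pest_range(pest_range_path, registry, routes)
        return cls(routes, registry, pest_range, **kwargs)

    @property
    def segment_counts(self) -> SegmentCountMatrix:
        if self._counts is None:
            self._counts = count_segments(
                self.routes,
                self.registry,
                dedupe=self.dedupe_segments,
                period_label=self.period_label,
            )
        return self._counts

    @property
    def transmission(self) -> TransmissionMatrix:
        if self._transmission is None:
            self._transmission = build_transmission(self.segment_counts, cap=self.cap)
        return self._transmission

    @property
    def origins(self) -> list[str]:
        """Pest-range ports observed on routes, sorted."""
        on_routes = set(self.segment_counts.ports)
        return sorted(
            p
            for p, rec in self.registry_index.items()
            if rec.country in self.pest_range and not rec.is_domestic and p in on_routes
        )

    @property
    def degree_centrality(self) -> dict[str, int]:
        return degree_centrality(self.routes)

    def degree_frame(self) -> pd.DataFrame:
        deg = self.degree_centrality
        df = pd.DataFrame(sorted(deg.items()), columns=["port_id", "degree_centrality"])
        return df.sort_values(
            ["degree_centrality", "port_id"], ascending=[False, True]
        ).reset_index(drop=True)

    def visit_probabilities(self) -> VisitProbabilityMatrix:
        """Exact arrival probabilities by linear solve (no Monte Carlo)."""
        return visit_probability_matrix(self.transmission, self.origins)

    def fit(
        self,
        K: int = 2_000_000,
        seed: int = 0,
        max_steps: int = 10_000,
        count_mode: str = "first_visit",
    ) -> "PathwayResults":
        """Run the Monte-Carlo pathway simulation and summarise it."""
        origins = self.origins
        if not origins:
            raise ValueError("no ports within the pest range appear on the network")
        config = SimulationConfig(K=K, seed=seed, max_steps=max_steps, count_mode=count_mode)
        logger.info(
            "fit: Y=%d ports, %d origins, K=%d, lam=%.3g",
            self.transmission.n_ports,
            len(origins),
            K,
            self.transmission.lam,
        )
        table = estimate_arrival_rates(self.transmission, origins, config)
        return PathwayResults(model=self, config=config, arrival_rates=table)


@dataclass
class PathwayResults:
    """Fitted arrival rates and the rankings derived from them."""

    model: PathwayModel
    config: SimulationConfig
    arrival_rates: ArrivalRateTable
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def phi(self) -> np.ndarray:
        return self.arrival_rates.phi

    def phi_std_err(self) -> np.ndarray:
        """Binomial standard error sqrt(phi (1 - phi) / K) per cell."""
        phi = self.arrival_rates.phi
        return np.sqrt(phi * (1 - phi) / self.arrival_rates.K)

    @property
    def domestic_ports(self) -> RankingTable:
        if "domestic" not in self._cache:
            self._cache["domestic"] = rank_domestic_ports(self.arrival_rates, self.model.registry)
        return self._cache["domestic"]

    @property
    def foreign_ports(self) -> RankingTable:
        if "foreign" not in self._cache:
            self._cache["foreign"] = rank_foreign_ports(self.arrival_rates, self.model.registry)
        return self._cache["foreign"]

    @property
    def countries(self) -> RankingTable:
        if "countries" not in self._cache:
            self._cache["countries"] = rank_countries(self.foreign_ports, self.model.registry)
        return self._cache["countries"]

    def per_destination_breakdown(self, destination: str) -> pd.DataFrame:
        """Origins ranked by phi to one destination port, with relative
        rates against the mean over all origin-destination pairs."""
        tab = self.arrival_rates
        j = tab.dest_index[destination]
        phi = tab.phi
        mean = float(phi.mean())
        df = pd.DataFrame({"origin": tab.origins, "phi": phi[:, j]})
        df["relative_phi"] = df["phi"] / mean if mean > 0 else np.nan
        df = df.sort_values(["phi", "origin"], ascending=[False, True]).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df

    def sensitivity(
        self,
        scenario: str = "multiplicative",
        config: PerturbationConfig | None = None,
        sim_config: SimulationConfig | None = None,
    ) -> list[RankStabilityResult]:
        """Rank-stability experiment against this fit's baseline rankings.

        Uses this results object's rankings as the baseline; the
        simulation seed is shared between baseline and perturbed runs
        (common random numbers) unless ``sim_config`` overrides it.
        """
        if config is None:
            config = PerturbationConfig(scenario=scenario)
        sim = sim_config or self.config
        baseline = None
        if sim.K == self.config.K and sim.seed == self.config.seed:
            baseline = {"foreign_port": self.foreign_ports, "domestic_port": self.domestic_ports}
        return run_sensitivity(
            self.model.transmission,
            self.model.origins,
            self.model.registry,
            sim,
            config,
            baseline=baseline,
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked entities."""
        model = self.model
        P = model.transmission
        lines = [
            "Pathway model: organism arrival via container-shipping network",
            "=" * 62,
            f"Ports (network nodes):      {P.n_ports}",
            f"Voyages:                    {len(model.routes)}",
            f"Origin ports (pest range):  {len(model.origins)}",
            f"Scaling lam:                {P.lam:.6g} (row-sum cap {P.cap})",
            f"Realizations per origin K:  {self.arrival_rates.K}",
            f"Seed:                       {self.config.seed}",
            "",
        ]
        for title, table in [
            ("Destination ports of entry", self.domestic_ports),
            ("Foreign origin ports", self.foreign_ports),
            ("Origin countries", self.countries),
        ]:
            df = table.to_frame().head(top)
            lines.append(f"{title} (top {min(top, len(table))} of {len(table)}, "
                         f"mean phi {table.mean_phi:.6g})")
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.6f}"))
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path, breakdowns: bool = False) -> dict[str, Path]:
        """Write arrival rates, rankings and degree centrality to CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "arrival_rates": out_dir / "arrival_rates.csv",
            "domestic_ports": out_dir / "ranking_domestic_ports.csv",
            "foreign_ports": out_dir / "ranking_foreign_ports.csv",
            "countries": out_dir / "ranking_countries.csv",
            "degree": out_dir / "degree_centrality.csv",
        }
        self.arrival_rates.to_csv(paths["arrival_rates"])
        self.domestic_ports.to_csv(paths["domestic_ports"])
        self.foreign_ports.to_csv(paths["foreign_ports"])
        self.countries.to_csv(paths["countries"])
        self.model.degree_frame().to_csv(paths["degree"], index=False)
        if breakdowns:
            bdir = out_dir / "per_destination"
            bdir.mkdir(exist_ok=True)
            for dest in self.domestic_ports.phi_overall:
                p = bdir / f"origins_to_{dest}.csv"
                self.per_destination_breakdown(dest).to_csv(p, index=False, float_format="%.6f")
                paths[f"breakdown_{dest}"] = p
        return paths
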