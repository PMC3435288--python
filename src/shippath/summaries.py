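"""Risk summaries: overall arrival rates, relative rates, and rankings.

Per-pair arrival rates phi_ij are aggregated into overall rates with the
complementary product

    combined = 1 - prod_i (1 - phi_i),

the probability that at least one source pathway delivers the organism
when the per-source rates are treated as independent. The aggregate is
bounded by max(phi) from below and min(1, sum(phi)) from above, and
reduces to sum(phi) in the small-rate limit.

Relative rates divide an entity's overall rate by the mean rate over the
full entity set of the ranking at hand, expressing risk as a multiple of
the network average; rankings are by descending overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import fsum, log1p
from pathlib import Path

import numpy as np
import pandas as pd

from .io import _registry_index
from .simulate import ArrivalRateTable

__all__ = [
    "RankingTable",
    "combine_rates",
    "rank_domestic_ports",
    "rank_foreign_ports",
    "rank_countries",
]

ENTITY_KINDS = ("domestic_port", "foreign_port", "foreign_country")


@dataclass
class RankingTable:
    """Entities ordered by overall arrival rate.

    ``rows`` maps entity_id -> phi_overall; derived columns (relative rate,
    rank) are materialised by :meth:`to_frame`. ``mean_phi`` is the
    denominator of the relative rates: the mean phi_overall over the full
    entity set.
    """

    entity_kind: str
    phi_overall: dict[str, float]
    mean_phi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"entity_kind must be one of {ENTITY_KINDS}")
        values = list(self.phi_overall.values())
        self.mean_phi = float(np.mean(values)) if values else float("nan")

    def __len__(self) -> int:
        return len(self.phi_overall)

    def to_frame(self) -> pd.DataFrame:
        """Columns ``rank,entity_id,entity_kind,phi,relative_phi``; rows
        sorted by descending phi with lexicographic entity-id tie-break;
        ranks 1..n without gaps."""
        items = sorted(self.phi_overall.items(), key=lambda kv: (-kv[1], kv[0]))
        mean = self.mean_phi
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(items) + 1),
                "entity_id": pd.Series([e for e, _ in items], dtype=str),
                "entity_kind": self.entity_kind,
                "phi": pd.Series([p for _, p in items], dtype=float),
                "relative_phi": pd.Series(
                    [p / mean if mean > 0 else np.nan for _, p in items], dtype=float
                ),
            }
        )

    def ranks(self, average_ties: bool = True) -> pd.Series:
        """Entity -> rank. With ``average_ties`` equal phi values share
        their average rank (the form rank statistics consume)."""
        df = self.to_frame()
        if average_ties:
            from scipy.stats import rankdata

            r = rankdata(-df["phi"].to_numpy(), method="average")
            return pd.Series(r, index=df["entity_id"].to_numpy())
        return pd.Series(df["rank"].to_numpy(), index=df["entity_id"].to_numpy())

    def rank_of(self, entity_id: str) -> int:
        df = self.to_frame()
        return int(df.loc[df["entity_id"] == entity_id, "rank"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        from .io import write_ranking

        write_ranking(self, path)


def combine_rates(rates) -> float:
    """Overall arrival rate from per-source rates: ``1 - prod(1 - phi)``.

    The probability that at least one source delivers, for independent
    per-source rates in [0, 1]. Empty input gives 0; a single rate is
    returned unchanged. Computed through log1p for accuracy with many
    small rates.
    """
    rates = list(rates)
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        return 0.0
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("all rates must lie in [0, 1]")
    if np.any(arr == 1.0):
        return 1.0
    return -np.expm1(fsum(log1p(-x) for x in arr))


def _domestic_ids(registry) -> set[str]:
    index = _registry_index(registry)
    return {p for p, rec in index.items() if rec.is_domestic}


def rank_domestic_ports(table: ArrivalRateTable, registry) -> RankingTable:
    """Rank destination-country ports of entry by their overall arrival
    rate from all pest-range origins combined."""
    domestic = _domestic_ids(registry) & set(table.destinations)
    if not domestic:
        raise ValueError("no domestic ports present in the arrival-rate table")
    phi = table.phi
    overall = {
        d: combine_rates(phi[:, table.dest_index[d]]) for d in sorted(domestic)
    }
    return RankingTable(entity_kind="domestic_port", phi_overall=overall)


def rank_foreign_ports(table: ArrivalRateTable, registry) -> RankingTable:
    """Rank pest-range origin ports by their overall rate of delivering the
    organism to any domestic port."""
    domestic = _domestic_ids(registry) & set(table.destinations)
    if not domestic:
        raise ValueError("no domestic ports present in the arrival-rate table")
    cols = [table.dest_index[d] for d in sorted(domestic)]
    phi = table.phi
    overall = {
        o: combine_rates(phi[table.origin_index[o], cols]) for o in table.origins
    }
    return RankingTable(entity_kind="foreign_port", phi_overall=overall)


def rank_countries(foreign_ports: RankingTable, registry) -> RankingTable:
    """Pool per-origin-port overall rates to the country level.

    A country's rate is the complement-product combination of its ports'
    combined rates.
    """
    index = _registry_index(registry)
    by_country: dict[str, list[float]] = {}
    for port, rate in foreign_ports.phi_overall.items():
        country = index[port].country
        by_country.setdefault(country, []).append(rate)
    overall = {c: combine_rates(v) for c, v in sorted(by_country.items())}
    return RankingTable(entity_kind="foreign_country", phi_overall=overall)
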