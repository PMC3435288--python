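"""Reading, writing and validation of route-history, port-registry and
pest-range files.

File dialects
-------------
``routes.csv``
    Comma-separated, UTF-8, header ``ship_id,voyage_id,seq,port_id,arrival_date``
    (an optional ``leg_days`` column carries per-leg transit durations in days).
    One row per port call; ``seq`` orders the calls of a voyage (earliest
    first, the final call is the destination port); ``voyage_id``
    disambiguates repeat arrivals by the same ship.
``ports.csv``
    Header ``port_id,name,country,is_domestic`` with ``is_domestic`` in {0,1}.
    Domestic ports are destination-country ports of entry.
``pest_range.txt``
    One country code per line; ``#`` starts a comment.
``rankings``
    Header ``rank,entity_id,entity_kind,phi,relative_phi``; floats at six
    decimals; rows sorted by rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PortRecord",
    "VoyageRoute",
    "PestRange",
    "RouteFormatError",
    "RouteValidationError",
    "read_ports",
    "write_ports",
    "read_routes",
    "write_routes",
    "read_pest_range",
    "write_pest_range",
    "write_ranking",
    "read_ranking",
]

logger = logging.getLogger(__name__)

ROUTE_COLUMNS = ["ship_id", "voyage_id", "seq", "port_id", "arrival_date"]
PORT_COLUMNS = ["port_id", "name", "country", "is_domestic"]
RANKING_COLUMNS = ["rank", "entity_id", "entity_kind", "phi", "relative_phi"]

#: ten prior ports of call plus the destination port
MAX_CALLS = 11


class RouteFormatError(ValueError):
    """A file does not match the expected dialect (e.g. missing column)."""


class RouteValidationError(ValueError):
    """File contents violate a domain invariant (e.g. unknown port)."""


@dataclass(frozen=True)
class PortRecord:
    """A port in the shipping network.

    ``is_domestic`` marks a destination-country port of entry (an
    "Australian" port in the original study's framing).
    """

    port_id: str
    name: str
    country: str
    is_domestic: bool = False

    def __post_init__(self) -> None:
        if not self.port_id:
            raise RouteValidationError("port_id must be non-empty")
        if not self.country:
            raise RouteValidationError(f"port {self.port_id!r}: country must be non-empty")


@dataclass
class VoyageRoute:
    """One ship arrival's ordered port-call sequence.

    ``calls`` lists port ids earliest first; the final element is the
    destination port. ``leg_days`` optionally gives the transit duration of
    each leg (``len(calls) - 1`` values).
    """

    ship_id: str
    arrival_date: str
    calls: list[str]
    voyage_id: str = ""
    leg_days: list[float] | None = None

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class PestRange:
    """Set of country codes where the organism is established."""

    countries: set[str] = field(default_factory=set)

    def __contains__(self, country: str) -> bool:
        return country in self.countries

    def __len__(self) -> int:
        return len(self.countries)


def _registry_index(registry) -> dict[str, PortRecord]:
    """Accept a list of PortRecord or an existing mapping; check uniqueness."""
    if isinstance(registry, dict):
        return registry
    index: dict[str, PortRecord] = {}
    for rec in registry:
        if rec.port_id in index:
            raise RouteValidationError(f"duplicate port_id {rec.port_id!r} in registry")
        index[rec.port_id] = rec
    return index


def read_ports(path: str | Path) -> list[PortRecord]:
    """Read a port registry from ``ports.csv``."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PORT_COLUMNS if c not in df.columns]
    if missing:
        raise RouteFormatError(f"{path}: missing column(s) {missing}")
    records = [
        PortRecord(
            port_id=row.port_id,
            name=row.name if isinstance(row.name, str) else "",
            country=row.country,
            is_domestic=str(row.is_domestic).strip() in {"1", "true", "True"},
        )
        for row in df.itertuples(index=False)
    ]
    _registry_index(records)  # uniqueness check
    return records


def write_ports(registry: list[PortRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.port_id, r.name, r.country, int(r.is_domestic)) for r in registry],
        columns=PORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_routes(
    path: str | Path,
    registry,
    *,
    require_domestic_final: bool = False,
    enforce_truncation: bool = False,
) -> list[VoyageRoute]:
    """Read voyage routes from ``routes.csv`` and validate against a registry.

    Rows are grouped by ``(ship_id, voyage_id)`` and ordered by ``seq``;
    file order is irrelevant. Unknown port ids raise
    :class:`RouteValidationError` listing the offenders. Consecutive duplicate
    calls within a voyage are collapsed with a warning (a ship cannot make a
    zero-length leg).

    Parameters
    ----------
    require_domestic_final
        Enforce that each voyage ends at a domestic port, as in an
        arrival-conditioned extract of destination-country arrivals.
    enforce_truncation
        Enforce the ten-prior-ports-of-call truncation
        (``len(calls) <= 11``).
    """
    index = _registry_index(registry)
    df = pd.read_csv(path, dtype={"ship_id": str, "voyage_id": str, "port_id": str})
    missing = [c for c in ROUTE_COLUMNS if c not in df.columns]
    if missing:
        raise RouteFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty route file", path)
        return []

    unknown = sorted(set(df["port_id"]) - set(index))
    if unknown:
        raise RouteValidationError(f"{path}: unknown port_id(s): {unknown}")

    has_legs = "leg_days" in df.columns
    routes: list[VoyageRoute] = []
    for (ship_id, voyage_id), grp in df.groupby(["ship_id", "voyage_id"], sort=True):
        grp = grp.sort_values("seq")
        calls = list(grp["port_id"])
        legs = list(grp["leg_days"]) if has_legs else None
        # collapse zero-length legs
        cleaned, cleaned_legs = [calls[0]], []
        for k, c in enumerate(calls[1:], start=1):
            if c == cleaned[-1]:
                warnings.warn(
                    f"voyage {ship_id}/{voyage_id}: collapsed duplicate consecutive call {c!r}",
                    stacklevel=2,
                )
                continue
            cleaned.append(c)
            if legs is not None:
                cleaned_legs.append(legs[k])
        route = VoyageRoute(
            ship_id=ship_id,
            voyage_id=voyage_id,
            arrival_date=str(grp["arrival_date"].iloc[-1]),
            calls=cleaned,
            leg_days=cleaned_legs if legs is not None else None,
        )
        if len(route.calls) < 2:
            raise RouteValidationError(
                f"voyage {ship_id}/{voyage_id}: fewer than two distinct calls"
            )
        if enforce_truncation and len(route.calls) > MAX_CALLS:
            raise RouteValidationError(
                f"voyage {ship_id}/{voyage_id}: {len(route.calls)} calls exceeds "
                f"the {MAX_CALLS}-call truncation"
            )
        if require_domestic_final and not index[route.calls[-1]].is_domestic:
            raise RouteValidationError(
                f"voyage {ship_id}/{voyage_id}: final call {route.calls[-1]!r} is not domestic"
            )
        routes.append(route)
    return routes


def write_routes(routes: list[VoyageRoute], path: str | Path) -> None:
    rows = []
    for r in routes:
        voyage_id = r.voyage_id or f"{r.ship_id}-{r.arrival_date}"
        for seq, port in enumerate(r.calls, start=1):
            leg = ""
            if r.leg_days is not None and seq >= 2:
                leg = f"{r.leg_days[seq - 2]:.3f}"
            rows.append((r.ship_id, voyage_id, seq, port, r.arrival_date, leg))
    df = pd.DataFrame(rows, columns=ROUTE_COLUMNS + ["leg_days"])
    df.to_csv(path, index=False)


def read_pest_range(path: str | Path, registry, routes=None):
    """Read a pest range and derive the origin-port set.

    Returns ``(PestRange, origin_ports)`` where ``origin_ports`` is the set
    of registry ports whose country is in the range and which — when
    ``routes`` is given — appear in at least one route. A range country with
    no matching port on the network is logged as a warning, not an error:
    the organism's worldwide range routinely exceeds the ports the network
    actually touches.
    """
    index = _registry_index(registry)
    countries: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            code = line.split("#", 1)[0].strip()
            if code:
                countries.add(code)
    if not countries:
        raise RouteValidationError(f"{path}: empty pest range")

    on_routes: set[str] | None = None
    if routes is not None:
        on_routes = {c for r in routes for c in r.calls}

    origin_ports: set[str] = set()
    for port_id, rec in index.items():
        if rec.country in countries and not rec.is_domestic:
            if on_routes is None or port_id in on_routes:
                origin_ports.add(port_id)

    matched_countries = {index[p].country for p in origin_ports}
    for country in sorted(countries - matched_countries):
        logger.warning("pest-range country %s has no port on the network", country)
    return PestRange(countries=countries), origin_ports


def write_pest_range(pest_range: PestRange, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for country in sorted(pest_range.countries):
            fh.write(country + "\n")


def write_ranking(table, path: str | Path) -> None:
    """Write a ranking table to CSV (six-decimal floats, sorted by rank)."""
    df = table.to_frame()
    df = df.sort_values("rank")
    df = df[RANKING_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def read_ranking(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"entity_id": str, "entity_kind": str})
    missing = [c for c in RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise RouteFormatError(f"{path}: missing column(s) {missing}")
    return df
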