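"""Synthetic route-data generation.

The vessel-movement records this analysis was designed for (Lloyd's
Maritime Intelligence Unit extracts) are proprietary, so this module
generates route datasets with the statistical structure the pipeline
assumes: ~550 foreign ports in ~126 countries feeding ~30 domestic ports
of entry, ~25,500 port-call events, hub-dominated traffic in which a
couple of ports carry roughly four times the degree centrality of the next
tier, route histories truncated at ten prior ports of call, and mean leg
durations around 7.9 days at sea.

Port popularity follows a hub-plus-power-law-tail distribution rather
than a fitted gravity model: a pair of super-hubs carries a fixed multiple
of the busiest ordinary port's traffic, and the remaining ports' weights
decay as a Zipf tail. This targets the observables the analysis relies on
— the hubs' share of call events, the roughly four-fold degree-centrality
gap between the hubs and the third-ranked port, and genuinely separated
traffic (hence risk) levels across ports — and nothing finer.

A small catalogue of hand-solvable known-answer cases (with their exact
visit probabilities attached) backs the oracle and ranking tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import PestRange, PortRecord, VoyageRoute, write_pest_range, write_ports, write_routes

__all__ = [
    "SyntheticNetworkConfig",
    "KnownAnswerCase",
    "generate_network",
    "generate_known_answer_case",
    "write_dataset",
    "KNOWN_CASES",
]

#: default route-length distribution over 2..11 calls (ten prior ports plus
#: the destination); most arrival records carry a full ten-port history
DEFAULT_LENGTH_DIST = {
    11: 0.60,
    10: 0.10,
    9: 0.05,
    8: 0.05,
    7: 0.05,
    6: 0.04,
    5: 0.04,
    4: 0.03,
    3: 0.02,
    2: 0.02,
}


@dataclass
class SyntheticNetworkConfig:
    """Shape parameters of the generated network.

    Defaults emulate the 2002–2007 Australian container-arrival extract:
    553 foreign ports in 126 countries, 30 domestic ports, 557 ships,
    ~25,507 call events, a pest range of 36 countries of which 24 lie on
    the network, and a mean leg duration of 7.9 days.
    """

    n_foreign_ports: int = 553
    n_domestic_ports: int = 30
    n_countries: int = 126
    n_ships: int = 557
    n_voyages: int = 2700
    route_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    hub_fraction: float = 2 / 553
    hub_weight: float = 4.5
    tail_exponent: float = 0.6
    pest_country_fraction: float = 24 / 126
    pest_extra_countries: int = 12
    mean_leg_days: float = 7.9
    domestic_country: str = "AUS"
    domestic_intermediate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_foreign_ports", "n_domestic_ports", "n_countries", "n_ships", "n_voyages"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.hub_fraction < 1 or not 0 < self.pest_country_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.n_countries > self.n_foreign_ports:
            raise ValueError("cannot have more countries than foreign ports")
        lengths = sorted(self.route_length_dist)
        if lengths[0] < 2 or lengths[-1] > 11:
            raise ValueError("route lengths must lie in 2..11")
        if abs(sum(self.route_length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("route_length_dist must sum to 1")
        if self.n_hubs > self.n_foreign_ports:
            raise ValueError("more hubs than foreign ports")

    @property
    def n_hubs(self) -> int:
        return max(1, round(self.hub_fraction * self.n_foreign_ports))


def generate_network(
    config: SyntheticNetworkConfig,
) -> tuple[list[PortRecord], list[VoyageRoute], PestRange]:
    """Generate (registry, routes, pest range), fully reproducible from
    ``config.seed``.

    Ports are assigned to countries multinomially (each country gets at
    least one port). Intermediate calls are drawn from the hub-plus-Zipf
    popularity distribution without immediate repeats; the
    final call of every voyage is a domestic port. Every foreign port is
    guaranteed to appear on at least one route, so the route-observed
    network spans the whole registry. Leg durations are exponential with
    the configured mean. The pest range holds a fraction of the network's
    countries plus ``pest_extra_countries`` codes outside the registry
    (the organism's worldwide range exceeds the countries the network
    touches).
    """
    # independent substreams per component, so reconfiguring one aspect
    # (e.g. hub weights) does not reshuffle the draws of another
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(ss[0])  # structure: countries, hubs
    rng_routes = np.random.default_rng(ss[1])  # calls, ships, dates
    rng_legs = np.random.default_rng(ss[2])  # leg durations
    rng_pest = np.random.default_rng(ss[3])  # pest range

    countries = [f"C{k + 1:03d}" for k in range(config.n_countries)]
    foreign_ids = [f"F{k + 1:04d}" for k in range(config.n_foreign_ports)]
    domestic_ids = [f"D{k + 1:02d}" for k in range(config.n_domestic_ports)]

    # each country seeded with one port, the rest multinomial-uniform
    assignment = list(range(config.n_countries))
    assignment += list(
        rng.integers(0, config.n_countries, size=config.n_foreign_ports - config.n_countries)
    )
    registry = [
        PortRecord(port_id=pid, name=f"Port {pid}", country=countries[assignment[k]])
        for k, pid in enumerate(foreign_ids)
    ]
    registry += [
        PortRecord(
            port_id=pid, name=f"Port {pid}", country=config.domestic_country, is_domestic=True
        )
        for pid in domestic_ids
    ]

    # hub ports carry hub_weight times the busiest ordinary port; the rest
    # follow a Zipf tail so traffic (and risk) levels are genuinely separated
    order = rng.permutation(config.n_foreign_ports)
    hubs = order[: config.n_hubs]
    tail = order[config.n_hubs :]
    foreign_weights = np.empty(config.n_foreign_ports)
    foreign_weights[hubs] = config.hub_weight
    foreign_weights[tail] = (1.0 + np.arange(len(tail))) ** -config.tail_exponent
    foreign_p = foreign_weights / foreign_weights.sum()
    # mild skew across entry ports so destination rankings are non-trivial
    domestic_weights = 1.0 / np.sqrt(1.0 + np.arange(config.n_domestic_ports))
    domestic_p = domestic_weights / domestic_weights.sum()

    lengths_support = np.array(sorted(config.route_length_dist))
    lengths_p = np.array([config.route_length_dist[v] for v in lengths_support], dtype=float)

    start = np.datetime64("2002-01-01")
    n_days = int((np.datetime64("2008-01-01") - start) / np.timedelta64(1, "D"))

    routes: list[VoyageRoute] = []
    for v in range(config.n_voyages):
        length = int(rng_routes.choice(lengths_support, p=lengths_p))
        calls: list[str] = []
        for _ in range(length - 1):
            if config.domestic_intermediate and rng_routes.random() < 0.02:
                pool, p = domestic_ids, domestic_p
                nxt = str(rng_routes.choice(pool, p=p))
            else:
                nxt = foreign_ids[int(rng_routes.choice(config.n_foreign_ports, p=foreign_p))]
            while calls and nxt == calls[-1]:
                nxt = foreign_ids[int(rng_routes.choice(config.n_foreign_ports, p=foreign_p))]
            calls.append(nxt)
        calls.append(domestic_ids[int(rng_routes.choice(config.n_domestic_ports, p=domestic_p))])
        date = str(start + np.timedelta64(int(rng_routes.integers(0, n_days)), "D"))
        legs = list(np.round(rng_legs.exponential(config.mean_leg_days, size=length - 1), 3))
        routes.append(
            VoyageRoute(
                ship_id=f"S{int(rng_routes.integers(0, config.n_ships)) + 1:04d}",
                voyage_id=f"V{v + 1:05d}",
                arrival_date=date,
                calls=calls,
                leg_days=legs,
            )
        )

    _ensure_coverage(routes, foreign_ids, rng_routes)

    n_pest = max(1, round(config.pest_country_fraction * config.n_countries))
    # the organism's range covers the hub ports' countries, as in the
    # study setting this emulates (the top transit hubs lie inside the
    # infested region and dominate the origin rankings)
    hub_countries = {assignment[k] for k in hubs}
    others = [k for k in range(config.n_countries) if k not in hub_countries]
    n_extra = max(0, n_pest - len(hub_countries))
    pest_in = set(hub_countries) | set(rng_pest.choice(others, size=n_extra, replace=False))
    pest_countries = {countries[k] for k in pest_in}
    pest_countries |= {f"X{k + 1:02d}" for k in range(config.pest_extra_countries)}
    return registry, routes, PestRange(countries=pest_countries)


def _ensure_coverage(routes: list[VoyageRoute], foreign_ids: list[str], rng) -> None:
    """Swap rarely-used calls so every foreign port appears on some route."""
    occurrences: dict[str, int] = {p: 0 for p in foreign_ids}
    for r in routes:
        for c in r.calls:
            if c in occurrences:
                occurrences[c] += 1
    unused = [p for p, n in occurrences.items() if n == 0]
    long_routes = [r for r in routes if len(r.calls) >= 4]
    for port in unused:
        for _ in range(1000):
            r = long_routes[int(rng.integers(0, len(long_routes)))]
            pos = int(rng.integers(0, len(r.calls) - 1))  # never the domestic final call
            old = r.calls[pos]
            if occurrences.get(old, 0) < 2:
                continue
            neighbours = set()
            if pos > 0:
                neighbours.add(r.calls[pos - 1])
            if pos < len(r.calls) - 1:
                neighbours.add(r.calls[pos + 1])
            if port in neighbours:
                continue
            r.calls[pos] = port
            occurrences[old] -= 1
            occurrences[port] = occurrences.get(port, 0) + 1
            break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError(f"could not place port {port} on any route")


def write_dataset(
    registry: list[PortRecord],
    routes: list[VoyageRoute],
    pest_range: PestRange,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write routes.csv / ports.csv / pest_range.txt into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "routes": out_dir / "routes.csv",
        "ports": out_dir / "ports.csv",
        "pest_range": out_dir / "pest_range.txt",
    }
    write_routes(routes, paths["routes"])
    write_ports(registry, paths["ports"])
    write_pest_range(pest_range, paths["pest_range"])
    return paths


@dataclass
class KnownAnswerCase:
    """A tiny hand-solvable fixture with its exact answers attached.

    ``visit_probabilities`` maps (origin, destination) to the exact
    probability that the walk from origin ever visits the destination,
    under ``cap``. ``facts`` carries additional hand-derived statements
    (e.g. degree centralities, expected rank inversions).
    """

    case_id: str
    description: str
    registry: list[PortRecord]
    routes: list[VoyageRoute]
    pest_range: PestRange
    cap: float
    visit_probabilities: dict[tuple[str, str], float]
    facts: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        paths = write_dataset(self.registry, self.routes, self.pest_range, out_dir)
        manifest = {
            "case_id": self.case_id,
            "description": self.description,
            "cap": self.cap,
            "visit_probabilities": {
                f"{o}->{d}": h for (o, d), h in self.visit_probabilities.items()
            },
            "facts": self.facts,
        }
        paths["manifest"] = Path(out_dir) / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def _voyage(vid: int, calls: list[str]) -> VoyageRoute:
    return VoyageRoute(
        ship_id=f"S{vid:03d}", voyage_id=f"V{vid:03d}", arrival_date="2004-01-01", calls=calls
    )


def _twoport() -> KnownAnswerCase:
    registry = [
        PortRecord("X", "Port X", "PC"),
        PortRecord("Y", "Port Y", "AUS", is_domestic=True),
    ]
    return KnownAnswerCase(
        case_id="twoport",
        description="Single segment X->Y with p=0.9; walk from X reaches Y "
        "with probability 0.9.",
        registry=registry,
        routes=[_voyage(1, ["X", "Y"])],
        pest_range=PestRange({"PC"}),
        cap=0.9,
        visit_probabilities={("X", "Y"): 0.9},
    )


def _chain3() -> KnownAnswerCase:
    registry = [
        PortRecord("X", "Port X", "PC"),
        PortRecord("Y", "Port Y", "QC"),
        PortRecord("Z", "Port Z", "AUS", is_domestic=True),
    ]
    return KnownAnswerCase(
        case_id="chain3",
        description="Chain X->Y->Z with p=0.5 per leg: h(X->Y)=0.5, "
        "h(Y->Z)=0.5, h(X->Z)=0.25.",
        registry=registry,
        routes=[_voyage(1, ["X", "Y"]), _voyage(2, ["Y", "Z"])],
        pest_range=PestRange({"PC", "QC"}),
        cap=0.5,
        visit_probabilities={("X", "Y"): 0.5, ("X", "Z"): 0.25, ("Y", "Z"): 0.5},
    )


def _cycle2() -> KnownAnswerCase:
    registry = [
        PortRecord("X", "Port X", "PC"),
        PortRecord("Y", "Port Y", "AUS", is_domestic=True),
    ]
    return KnownAnswerCase(
        case_id="cycle2",
        description="Two-cycle X<->Y with p=0.5 each way: from X the first "
        "step either reaches Y or absorbs, so h(X->Y)=0.5.",
        registry=registry,
        routes=[_voyage(1, ["X", "Y"]), _voyage(2, ["Y", "X"])],
        pest_range=PestRange({"PC"}),
        cap=0.5,
        visit_probabilities={("X", "Y"): 0.5, ("Y", "X"): 0.5},
    )


def _corridor6() -> KnownAnswerCase:
    registry = [
        PortRecord("SRCA", "Source A", "CA"),
        PortRecord("SRCB", "Source B", "CB"),
        PortRecord("COR", "Corridor", "CC"),
        PortRecord("HUB", "Busy Hub", "CH"),
        PortRecord("REM", "Remote", "CR"),
        PortRecord("DST", "Entry", "AUS", is_domestic=True),
    ]
    routes = []
    vid = 0
    for _ in range(12):
        vid += 1
        routes.append(_voyage(vid, ["HUB", "REM"]))
        vid += 1
        routes.append(_voyage(vid, ["REM", "HUB"]))
    for _ in range(3):
        vid += 1
        routes.append(_voyage(vid, ["SRCA", "COR", "DST"]))
        vid += 1
        routes.append(_voyage(vid, ["SRCB", "COR", "DST"]))
    # cap 0.9 -> lam = 0.9/12: p(COR->DST)=0.45, p(SRC*->COR)=p(SRC*->DST)=0.225,
    # p(HUB->REM)=p(REM->HUB)=0.9; h(SRC*->DST)=0.225 + 0.225*0.45 = 0.32625
    return KnownAnswerCase(
        case_id="corridor6",
        description="A low-degree corridor port outranks a high-degree "
        "peripheral hub on pathway risk: HUB/REM carry heavy traffic that "
        "never leads to the entry port, while COR sits on the corridor "
        "feeding it.",
        registry=registry,
        routes=routes,
        pest_range=PestRange({"CA", "CB", "CC", "CH", "CR"}),
        cap=0.9,
        visit_probabilities={
            ("COR", "DST"): 0.45,
            ("SRCA", "DST"): 0.32625,
            ("SRCB", "DST"): 0.32625,
            ("HUB", "DST"): 0.0,
            ("REM", "DST"): 0.0,
            ("SRCA", "COR"): 0.225,
        },
        facts={
            "degree_centrality": {"HUB": 24, "REM": 24, "COR": 12, "SRCA": 3, "SRCB": 3, "DST": 6},
            "rank_inversion": {
                "higher_pathway_rank": "COR",
                "higher_degree": "HUB",
            },
        },
    )


KNOWN_CASES = {
    "twoport": _twoport,
    "chain3": _chain3,
    "cycle2": _cycle2,
    "corridor6": _corridor6,
}


def generate_known_answer_case(case_id: str) -> KnownAnswerCase:
    """Fetch a catalogue fixture by id; unknown ids list the catalogue."""
    try:
        return KNOWN_CASES[case_id]()
    except KeyError:
        raise KeyError(
            f"unknown case {case_id!r}; catalogue: {sorted(KNOWN_CASES)}"
        ) from None
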