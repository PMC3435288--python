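"""Shipping-network construction: route decomposition, segment counts, and
the scaled transmission matrix with its absorption column.

A voyage calling at ports ``A-B-C-D`` can move an infested container through
every ordered pair of calls (A-B, B-C, C-D and also A-C, B-D, A-D), because
the container may be loaded and unloaded at any pair of ports along the
route. Each voyage is therefore decomposed into its set of unique ordered
segments (i, j); the number of voyages whose decomposition contains (i, j)
is the segment count m_ij.

The per-vessel transmission rate over the pooled survey period is taken as
linear in traffic: p_ij = lam * m_ij, with the scaling coefficient lam
chosen so every row sum of the rate matrix stays below 1. The residual
1 - sum_j p_ij of each row is the absorption rate — the organism failing to
survive transit — appended as a terminal-state column. Only the relative
ordering of downstream arrival rates is meaningful, so a precise value of
lam is unnecessary; it is fixed by capping the largest row sum at ``cap``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import VoyageRoute, _registry_index

__all__ = [
    "SegmentCountMatrix",
    "TransmissionMatrix",
    "decompose_route",
    "count_segments",
    "build_transmission",
    "degree_centrality",
]

logger = logging.getLogger(__name__)

#: additive tolerance for the row-closure invariant rates + absorption = 1
CLOSURE_TOL = 1e-12


@dataclass
class SegmentCountMatrix:
    """Vessel counts m_ij per ordered port pair over a pooled period.

    ``counts[i, j]`` is the number of voyages that include port ``ports[i]``
    at an earlier call than ``ports[j]``. The network is directional:
    symmetry only by coincidence.
    """

    ports: list[str]
    counts: np.ndarray
    period_label: str = ""
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        y = len(self.ports)
        if self.counts.shape != (y, y):
            raise ValueError(f"counts shape {self.counts.shape} != ({y}, {y})")
        if np.any(self.counts < 0):
            raise ValueError("segment counts must be non-negative")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("segment count diagonal must be zero")
        self.index = {p: k for k, p in enumerate(self.ports)}

    @property
    def n_ports(self) -> int:
        return len(self.ports)

    def to_edge_frame(self) -> pd.DataFrame:
        """Edge-list representation with columns ``from,to,count``."""
        i, j = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "from": [self.ports[k] for k in i],
                "to": [self.ports[k] for k in j],
                "count": self.counts[i, j],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, index=False)


@dataclass
class TransmissionMatrix:
    """Scaled transmission rates p_ij = lam * m_ij plus the absorption column.

    Invariants: zero diagonal, 0 <= p_ij <= 1, every row sum of ``rates``
    strictly below 1, and ``rates.sum(axis=1) + absorption == 1`` within
    1e-12. Rows with no outgoing traffic have absorption exactly 1.
    """

    ports: list[str]
    rates: np.ndarray
    absorption: np.ndarray
    lam: float
    cap: float
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        self.index = {p: k for k, p in enumerate(self.ports)}
        self.validate()

    def validate(self) -> None:
        y = len(self.ports)
        if self.rates.shape != (y, y) or self.absorption.shape != (y,):
            raise ValueError("inconsistent matrix shapes")
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("transmission rates must lie in [0, 1]")
        if np.any(np.diag(self.rates) != 0):
            raise ValueError("transmission-rate diagonal must be zero")
        row_sums = self.rates.sum(axis=1)
        if np.any(row_sums >= 1):
            raise ValueError("every row sum of rates must be below 1")
        if np.any(np.abs(row_sums + self.absorption - 1.0) > CLOSURE_TOL):
            raise ValueError("rates row sum + absorption must equal 1")

    @property
    def n_ports(self) -> int:
        return len(self.ports)

    def row_sums(self) -> np.ndarray:
        return self.rates.sum(axis=1)

    def copy_with_rates(self, rates: np.ndarray) -> "TransmissionMatrix":
        """New matrix with the given rates and recomputed absorption."""
        rates = np.asarray(rates, dtype=float)
        absorption = 1.0 - rates.sum(axis=1)
        return TransmissionMatrix(
            ports=self.ports, rates=rates, absorption=absorption, lam=self.lam, cap=self.cap
        )

    def to_edge_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(self.rates)
        return pd.DataFrame(
            {
                "from": [self.ports[k] for k in i],
                "to": [self.ports[k] for k in j],
                "rate": self.rates[i, j],
            }
        )

    def to_csv(self, path: str | Path, absorption_path: str | Path | None = None) -> None:
        self.to_edge_frame().to_csv(path, index=False)
        if absorption_path is not None:
            pd.DataFrame({"port": self.ports, "absorption": self.absorption}).to_csv(
                absorption_path, index=False
            )


def decompose_route(route: VoyageRoute) -> set[tuple[str, str]]:
    """All unique ordered segments (i, j) realised by a voyage.

    Every pair with i at an earlier call position than j (and i != j) is
    included once, regardless of how many position pairs realise it. For a
    duplicate-free route of length L this yields exactly L(L-1)/2 segments.
    """
    calls = route.calls
    if len(calls) < 2:
        warnings.warn(f"route {route.ship_id!r} has fewer than two calls", stacklevel=2)
        return set()
    return {(calls[a], calls[b]) for a in range(len(calls)) for b in range(a + 1, len(calls)) if calls[a] != calls[b]}


def count_segments(
    routes: list[VoyageRoute],
    registry=None,
    *,
    dedupe: bool = True,
    period_label: str = "",
) -> SegmentCountMatrix:
    """Count vessels per ordered segment across all voyages.

    With ``dedupe`` (default), a voyage contributes at most 1 to any m_ij —
    counts are numbers of vessels, not of position pairs. The node list is
    the set of ports observed on routes, in sorted order; registry-only
    ports are excluded.
    """
    if not routes:
        raise ValueError("routes must be non-empty")
    if registry is not None:
        index = _registry_index(registry)
        for r in routes:
            for c in r.calls:
                if c not in index:
                    raise ValueError(f"route port {c!r} absent from registry")

    ports = sorted({c for r in routes for c in r.calls})
    pidx = {p: k for k, p in enumerate(ports)}
    counts = np.zeros((len(ports), len(ports)), dtype=np.int64)
    for r in routes:
        if dedupe:
            for i, j in decompose_route(r):
                counts[pidx[i], pidx[j]] += 1
        else:
            calls = r.calls
            for a in range(len(calls)):
                for b in range(a + 1, len(calls)):
                    if calls[a] != calls[b]:
                        counts[pidx[calls[a]], pidx[calls[b]]] += 1
    return SegmentCountMatrix(ports=ports, counts=counts, period_label=period_label)


def build_transmission(counts: SegmentCountMatrix, cap: float = 0.9) -> TransmissionMatrix:
    """Scale segment counts into a transmission matrix.

    ``lam = cap / max_i sum_j m_ij`` so the largest row sum of rates equals
    ``cap`` exactly and every absorption entry stays strictly positive.
    Rows with no outgoing counts get absorption 1.
    """
    if not 0 < cap < 1:
        raise ValueError(f"cap must lie in (0, 1), got {cap}")
    row_totals = counts.counts.sum(axis=1)
    max_total = row_totals.max() if len(row_totals) else 0
    if max_total == 0:
        raise ValueError("all-zero segment count matrix: no network")
    lam = cap / float(max_total)
    rates = lam * counts.counts.astype(float)
    absorption = 1.0 - rates.sum(axis=1)
    logger.info(
        "transmission matrix: Y=%d ports, lam=%.3g, cap=%.3g", counts.n_ports, lam, cap
    )
    return TransmissionMatrix(
        ports=list(counts.ports), rates=rates, absorption=absorption, lam=lam, cap=cap
    )


def degree_centrality(routes: list[VoyageRoute]) -> dict[str, int]:
    """Total ship arrivals plus departures at each port.

    An interior call contributes one arrival and one departure; the first
    call of a voyage a departure only, the last an arrival only — so each
    leg contributes exactly one arrival and one departure, and the total
    over all ports is 2 * (L - 1) summed over voyages.
    """
    deg: dict[str, int] = {}
    for r in routes:
        calls = r.calls
        for k, port in enumerate(calls):
            events = (1 if k > 0 else 0) + (1 if k < len(calls) - 1 else 0)
            deg[port] = deg.get(port, 0) + events
    return deg
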