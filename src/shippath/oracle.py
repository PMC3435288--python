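"""Exact visit probabilities for the absorbing walk, by linear solve.

For a substochastic transmission matrix (every row sum strictly below 1)
the probability h_i that a walk started at i ever visits a destination d
before absorption satisfies the first-passage system

    h_i = p_id + sum_{k != d} p_ik h_k        (i != d),

which is well posed because the spectral radius of the transient block is
below 1. This gives the ground truth against which the Monte-Carlo
estimates are checked. A brute-force path enumerator with an explicit
remainder bracket provides an independent cross-check for tiny networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .network import TransmissionMatrix

__all__ = [
    "VisitProbabilityMatrix",
    "visit_probability",
    "visit_probability_matrix",
    "enumerate_visit_probability",
]


@dataclass
class VisitProbabilityMatrix:
    """Exact visit probabilities h_ij, same index sets as an ArrivalRateTable.

    By the convention that an origin is never its own destination,
    ``h[i, i] = 0``.
    """

    origins: list[str]
    destinations: list[str]
    h: np.ndarray
    origin_index: dict[str, int] = field(init=False, repr=False)
    dest_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.origin_index = {p: k for k, p in enumerate(self.origins)}
        self.dest_index = {p: k for k, p in enumerate(self.destinations)}

    def h_for(self, origin: str, destination: str) -> float:
        return float(self.h[self.origin_index[origin], self.dest_index[destination]])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (o, d, self.h[i, j])
            for i, o in enumerate(self.origins)
            for j, d in enumerate(self.destinations)
        ]
        return pd.DataFrame(rows, columns=["origin", "destination", "h"])


def visit_probability(P: TransmissionMatrix, destination: str) -> np.ndarray:
    """Probability, for every node, of ever visiting ``destination``.

    Returns a vector over ``P.ports``; the destination's own entry is 0
    (an origin is not counted as its own destination). Dense solve — at a
    few hundred ports the system is trivial.
    """
    if destination not in P.index:
        raise KeyError(f"destination {destination!r} not in transmission matrix")
    d = P.index[destination]
    y = P.n_ports
    others = np.array([i for i in range(y) if i != d], dtype=int)
    Q = P.rates[np.ix_(others, others)]
    b = P.rates[others, d]
    A = np.eye(y - 1) - Q
    try:
        h_others = scipy.linalg.solve(A, b)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur for valid P
        raise ValueError(f"singular first-passage system for destination {destination!r}") from exc
    h = np.zeros(y)
    h[others] = h_others
    # numerical guard: probabilities live in [0, 1]
    return np.clip(h, 0.0, 1.0)


def visit_probability_matrix(P: TransmissionMatrix, origins) -> VisitProbabilityMatrix:
    """h_ij for each origin in ``origins`` and every destination — one
    linear solve per destination, vectorized over origins."""
    origins = sorted(origins)
    oidx = [P.index[o] for o in origins]
    h = np.zeros((len(origins), P.n_ports))
    for j in range(P.n_ports):
        col = visit_probability(P, P.ports[j])
        h[:, j] = col[oidx]
        for i, o in enumerate(origins):
            if P.index[o] == j:
                h[i, j] = 0.0
    return VisitProbabilityMatrix(origins=origins, destinations=list(P.ports), h=h)


def enumerate_visit_probability(
    P: TransmissionMatrix,
    origin: str,
    destination: str,
    max_len: int = 20,
) -> tuple[float, float]:
    """Brute-force first-visit probability by path enumeration.

    Sums the probability of every walk of length <= ``max_len`` whose
    first visit to ``destination`` is its final step, and separately
    accumulates the probability mass still alive (un-absorbed, destination
    not yet visited) at the cutoff. Returns ``(lower, remainder)``: the
    exact probability lies in ``[lower, lower + remainder]``. Intended for
    networks of a handful of nodes only — cost grows geometrically.
    """
    if origin not in P.index or destination not in P.index:
        raise KeyError("origin/destination not in transmission matrix")
    d = P.index[destination]
    rates = P.rates
    y = P.n_ports

    total = 0.0
    # frontier: probability mass per current state, among walks that have
    # not yet visited the destination and are not absorbed
    frontier = np.zeros(y)
    frontier[P.index[origin]] = 1.0
    for _ in range(max_len):
        new_frontier = np.zeros(y)
        for s in range(y):
            mass = frontier[s]
            if mass == 0.0:
                continue
            total += mass * rates[s, d]
            for t in range(y):
                if t != d and rates[s, t] > 0.0:
                    new_frontier[t] += mass * rates[s, t]
        frontier = new_frontier
        if frontier.sum() == 0.0:
            break
    return total, float(frontier.sum())
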