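"""Uncertainty analysis: perturb the transmission matrix and measure how
stable the risk rankings are.

Three scenarios mirror distinct kinds of ignorance about the network:

* ``multiplicative`` — each positive rate is redrawn uniformly within
  +/- ``mult_bound`` * p_ij of its value (mean-preserving measurement error;
  the support of the matrix, i.e. the network structure, is unchanged).
* ``additive`` — every off-diagonal entry, including zeros, gains an
  independent uniform variate from ``add_bounds`` (drifts the network
  toward a uniform random topology by adding new links).
* ``removal`` — a random fraction f ~ U[0, ``removal_max``] of the positive
  entries is deleted (uncertainty about connectivity itself).

Stability is summarised by ordinary least squares of perturbed rank on
baseline rank (average ranks for ties), reporting slope, R^2, t = slope/SE
and dof = n - 2.

Perturbed rows can sum past 1, which a probability row cannot; rows are
re-closed after perturbation (see :func:`close_rows`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import TransmissionMatrix
from .simulate import ArrivalRateTable, SimulationConfig, estimate_arrival_rates, origin_seed
from .summaries import RankingTable, rank_domestic_ports, rank_foreign_ports

__all__ = [
    "PerturbationConfig",
    "RankStabilityResult",
    "perturb_multiplicative",
    "perturb_additive",
    "perturb_remove",
    "close_rows",
    "rank_regression",
    "run_sensitivity",
    "results_frame",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("multiplicative", "additive", "removal")
REDRAW_MODES = ("per_realization", "per_replicate")
CLOSURE_MODES = ("rescale", "clip")


@dataclass
class PerturbationConfig:
    """Settings for one uncertainty scenario.

    Defaults are the standard bounds for this analysis: +/-0.3 p_ij
    multiplicative, additive U[0, 0.05], removal fraction U[0, 0.3].
    ``redraw`` chooses whether a fresh perturbed matrix is drawn for every
    walk (``per_realization``, the literal reading of redrawing at each
    pathway simulation event) or once per replicate (``per_replicate``,
    cheap enough for replicate experiments at scale).
    """

    scenario: str = "multiplicative"
    mult_bound: float = 0.3
    add_bounds: tuple[float, float] = (0.0, 0.05)
    removal_max: float = 0.3
    redraw: str = "per_realization"
    seed: int = 0
    n_replicates: int = 10
    row_closure: str = "rescale"
    closure_cap: float = 0.99
    node_removal: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0 <= self.mult_bound < 1:
            raise ValueError("mult_bound must lie in [0, 1)")
        lo, hi = self.add_bounds
        if not (0 <= lo <= hi <= 1):
            raise ValueError("add_bounds must be an interval within [0, 1]")
        if not 0 <= self.removal_max < 1:
            raise ValueError("removal_max must lie in [0, 1)")
        if self.redraw not in REDRAW_MODES:
            raise ValueError(f"redraw must be one of {REDRAW_MODES}")
        if self.row_closure not in CLOSURE_MODES:
            raise ValueError(f"row_closure must be one of {CLOSURE_MODES}")

    @property
    def is_identity(self) -> bool:
        """True when the scenario's magnitude is zero, so perturbation is
        the identity map and consumes no randomness."""
        if self.scenario == "multiplicative":
            return self.mult_bound == 0
        if self.scenario == "additive":
            return self.add_bounds == (0.0, 0.0)
        return self.removal_max == 0


@dataclass
class RankStabilityResult:
    """Rank-on-rank regression for one scenario replicate and entity kind."""

    entity_kind: str
    scenario: str
    replicate: int
    n: int
    slope: float
    r_squared: float
    t_statistic: float
    dof: int
    seed: int
    rank_pairs: pd.DataFrame  # columns: entity_id, baseline_rank, perturbed_rank


def close_rows(
    rates: np.ndarray, cap: float = 0.99, mode: str = "rescale"
) -> tuple[np.ndarray, np.ndarray]:
    """Re-close perturbed rows into valid probability rows.

    A row whose rate sum exceeds ``cap`` is brought back to it: ``rescale``
    multiplies the row by cap/sum (preserving within-row relative
    structure, which is what the rankings consume); ``clip`` subtracts the
    excess equally from the row's positive entries, flooring at zero.
    Absorption is the complement of the final row sum.
    """
    rates = np.clip(rates, 0.0, 1.0)
    np.fill_diagonal(rates, 0.0)
    sums = rates.sum(axis=1)
    over = sums > cap
    if np.any(over):
        if mode == "rescale":
            rates[over] *= (cap / sums[over])[:, None]
        else:  # clip
            for i in np.nonzero(over)[0]:
                row = rates[i]
                excess = row.sum() - cap
                pos = row > 0
                while excess > 1e-15 and pos.any():
                    cut = excess / pos.sum()
                    newrow = np.where(pos, np.maximum(row - cut, 0.0), row)
                    excess = newrow.sum() - cap
                    row = newrow
                    pos = row > 0
                rates[i] = row
    absorption = 1.0 - rates.sum(axis=1)
    return rates, absorption


def _closed(P: TransmissionMatrix, rates: np.ndarray, config: PerturbationConfig):
    rates, absorption = close_rows(rates, config.closure_cap, config.row_closure)
    return TransmissionMatrix(
        ports=P.ports, rates=rates, absorption=absorption, lam=P.lam, cap=P.cap
    )


def perturb_multiplicative(
    P: TransmissionMatrix,
    bound: float,
    rng: np.random.Generator,
    config: PerturbationConfig | None = None,
) -> TransmissionMatrix:
    """Redraw each positive rate uniformly in [p(1-bound), p(1+bound)].

    Draws are clipped to [0, 1]; zero entries stay zero, so the network's
    support is unchanged. A zero bound is the identity and draws nothing.
    """
    if not 0 <= bound < 1:
        raise ValueError("bound must lie in [0, 1)")
    if bound == 0:
        return P
    config = config or PerturbationConfig(scenario="multiplicative", mult_bound=bound)
    rates = P.rates.copy()
    mask = rates > 0
    lo = rates[mask] * (1 - bound)
    hi = rates[mask] * (1 + bound)
    rates[mask] = rng.uniform(lo, hi)
    return _closed(P, rates, config)


def perturb_additive(
    P: TransmissionMatrix,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    config: PerturbationConfig | None = None,
) -> TransmissionMatrix:
    """Add an independent U[bounds] variate to every off-diagonal entry
    (including zeros, so the support almost surely becomes complete)."""
    lo, hi = bounds
    if not (0 <= lo <= hi <= 1):
        raise ValueError("bounds must be an interval within [0, 1]")
    if lo == hi == 0:
        return P
    config = config or PerturbationConfig(scenario="additive", add_bounds=(lo, hi))
    y = P.n_ports
    rates = P.rates + rng.uniform(lo, hi, size=(y, y))
    np.fill_diagonal(rates, 0.0)
    return _closed(P, rates, config)


def perturb_remove(
    P: TransmissionMatrix,
    removal_max: float,
    rng: np.random.Generator,
    config: PerturbationConfig | None = None,
    node_removal: bool = False,
) -> TransmissionMatrix:
    """Delete a random portion of the network.

    A removal fraction f ~ U[0, removal_max] is drawn; then floor(f * E) of
    the E positive entries are chosen uniformly without replacement and set
    to zero. With ``node_removal`` whole nodes (rows and columns) are
    removed instead: floor(f * Y) nodes are zeroed.
    """
    if not 0 <= removal_max < 1:
        raise ValueError("removal_max must lie in [0, 1)")
    if removal_max == 0:
        return P
    config = config or PerturbationConfig(scenario="removal", removal_max=removal_max)
    f = rng.uniform(0.0, removal_max)
    rates = P.rates.copy()
    if node_removal:
        n_remove = int(f * P.n_ports)
        if n_remove:
            nodes = rng.choice(P.n_ports, size=n_remove, replace=False)
            rates[nodes, :] = 0.0
            rates[:, nodes] = 0.0
    else:
        i, j = np.nonzero(rates)
        n_remove = int(f * len(i))
        if n_remove:
            pick = rng.choice(len(i), size=n_remove, replace=False)
            rates[i[pick], j[pick]] = 0.0
    return _closed(P, rates, config)


def draw_perturbed(
    P: TransmissionMatrix, config: PerturbationConfig, rng: np.random.Generator
) -> TransmissionMatrix:
    """One perturbed matrix under the configured scenario."""
    if config.scenario == "multiplicative":
        return perturb_multiplicative(P, config.mult_bound, rng, config)
    if config.scenario == "additive":
        return perturb_additive(P, config.add_bounds, rng, config)
    return perturb_remove(P, config.removal_max, rng, config, config.node_removal)


def rank_regression(baseline: pd.Series, perturbed: pd.Series):
    """OLS of perturbed rank on baseline rank over a shared entity index.

    Returns ``(n, slope, r_squared, t_statistic, dof)``. A perfect fit has
    zero slope standard error; its t statistic is reported as +inf.
    """
    entities = baseline.index
    if len(entities) < 3:
        raise ValueError("rank regression needs at least 3 entities")
    x = baseline.to_numpy(dtype=float)
    y = perturbed.reindex(entities).to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate baseline ranks")
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t = np.inf if res.slope != 0 else 0.0
    else:
        t = res.slope / res.stderr
    return len(entities), float(res.slope), float(res.rvalue**2), float(t), len(entities) - 2


def _zero_magnitude(config: PerturbationConfig) -> PerturbationConfig:
    """The same scenario at zero magnitude (the paired-baseline config)."""
    return replace(config, mult_bound=0.0, add_bounds=(0.0, 0.0), removal_max=0.0)


def _replace_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    return SimulationConfig(
        K=sim.K, seed=seed, max_steps=sim.max_steps, count_mode=sim.count_mode
    )


def _estimate_removal_rb(
    P: TransmissionMatrix,
    origins,
    sim_config: SimulationConfig,
    removal_max: float,
) -> tuple[ArrivalRateTable, ArrivalRateTable]:
    """Coupled (baseline, removal-perturbed) estimates in one pass.

    The event-wise removal randomness — one removal fraction f ~
    U[0, removal_max] per walk, each traversed segment dead with
    probability f — integrates out analytically: a first visit reached
    after m segments survives with probability E_f[(1-f)^m]. Weighting the
    baseline walk's visits by those survival probabilities is an unbiased
    estimator of the perturbed arrival rate with strictly smaller variance
    than simulating the removal draws, and it shares every walk with the
    baseline estimate, so the pair isolates the removal effect exactly.
    The perturbed table's visit counts are expected (fractional) counts.
    """
    from ._kernels import csr_from_rates, removal_survival_weights, walk_counts_removal_rb

    origins = sorted(origins)
    row_ptr, col_idx, cdf = csr_from_rates(P.rates)
    weights = removal_survival_weights(removal_max, sim_config.max_steps)
    first_visit = sim_config.count_mode == "first_visit"
    J_base = np.zeros((len(origins), P.n_ports))
    J_rb = np.zeros((len(origins), P.n_ports))
    for i, origin in enumerate(origins):
        J_base[i], J_rb[i], _ = walk_counts_removal_rb(
            row_ptr,
            col_idx,
            cdf,
            P.index[origin],
            sim_config.K,
            sim_config.max_steps,
            origin_seed(sim_config.seed, origin),
            first_visit,
            weights,
        )
    base = ArrivalRateTable(
        origins=origins, destinations=list(P.ports), J=J_base, K=sim_config.K
    )
    pert = ArrivalRateTable(origins=origins, destinations=list(P.ports), J=J_rb, K=sim_config.K)
    return base, pert


def _estimate_per_realization(
    P: TransmissionMatrix,
    origins,
    sim_config: SimulationConfig,
    pert_config: PerturbationConfig,
    replicate_seed: int,
) -> ArrivalRateTable:
    """Arrival rates with the perturbation redrawn at every simulation event.

    Multiplicative and removal scenarios (with ``rescale`` row closure) run
    in a counter-based kernel that redraws the visited row's entries at
    every event — entrywise redraws are independent, so perturbing rows
    lazily at visit time is distributionally identical to perturbing the
    whole matrix per event (for removal, the per-walk fraction f is
    applied as per-entry Bernoulli(f) drops, the marginal of
    without-replacement removal). The walk draws depend only on the
    simulation seed, so a zero-magnitude run of the same kernel is the
    coupled baseline. The additive scenario (and ``clip`` closure) falls
    back to literally redrawing the full matrix before every walk, which
    is exact but only practical for small K and networks.
    """
    from ._kernels import csr_vals_from_rates, walk_counts_eventwise
    from .simulate import simulate_walk

    kernel_ok = (
        pert_config.scenario in ("multiplicative", "removal")
        and pert_config.row_closure == "rescale"
        and not pert_config.node_removal
    )
    if kernel_ok:
        origins = sorted(origins)
        row_ptr, col_idx, vals = csr_vals_from_rates(P.rates)
        first_visit = sim_config.count_mode == "first_visit"
        scenario_code = 1 if pert_config.scenario == "multiplicative" else 2
        magnitude = (
            pert_config.mult_bound
            if pert_config.scenario == "multiplicative"
            else pert_config.removal_max
        )
        J = np.zeros((len(origins), P.n_ports), dtype=np.int64)
        for i, origin in enumerate(origins):
            J[i], _ = walk_counts_eventwise(
                row_ptr,
                col_idx,
                vals,
                P.index[origin],
                sim_config.K,
                sim_config.max_steps,
                origin_seed(sim_config.seed, origin),
                origin_seed(replicate_seed, origin),
                first_visit,
                scenario_code,
                magnitude,
                pert_config.closure_cap,
            )
        return ArrivalRateTable(origins=origins, destinations=list(P.ports), J=J, K=sim_config.K)

    origins = sorted(origins)
    first_visit = sim_config.count_mode == "first_visit"
    J = np.zeros((len(origins), P.n_ports), dtype=np.int64)
    didx = {p: k for k, p in enumerate(P.ports)}
    for i, origin in enumerate(origins):
        walk_rng = np.random.default_rng(
            np.random.SeedSequence([origin_seed(sim_config.seed, origin), 1])
        )
        pert_rng = np.random.default_rng(
            np.random.SeedSequence([origin_seed(replicate_seed, origin), 2])
        )
        for _ in range(sim_config.K):
            P_k = draw_perturbed(P, pert_config, pert_rng)
            walk = simulate_walk(P_k, origin, walk_rng, sim_config.max_steps)
            visited = [p for p in walk if p != origin]
            if first_visit:
                visited = set(visited)
            for p in visited:
                J[i, didx[p]] += 1
    return ArrivalRateTable(origins=origins, destinations=list(P.ports), J=J, K=sim_config.K)


def _estimate_removal_coupled(
    P: TransmissionMatrix,
    origins,
    sim_config: SimulationConfig,
    removal_max: float,
    rep_seed: int,
) -> ArrivalRateTable:
    """Per-replicate removal estimate, maximally coupled to the baseline.

    Draws f ~ U[0, removal_max] and floor(f * E) entries exactly as
    :func:`perturb_remove` does, then runs walks in which removed entries
    keep their slice of the original row cdf but act as absorbing draws —
    the identical chain law, with the same per-origin random streams as
    the unperturbed estimate, so a walk deviates from its baseline twin
    only when it actually draws a removed segment.
    """
    from ._kernels import csr_from_rates, walk_counts_dead

    origins = sorted(origins)
    rng = np.random.default_rng(rep_seed)
    f = rng.uniform(0.0, removal_max)
    row_ptr, col_idx, cdf = csr_from_rates(P.rates)
    n_entries = len(col_idx)
    dead = np.zeros(n_entries, dtype=np.bool_)
    n_remove = int(f * n_entries)
    if n_remove:
        dead[rng.choice(n_entries, size=n_remove, replace=False)] = True
    first_visit = sim_config.count_mode == "first_visit"
    J = np.zeros((len(origins), P.n_ports), dtype=np.int64)
    for i, origin in enumerate(origins):
        seed = origin_seed(sim_config.seed, origin)
        J[i], _ = walk_counts_dead(
            row_ptr,
            col_idx,
            cdf,
            dead,
            P.index[origin],
            sim_config.K,
            sim_config.max_steps,
            seed,
            first_visit,
        )
    return ArrivalRateTable(origins=origins, destinations=list(P.ports), J=J, K=sim_config.K)


def run_sensitivity(
    P: TransmissionMatrix,
    origins,
    registry,
    sim_config: SimulationConfig,
    pert_config: PerturbationConfig,
    baseline: dict[str, RankingTable] | None = None,
) -> list[RankStabilityResult]:
    """Replicated perturbation experiment with rank-stability statistics.

    Common random numbers pair each perturbed run with its baseline so the
    regression isolates the perturbation effect rather than Monte-Carlo
    resampling noise. In ``per_replicate`` mode the baseline (supplied or
    computed once on the unperturbed matrix) shares the simulation seed
    with every perturbed replicate. In ``per_realization`` mode the
    baseline is recomputed per replicate seed by running the identical
    simulation at zero perturbation magnitude — the random stream consumes
    the same draws, so baseline and perturbed walks coincide until a
    perturbation actually diverts one. Either way a zero-magnitude
    scenario reproduces its baseline exactly, and the regression returns
    slope 1, R^2 1.

    Returns one :class:`RankStabilityResult` per (replicate, entity kind)
    for foreign ports (origins) and domestic ports.
    """
    if pert_config.redraw == "per_replicate":
        if baseline is None:
            base_table = estimate_arrival_rates(P, origins, sim_config)
            baseline = {
                "foreign_port": rank_foreign_ports(base_table, registry),
                "domestic_port": rank_domestic_ports(base_table, registry),
            }
        fixed_base_ranks = {kind: rt.ranks() for kind, rt in baseline.items()}
    else:
        fixed_base_ranks = None

    results: list[RankStabilityResult] = []
    for r in range(pert_config.n_replicates):
        rep_seed = int(
            np.random.SeedSequence([int(pert_config.seed), r]).generate_state(1)[0] % (2**31)
        )
        if pert_config.redraw == "per_realization":
            # paired design: each replicate draws its own walk paths and a
            # coupled zero-magnitude baseline on the identical draw grid
            path_seed = int(
                np.random.SeedSequence([int(sim_config.seed), 1, r]).generate_state(1)[0]
                % (2**31)
            )
            sim_r = _replace_seed(sim_config, path_seed)
            if (
                pert_config.scenario == "removal"
                and pert_config.row_closure == "rescale"
                and not pert_config.node_removal
            ):
                base_table, table = _estimate_removal_rb(
                    P, origins, sim_r, pert_config.removal_max
                )
            else:
                zero = _zero_magnitude(pert_config)
                base_table = _estimate_per_realization(P, origins, sim_r, zero, 0)
                if pert_config.is_identity:
                    table = base_table
                else:
                    table = _estimate_per_realization(P, origins, sim_r, pert_config, rep_seed)
            base_ranks = {
                "foreign_port": rank_foreign_ports(base_table, registry).ranks(),
                "domestic_port": rank_domestic_ports(base_table, registry).ranks(),
            }
        else:
            if pert_config.is_identity:
                # identity map: no perturbation randomness, same walk seed
                table = estimate_arrival_rates(P, origins, sim_config)
            elif pert_config.scenario == "removal" and not pert_config.node_removal:
                table = _estimate_removal_coupled(
                    P, origins, sim_config, pert_config.removal_max, rep_seed
                )
            else:
                rng = np.random.default_rng(rep_seed)
                P_r = draw_perturbed(P, pert_config, rng)
                table = estimate_arrival_rates(P_r, origins, sim_config)
            base_ranks = fixed_base_ranks
        rankings = {
            "foreign_port": rank_foreign_ports(table, registry),
            "domestic_port": rank_domestic_ports(table, registry),
        }
        for kind, rt in rankings.items():
            pert_ranks = rt.ranks()
            n, slope, r2, t, dof = rank_regression(base_ranks[kind], pert_ranks)
            pairs = pd.DataFrame(
                {
                    "entity_id": base_ranks[kind].index,
                    "baseline_rank": base_ranks[kind].to_numpy(),
                    "perturbed_rank": pert_ranks.reindex(base_ranks[kind].index).to_numpy(),
                }
            )
            results.append(
                RankStabilityResult(
                    entity_kind=kind,
                    scenario=pert_config.scenario,
                    replicate=r,
                    n=n,
                    slope=slope,
                    r_squared=r2,
                    t_statistic=t,
                    dof=dof,
                    seed=rep_seed,
                    rank_pairs=pairs,
                )
            )
    return results


def results_frame(results: list[RankStabilityResult]) -> pd.DataFrame:
    """Report table: ``entity_kind,scenario,n,slope,r_squared,t_statistic,dof,seed``."""
    return pd.DataFrame(
        [
            (
                res.entity_kind,
                res.scenario,
                res.replicate,
                res.n,
                res.slope,
                res.r_squared,
                res.t_statistic,
                res.dof,
                res.seed,
            )
            for res in results
        ],
        columns=[
            "entity_kind",
            "scenario",
            "replicate",
            "n",
            "slope",
            "r_squared",
            "t_statistic",
            "dof",
            "seed",
        ],
    )
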