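"""Numba-accelerated random-walk kernel over a CSR transmission matrix.

Falls back to a pure-Python implementation with identical semantics and an
identical random sequence when numba is unavailable (the fallback uses the
same MT19937 stream through ``numpy.random``), so results do not depend on
the backend.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


def csr_from_rates(rates: np.ndarray):
    """Per-row CSR arrays (row_ptr, col_idx, cdf) of the positive entries.

    ``cdf`` holds the within-row cumulative sums of the rates; the last
    value of a row is its total outgoing rate, so a uniform draw above it
    means absorption.
    """
    y = rates.shape[0]
    row_ptr = np.zeros(y + 1, dtype=np.int64)
    cols = []
    cdfs = []
    for i in range(y):
        (idx,) = np.nonzero(rates[i])
        row_ptr[i + 1] = row_ptr[i] + len(idx)
        cols.append(idx.astype(np.int64))
        cdfs.append(np.cumsum(rates[i, idx]))
    col_idx = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    cdf = np.concatenate(cdfs) if cdfs else np.zeros(0, dtype=np.float64)
    return row_ptr, col_idx, cdf


def csr_vals_from_rates(rates: np.ndarray):
    """Like :func:`csr_from_rates` but with raw rates instead of the cdf."""
    y = rates.shape[0]
    row_ptr = np.zeros(y + 1, dtype=np.int64)
    cols = []
    vals = []
    for i in range(y):
        (idx,) = np.nonzero(rates[i])
        row_ptr[i + 1] = row_ptr[i] + len(idx)
        cols.append(idx.astype(np.int64))
        vals.append(rates[i, idx])
    col_idx = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    val_arr = np.concatenate(vals) if vals else np.zeros(0, dtype=np.float64)
    return row_ptr, col_idx, val_arr


@njit(cache=True)
def _walk_counts(row_ptr, col_idx, cdf, origin, K, max_steps, seed, first_visit):
    """Run K walks from ``origin``; return (J, n_truncated).

    J[j] counts realizations that visited j (first-visit mode) or total
    visits to j (raw mode). The origin is never counted as its own
    destination. Walks end on an absorption draw, on a row with no outgoing
    rates, or after ``max_steps`` steps.
    """
    np.random.seed(seed)
    y = row_ptr.shape[0] - 1
    J = np.zeros(y, dtype=np.int64)
    last_walk = np.full(y, -1, dtype=np.int64)
    n_truncated = 0
    for k in range(K):
        state = origin
        steps = 0
        truncated = True
        while steps < max_steps:
            lo = row_ptr[state]
            hi = row_ptr[state + 1]
            if hi == lo:  # no outgoing paths
                truncated = False
                break
            u = np.random.random()
            if u >= cdf[hi - 1]:  # terminal state drawn
                truncated = False
                break
            a = lo
            b = hi - 1
            while a < b:
                mid = (a + b) // 2
                if cdf[mid] > u:
                    b = mid
                else:
                    a = mid + 1
            state = col_idx[a]
            if state != origin:
                if first_visit:
                    if last_walk[state] != k:
                        last_walk[state] = k
                        J[state] += 1
                else:
                    J[state] += 1
            steps += 1
        if truncated:
            n_truncated += 1
    return J, n_truncated


def _walk_counts_py(row_ptr, col_idx, cdf, origin, K, max_steps, seed, first_visit):
    """Pure-Python twin of :func:`_walk_counts` (same MT19937 sequence)."""
    np.random.seed(seed)
    y = row_ptr.shape[0] - 1
    J = np.zeros(y, dtype=np.int64)
    last_walk = np.full(y, -1, dtype=np.int64)
    n_truncated = 0
    for k in range(K):
        state = origin
        steps = 0
        truncated = True
        while steps < max_steps:
            lo, hi = row_ptr[state], row_ptr[state + 1]
            if hi == lo:
                truncated = False
                break
            u = np.random.random()
            if u >= cdf[hi - 1]:
                truncated = False
                break
            a = lo + int(np.searchsorted(cdf[lo:hi], u, side="right"))
            state = int(col_idx[a])
            if state != origin:
                if first_visit:
                    if last_walk[state] != k:
                        last_walk[state] = k
                        J[state] += 1
                else:
                    J[state] += 1
            steps += 1
        if truncated:
            n_truncated += 1
    return J, n_truncated


walk_counts = _walk_counts if HAVE_NUMBA else _walk_counts_py


@njit(cache=True)
def _walk_counts_dead(row_ptr, col_idx, cdf, dead, origin, K, max_steps, seed, first_visit):
    """:func:`_walk_counts` on a matrix with entries in ``dead`` removed.

    Removed entries keep their interval of the original row cdf but map to
    the terminal state, which is distributionally identical to deleting
    them (the lost rate mass becomes absorption — removal rows never need
    rescaling) while consuming exactly one uniform per step. With the same
    seed, a walk follows the unperturbed walk until it first draws a
    removed segment — a maximal coupling that lets rank-stability
    comparisons isolate the removal effect from resampling noise.
    """
    np.random.seed(seed)
    y = row_ptr.shape[0] - 1
    J = np.zeros(y, dtype=np.int64)
    last_walk = np.full(y, -1, dtype=np.int64)
    n_truncated = 0
    for k in range(K):
        state = origin
        steps = 0
        truncated = True
        while steps < max_steps:
            lo = row_ptr[state]
            hi = row_ptr[state + 1]
            if hi == lo:
                truncated = False
                break
            u = np.random.random()
            if u >= cdf[hi - 1]:
                truncated = False
                break
            a = lo
            b = hi - 1
            while a < b:
                mid = (a + b) // 2
                if cdf[mid] > u:
                    b = mid
                else:
                    a = mid + 1
            if dead[a]:  # removed segment: the pathway ends here
                truncated = False
                break
            state = col_idx[a]
            if state != origin:
                if first_visit:
                    if last_walk[state] != k:
                        last_walk[state] = k
                        J[state] += 1
                else:
                    J[state] += 1
            steps += 1
        if truncated:
            n_truncated += 1
    return J, n_truncated


walk_counts_dead = _walk_counts_dead


@njit(cache=True)
def _mix64(z):
    """splitmix64 finalizer: a well-mixed 64-bit hash of the input."""
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _u01(a, b, c, d):
    """Counter-based uniform in [0, 1): hash of four 64-bit coordinates."""
    h = _mix64(np.uint64(a))
    h = _mix64(h ^ np.uint64(b))
    h = _mix64(h ^ np.uint64(c))
    h = _mix64(h ^ np.uint64(d))
    return (h >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _walk_counts_eventwise(
    row_ptr,
    col_idx,
    vals,
    origin,
    K,
    max_steps,
    seed_u,
    seed_p,
    first_visit,
    scenario,  # 0 = none (baseline), 1 = multiplicative, 2 = removal
    magnitude,  # mult bound, or removal_max
    closure_cap,
):
    """Walks with the perturbation redrawn at every simulation event,
    driven by counter-based uniforms.

    Every uniform is a pure hash of (seed, walk, step, entry), so a
    baseline run (scenario 0) and a perturbed run with the same ``seed_u``
    share an identical grid of step draws and their walks coincide until a
    perturbation actually changes a transition — the coupling that lets
    rank-stability experiments isolate the perturbation effect from
    Monte-Carlo resampling noise. Perturbation draws use ``seed_p`` only,
    so replicates differ through the perturbation alone.

    Multiplicative: each positive entry of the visited row is redrawn
    uniformly in [p(1-b), p(1+b)] (clipped above at 1) at every visit;
    rows whose perturbed sum exceeds ``closure_cap`` are rescaled to it.
    Removal: a removal fraction f ~ U[0, magnitude] is drawn per walk and
    each entry is dropped for that walk with probability f (the marginal
    of removing floor(f*E) of the E entries without replacement); removal
    only shrinks row sums, and the lost mass becomes absorption.
    """
    y = row_ptr.shape[0] - 1
    J = np.zeros(y, dtype=np.int64)
    last_walk = np.full(y, -1, dtype=np.int64)
    n_truncated = 0
    max_nnz = 0
    for i in range(y):
        nnz = row_ptr[i + 1] - row_ptr[i]
        if nnz > max_nnz:
            max_nnz = nnz
    cum = np.empty(max_nnz, dtype=np.float64)
    for k in range(K):
        state = origin
        steps = 0
        truncated = True
        f = 0.0
        if scenario == 2:
            f = magnitude * _u01(seed_p, k, 0, 1)
        while steps < max_steps:
            lo = row_ptr[state]
            hi = row_ptr[state + 1]
            n = hi - lo
            if n == 0:
                truncated = False
                break
            s = 0.0
            for a in range(n):
                v = vals[lo + a]
                if scenario == 1 and magnitude > 0.0:
                    scale = 1.0 - magnitude + 2.0 * magnitude * _u01(seed_p, k, steps, lo + a + 2)
                    v *= scale
                    if v > 1.0:
                        v = 1.0
                elif scenario == 2 and f > 0.0:
                    if _u01(seed_p, k, lo + a, 0) < f:
                        v = 0.0
                s += v
                cum[a] = s
            if s == 0.0:
                truncated = False
                break
            u = _u01(seed_u, k, steps, 0)
            if s > closure_cap:
                # row rescaled to closure_cap: absorb with prob 1 - cap
                if u >= closure_cap:
                    truncated = False
                    break
                u = u * s / closure_cap
            elif u >= s:
                truncated = False
                break
            a = 0
            b = n - 1
            while a < b:
                mid = (a + b) // 2
                if cum[mid] > u:
                    b = mid
                else:
                    a = mid + 1
            state = col_idx[lo + a]
            if state != origin:
                if first_visit:
                    if last_walk[state] != k:
                        last_walk[state] = k
                        J[state] += 1
                else:
                    J[state] += 1
            steps += 1
        if truncated:
            n_truncated += 1
    return J, n_truncated
@njit(cache=True)
def _walk_counts_removal_rb(
    row_ptr, col_idx, cdf, origin, K, max_steps, seed_u, first_visit, weights
):
    """Coupled baseline and removal-averaged counts in one pass.

    For event-wise removal the thinning randomness integrates out exactly:
    a walk whose first visit to j traverses m segments survives the
    removal with probability E_f[(1-f)^m] (f drawn once per walk), so
    weighting each baseline first visit by ``weights[m]`` estimates the
    perturbed arrival rate without simulating any removal draws —
    unbiased for the same quantity, with strictly smaller variance, and
    perfectly coupled to the baseline count it is returned alongside.
    """
    y = row_ptr.shape[0] - 1
    J = np.zeros(y, dtype=np.float64)
    J_rb = np.zeros(y, dtype=np.float64)
    last_walk = np.full(y, -1, dtype=np.int64)
    n_truncated = 0
    for k in range(K):
        state = origin
        steps = 0
        truncated = True
        while steps < max_steps:
            lo = row_ptr[state]
            hi = row_ptr[state + 1]
            if hi == lo:
                truncated = False
                break
            u = _u01(seed_u, k, steps, 0)
            if u >= cdf[hi - 1]:
                truncated = False
                break
            a = lo
            b = hi - 1
            while a < b:
                mid = (a + b) // 2
                if cdf[mid] > u:
                    b = mid
                else:
                    a = mid + 1
            state = col_idx[a]
            if state != origin:
                if first_visit:
                    if last_walk[state] != k:
                        last_walk[state] = k
                        J[state] += 1.0
                        J_rb[state] += weights[steps + 1]
                else:
                    J[state] += 1.0
                    J_rb[state] += weights[steps + 1]
            steps += 1
        if truncated:
            n_truncated += 1
    return J, J_rb, n_truncated


walk_counts_eventwise = _walk_counts_eventwise
walk_counts_removal_rb = _walk_counts_removal_rb


def removal_survival_weights(removal_max: float, max_steps: int) -> np.ndarray:
    """E_{f~U[0,F]}[(1-f)^m] for m = 0..max_steps+1.

    The probability that a walk survives m segment traversals when each
    traversed segment has been removed with probability f, with one f per
    walk. F = 0 gives all-ones (no removal).
    """
    m = np.arange(max_steps + 2, dtype=np.float64)
    if removal_max == 0:
        return np.ones_like(m)
    F = removal_max
    return (1.0 - (1.0 - F) ** (m + 1)) / (F * (m + 1))
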