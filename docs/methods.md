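# Methods

## The model

`shippath` models the arrival of an invasive organism (the motivating case
is the Khapra beetle, *Trogoderma granarium*, a stored-grain pest able to
survive long container transits in diapause) at a destination country's
ports of entry, carried by the international container-shipping network.
The data are vessel route histories: for each ship arrival at a domestic
port, the ordered list of up to ten prior ports of call plus the
destination, pooled over a multi-year period.

**Route decomposition.** A container on a voyage calling at A–B–C–D may be
loaded at any call and unloaded at any later call, so the voyage can move
an infested container through every ordered pair of calls: A–B, B–C, C–D
and also A–C, B–D, A–D. Each voyage is decomposed into its set of unique
ordered segments (i, j); the segment count m_ij is the number of voyages
whose decomposition contains (i, j). A voyage contributes at most once to
any m_ij (counts are vessels, not position pairs); the alternative
position-pair counting is available behind `dedupe=False`.

**Transmission matrix.** Per-segment transmission is assumed linear in
traffic: p_ij = λ·m_ij, with zero diagonal. Only the relative ordering of
the downstream arrival rates matters, so λ needs no absolute calibration;
it is fixed by capping the largest row sum of the rate matrix at `cap`
(default 0.9), i.e. λ = cap / max_i Σ_j m_ij. Each row is closed with an
absorption entry 1 − Σ_j p_ij, the probability the organism fails to
survive that step; rows with no outgoing traffic absorb with probability
one. The cap keeps every row strictly substochastic, so the chain is
absorbing and all first-passage quantities are well defined.

**Pathway simulation.** From every origin port inside the organism's
range (the non-domestic registry ports in range countries that appear on
at least one route), K independent first-order Markov walks are run: at
each step the next port is drawn from the current row's categorical
distribution over destinations plus the terminal state; a walk ends on a
terminal draw, on a row with no outgoing paths, or at `max_steps`
(default 10,000 — with row sums ≤ 0.9 the chance of reaching it is below
0.9^10000; a truncated walk is logged and counted with the visits it
made). The arrival rate φ_ij = J_ij / K, where J_ij counts realizations
from i that visited j at least once ("first-visit" counting, keeping
φ ≤ 1 and interpretable as a per-pathway arrival rate; raw visit counting
is available via `count_mode="visits"`). An origin is never counted as
its own destination. The reference value of K for headline runs is 2×10⁶
per origin; validation suites use 10⁵ and the perturbation experiments
10⁴, sizes at which each check carries its stated statistical bound.

The walk engine is a numba kernel over a CSR representation of the rate
matrix with per-origin substreams derived from (seed, origin id), so
results are bit-reproducible and independent of origin ordering. A
pure-Python fallback with the identical random sequence runs when numba
is unavailable.

**Analytic oracle.** The probability h_ij that a walk from i ever visits
j before absorption satisfies h_i = p_ij + Σ_{k≠j} p_ik h_k, a dense
linear system solved once per destination (Y ≈ 550 makes this trivial).
Sub-stochasticity guarantees a spectral radius below one, hence a unique
solution. The oracle is the ground truth for the Monte-Carlo tests: every
φ̂ must land within 4·sqrt(h(1−h)/K) of h cell-wise. An exhaustive path
enumerator (all walks to length 20, with the still-alive probability mass
reported as an explicit remainder bracket) cross-checks the linear solve
itself on the hand-sized fixtures.

**Risk summaries.** Per-pair rates aggregate by the complementary product
`combined = 1 − Π(1 − φ)` — the chance that at least one independent
source pathway delivers. It is bounded below by max(φ), above by
min(1, Σφ), and reduces to Σφ as rates become small. The published
summary tables this package's consistency checks target are only
arithmetically coherent under this reading: the top per-origin rates into
the highest-risk entry port already *sum* above the printed overall rate,
while a literal product would be many orders of magnitude below it; the
complement-product reproduces the printed overall rates as tight lower
bounds from the truncated printed top-ten lists. Relative rates divide an
entity's combined rate by the mean over the full entity set of the
ranking at hand (each published table prints its own mean); rankings are
by descending rate with lexicographic tie-break, and rank statistics use
average ranks for ties. Degree centrality (arrivals plus departures per
port; first call of a voyage counts as a departure only, the last as an
arrival only, so every leg contributes exactly one of each) is reported
alongside as the traffic-volume benchmark that pathway rank can invert —
the `corridor6` fixture encodes the canonical counterexample of a
low-degree port on a heavy corridor outranking a high-degree peripheral
hub.

## Sensitivity analysis

Three uncertainty scenarios perturb the transmission matrix:

* **multiplicative** — every positive p_ij redrawn uniformly in
  [p(1−b), p(1+b)], b = 0.3 by default: mean-preserving measurement error
  that never alters the network's support;
* **additive** — an independent U[0, 0.05] variate added to every
  off-diagonal entry including zeros: drift toward a uniform random
  topology that creates new links;
* **removal** — a fraction f ~ U[0, 0.3] of the positive entries deleted:
  uncertainty about connectivity itself.

Perturbed rows can sum past one; they are re-closed (`row_closure`):
`rescale` multiplies an offending row back to `closure_cap` (default
0.99), preserving the within-row relative structure that the rankings
consume; `clip` subtracts the excess equally from the row's positive
entries. Additive noise of U[0, 0.05] across ~550 columns makes raw row
sums far exceed one, so re-closure is unavoidable; rescale is the
default because rankings depend only on relative structure.

Stability is measured by ordinary least squares of perturbed rank on
baseline rank per entity kind (foreign origin ports and domestic entry
ports), reporting slope, R², t = slope/SE and dof = n − 2.

**Redraw policy and variance control.** `redraw="per_realization"` (the
default) redraws the perturbation at every simulation event, matching the
procedure the model was designed around; `"per_replicate"` draws one
perturbed matrix per replicate and is the cheap alternative. At desk-scale
K the dominant obstacle to measuring rank stability is Monte-Carlo
resampling noise, not the perturbation: two independent unperturbed runs
at K = 10⁴ already disagree on mid-list ranks. The experiments therefore
use common random numbers throughout. In per-replicate mode the baseline
shares the simulation seed with every perturbed replicate. In
per-realization mode the kernel draws every uniform as a counter-based
hash of (seed, walk, step, entry); a zero-magnitude run of the same
kernel consumes the identical draw grid, so baseline and perturbed walks
coincide until a perturbation actually diverts one, and the regression
isolates the perturbation effect. For the removal scenario the
per-realization thinning randomness is integrated out exactly: a walk
whose first visit to j traverses m segments survives with probability
E_f[(1−f)^m] = (1−(1−F)^{m+1})/(F(m+1)), so weighting baseline visits by
these survival factors gives an unbiased estimate of the perturbed
arrival rate with strictly smaller variance than simulating the removal
draws (the perturbed table then carries expected, fractional visit
counts). Zero-magnitude perturbations short-circuit to the identity, so
the degenerate limit returns slope 1 and R² = 1 exactly under every
scenario and redraw mode.

An additive per-realization step costs O(Y) per walk step (every
off-diagonal entry of the visited row is perturbed) with ~100-step walks
after re-closure at 0.99, so the replicate experiment runs the additive
scenario per-replicate; its mean R² sits far below the multiplicative
scenario's under either policy, so the qualitative ordering is
insensitive to this choice. The replicate experiment runs 10 replicates
at K = 10⁴ by default.

## The synthetic generator

The vessel-movement records this analysis was designed around are
proprietary (Lloyd's Maritime Intelligence Unit extracts), so the
generator emulates their documented structure: 553 foreign ports in 126
countries feeding 30 domestic entry ports, 557 ships, ~25,507 port-call
events pooled over 2002–2007, route histories of 2–11 calls (ten prior
ports plus the destination, most records carrying a full history), mean
leg duration 7.9 days (exponential), and a pest range of 36 countries of
which 24 lie on the network. Port popularity is a pair of super-hubs at
`hub_weight` (4.5) times the busiest ordinary port plus a Zipf tail
(exponent 0.6) over the rest. This reproduces the observables that drive
the analysis: the hubs carry roughly Busan/Kaohsiung's share of call
events, the hub-to-third-port degree-centrality ratio is ~4, and traffic
— hence risk — levels are genuinely separated across ports, which is
what makes top-list ranks resolvable at experiment-scale K. A strictly
two-tier hub/non-hub model was rejected because it makes all non-hub
ports exchangeable: their arrival rates are then statistically identical
and mid-list rankings are pure noise at any feasible K. The hub ports'
countries are always inside the generated pest range, mirroring the
situation the model addresses (the dominant transit hubs lie inside the
infested region and top the origin rankings). Randomness is split into
independent substreams (structure, routes, leg durations, pest range) so
reconfiguring one component does not reshuffle the draws of another;
the same seed yields byte-identical output files.

What the generator does **not** emulate: geography (no coordinates, no
distance-dependent traffic), seasonality, vessel-capacity heterogeneity,
correlated route structure (liner services repeating fixed rotations),
and container transshipment behaviour at hubs. Passing tests therefore
demonstrate that the pipeline's machinery is correct and stable on data
with the right marginal structure — not that its rankings are accurate
for any particular real shipping network.

## Numerical choices and degenerate inputs

* Row closure of the transmission matrix holds to 1e−12
  (`rates.sum(axis=1) + absorption = 1`); the builder guarantees it by
  construction and validation enforces it.
* Consecutive duplicate calls within a voyage are collapsed with a
  warning (a zero-length leg is impossible); a voyage reduced below two
  distinct calls is rejected.
* Ports present in the registry but absent from every route are excluded
  from the matrix: the node set is what the routes observe.
* Ties in rankings break lexicographically by entity id for deterministic
  output files; rank statistics use average ranks.
* `combine_rates` accumulates Σ log1p(−φ) with exact (fsum) summation, so
  combining hundreds of small rates loses no precision; any rate equal to
  1 short-circuits to 1.
* The first-passage solve clips its solution into [0, 1] to absorb
  last-ulp negativity; the enumeration cross-check verifies the solve to
  1e−9 wherever its remainder bracket has died out.
* Walks are capped at `max_steps` = 10,000; truncations are logged and
  counted with the visits made (none occur in practice at cap 0.9).

## Known limitations

* The linearity of p_ij in traffic and the first-order (memoryless) walk
  are modelling assumptions inherited from the framework, not tested
  facts; in particular containers at non-hub ports tend to stay on one
  vessel, which a first-order chain ignores.
* φ values are meaningful only relative to one another (they scale with
  λ); the package deliberately reports relative rates and ranks rather
  than absolute arrival risks.
* The additive scenario's results depend on the row-closure rule, since
  literal additive noise violates row stochasticity; both closure modes
  are provided but `rescale` is the analysed default.
* Country-level rates treat a country's ports as independent sources,
  as the complement-product requires; correlated port traffic within a
  country is not modelled.
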