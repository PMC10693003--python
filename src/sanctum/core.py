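"""Stochastic per-generation dynamics of the metapopulation model.

Each patch holds a fixed number of spaces; a space is empty or occupied by a
single agent of one of two heritable types, *wild* (antibiotic-sensitive)
and *mutant* (resistant).  One generation consists of three phases:

1. **Death** — an agent of type ``t`` is removed with probability
   ``min(1, Z_t * A)``, where ``Z_t`` is its first-order kill coefficient
   and ``A`` the antibiotic concentration.
2. **Birth** — an agent of type ``t`` proposes one offspring with
   probability ``R_t * empty / K``: reproduction is space-limited, as in
   discrete logistic growth.  Survival and reproduction within a generation
   are evaluated simultaneously from the generation-start state, so a
   single type equilibrates at the effective carrying capacity
   ``(1 - Z*A/R) * K`` in expectation.  Offspring fill spaces left free
   after the death draw; if proposals outnumber free spaces, the survivors
   are chosen without replacement from the pooled proposals (hypergeometric
   across types), which is unbiased between types.
3. **Migration** — each agent independently crosses the outgoing edge
   ``(i, j)`` of weight ``w`` with probability ``m * w``, so edge weights
   are absolute dispersal propensities and the expected migrant flux along
   an edge is ``m * w * N_i``.  Moves are resolved one at a time in a
   uniformly random global order, and a move into a patch with no empty
   space is aborted (the agent stays).  Migration conserves the total
   agent count exactly.

Because agents are exchangeable within a type, the state is stored as
per-patch ``(wild, mutant)`` counts and the phases use binomial /
multinomial / hypergeometric draws; this is distributionally identical to
iterating over individual agents and is what makes large replicate sweeps
cheap.

An optional periodic bottleneck (binomial thinning of every patch) mimics
the serial-transfer dilution of an evolution experiment and lets one dial
up genetic drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .graphs import INTRO_LABEL, MetapopGraph

__all__ = [
    "TypeParams",
    "SimParams",
    "SimState",
    "Trajectory",
    "steps_for_days",
    "effective_carrying_capacity",
    "calibrate_wild_kill_rate",
    "seed_state",
    "death_phase",
    "birth_phase",
    "migration_phase",
    "bottleneck",
    "step",
    "run",
    "run_ensemble",
]

WILD, MUTANT = 0, 1


@dataclass(frozen=True)
class TypeParams:
    """Demographic parameters of one heritable type.

    ``birth_rate`` (R) is the per-generation reproduction propensity at a
    completely empty patch, in [0, 1].  ``kill_rate`` (Z) is the
    first-order antibiotic kill coefficient, >= 0; the per-generation death
    probability is ``min(1, Z * A)``.
    """

    birth_rate: float
    kill_rate: float

    def __post_init__(self):
        if not 0.0 <= self.birth_rate <= 1.0:
            raise InvalidParameterError("birth_rate must be in [0, 1]")
        if self.kill_rate < 0.0:
            raise InvalidParameterError("kill_rate must be >= 0")

    def death_prob(self, antibiotic: float) -> float:
        return min(1.0, self.kill_rate * antibiotic)


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of one simulation run."""

    wild: TypeParams
    mutant: TypeParams
    antibiotic: float = 0.0
    migration_prob: float = 0.0
    n_steps: int = 240
    founders: int = 1000
    founder_mutants: int = 1
    intro_node: str | None = None  # defaults to P3, else first non-hub node
    doubling_time_min: float = 30.0
    bottleneck_every: int | None = None
    bottleneck_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.antibiotic < 0:
            raise InvalidParameterError("antibiotic must be >= 0")
        if not 0.0 <= self.migration_prob <= 1.0:
            raise InvalidParameterError("migration_prob must be in [0, 1]")
        if self.n_steps < 0:
            raise InvalidParameterError("n_steps must be >= 0")
        if self.founders < 0 or self.founder_mutants < 0:
            raise InvalidParameterError("founder counts must be >= 0")
        if self.founder_mutants > self.founders:
            raise InvalidParameterError("founder_mutants cannot exceed founders")
        if self.bottleneck_fraction is not None and not (
            0.0 < self.bottleneck_fraction <= 1.0
        ):
            raise InvalidParameterError("bottleneck_fraction must be in (0, 1]")
        if self.bottleneck_every is not None and self.bottleneck_every < 1:
            raise InvalidParameterError("bottleneck_every must be >= 1")

    def type_params(self, which: int) -> TypeParams:
        return self.wild if which == WILD else self.mutant


@dataclass
class SimState:
    """Per-patch (wild, mutant) counts plus the current step index."""

    counts: np.ndarray  # shape (n_nodes, 2), int64
    step: int = 0

    def copy(self) -> "SimState":
        return SimState(self.counts.copy(), self.step)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_wild(self) -> int:
        return int(self.counts[:, WILD].sum())

    @property
    def total_mutant(self) -> int:
        return int(self.counts[:, MUTANT].sum())


@dataclass
class Trajectory:
    """Per-step, per-patch record of one replicate run."""

    node_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_steps + 1, n_nodes, 2), int64
    seed: int | None = None
    params: SimParams | None = None

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0] - 1

    def totals(self) -> np.ndarray:
        """Total agents per step."""
        return self.counts.sum(axis=(1, 2))

    def mutant_totals(self) -> np.ndarray:
        return self.counts[:, :, MUTANT].sum(axis=1)

    def metapop_fractions(self) -> np.ndarray:
        """Metapopulation mutant fraction per step; NaN where extinct."""
        tot = self.totals().astype(float)
        mut = self.mutant_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mut / np.where(tot > 0, tot, 1.0), np.nan)
        return frac

    def node_fractions(self) -> np.ndarray:
        """Per-patch mutant fraction per step; NaN where the patch is empty."""
        tot = self.counts.sum(axis=2).astype(float)
        mut = self.counts[:, :, MUTANT].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, mut / np.where(tot > 0, tot, 1.0), np.nan)

    def fixation_step(self) -> int | None:
        """First step with zero wild agents and at least one mutant."""
        wild = self.counts[:, :, WILD].sum(axis=1)
        mut = self.mutant_totals()
        hits = np.nonzero((wild == 0) & (mut > 0))[0]
        return int(hits[0]) if hits.size else None

    def extinction_step(self) -> int | None:
        """First step with no agents at all, if any."""
        hits = np.nonzero(self.totals() == 0)[0]
        return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# scalar helpers


def steps_for_days(days: float, doubling_time_min: float = 30.0) -> int:
    """Generations equivalent to ``days`` of experiment.

    One simulation step is one generation of length ``doubling_time_min``
    minutes, so ``steps = round(days * 24 * 60 / doubling_time_min)``;
    five days at a 30-minute generation time is 240 steps.
    """
    if days <= 0 or doubling_time_min <= 0:
        raise InvalidParameterError("days and doubling time must be positive")
    return round(days * 24.0 * 60.0 / doubling_time_min)


def effective_carrying_capacity(Z: float, A: float, R: float, K: int) -> float:
    """Antibiotic-reduced equilibrium occupancy ``(1 - Z*A/R) * K``.

    Zero when ``Z*A/R >= 1``: at antibiotic concentrations at or above the
    normalized resistance ``R/Z`` the type cannot persist.
    """
    if R <= 0:
        raise InvalidParameterError("R must be > 0")
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    if Z < 0 or A < 0:
        raise InvalidParameterError("Z and A must be >= 0")
    return max(0.0, (1.0 - Z * A / R) * K)


def calibrate_wild_kill_rate(
    mutant: TypeParams, antibiotic: float, advantage: float = 0.2
) -> float:
    """Wild-type kill coefficient giving the mutant a chosen low-density edge.

    At low density the per-generation growth factor of type ``t`` is
    ``(1 - Z_t*A) * (1 + R_t)``.  With both types sharing the birth rate R,
    the wild kill coefficient that leaves the mutant a relative advantage
    ``1 + advantage`` is ``Z_w = (1 - (1 - Z_m*A)/(1+advantage)) / A``.
    """
    if antibiotic <= 0:
        raise InvalidParameterError("calibration needs antibiotic > 0")
    if advantage <= -1:
        raise InvalidParameterError("advantage must be > -1")
    s_mut = 1.0 - mutant.death_prob(antibiotic)
    s_wild = s_mut / (1.0 + advantage)
    if not 0.0 <= s_wild <= 1.0:
        raise InvalidParameterError("advantage not achievable at this dose")
    return (1.0 - s_wild) / antibiotic


# ---------------------------------------------------------------------------
# seeding


def default_intro_node(graph: MetapopGraph) -> str:
    """P3 if present and not the hub, else the first non-hub node."""
    hub = graph.hub_id
    ids = graph.node_ids
    if INTRO_LABEL in ids and INTRO_LABEL != hub:
        return INTRO_LABEL
    for i in ids:
        if i != hub:
            return i
    raise InvalidParameterError("graph has no non-hub node to seed mutants in")


def seed_state(
    graph: MetapopGraph, params: SimParams, rng: np.random.Generator
) -> SimState:
    """Scatter founders uniformly over all spaces; place mutants in one patch.

    Exactly ``params.founders`` agents are placed uniformly at random over
    the empty spaces of the whole metapopulation (multivariate
    hypergeometric over patches).  ``params.founder_mutants`` of them are
    then made mutant, all in the designated introduction patch (a non-hub
    patch, ``P3`` by default); if the uniform scatter left that patch short,
    the deficit is drawn from the other patches so the mutant count is
    exact.
    """
    caps = np.asarray(graph.capacities, dtype=np.int64)
    n = len(caps)
    if params.founders > caps.sum():
        raise InvalidParameterError("founders exceed total capacity")
    counts = np.zeros((n, 2), dtype=np.int64)
    if params.founders == 0:
        return SimState(counts, 0)
    placed = rng.multivariate_hypergeometric(caps, params.founders)
    counts[:, WILD] = placed
    if params.founder_mutants > 0:
        intro = params.intro_node or default_intro_node(graph)
        if intro == graph.hub_id:
            raise InvalidParameterError("mutants must be introduced outside the hub")
        i = graph.index(intro)
        deficit = params.founder_mutants - int(counts[i, WILD])
        while deficit > 0:
            # top up the introduction patch from the fullest other patch
            if counts[i].sum() >= caps[i]:
                raise InvalidParameterError(
                    "introduction patch cannot hold all founder mutants"
                )
            j = int(np.argmax(np.where(np.arange(n) == i, -1, counts[:, WILD])))
            if counts[j, WILD] <= 0:
                raise InvalidParameterError("not enough founders to convert")
            counts[j, WILD] -= 1
            counts[i, WILD] += 1
            deficit -= 1
        counts[i, WILD] -= params.founder_mutants
        counts[i, MUTANT] += params.founder_mutants
    return SimState(counts, 0)


# ---------------------------------------------------------------------------
# phases


def _binomial(rng: np.random.Generator, n: int, p: float) -> int:
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return int(n)
    return int(rng.binomial(n, p))


def death_phase(
    state: SimState, params: SimParams, rng: np.random.Generator
) -> SimState:
    """Binomial survival of each type in each patch (standalone operator)."""
    new = state.copy()
    for t in (WILD, MUTANT):
        p_surv = 1.0 - params.type_params(t).death_prob(params.antibiotic)
        for i in range(new.counts.shape[0]):
            new.counts[i, t] = _binomial(rng, int(state.counts[i, t]), p_surv)
    return new


def birth_phase(
    state: SimState,
    graph: MetapopGraph,
    params: SimParams,
    rng: np.random.Generator,
    *,
    parents: np.ndarray | None = None,
    rate_empty: np.ndarray | None = None,
) -> SimState:
    """Space-limited reproduction (standalone operator).

    Each agent of type ``t`` proposes an offspring with probability
    ``R_t * empty / K``; proposals beyond the free spaces are thinned
    without replacement across types.  ``parents`` and ``rate_empty``
    let :func:`step` evaluate the proposals on the generation-start state
    while filling the spaces actually free after deaths; called without
    them, the operator uses the given state for both.
    """
    caps = np.asarray(graph.capacities, dtype=np.int64)
    new = state.copy()
    cur_empty = caps - state.counts.sum(axis=1)
    if parents is None:
        parents = state.counts
    if rate_empty is None:
        rate_empty = cur_empty
    for i in range(len(caps)):
        K = int(caps[i])
        free = int(cur_empty[i])
        if free <= 0:
            continue
        frac_empty = max(0.0, float(rate_empty[i])) / K
        props = [
            _binomial(
                rng,
                int(parents[i, t]),
                params.type_params(t).birth_rate * frac_empty,
            )
            for t in (WILD, MUTANT)
        ]
        total = props[0] + props[1]
        if total > free:
            kept_m = int(rng.hypergeometric(props[MUTANT], props[WILD], free))
            props = [free - kept_m, kept_m]
        new.counts[i, WILD] += props[WILD]
        new.counts[i, MUTANT] += props[MUTANT]
    return new


def migration_phase(
    state: SimState,
    graph: MetapopGraph,
    params: SimParams,
    rng: np.random.Generator,
) -> SimState:
    """Per-agent dispersal with random-order resolution and full-patch abort.

    Edge weights are absolute dispersal propensities: an agent crosses
    edge ``(i, j)`` of weight ``w`` with probability ``m * w`` per
    generation (capped so the total never exceeds 1), so the expected
    migrant flux along an edge from a patch holding ``N`` agents is
    ``m * w * N`` and weight asymmetries between the two directions of a
    route are dynamically meaningful.  Conditional on migrating, the
    destination follows the normalised outgoing-weight distribution.
    """
    m = params.migration_prob
    new = state.copy()
    if m <= 0.0:
        return new
    ids = graph.node_ids
    caps = np.asarray(graph.capacities, dtype=np.int64)
    dests = []
    for i, nid in enumerate(ids):
        dist = graph.outgoing_distribution(nid)
        if dist:
            labels = sorted(dist)
            dests.append(
                (np.array([graph.index(d) for d in labels]),
                 np.array([dist[d] for d in labels]),
                 min(1.0, m * graph.outgoing_weight(nid)))
            )
        else:
            dests.append(None)

    moves = []  # (src, dst, type) per migrating agent
    for i in range(len(ids)):
        if dests[i] is None:
            continue  # no outgoing route: agents here never move
        idx, probs, p_mig = dests[i]
        for t in (WILD, MUTANT):
            k = _binomial(rng, int(state.counts[i, t]), p_mig)
            if k == 0:
                continue
            split = rng.multinomial(k, probs)
            for j, cnt in zip(idx, split):
                moves.extend([(i, int(j), t)] * int(cnt))
    if not moves:
        return new
    order = rng.permutation(len(moves))
    occ = new.counts.sum(axis=1)
    for o in order:
        src, dst, t = moves[o]
        if occ[dst] < caps[dst]:
            new.counts[src, t] -= 1
            new.counts[dst, t] += 1
            occ[src] -= 1
            occ[dst] += 1
    return new


def bottleneck(
    state: SimState, fraction: float, rng: np.random.Generator
) -> SimState:
    """Binomial thinning of every patch and type (serial-transfer dilution)."""
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError("bottleneck fraction must be in (0, 1]")
    new = state.copy()
    if fraction >= 1.0:
        return new
    for i in range(new.counts.shape[0]):
        for t in (WILD, MUTANT):
            new.counts[i, t] = _binomial(rng, int(state.counts[i, t]), fraction)
    return new


def step(
    state: SimState,
    graph: MetapopGraph,
    params: SimParams,
    rng: np.random.Generator,
) -> SimState:
    """One generation: death, birth, migration (and scheduled bottleneck).

    Death and birth draws are both taken on the generation-start counts
    (simultaneous evaluation), with offspring placed into the spaces free
    after the deaths; migration then moves the resulting agents.
    """
    start_counts = state.counts.copy()
    caps = np.asarray(graph.capacities, dtype=np.int64)
    after_death = death_phase(state, params, rng)
    after_birth = birth_phase(
        after_death,
        graph,
        params,
        rng,
        parents=start_counts,
        rate_empty=caps - start_counts.sum(axis=1),
    )
    new = migration_phase(after_birth, graph, params, rng)
    if (
        params.bottleneck_every is not None
        and params.bottleneck_fraction is not None
        and (state.step + 1) % params.bottleneck_every == 0
    ):
        new = bottleneck(new, params.bottleneck_fraction, rng)
    new.step = state.step + 1
    return new


# ---------------------------------------------------------------------------
# runs


def run(
    graph: MetapopGraph,
    params: SimParams,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate one replicate and record every step, including the seed state."""
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = params.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    state = seed_state(graph, params, rng)
    n = len(graph.nodes)
    rec = np.zeros((params.n_steps + 1, n, 2), dtype=np.int64)
    rec[0] = state.counts
    for k in range(params.n_steps):
        state = step(state, graph, params, rng)
        rec[k + 1] = state.counts
    return Trajectory(graph.node_ids, rec, seed=seed, params=params)


def run_ensemble(
    graph: MetapopGraph,
    params: SimParams,
    n_replicates: int,
    base_seed: int,
) -> list[Trajectory]:
    """Independent replicates seeded ``base_seed + i`` for replicate ``i``."""
    out = []
    for i in range(n_replicates):
        p = replace(params, seed=base_seed + i)
        out.append(run(graph, p))
    return out


def run_to_absorption(
    graph: MetapopGraph,
    params: SimParams,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> tuple[str, SimState, int]:
    """Step until one type is extinct (or the whole system is empty).

    Returns ``(outcome, state, steps)`` with outcome one of
    ``"mutant_fix"``, ``"wild_fix"``, ``"extinct"``.  Raises if absorption
    has not happened after ``max_steps`` generations.
    """
    state = seed_state(graph, params, rng)
    for k in range(max_steps + 1):
        w, mu = state.total_wild, state.total_mutant
        if w == 0 and mu == 0:
            return "extinct", state, k
        if w == 0:
            return "mutant_fix", state, k
        if mu == 0:
            return "wild_fix", state, k
        state = step(state, graph, params, rng)
    raise RuntimeError(f"no absorption within {max_steps} steps")
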