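"""Exact absorption analysis of tiny instances by full Markov enumeration.

For metapopulations small enough to enumerate (a handful of spaces per
patch), the generation dynamics define a finite Markov chain on per-patch
``(wild, mutant)`` count vectors.  This module builds the exact transition
kernels of the death, birth and migration phases under the same
distributional rules as the simulator — binomial deaths and birth
proposals evaluated simultaneously on the generation-start state,
hypergeometric thinning of oversubscribed births, and migration resolved
as the exact mixture over per-agent destination draws and uniformly random
processing orders with full-patch rejection — and solves the standard
first-step linear system for absorption.

Absorbing classes are defined by first hitting:

* ``mutant_fix`` — no wild agents and at least one mutant (the mutant
  population may still fluctuate afterwards);
* ``wild_fix``  — no mutants and at least one wild agent;
* ``extinct``   — no agents at all.

The solve is the ground truth against which the stochastic simulator is
validated; exactness is its entire point, so the migration kernel
enumerates every migrant configuration and processing order rather than
approximating.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SimParams, WILD, MUTANT
from .errors import StateSpaceTooLargeError, StructuralError
from .graphs import MetapopGraph

__all__ = [
    "StateSpace",
    "FixationTable",
    "enumerate_states",
    "phase_kernel",
    "fixation_probabilities",
]

DEFAULT_STATE_LIMIT = 200_000


def _node_states(K: int) -> list[tuple[int, int]]:
    return [(w, m) for w in range(K + 1) for m in range(K + 1 - w)]


@dataclass
class StateSpace:
    """Dense bijective indexing of all feasible count vectors."""

    graph: MetapopGraph
    per_node: list  # list of per-node (w, m) state lists
    states: list  # global states: tuples of per-node (w, m)
    index: dict  # global state -> dense integer

    @property
    def size(self) -> int:
        return len(self.states)

    def wild_total(self, s) -> int:
        return sum(wm[0] for wm in s)

    def mutant_total(self, s) -> int:
        return sum(wm[1] for wm in s)


def enumerate_states(
    graph: MetapopGraph, limit: int = DEFAULT_STATE_LIMIT
) -> StateSpace:
    """Enumerate every feasible state; refuse if the space exceeds ``limit``."""
    per_node = [_node_states(K) for K in graph.capacities]
    size = math.prod(len(s) for s in per_node)
    if size > limit:
        raise StateSpaceTooLargeError(size, limit)
    states = [tuple(s) for s in itertools.product(*per_node)]
    index = {s: i for i, s in enumerate(states)}
    return StateSpace(graph, per_node, states, index)


# ---------------------------------------------------------------------------
# exact per-node distributions


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Exact-ish binomial pmf over 0..n."""
    if p <= 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p >= 1.0:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    ks = np.arange(n + 1)
    return np.array(
        [math.comb(n, int(k)) * p**int(k) * (1 - p) ** int(n - k) for k in ks]
    )


def _hypergeom_pmf(ngood: int, nbad: int, nsample: int) -> dict[int, float]:
    """P(k good drawn) for k in the feasible range."""
    total = ngood + nbad
    denom = math.comb(total, nsample)
    out = {}
    for k in range(max(0, nsample - nbad), min(ngood, nsample) + 1):
        out[k] = math.comb(ngood, k) * math.comb(nbad, nsample - k) / denom
    return out


def _node_death_dist(wm, params: SimParams) -> dict:
    """Standalone death phase on one patch: independent binomial survival."""
    w, m = wm
    pw = 1.0 - params.wild.death_prob(params.antibiotic)
    pm = 1.0 - params.mutant.death_prob(params.antibiotic)
    dist = {}
    pmf_w = _binom_pmf(w, pw)
    pmf_m = _binom_pmf(m, pm)
    for sw in range(w + 1):
        for sm in range(m + 1):
            p = pmf_w[sw] * pmf_m[sm]
            if p > 0:
                dist[(sw, sm)] = dist.get((sw, sm), 0.0) + p
    return dist


def _births_into(
    free: int, w_par: int, m_par: int, pb_w: float, pb_m: float
) -> dict[tuple[int, int], float]:
    """Distribution of (wild, mutant) offspring placed into ``free`` spaces."""
    dist: dict[tuple[int, int], float] = {}
    pmf_bw = _binom_pmf(w_par, pb_w)
    pmf_bm = _binom_pmf(m_par, pb_m)
    for bw in range(w_par + 1):
        for bm in range(m_par + 1):
            p = pmf_bw[bw] * pmf_bm[bm]
            if p <= 0:
                continue
            if bw + bm <= free:
                dist[(bw, bm)] = dist.get((bw, bm), 0.0) + p
            else:
                for kept_m, ph in _hypergeom_pmf(bm, bw, free).items():
                    key = (free - kept_m, kept_m)
                    dist[key] = dist.get(key, 0.0) + p * ph
    return dist


def _node_birth_dist(wm, K: int, params: SimParams) -> dict:
    """Standalone birth phase on one patch (rates from the patch as given)."""
    w, m = wm
    free = K - w - m
    if free <= 0:
        return {(w, m): 1.0}
    frac = free / K
    births = _births_into(
        free, w, m, params.wild.birth_rate * frac, params.mutant.birth_rate * frac
    )
    return {(w + bw, m + bm): p for (bw, bm), p in births.items()}


def _node_demography_dist(wm, K: int, params: SimParams) -> dict:
    """One generation of death + birth evaluated on the start state."""
    w, m = wm
    e0 = K - w - m
    frac = e0 / K
    pb_w = params.wild.birth_rate * frac
    pb_m = params.mutant.birth_rate * frac
    dist: dict[tuple[int, int], float] = {}
    for (sw, sm), pd_ in _node_death_dist(wm, params).items():
        free = K - sw - sm
        for (bw, bm), pb in _births_into(free, w, m, pb_w, pb_m).items():
            key = (sw + bw, sm + bm)
            dist[key] = dist.get(key, 0.0) + pd_ * pb
    return dist


def _product_kernel(space: StateSpace, node_dist) -> np.ndarray:
    """Global kernel from independent per-node distributions."""
    n = space.size
    P = np.zeros((n, n))
    caps = space.graph.capacities
    for i, s in enumerate(space.states):
        dists = [node_dist(s[j], caps[j]) for j in range(len(caps))]
        for combo in itertools.product(*(d.items() for d in dists)):
            p = 1.0
            tgt = []
            for wm, q in combo:
                p *= q
                tgt.append(wm)
            if p > 0:
                P[i, space.index[tuple(tgt)]] += p
    return P


# ---------------------------------------------------------------------------
# exact migration kernel


def _migration_dist(space: StateSpace, s, params: SimParams) -> dict:
    """Exact one-phase migration distribution from global state ``s``.

    Mixture over (i) binomial migrant counts per patch and type, (ii)
    independent destination draws per migrant, (iii) uniformly random
    processing orders with full-patch rejection.
    """
    graph = space.graph
    m = params.migration_prob
    caps = graph.capacities
    ids = graph.node_ids
    n = len(ids)
    if m <= 0.0:
        return {s: 1.0}
    # destination distributions and per-agent migration probabilities by node
    dests, p_migs = [], []
    for nid in ids:
        d = graph.outgoing_distribution(nid)
        dests.append(
            sorted(((graph.index(k), p) for k, p in d.items())) if d else None
        )
        p_migs.append(min(1.0, m * graph.outgoing_weight(nid)) if d else 0.0)

    # enumerate migrant counts per (node, type)
    sources = []  # (node, type, count_available)
    for i in range(n):
        if dests[i] is None:
            continue
        for t in (WILD, MUTANT):
            c = s[i][t]
            if c > 0:
                sources.append((i, t, c))

    result: dict[tuple, float] = {}

    def add(state_tuple, p):
        result[state_tuple] = result.get(state_tuple, 0.0) + p

    def resolve(events, counts, p_branch):
        """Average over uniformly random processing orders of ``events``."""
        memo: dict = {}

        def rec(ev, cnts):
            total = sum(c for _, c in ev)
            if total == 0:
                return {cnts: 1.0}
            key = (ev, cnts)
            if key in memo:
                return memo[key]
            out: dict = {}
            occ = [sum(wm) for wm in cnts]
            for k, ((src, dst, t), c) in enumerate(ev):
                w_pick = c / total
                nxt = list(ev)
                if c == 1:
                    nxt.pop(k)
                else:
                    nxt[k] = ((src, dst, t), c - 1)
                if occ[dst] < caps[dst]:
                    new = [list(wm) for wm in cnts]
                    new[src][t] -= 1
                    new[dst][t] += 1
                    ncnts = tuple(tuple(wm) for wm in new)
                else:
                    ncnts = cnts
                for fs, fp in rec(tuple(nxt), ncnts).items():
                    out[fs] = out.get(fs, 0.0) + w_pick * fp
            memo[key] = out
            return out

        for fs, fp in rec(events, counts).items():
            add(fs, p_branch * fp)

    def enum_destinations(src_idx, events, p_branch, migrant_counts):
        if src_idx == len(sources):
            resolve(tuple(sorted(events.items())), s, p_branch)
            return
        i, t, _ = sources[src_idx]
        k = migrant_counts[src_idx]
        if k == 0:
            enum_destinations(src_idx + 1, events, p_branch, migrant_counts)
            return
        dst_list = dests[i]

        # compositions of k migrants over destinations with multinomial
        # weight k! / prod(k_d!) * prod(p_d^k_d)
        def comp2(rem, di, cur, pc, used_fact):
            if di == len(dst_list):
                if rem != 0:
                    return
                coeff = math.factorial(k) / used_fact
                enum_destinations(
                    src_idx + 1, {**events, **cur}, p_branch * pc * coeff,
                    migrant_counts,
                )
                return
            j, pj = dst_list[di]
            top = rem if di < len(dst_list) - 1 else rem
            for took in range(top + 1):
                if di == len(dst_list) - 1 and took != rem:
                    continue
                cur2 = dict(cur)
                if took:
                    cur2[(i, j, t)] = cur2.get((i, j, t), 0) + took
                comp2(
                    rem - took,
                    di + 1,
                    cur2,
                    pc * pj**took,
                    used_fact * math.factorial(took),
                )

        comp2(k, 0, {}, 1.0, 1.0)

    # enumerate binomial migrant counts over all sources
    ranges = [range(c + 1) for (_, _, c) in sources]
    for migrant_counts in itertools.product(*ranges) if sources else [()]:
        p = 1.0
        for (i, t, c), k in zip(sources, migrant_counts):
            pm = p_migs[i]
            p *= math.comb(c, k) * pm**k * (1 - pm) ** (c - k)
        if p > 0:
            enum_destinations(0, {}, p, migrant_counts)

    return result


# ---------------------------------------------------------------------------
# public kernels and solve


def phase_kernel(
    space: StateSpace, phase: str, params: SimParams
) -> np.ndarray:
    """Exact row-stochastic transition matrix of one phase.

    ``phase`` is one of ``death``, ``birth``, ``migration``, ``demography``
    (the simultaneous death+birth used by the generation step) or ``step``
    (demography followed by migration — the one-generation kernel).
    """
    if phase == "death":
        return _product_kernel(
            space, lambda wm, K: _node_death_dist(wm, params)
        )
    if phase == "birth":
        return _product_kernel(
            space, lambda wm, K: _node_birth_dist(wm, K, params)
        )
    if phase == "demography":
        return _product_kernel(
            space, lambda wm, K: _node_demography_dist(wm, K, params)
        )
    if phase == "migration":
        n = space.size
        P = np.zeros((n, n))
        for i, s in enumerate(space.states):
            for tgt, p in _migration_dist(space, s, params).items():
                P[i, space.index[tgt]] += p
        return P
    if phase == "step":
        return phase_kernel(space, "demography", params) @ phase_kernel(
            space, "migration", params
        )
    raise ValueError(f"unknown phase {phase!r}")


@dataclass
class FixationTable:
    """Exact first-hit absorption probabilities for every state."""

    space: StateSpace
    p_mutant_fix: np.ndarray
    p_wild_fix: np.ndarray
    p_extinct: np.ndarray
    expected_steps: np.ndarray

    def for_state(self, state) -> dict:
        i = self.space.index[tuple(tuple(wm) for wm in state)]
        return {
            "p_mutant_fix": float(self.p_mutant_fix[i]),
            "p_wild_fix": float(self.p_wild_fix[i]),
            "p_extinct": float(self.p_extinct[i]),
            "expected_steps": float(self.expected_steps[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [str(s) for s in self.space.states],
                "p_mutant_fix": self.p_mutant_fix,
                "p_wild_fix": self.p_wild_fix,
                "p_extinct": self.p_extinct,
                "expected_steps": self.expected_steps,
            }
        )


def classify_states(space: StateSpace) -> dict[str, np.ndarray]:
    """Boolean masks for the transient set and the three absorbing classes."""
    w = np.array([space.wild_total(s) for s in space.states])
    m = np.array([space.mutant_total(s) for s in space.states])
    return {
        "transient": (w > 0) & (m > 0),
        "mutant_fix": (w == 0) & (m > 0),
        "wild_fix": (w > 0) & (m == 0),
        "extinct": (w == 0) & (m == 0),
    }


def fixation_probabilities(
    space: StateSpace, params: SimParams, kernel: np.ndarray | None = None
) -> FixationTable:
    """Solve the first-step equations for absorption from every state.

    States already inside an absorbing class get probability 1 for their
    class and zero expected steps (first hit is immediate).
    """
    if kernel is None:
        kernel = phase_kernel(space, "step", params)
    masks = classify_states(space)
    n = space.size
    p_mut = np.zeros(n)
    p_wld = np.zeros(n)
    p_ext = np.zeros(n)
    steps = np.zeros(n)
    p_mut[masks["mutant_fix"]] = 1.0
    p_wld[masks["wild_fix"]] = 1.0
    p_ext[masks["extinct"]] = 1.0
    tr = np.nonzero(masks["transient"])[0]
    if tr.size:
        Q = kernel[np.ix_(tr, tr)]
        A = np.eye(tr.size) - Q
        r_mut = kernel[np.ix_(tr, np.nonzero(masks["mutant_fix"])[0])].sum(axis=1)
        r_wld = kernel[np.ix_(tr, np.nonzero(masks["wild_fix"])[0])].sum(axis=1)
        r_ext = kernel[np.ix_(tr, np.nonzero(masks["extinct"])[0])].sum(axis=1)
        try:
            sol = np.linalg.solve(A, np.column_stack([r_mut, r_wld, r_ext, np.ones(tr.size)]))
        except np.linalg.LinAlgError as exc:
            raise StructuralError(
                "absorption system is singular: no absorbing class reachable"
            ) from exc
        p_mut[tr], p_wld[tr], p_ext[tr], steps[tr] = (
            sol[:, 0],
            sol[:, 1],
            sol[:, 2],
            sol[:, 3],
        )
    total = p_mut + p_wld + p_ext
    if np.any(np.abs(total - 1.0) > 1e-8):
        raise StructuralError(
            "absorption probabilities do not sum to 1; chain may not absorb"
        )
    return FixationTable(space, p_mut, p_wld, p_ext, steps)
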