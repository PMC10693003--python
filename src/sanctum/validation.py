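"""Side-by-side validation of the stochastic simulator against the exact oracle.

For instances small enough to enumerate, the absorption probabilities of
the simulator's Markov chain can be computed exactly; running the
simulator many times from the same start state and comparing the
empirical absorption frequencies against the exact values (within three
binomial standard errors) is the strongest end-to-end correctness check
the package has.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SimParams, SimState, step
from .graphs import MetapopGraph
from .oracle import enumerate_states, fixation_probabilities

__all__ = ["OracleCheckReport", "simulate_absorptions", "oracle_check"]

OUTCOMES = ("mutant_fix", "wild_fix", "extinct")


@dataclass
class OracleCheckReport:
    """Exact vs empirical absorption frequencies for one start state."""

    start_state: tuple
    n_runs: int
    exact: dict  # outcome -> probability
    empirical: dict  # outcome -> frequency
    se: dict  # outcome -> binomial SE of the empirical frequency
    deviations: dict  # outcome -> |empirical - exact| in SE units (inf if SE=0)
    passed: bool

    def summary_lines(self) -> list[str]:
        lines = [f"start state {self.start_state}, {self.n_runs} runs"]
        for o in OUTCOMES:
            lines.append(
                f"  {o:11s} exact={self.exact[o]:.6f} "
                f"empirical={self.empirical[o]:.6f} "
                f"se={self.se[o]:.6f} "
                f"{'ok' if self.deviations[o] <= 3.0 else 'DEVIATES'}"
            )
        lines.append("PASS" if self.passed else "FAIL")
        return lines


def _classify(state: SimState) -> str | None:
    w, m = state.total_wild, state.total_mutant
    if w == 0 and m == 0:
        return "extinct"
    if w == 0:
        return "mutant_fix"
    if m == 0:
        return "wild_fix"
    return None


def simulate_absorptions(
    graph: MetapopGraph,
    params: SimParams,
    start_state,
    n_runs: int,
    base_seed: int,
    max_steps: int = 100_000,
) -> dict:
    """Absorption outcome frequencies over ``n_runs`` independent runs."""
    counts = dict.fromkeys(OUTCOMES, 0)
    start = np.array([list(wm) for wm in start_state], dtype=np.int64)
    for i in range(n_runs):
        rng = np.random.default_rng(base_seed + i)
        state = SimState(start.copy(), 0)
        outcome = _classify(state)
        k = 0
        while outcome is None:
            if k >= max_steps:
                raise RuntimeError(f"run {i}: no absorption in {max_steps} steps")
            state = step(state, graph, params, rng)
            k += 1
            outcome = _classify(state)
        counts[outcome] += 1
    return {o: counts[o] / n_runs for o in OUTCOMES}


def oracle_check(
    graph: MetapopGraph,
    params: SimParams,
    start_state,
    n_runs: int = 10_000,
    base_seed: int = 0,
    empirical: dict | None = None,
    state_limit: int | None = None,
) -> OracleCheckReport:
    """Compare exact absorption probabilities with simulated frequencies.

    ``empirical`` overrides the simulation (used for negative controls);
    the check passes when every outcome frequency lies within three
    binomial standard errors of its exact probability (exact probabilities
    of 0 or 1 must be matched with slack one count).
    """
    kwargs = {} if state_limit is None else {"limit": state_limit}
    space = enumerate_states(graph, **kwargs)
    table = fixation_probabilities(space, params)
    exact_all = table.for_state(start_state)
    exact = {o: exact_all[f"p_{o}"] for o in OUTCOMES}
    if empirical is None:
        empirical = simulate_absorptions(
            graph, params, start_state, n_runs, base_seed
        )
    se, dev = {}, {}
    passed = True
    for o in OUTCOMES:
        p = exact[o]
        se[o] = math.sqrt(p * (1.0 - p) / n_runs)
        gap = abs(empirical[o] - p)
        if se[o] > 0:
            dev[o] = gap / se[o]
            ok = dev[o] <= 3.0
        else:
            # degenerate probability: allow at most one stray count
            dev[o] = math.inf if gap > 0 else 0.0
            ok = gap <= 1.0 / n_runs
        passed = passed and ok
    return OracleCheckReport(
        start_state=tuple(tuple(wm) for wm in start_state),
        n_runs=n_runs,
        exact=exact,
        empirical=empirical,
        se=se,
        deviations=dev,
        passed=passed,
    )
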