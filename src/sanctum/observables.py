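"""Summary statistics over trajectories and replicate ensembles.

The central observable is the metapopulation mutant fraction — total
mutants over total agents — tracked per generation and averaged across
replicate instantiations.  Derived diagnostics:

* time-to-majority: the first generation at which the mutant reaches at
  least 50% of the metapopulation (threshold configurable);
* the amplification curve: the per-step difference between the mean
  fractions of a star ensemble and a matched well-mixed ensemble, which is
  positive at intermediate steps under transient amplification;
* the per-patch spread order: the sequence in which patches first reach a
  mutant-fraction threshold, used to test hub-first spread;
* expected migrants per edge per step at the mutant's effective carrying
  capacity, ``m * K * (1 - A / (R/Z))`` — the quantity whose magnitude
  (of order one) marks the amplification regime.

Replicates whose metapopulation goes extinct have an undefined fraction;
they are dropped from the ensemble mean from the extinction step onward
and counted separately, rather than imputed as zero, so extinction is not
conflated with wild-type fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trajectory, SimState
from .errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedFractionError,
)

__all__ = [
    "EnsembleSummary",
    "metapop_fraction",
    "time_to_majority",
    "ensemble_average",
    "expected_migrants",
    "migration_for_expected_migrants",
    "migrant_headcount",
    "amplification_curve",
    "per_node_spread_order",
]


def metapop_fraction(state: SimState) -> float:
    """Total mutants / total agents; undefined for an empty metapopulation."""
    total = state.counts.sum()
    if total <= 0:
        raise UndefinedFractionError("metapopulation is extinct")
    return float(state.counts[:, 1].sum() / total)


def time_to_majority(traj: Trajectory, threshold: float = 0.5) -> int | None:
    """Smallest step with metapopulation mutant fraction >= ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError("threshold must be in (0, 1]")
    frac = traj.metapop_fractions()
    hits = np.nonzero(frac >= threshold)[0]
    return int(hits[0]) if hits.size else None


@dataclass
class EnsembleSummary:
    """Per-step mean and SE of the metapopulation mutant fraction."""

    steps: np.ndarray
    mean_fraction: np.ndarray
    se: np.ndarray
    n_alive: np.ndarray  # replicates with a defined fraction at each step
    n_replicates: int
    times_to_majority: list  # one entry per replicate, None if never reached
    fixed: list  # per replicate: True if the wild type went extinct
    n_extinct: int
    fractions: np.ndarray = field(repr=False, default=None)  # (reps, steps)

    @property
    def fixation_fraction(self) -> float:
        return sum(bool(f) for f in self.fixed) / self.n_replicates


def ensemble_average(
    trajs: list[Trajectory], majority_threshold: float = 0.5
) -> EnsembleSummary:
    """Average an ensemble of equal-length replicate trajectories."""
    if not trajs:
        raise InvalidInputError("need at least one trajectory")
    lengths = {t.counts.shape[0] for t in trajs}
    if len(lengths) != 1:
        raise InvalidInputError(f"trajectories have mixed lengths: {sorted(lengths)}")
    fracs = np.vstack([t.metapop_fractions() for t in trajs])  # NaN once extinct
    alive = np.isfinite(fracs)
    n_alive = alive.sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fracs, axis=0)
        sd = np.nanstd(fracs, axis=0, ddof=1) if len(trajs) > 1 else np.zeros_like(mean)
    se = np.where(n_alive > 0, sd / np.sqrt(np.maximum(n_alive, 1)), np.nan)
    if len(trajs) == 1:
        se = np.zeros_like(mean)
    ttm = [time_to_majority(t, majority_threshold) for t in trajs]
    fixed = [t.fixation_step() is not None for t in trajs]
    n_extinct = sum(t.extinction_step() is not None for t in trajs)
    return EnsembleSummary(
        steps=np.arange(fracs.shape[1]),
        mean_fraction=mean,
        se=se,
        n_alive=n_alive,
        n_replicates=len(trajs),
        times_to_majority=ttm,
        fixed=fixed,
        n_extinct=n_extinct,
        fractions=fracs,
    )


def expected_migrants(
    migration_rate: float,
    spaces_per_node: int,
    antibiotic: float,
    normalized_resistance: float,
) -> float:
    """Expected mutant migrants per step per edge at effective capacity.

    ``m * K * max(0, 1 - A / rho)`` where ``rho = R/Z`` is the normalized
    resistance.  Linear in ``m`` and ``K``, non-increasing in ``A``, zero
    at or above the eradication threshold ``A = rho``.
    """
    if normalized_resistance <= 0:
        raise InvalidParameterError("normalized_resistance must be > 0")
    if migration_rate < 0 or spaces_per_node < 1 or antibiotic < 0:
        raise InvalidParameterError("invalid expected-migrants inputs")
    return (
        migration_rate
        * spaces_per_node
        * max(0.0, 1.0 - antibiotic / normalized_resistance)
    )


def migration_for_expected_migrants(
    target: float,
    spaces_per_node: int,
    antibiotic: float,
    normalized_resistance: float,
) -> float:
    """Migration probability whose expected migrants per edge equals ``target``."""
    if target < 0:
        raise InvalidParameterError("target must be >= 0")
    depletion = 1.0 - antibiotic / normalized_resistance
    if depletion <= 0:
        raise InvalidParameterError(
            "no migration rate can reach the target: effective capacity is 0"
        )
    m = target / (spaces_per_node * depletion)
    if m > 1.0:
        raise InvalidParameterError(f"required migration probability {m:.3g} > 1")
    return m


def migrant_headcount(migration_percent: float, census: float = 1e7) -> float:
    """Dispersal-pool head count implied by a percentage migration rate.

    A serial-transfer aliquot of ``census`` colony-forming units diluted to
    a ``migration_percent`` dispersal rate carries
    ``census * migration_percent / 100`` individuals (e.g. 0.001% of 1e7
    is 100 migrants).
    """
    if migration_percent < 0 or census <= 0:
        raise InvalidParameterError("invalid head-count inputs")
    return census * migration_percent / 100.0


def amplification_curve(
    star: EnsembleSummary, mixed: EnsembleSummary
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (star mean - well-mixed mean) with pooled standard error.

    Positive values at intermediate steps that shrink toward the end of the
    run are the signature of transient amplification.
    """
    if star.steps.shape != mixed.steps.shape or np.any(star.steps != mixed.steps):
        raise InvalidInputError("ensembles are on different step grids")
    diff = star.mean_fraction - mixed.mean_fraction
    pooled_se = np.sqrt(star.se**2 + mixed.se**2)
    return diff, pooled_se


def per_node_spread_order(
    traj: Trajectory, threshold: float = 0.5
) -> list[tuple[str, int | None]]:
    """Patches ordered by first step at which their mutant fraction >= threshold.

    Returns ``(node_id, step)`` pairs; patches that never reach the
    threshold come last with step ``None``.  Ties break by node id.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must be in (0, 1)")
    fracs = traj.node_fractions()  # (steps, nodes), NaN where patch empty
    order = []
    for j, nid in enumerate(traj.node_ids):
        with np.errstate(invalid="ignore"):
            hits = np.nonzero(fracs[:, j] >= threshold)[0]
        order.append((nid, int(hits[0]) if hits.size else None))
    return sorted(order, key=lambda p: (p[1] is None, p[1], p[0]))


# ---------------------------------------------------------------------------
# tidy exports


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Tidy per-step table: replicate, step, node_id, wild, mutant."""
    rows = []
    for r, t in enumerate(trajs):
        n_steps, n_nodes, _ = t.counts.shape
        for s in range(n_steps):
            for j, nid in enumerate(t.node_ids):
                rows.append(
                    (r, s, nid, int(t.counts[s, j, 0]), int(t.counts[s, j, 1]))
                )
    return pd.DataFrame(rows, columns=["replicate", "step", "node_id", "wild", "mutant"])


def summary_to_frame(summary: EnsembleSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": summary.steps,
            "mean_fraction": summary.mean_fraction,
            "se": summary.se,
            "n_alive": summary.n_alive,
        }
    )


def majority_histogram_frame(summary: EnsembleSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": np.arange(summary.n_replicates),
            "time_to_majority": [
                -1 if t is None else t for t in summary.times_to_majority
            ],
            "fixed": [bool(f) for f in summary.fixed],
        }
    )
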