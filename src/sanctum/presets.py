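"""Scenario presets: the standard four-patch study conditions.

All presets share one demographic calibration:

* four patches of ``K = 1600`` spaces;
* antibiotic ``A = 0.25`` with mutant rates ``R = 1, Z = 1``, so the
  mutant's effective carrying capacity is ``(1 - Z*A/R) K = 1200`` and its
  normalized resistance is ``R/Z = 1`` (the dose sits at 25% of the
  eradication threshold);
* the wild type shares ``R`` and carries a larger kill coefficient,
  calibrated so the mutant's low-density per-generation growth advantage
  is 20% (``Z_w = 1.5`` at this dose);
* 1000 founders scattered uniformly, exactly one of them mutant, placed in
  leaf patch ``P3`` (never the hub ``P2``);
* 240 generations (five days at a 30-minute generation time) and 100
  replicate instantiations.

Migration levels are expressed as the expected number of mutant migrants
leaving a source patch per generation at the mutant's effective carrying
capacity: ``low = 0.1``, ``intermediate = 1`` and ``high = 10`` migrants
per step, converted to a per-agent migration probability via
``m = target / (K * (1 - A / (R/Z)))``.  Transient amplification is
expected where this head count is of order one.

Dispersal asymmetry on the star is a weight ratio between the hub-bound
and leaf-bound edges (default 2:1), since only the direction of the
asymmetry — not its magnitude — is pinned down by the study design.

The bottleneck presets thin every patch to 10% once per experimental day
(48 generations), emulating a stricter serial-transfer dilution and hence
stronger drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import SimParams, TypeParams, calibrate_wild_kill_rate
from .errors import InvalidParameterError
from .graphs import MetapopGraph, build_star, build_well_mixed
from .observables import migration_for_expected_migrants

__all__ = [
    "ScenarioConfig",
    "default_params",
    "get_preset",
    "preset_names",
    "MIGRATION_LEVELS",
]

CAPACITY = 1600
N_LEAVES = 3
ANTIBIOTIC = 0.25
MUTANT = TypeParams(birth_rate=1.0, kill_rate=1.0)
#: calibrated for a ~20% low-density growth advantage of the mutant
WILD = TypeParams(
    birth_rate=1.0,
    kill_rate=calibrate_wild_kill_rate(MUTANT, ANTIBIOTIC, advantage=0.2),
)
NORMALIZED_RESISTANCE = MUTANT.birth_rate / MUTANT.kill_rate

#: expected mutant migrants per source patch per generation, by level
MIGRATION_LEVELS = {"low": 0.1, "intermediate": 1.0, "high": 10.0}

ASYMMETRY_RATIO = 2.0
BOTTLENECK_EVERY = 48  # one experimental day of generations
BOTTLENECK_FRACTION = 0.1


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved scenario: graph, parameters, replicate count."""

    name: str
    graph: MetapopGraph
    params: SimParams
    replicates: int = 100

    def resolved(self, replicates=None, seed=None, n_steps=None) -> "ScenarioConfig":
        params = self.params
        if seed is not None:
            params = replace(params, seed=int(seed))
        if n_steps is not None:
            params = replace(params, n_steps=int(n_steps))
        return ScenarioConfig(
            self.name, self.graph, params, replicates or self.replicates
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "name": self.name,
            "graph": self.graph.to_dict(),
            "params": asdict(self.params),
            "replicates": self.replicates,
        }


def migration_prob_for_level(level: str) -> float:
    try:
        target = MIGRATION_LEVELS[level]
    except KeyError:
        raise InvalidParameterError(
            f"unknown migration level {level!r}; choose from {sorted(MIGRATION_LEVELS)}"
        ) from None
    return migration_for_expected_migrants(
        target, CAPACITY, ANTIBIOTIC, NORMALIZED_RESISTANCE
    )


def default_params(migration_level: str = "low", **overrides) -> SimParams:
    base = dict(
        wild=WILD,
        mutant=MUTANT,
        antibiotic=ANTIBIOTIC,
        migration_prob=migration_prob_for_level(migration_level),
        n_steps=240,
        founders=1000,
        founder_mutants=1,
        intro_node="P3",
    )
    base.update(overrides)
    return SimParams(**base)


def _star(w_in=1.0, w_out=1.0):
    return build_star(N_LEAVES, CAPACITY, w_leaf_to_hub=w_in, w_hub_to_leaf=w_out)


def _mixed():
    return build_well_mixed(N_LEAVES + 1, CAPACITY)


def _build_presets() -> dict:
    presets = {}
    for level in MIGRATION_LEVELS:
        presets[f"star_{level}_m"] = lambda level=level: ScenarioConfig(
            f"star_{level}_m", _star(), default_params(level)
        )
        presets[f"mixed_{level}_m"] = lambda level=level: ScenarioConfig(
            f"mixed_{level}_m", _mixed(), default_params(level)
        )
        presets[f"star_in_gt_out_{level}_m"] = lambda level=level: ScenarioConfig(
            f"star_in_gt_out_{level}_m",
            _star(w_in=ASYMMETRY_RATIO, w_out=1.0),
            default_params(level),
        )
        presets[f"star_out_gt_in_{level}_m"] = lambda level=level: ScenarioConfig(
            f"star_out_gt_in_{level}_m",
            _star(w_in=1.0, w_out=ASYMMETRY_RATIO),
            default_params(level),
        )
    for topo, graph in (("star_in_gt_out", _star(ASYMMETRY_RATIO, 1.0)), ("mixed", _mixed())):
        presets[f"{topo}_bottleneck"] = lambda topo=topo, graph=graph: ScenarioConfig(
            f"{topo}_bottleneck",
            graph,
            default_params(
                "intermediate",
                bottleneck_every=BOTTLENECK_EVERY,
                bottleneck_fraction=BOTTLENECK_FRACTION,
            ),
        )
    return presets


_PRESETS = _build_presets()


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str) -> ScenarioConfig:
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return factory()
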