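"""Domain types and parameter validation for the deme-structured game model.

The population consists of ``N`` individuals spread over ``D`` demes
(subpopulations), each with carrying capacity ``N0 = N / D``.  Every
individual plays one of the two pure prisoner's-dilemma strategies,
cooperate or defect, and carries a bounded, generation-accumulated
fitness.  Demes sit on the nodes of an undirected migration network;
the life cycle each generation is game -> migration -> selection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Strategy",
    "PayoffMatrix",
    "TopologyKind",
    "TopologySpec",
    "ModelParams",
    "PopulationState",
    "validate_params",
    "initialize_population",
]


class Strategy(enum.IntEnum):
    """A pure strategy: cooperate or defect. No mixed strategies exist."""

    DEFECT = 0
    COOPERATE = 1


@dataclass(frozen=True)
class PayoffMatrix:
    """The four prisoner's-dilemma payoffs.

    ``T`` (temptation, D vs C), ``R`` (reward, C vs C), ``P`` (punishment,
    D vs D) and ``S`` (sucker, C vs D) must satisfy ``T > R > P > S`` and
    ``2R > T + S``; the second inequality gives cooperation a non-null
    chance of persisting.
    """

    T: float = 1.5
    R: float = 1.0
    P: float = 0.1
    S: float = 0.0

    def validate(self) -> None:
        vals = (self.T, self.R, self.P, self.S)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"payoffs must be finite, got {vals}")
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoff ordering T > R > P > S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError(
                f"2R > T + S violated: 2R={2 * self.R}, T+S={self.T + self.S}"
            )

    def table(self) -> np.ndarray:
        """Payoff lookup ``table()[own, other]`` with 1 = cooperate."""
        return np.array([[self.P, self.T], [self.S, self.R]], dtype=np.float64)

    @property
    def fitness_bounds(self) -> tuple[float, float]:
        """Interval containing every reachable fitness: [min(S, 0), T]."""
        return (min(self.S, 0.0), self.T)


class TopologyKind(str, enum.Enum):
    ERDOS_RENYI = "er"
    ISLAND = "island"
    SCALE_FREE = "ba"
    USER = "user"


@dataclass(frozen=True)
class TopologySpec:
    """Which migration network to build and with what mean degree.

    ``mean_degree`` (z) is ignored for the island model (complete graph,
    degree D-1 everywhere) and for user-supplied edge lists.
    """

    kind: TopologyKind = TopologyKind.ERDOS_RENYI
    mean_degree: float = 4.0
    edge_list_path: Optional[str] = None

    def validate(self, D: int) -> None:
        if self.kind in (TopologyKind.ERDOS_RENYI, TopologyKind.SCALE_FREE):
            if not self.mean_degree > 0:
                raise ValueError(f"mean_degree must be > 0, got {self.mean_degree}")
            if self.kind is TopologyKind.ERDOS_RENYI and not self.mean_degree < D:
                raise ValueError(
                    f"Erdos-Renyi mean degree z={self.mean_degree} must be < D={D}"
                )
        if self.kind is TopologyKind.USER and self.edge_list_path is None:
            raise ValueError("topology kind 'user' requires edge_list_path")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation of one simulation.

    Attributes
    ----------
    N : total initial population size.
    D : number of demes; ``N`` must be divisible by ``D``.
    m : per-individual, per-generation migration probability in [0, 1].
    E : elimination threshold (payoff units); individuals with fitness
        strictly below E are removed at the selection stage.  Must be
        < R or even a pure cooperator deme is doomed.
    w : fitness memory weight in (0, 1]; fitness update is
        ``f' = (1 - w) f + w G`` with G the round payoff.
    payoffs : the prisoner's-dilemma payoff matrix.
    topology : migration-network specification.
    init_coop_frac : probability each founder cooperates (i.i.d.).
    init_fitness : fitness of founders and of newborn daughters.
    leftover_decay : if True, an unpaired individual in an odd-sized deme
        takes a zero payoff (fitness decays); default False (sits out).
    resample_isolated : if True, resample random networks until every
        node has degree >= 1.
    max_generations, stationarity_window, stationarity_tol : horizon and
        stationarity detection settings for a replicate.
    seed : base RNG seed.
    """

    N: int = 400
    D: int = 20
    m: float = 0.1
    E: float = 0.4
    w: float = 0.5
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    topology: TopologySpec = field(default_factory=TopologySpec)
    init_coop_frac: float = 0.5
    init_fitness: float = 0.0
    leftover_decay: bool = False
    resample_isolated: bool = False
    max_generations: int = 5000
    stationarity_window: int = 200
    stationarity_tol: float = 0.01
    seed: int = 0

    @property
    def N0(self) -> int:
        """Carrying capacity of each deme, N / D."""
        return self.N // self.D

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        return validate_params(replace(self, **kwargs))


def validate_params(params: ModelParams) -> ModelParams:
    """Check every model invariant; return the params or raise ValueError."""
    if params.N <= 0 or params.D <= 0:
        raise ValueError(f"N and D must be positive, got N={params.N}, D={params.D}")
    if params.N % params.D != 0:
        raise ValueError(
            f"N={params.N} must be divisible by D={params.D} "
            f"(carrying capacity N0 = N/D must be an integer)"
        )
    if not (0.0 <= params.m <= 1.0):
        raise ValueError(f"migration rate m must be in [0, 1], got {params.m}")
    if not (0.0 < params.w <= 1.0):
        raise ValueError(f"fitness memory weight w must be in (0, 1], got {params.w}")
    params.payoffs.validate()
    if not params.E < params.payoffs.R:
        raise ValueError(
            f"elimination threshold E={params.E} must be < R={params.payoffs.R}: "
            f"otherwise even a pure cooperator population is eliminated"
        )
    if not (0.0 <= params.init_coop_frac <= 1.0):
        raise ValueError(f"init_coop_frac must be in [0, 1], got {params.init_coop_frac}")
    params.topology.validate(params.D)
    if params.max_generations <= 0:
        raise ValueError("max_generations must be positive")
    if params.stationarity_window <= 0:
        raise ValueError("stationarity_window must be positive")
    if params.stationarity_tol < 0:
        raise ValueError("stationarity_tol must be >= 0")
    return params


@dataclass
class PopulationState:
    """Variable-size rosters of all demes at one census point.

    ``strategies[d]`` is an int8 array (1 = cooperate, 0 = defect) and
    ``fitness[d]`` the matching float array for deme ``d``.  Deme sizes
    vary freely between stages; immediately after selection each deme
    holds either ``N0`` individuals or none.
    """

    generation: int
    strategies: list[np.ndarray]
    fitness: list[np.ndarray]

    @property
    def n_demes(self) -> int:
        return len(self.strategies)

    def deme_sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.strategies], dtype=np.int64)

    @property
    def total_size(self) -> int:
        return int(sum(len(s) for s in self.strategies))

    def n_cooperators(self) -> int:
        return int(sum(int(s.sum()) for s in self.strategies))

    def rho(self) -> float:
        """Frequency of cooperators; nan for an empty population."""
        n = self.total_size
        return self.n_cooperators() / n if n > 0 else float("nan")

    def occupied_demes(self) -> int:
        return int(sum(1 for s in self.strategies if len(s) > 0))

    def copy(self) -> "PopulationState":
        return PopulationState(
            generation=self.generation,
            strategies=[s.copy() for s in self.strategies],
            fitness=[f.copy() for f in self.fitness],
        )


def initialize_population(params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Found the population: D demes of N0 individuals each.

    Each founder cooperates independently with probability
    ``init_coop_frac`` and starts at fitness ``init_fitness``.  One
    ``rng.random(N0)`` draw per deme, demes in id order.
    """
    N0 = params.N0
    strategies, fitness = [], []
    for _ in range(params.D):
        s = (rng.random(N0) < params.init_coop_frac).astype(np.int8)
        strategies.append(s)
        fitness.append(np.full(N0, params.init_fitness, dtype=np.float64))
    return PopulationState(generation=0, strategies=strategies, fitness=fitness)
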