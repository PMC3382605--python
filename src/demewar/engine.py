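"""Replicate engine: life cycle orchestration, absorption, stationarity.

One generation applies, in order, the game stage, migration, and
selection, then takes a census (the cooperator frequency rho is
measured after selection, at the end of the life cycle).  The states
rho = 1 (all cooperators) and total extinction are absorbing: the
dynamics has no mutation, so an eliminated strategy never reappears.
An all-defector population is *not* short-circuited — elimination is
left to play out, because under user-modified payoffs (P >= E) pure
defection could persist; with the defaults it cannot.

A mixed population that stops drifting is classified as coexistence:
stationarity is declared when the mean of rho over the last window of
generations differs from the mean over the preceding window by at most
a tolerance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .game import play_generation
from .model import ModelParams, PopulationState, initialize_population, validate_params
from .network import MigrationNetwork, build_network, migrate
from .selection import select_generation

__all__ = [
    "OutcomeLabel",
    "ReplicateOutcome",
    "Trajectory",
    "step_generation",
    "is_absorbing",
    "detect_stationary",
    "run_replicate",
]


class OutcomeLabel(str, enum.Enum):
    EXTINCT = "EXTINCT"
    COOP_FIXED = "COOP_FIXED"
    COEXISTENCE = "COEXISTENCE"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class Trajectory:
    """Per-generation census records of one replicate."""

    generation: np.ndarray
    rho: np.ndarray
    total_size: np.ndarray
    occupied_demes: np.ndarray

    def __len__(self) -> int:
        return len(self.generation)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generation,
                "rho": self.rho,
                "total_size": self.total_size,
                "occupied_demes": self.occupied_demes,
            }
        )


@dataclass(frozen=True)
class ReplicateOutcome:
    label: OutcomeLabel
    final_rho: float
    generations_run: int
    seed: int


def step_generation(
    state: PopulationState,
    params: ModelParams,
    net: MigrationNetwork,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one generation: game, then migration, then selection."""
    play_generation(state, params, rng)
    migrate(state, net, params.m, rng)
    select_generation(state, params, rng)
    state.generation += 1
    return state


def is_absorbing(state: PopulationState) -> OutcomeLabel | None:
    """EXTINCT for an empty population, COOP_FIXED when rho = 1, else None.

    An all-defector state returns None: it heads to extinction on its
    own under any payoff setting with limiting defector fitness < E.
    """
    total = state.total_size
    if total == 0:
        return OutcomeLabel.EXTINCT
    if state.n_cooperators() == total:
        return OutcomeLabel.COOP_FIXED
    return None


def detect_stationary(rho: np.ndarray, window: int, tol: float) -> bool:
    """True iff the last two disjoint windows of rho have means within tol."""
    if len(rho) < 2 * window:
        raise ValueError(f"need >= {2 * window} records, got {len(rho)}")
    recent = float(np.mean(rho[-window:]))
    previous = float(np.mean(rho[-2 * window : -window]))
    return abs(recent - previous) <= tol


def run_replicate(
    params: ModelParams,
    seed: int | None = None,
    net: MigrationNetwork | None = None,
) -> tuple[Trajectory, ReplicateOutcome]:
    """Run one replicate to absorption, stationarity, or the horizon.

    A fresh PCG64 generator is seeded from ``seed`` (default
    ``params.seed``); the migration network, the founders, and every
    stochastic stage all draw from that single stream, so (params, seed)
    fully determine the trajectory.  Pass ``net`` to reuse a quenched
    network instead of generating one.
    """
    params = validate_params(params)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    if net is None:
        net = build_network(params.topology, params.D, rng, params.resample_isolated)
    state = initialize_population(params, rng)

    W = params.stationarity_window
    gens: list[int] = []
    rhos: list[float] = []
    totals: list[int] = []
    occupied: list[int] = []
    label = OutcomeLabel.UNRESOLVED
    final_rho = state.rho()

    for _ in range(params.max_generations):
        step_generation(state, params, net, rng)
        total = state.total_size
        ncoop = state.n_cooperators()
        rho = ncoop / total if total > 0 else float("nan")
        gens.append(state.generation)
        rhos.append(rho)
        totals.append(total)
        occupied.append(state.occupied_demes())

        if total == 0:
            label = OutcomeLabel.EXTINCT
            final_rho = float("nan")
            break
        if ncoop == total:
            label = OutcomeLabel.COOP_FIXED
            final_rho = 1.0
            break
        if len(rhos) >= 2 * W:
            recent = rhos[-W:]
            prev = rhos[-2 * W : -W]
            if abs(sum(recent) / W - sum(prev) / W) <= params.stationarity_tol:
                label = OutcomeLabel.COEXISTENCE
                final_rho = sum(recent) / W
                break
    else:
        final_rho = rhos[-1] if rhos else state.rho()

    traj = Trajectory(
        generation=np.array(gens, dtype=np.int64),
        rho=np.array(rhos, dtype=np.float64),
        total_size=np.array(totals, dtype=np.int64),
        occupied_demes=np.array(occupied, dtype=np.int64),
    )
    outcome = ReplicateOutcome(
        label=label,
        final_rho=float(final_rho),
        generations_run=state.generation,
        seed=seed,
    )
    return traj, outcome
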