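"""Deliberately naive reference engine: a literal, object-per-individual
transcription of the life cycle (game, migration, selection), used as an
independent oracle against the optimized array engine.

It shares the package's documented randomness contract — which rng
methods are called, with which arguments, in which order — because
trajectory-level identity is only defined relative to that contract.
Everything else (data layout, pairing, payoff lookup, culling,
roulette-wheel expansion) is re-derived here with plain Python loops
and no imports from the package's stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Ind:
    strategy: int  # 1 = cooperate, 0 = defect
    fitness: float


def payoff(me: int, other: int, T: float, R: float, P: float, S: float) -> float:
    if me == 1 and other == 1:
        return R
    if me == 1 and other == 0:
        return S
    if me == 0 and other == 1:
        return T
    return P


class NaiveEngine:
    """Lists of Ind objects, one deme per list; stage-by-stage loops."""

    def __init__(self, params, neighbors: list[np.ndarray], seed: int):
        self.p = params
        self.neighbors = neighbors
        self.rng = np.random.default_rng(seed)
        self.demes: list[list[Ind]] = []
        for _ in range(params.D):
            u = self.rng.random(params.N0)
            self.demes.append(
                [Ind(1 if u[i] < params.init_coop_frac else 0, params.init_fitness)
                 for i in range(params.N0)]
            )
        self.generation = 0

    # -- life cycle ----------------------------------------------------
    def game_stage(self) -> None:
        p = self.p
        for deme in self.demes:
            n = len(deme)
            if n < 2:
                if n == 1 and p.leftover_decay:
                    deme[0].fitness = (1.0 - p.w) * deme[0].fitness
                continue
            perm = self.rng.permutation(n)
            for j in range(n // 2):
                ia, ib = int(perm[2 * j]), int(perm[2 * j + 1])
                a, b = deme[ia], deme[ib]
                ga = payoff(a.strategy, b.strategy,
                            p.payoffs.T, p.payoffs.R, p.payoffs.P, p.payoffs.S)
                gb = payoff(b.strategy, a.strategy,
                            p.payoffs.T, p.payoffs.R, p.payoffs.P, p.payoffs.S)
                a.fitness = (1.0 - p.w) * a.fitness + p.w * ga
                b.fitness = (1.0 - p.w) * b.fitness + p.w * gb
            if n % 2 == 1 and p.leftover_decay:
                left = deme[int(perm[n - 1])]
                left.fitness = (1.0 - p.w) * left.fitness

    def migration_stage(self) -> None:
        m = self.p.m
        D = self.p.D
        stay: list[list[Ind]] = []
        incoming: list[list[Ind]] = [[] for _ in range(D)]
        for d in range(D):
            deme = self.demes[d]
            n = len(deme)
            if n == 0:
                stay.append(deme)
                continue
            u = self.rng.random(n)
            movers = [i for i in range(n) if u[i] < m]
            nbrs = self.neighbors[d]
            if not movers or len(nbrs) == 0:
                stay.append(deme)
                continue
            choice = self.rng.integers(0, len(nbrs), size=len(movers))
            mover_set = set(movers)
            stay.append([ind for i, ind in enumerate(deme) if i not in mover_set])
            for i, c in zip(movers, choice):
                incoming[int(nbrs[int(c)])].append(deme[i])
        self.demes = [stay[d] + incoming[d] for d in range(D)]

    def selection_stage(self) -> None:
        p = self.p
        N0 = p.N0
        for d in range(p.D):
            deme = [ind for ind in self.demes[d] if ind.fitness >= p.E]
            while len(deme) > N0:
                fmin = min(ind.fitness for ind in deme)
                ties = [i for i, ind in enumerate(deme) if ind.fitness == fmin]
                victim = ties[int(self.rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
                deme.pop(victim)
            if 0 < len(deme) < N0:
                weights = [max(ind.fitness, 0.0) for ind in deme]
                total = 0.0
                cum = []
                for wgt in weights:
                    total += wgt
                    cum.append(total)
                births = N0 - len(deme)
                babies = []
                if total > 0.0:
                    us = self.rng.random(births)
                    for u in us:
                        x = u * total
                        parent = len(deme) - 1
                        for j, c in enumerate(cum):
                            if c > x:
                                parent = j
                                break
                        babies.append(Ind(deme[parent].strategy, 0.0))
                else:
                    for _ in range(births):
                        parent = int(self.rng.integers(0, len(deme)))
                        babies.append(Ind(deme[parent].strategy, 0.0))
                deme = deme + babies
            self.demes[d] = deme

    def step(self) -> None:
        self.game_stage()
        self.migration_stage()
        self.selection_stage()
        self.generation += 1

    # -- census --------------------------------------------------------
    def census(self) -> tuple[float, int, int]:
        total = sum(len(d) for d in self.demes)
        ncoop = sum(ind.strategy for d in self.demes for ind in d)
        rho = ncoop / total if total else float("nan")
        occupied = sum(1 for d in self.demes if d)
        return rho, total, occupied

    def state_tuple(self):
        """Full state as nested tuples for exact comparison."""
        return tuple(
            tuple((ind.strategy, ind.fitness) for ind in deme) for deme in self.demes
        )
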