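"""Ensembles of replicates: probabilities, sweeps, and the phase diagram.

The observables mirror the model's standard presentation:

* ``p_coop`` — probability that cooperation fixates, counting both
  dominance (rho = 1) and stable coexistence;
* ``p_coex`` — probability of coexistence alone;
* ``mean_rho_given_persistence`` — mean stationary cooperator frequency
  conditioned on cooperation persisting, with dominance runs
  contributing exactly 1.

Replicate r of an ensemble uses seed ``base_seed + r``; unresolved
replicates (horizon hit before absorption or stationarity) are excluded
from the probability denominators and reported separately.

The (m, D) plane splits into four regimes — extinction, cooperation
likely, pure cooperation, coexistence — and the phase diagram reports
the critical deme number D_c: the smallest D whose regime at the
smallest scanned migration rate is not extinction.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import OutcomeLabel, ReplicateOutcome, run_replicate
from .model import ModelParams, TopologyKind, TopologySpec, validate_params

__all__ = [
    "EnsembleSummary",
    "Regime",
    "run_ensemble",
    "summarize_outcomes",
    "sweep_migration",
    "classify_regime",
    "phase_diagram",
    "compare_topologies",
    "sweep_threshold",
]

logger = logging.getLogger(__name__)

PERSISTING = (OutcomeLabel.COOP_FIXED, OutcomeLabel.COEXISTENCE)


@dataclass(frozen=True)
class EnsembleSummary:
    n_runs: int
    n_resolved: int
    n_unresolved: int
    p_coop: float
    p_coop_se: float
    p_coex: float
    p_coex_se: float
    mean_rho_given_persistence: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class Regime(str, enum.Enum):
    EXTINCTION = "EXTINCTION"
    COOP_LIKELY = "COOP_LIKELY"
    PURE_COOP = "PURE_COOP"
    COEXISTENCE = "COEXISTENCE"


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")


def summarize_outcomes(outcomes: Sequence[ReplicateOutcome]) -> EnsembleSummary:
    """Tally replicate outcomes into the ensemble observables."""
    n_runs = len(outcomes)
    resolved = [o for o in outcomes if o.label is not OutcomeLabel.UNRESOLVED]
    n_res = len(resolved)
    if n_res == 0:
        raise ValueError("zero resolved replicates: cannot form probabilities")
    n_unres = n_runs - n_res
    if n_unres > 0.01 * n_runs:
        logger.warning("%d/%d replicates unresolved (>1%%)", n_unres, n_runs)
    persisting = [o for o in resolved if o.label in PERSISTING]
    n_coex = sum(1 for o in resolved if o.label is OutcomeLabel.COEXISTENCE)
    p_coop = len(persisting) / n_res
    p_coex = n_coex / n_res
    mean_rho = (
        float(np.mean([o.final_rho for o in persisting])) if persisting else float("nan")
    )
    return EnsembleSummary(
        n_runs=n_runs,
        n_resolved=n_res,
        n_unresolved=n_unres,
        p_coop=p_coop,
        p_coop_se=_binom_se(p_coop, n_res),
        p_coex=p_coex,
        p_coex_se=_binom_se(p_coex, n_res),
        mean_rho_given_persistence=mean_rho,
    )


def run_ensemble(params: ModelParams, n_runs: int, base_seed: int) -> EnsembleSummary:
    """Run ``n_runs`` independent replicates with seeds base_seed..base_seed+n_runs-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = validate_params(params)
    outcomes = [run_replicate(params, seed=base_seed + r)[1] for r in range(n_runs)]
    return summarize_outcomes(outcomes)


def _summary_row(params: ModelParams, summary: EnsembleSummary) -> dict:
    return {
        "m": params.m,
        "D": params.D,
        "N0": params.N0,
        "E": params.E,
        "topology": params.topology.kind.value,
        **summary.as_dict(),
    }


def sweep_migration(
    params: ModelParams,
    m_grid: Iterable[float],
    n_runs: int,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """One ensemble per migration rate; returns a tidy table."""
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("m_grid must be non-empty")
    if base_seed is None:
        base_seed = params.seed
    rows = []
    for m in m_grid:
        p = params.with_(m=m)
        rows.append(_summary_row(p, run_ensemble(p, n_runs, base_seed)))
    return pd.DataFrame(rows)


def classify_regime(
    summary: EnsembleSummary,
    eps_onset: float = 0.01,
    eps_pure: float = 0.02,
    strict: bool = False,
) -> Regime:
    """Map an ensemble summary to one of the four regimes.

    Rules, in precedence order (coexistence is checked before pure
    cooperation):

    * EXTINCTION  if p_coop < eps_onset (cooperation never takes hold);
    * COEXISTENCE if p_coex > eps_onset;
    * PURE_COOP   if p_coop >= 1 - eps_pure (fixation essentially certain);
    * COOP_LIKELY otherwise.

    Resolving an onset probability of eps_onset needs roughly
    3/eps_onset replicates; with fewer the call warns (or raises when
    ``strict``).
    """
    n_min = 3.0 / eps_onset
    if summary.n_resolved < n_min:
        msg = (
            f"{summary.n_resolved} resolved runs cannot resolve "
            f"eps_onset={eps_onset} (need >= {n_min:.0f})"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    if summary.p_coop < eps_onset:
        return Regime.EXTINCTION
    if summary.p_coex > eps_onset:
        return Regime.COEXISTENCE
    if summary.p_coop >= 1.0 - eps_pure:
        return Regime.PURE_COOP
    return Regime.COOP_LIKELY


def phase_diagram(
    params: ModelParams,
    m_grid: Sequence[float],
    D_grid: Sequence[int],
    n_runs: int,
    base_seed: int | None = None,
    eps_onset: float = 0.01,
    eps_pure: float = 0.02,
) -> tuple[pd.DataFrame, int | None]:
    """Regime per (m, D) grid point at fixed total population N.

    N0 is recomputed as N/D at every point; a D that does not divide N
    is skipped with a warning.  Returns the phase table and D_c, the
    smallest D whose regime at min(m_grid) is not EXTINCTION (None if
    every scanned D goes extinct there).
    """
    if base_seed is None:
        base_seed = params.seed
    m_min = min(m_grid)
    rows = []
    d_c: int | None = None
    for D in sorted(D_grid):
        if params.N % D != 0:
            logger.warning("skipping D=%d: N=%d not divisible", D, params.N)
            continue
        for m in m_grid:
            p = params.with_(D=D, m=m)
            summary = run_ensemble(p, n_runs, base_seed)
            regime = classify_regime(summary, eps_onset, eps_pure)
            rows.append({**_summary_row(p, summary), "regime": regime.value})
            if m == m_min and regime is not Regime.EXTINCTION and d_c is None:
                d_c = D
    return pd.DataFrame(rows), d_c


def compare_topologies(
    params: ModelParams,
    topologies: Sequence[TopologyKind | str],
    m_grid: Iterable[float],
    n_runs: int,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Migration sweep per topology at matched mean degree."""
    m_grid = list(m_grid)
    frames = []
    for topo in topologies:
        kind = TopologyKind(topo)
        spec = TopologySpec(kind=kind, mean_degree=params.topology.mean_degree)
        p = params.with_(topology=spec)
        frames.append(sweep_migration(p, m_grid, n_runs, base_seed))
    return pd.concat(frames, ignore_index=True)


def sweep_threshold(
    params: ModelParams,
    E_values: Sequence[float],
    m_grid: Sequence[float],
    n_runs: int,
    base_seed: int | None = None,
    eps_onset: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Migration sweep per elimination threshold E.

    Returns the stacked sweep table and an onset table giving, per E,
    the smallest scanned m with p_coop >= eps_onset (NaN when
    cooperation never reaches the onset).  Raising E is expected to
    push the onset towards larger migration rates.
    """
    frames = []
    onset_rows = []
    for E in E_values:
        p = params.with_(E=E)
        tab = sweep_migration(p, m_grid, n_runs, base_seed)
        frames.append(tab)
        hit = tab[tab["p_coop"] >= eps_onset]
        onset_rows.append(
            {"E": E, "onset_m": float(hit["m"].min()) if len(hit) else float("nan")}
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(onset_rows)
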