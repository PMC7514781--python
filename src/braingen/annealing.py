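"""Simulated-annealing fit of the (γ, η) exponents on the similarity index.

The objective evolves the initial network under candidate parameters,
compares it to the target through the six-metric relative errors and scores
the fit with SI.  The annealer minimizes the loss 1/SI = Σξ (equivalently it
maximizes SI) over a discrete lattice of exponent values, by default
γ, η ∈ {0.2, 0.4, …, 2.0}.  Because every objective call at a lattice point
uses the same schedule-derived evolution seed, the objective is a
deterministic function of (γ, η) and repeated visits are served from a
cache; the 100-point lattice can also be swept exhaustively as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connection import DistanceMatrix, ModelParams
from .evolution import EvolutionQuota, evolve
from .graph_core import BrainGraph
from .metrics import fit_errors, metric_vector

DEFAULT_LATTICE = tuple(round(0.2 * k, 10) for k in range(1, 11))  # 0.2 .. 2.0


@dataclass(frozen=True)
class AnnealingSchedule:
    """Cooling schedule and proposal settings for the lattice walk."""

    initial_temperature: float = 1.0
    cooling: float = 0.9
    steps_per_temperature: int = 20
    min_temperature: float = 1e-3
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0 or self.min_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.steps_per_temperature < 1 or self.restarts < 1:
            raise ValueError("steps and restarts must be at least 1")


@dataclass
class FitResult:
    """Best parameters found, with the full evaluation history."""

    index_name: str
    best_gamma: float
    best_eta: float
    best_si: float
    history: list[tuple[float, float, float, bool]] = field(default_factory=list)
    seed: int = 0
    evaluations: int = 0

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=["gamma", "eta", "SI", "accepted"])

    def to_json(self, path: str | Path, bounds=None) -> None:
        payload = {
            "index_name": self.index_name,
            "best_gamma": self.best_gamma,
            "best_eta": self.best_eta,
            "best_si": self.best_si,
            "seed": self.seed,
            "evaluations": self.evaluations,
        }
        if bounds is not None:
            payload["bounds"] = {"gamma": list(bounds[0]), "eta": list(bounds[1])}
        Path(path).write_text(json.dumps(payload, indent=2))


def objective(
    initial: BrainGraph,
    target: BrainGraph,
    params: ModelParams,
    distances: DistanceMatrix | None,
    quota: EvolutionQuota,
    seed: int,
    metric_seed: int = 0,
    target_metrics=None,
) -> float:
    """SI of the network evolved from *initial* under *params* vs *target*.

    Deterministic for fixed seeds; returns +inf on a perfect metric match
    and 0 (the worst possible fit) when the evolved network disconnects,
    since the characteristic path length is undefined there.
    ``target_metrics`` may carry a precomputed metric vector of the target
    to avoid recomputation across many calls.
    """
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # engine warns when evolution disconnects
        evolved, _ = evolve(initial, params, distances, quota, seed=seed)
    if not evolved.is_connected():
        return 0.0
    if target_metrics is None:
        target_metrics = metric_vector(target, seed=metric_seed)
    errors = fit_errors(metric_vector(evolved, seed=metric_seed), target_metrics)
    return errors.SI


def _loss(si: float) -> float:
    if si == 0.0:
        return np.inf
    return 0.0 if np.isinf(si) else 1.0 / si


def _make_cached_objective(initial, target, index_name, distances, quota, evolution_seed):
    cache: dict[tuple[float, float], float] = {}
    target_metrics = metric_vector(target, seed=0)

    def evaluate(gamma: float, eta: float) -> float:
        key = (gamma, eta)
        if key not in cache:
            params = ModelParams(index_name=index_name, gamma=gamma, eta=eta)
            cache[key] = objective(initial, target, params, distances, quota,
                                   seed=evolution_seed, target_metrics=target_metrics)
        return cache[key]

    return evaluate, cache


def exhaustive_search(
    initial: BrainGraph,
    target: BrainGraph,
    index_name: str,
    distances: DistanceMatrix | None,
    quota: EvolutionQuota | None = None,
    gamma_values=DEFAULT_LATTICE,
    eta_values=DEFAULT_LATTICE,
    evolution_seed: int = 0,
    _evaluate=None,
) -> FitResult:
    """Evaluate every lattice point; the brute-force oracle for :func:`fit`."""
    if quota is None:
        from .evolution import edge_change_counts

        quota = edge_change_counts(initial, target)
    if _evaluate is None:
        _evaluate, _ = _make_cached_objective(
            initial, target, index_name, distances, quota, evolution_seed
        )
    result = FitResult(index_name=index_name, best_gamma=np.nan, best_eta=np.nan,
                       best_si=-np.inf, seed=evolution_seed)
    for gamma in gamma_values:
        for eta in eta_values:
            si = _evaluate(gamma, eta)
            result.history.append((gamma, eta, si, True))
            result.evaluations += 1
            if si > result.best_si:
                result.best_gamma, result.best_eta, result.best_si = gamma, eta, si
    return result


def fit(
    initial: BrainGraph,
    target: BrainGraph,
    index_name: str,
    distances: DistanceMatrix | None,
    quota: EvolutionQuota | None = None,
    gamma_values=DEFAULT_LATTICE,
    eta_values=DEFAULT_LATTICE,
    schedule: AnnealingSchedule | None = None,
) -> FitResult:
    """Simulated-annealing search for the best (γ, η) on the lattice.

    Worse moves are accepted with probability exp(−Δloss / temperature),
    where the loss is Σξ = 1/SI.  Restarts begin from random lattice points;
    the best evaluation across all restarts is returned.  Single-point
    lattices are evaluated once and returned directly.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    if quota is None:
        from .evolution import edge_change_counts

        quota = edge_change_counts(initial, target)
    gamma_values = list(gamma_values)
    eta_values = list(eta_values)
    if not gamma_values or not eta_values:
        raise ValueError("parameter bounds must be nonempty")
    rng = np.random.default_rng(schedule.seed)
    evolution_seed = schedule.seed
    evaluate, cache = _make_cached_objective(
        initial, target, index_name, distances, quota, evolution_seed
    )
    result = FitResult(index_name=index_name, best_gamma=np.nan, best_eta=np.nan,
                       best_si=-np.inf, seed=schedule.seed)

    def consider(gamma: float, eta: float, accepted: bool, si: float) -> None:
        result.history.append((gamma, eta, si, accepted))
        if si > result.best_si:
            result.best_gamma, result.best_eta, result.best_si = gamma, eta, si

    if len(gamma_values) == 1 and len(eta_values) == 1:
        si = evaluate(gamma_values[0], eta_values[0])
        consider(gamma_values[0], eta_values[0], True, si)
        result.evaluations = 1
        return result

    for _ in range(schedule.restarts):
        gi = int(rng.integers(len(gamma_values)))
        ei = int(rng.integers(len(eta_values)))
        current = evaluate(gamma_values[gi], eta_values[ei])
        consider(gamma_values[gi], eta_values[ei], True, current)
        temperature = schedule.initial_temperature
        while temperature > schedule.min_temperature:
            for _ in range(schedule.steps_per_temperature):
                # propose one lattice step along a uniformly chosen axis
                axis = rng.integers(2)
                if axis == 0 and len(gamma_values) > 1:
                    ng = gi + (1 if rng.random() < 0.5 else -1)
                    ng = min(max(ng, 0), len(gamma_values) - 1)
                    ne = ei
                else:
                    ng = gi
                    ne = ei + (1 if rng.random() < 0.5 else -1)
                    ne = min(max(ne, 0), len(eta_values) - 1)
                if (ng, ne) == (gi, ei):
                    continue
                proposal = evaluate(gamma_values[ng], eta_values[ne])
                loss_c, loss_p = _loss(current), _loss(proposal)
                if np.isinf(loss_c):
                    accept = True  # nothing is worse than an infeasible state
                else:
                    delta = loss_p - loss_c
                    accept = delta <= 0 or rng.random() < np.exp(-delta / temperature)
                consider(gamma_values[ng], eta_values[ne], accept, proposal)
                if accept:
                    gi, ei, current = ng, ne, proposal
            temperature *= schedule.cooling
    result.evaluations = len(cache)
    if not result.history or np.isnan(result.best_si):
        raise RuntimeError("no feasible objective evaluation completed")
    return result
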