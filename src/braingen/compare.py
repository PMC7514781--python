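"""Side-by-side comparison of generative models on one stage transition.

Produces one row per model with its best-fitting exponents (λ, η), the six
relative errors at those exponents and the resulting SI — the standard
model-comparison table layout.  The RANDOM baseline has no exponents and is
reported with dashes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annealing import DEFAULT_LATTICE, AnnealingSchedule, fit
from .connection import DistanceMatrix, ModelParams
from .evolution import EvolutionQuota, edge_change_counts, evolve
from .graph_core import BrainGraph
from .metrics import fit_errors, metric_vector

COMPARE_COLUMNS = [
    "model", "lambda", "eta", "xi_C", "xi_Eloc", "xi_M", "xi_L", "xi_Eglob", "xi_T", "SI",
]

DEFAULT_MODELS = ("CN", "PA", "JC", "AA", "RA", "MI", "RANDOM")


def compare_models(
    initial: BrainGraph,
    target: BrainGraph,
    distances: DistanceMatrix,
    models=DEFAULT_MODELS,
    gamma_values=DEFAULT_LATTICE,
    eta_values=DEFAULT_LATTICE,
    quota: EvolutionQuota | None = None,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
) -> pd.DataFrame:
    """Fit each model and tabulate its best exponents, errors and SI."""
    if quota is None:
        quota = edge_change_counts(initial, target)
    if schedule is None:
        schedule = AnnealingSchedule(seed=seed)
    target_metrics = metric_vector(target, seed=0)
    rows = []
    for model in models:
        if model == "RANDOM":
            params = ModelParams(index_name="RANDOM", gamma=0.0, eta=0.0)
            evolved, _ = evolve(initial, params, distances, quota, seed=schedule.seed)
            errors = fit_errors(metric_vector(evolved, seed=0), target_metrics)
            row = {"model": "RANDOM", "lambda": "-", "eta": "-", **errors.as_dict()}
        else:
            result = fit(
                initial, target, model, distances, quota,
                gamma_values=gamma_values, eta_values=eta_values, schedule=schedule,
            )
            params = ModelParams(index_name=model, gamma=result.best_gamma, eta=result.best_eta)
            evolved, _ = evolve(initial, params, distances, quota, seed=schedule.seed)
            errors = fit_errors(metric_vector(evolved, seed=0), target_metrics)
            row = {
                "model": model,
                "lambda": result.best_gamma,
                "eta": result.best_eta,
                **errors.as_dict(),
            }
        rows.append(row)
    return pd.DataFrame(rows, columns=COMPARE_COLUMNS)


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
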