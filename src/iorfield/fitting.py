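"""Fitting: RMSE of predicted vs observed inhibition, fitness, optimizer.

The model is scored against observed IOR increments (RT_cued - RT_uncued per
CTOA) by the root-mean-squared error between predicted (PI_i) and observed
(OI_i) inhibition, mapped to a dimensionless fitness with a theoretical
maximum of 100:

    F = 100 / (1 + RMSE)    with RMSE expressed in seconds.

F equals 100 exactly when the predictions match the observations and
decreases strictly with RMSE.  Six parameters are searched within bounds by
a seedable (mu + lambda) evolution strategy; the remaining constants are
hand-set and excluded from the search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .protocols import ior_sweep

__all__ = [
    "FitDataset",
    "FitResult",
    "DEFAULT_BOUNDS",
    "inhibition_rmse",
    "fitness",
    "evolve",
]

logger = logging.getLogger(__name__)

#: search bounds of the six fitted parameters (all others are hand-set)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_D": (0.01, 1.0),
    "tau_S": (0.01, 1.0),
    "tau_H": (0.01, 2.5),
    "w_SD": (0.0, 100.0),
    "m": (1.0, 100.0),
    "I0": (0.0, 20.0),
}


@dataclass
class FitDataset:
    """Observed inhibition increments (OI_i, ms) per CTOA.

    ``approximate`` marks datasets whose values were read off a published
    figure rather than printed numerically.
    """

    ctoas: np.ndarray
    observed_inhibition: np.ndarray
    approximate: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        self.ctoas = np.asarray(self.ctoas, dtype=float)
        self.observed_inhibition = np.asarray(self.observed_inhibition, dtype=float)
        if len(self.ctoas) != len(self.observed_inhibition):
            raise ValueError("ctoas and observed_inhibition must share one length")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"ctoa": self.ctoas, "observed_inhibition": self.observed_inhibition}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, approximate: bool = True, note: str = "") -> "FitDataset":
        df = pd.read_csv(path)
        return cls(
            df["ctoa"].to_numpy(),
            df["observed_inhibition"].to_numpy(),
            approximate=approximate,
            note=note,
        )


@dataclass
class FitResult:
    best_params: dict
    fitness: float
    rmse: float
    history: list = field(default_factory=list)  # per-generation best fitness

    def __post_init__(self) -> None:
        if self.fitness > 100.0:
            raise ValueError("fitness cannot exceed its theoretical maximum of 100")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "best_params": self.best_params,
                    "fitness": self.fitness,
                    "rmse_ms": self.rmse,
                    "history": self.history,
                },
                indent=2,
            )
        )


def inhibition_rmse(predicted, observed) -> float:
    """Root-mean-squared error between predicted and observed inhibition (ms)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must share one length")
    if predicted.size < 1:
        raise ValueError("need at least one CTOA")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def fitness(predicted, observed) -> float:
    """Fitness F = 100 / (1 + RMSE_seconds); maximum 100 at exact agreement."""
    rmse_s = inhibition_rmse(predicted, observed) / 1000.0
    return 100.0 / (1.0 + rmse_s)


def _evaluate(
    candidate: dict, dataset: FitDataset, base_params: ModelParams
) -> float:
    """Fitness of one parameter vector; worst possible (0) on failed trials."""
    try:
        params = base_params.replace(**candidate)
    except ValueError:
        return 0.0
    curve = ior_sweep(dataset.ctoas, params)
    if np.any(curve.no_response):
        logger.info("candidate %s produced a no-response trial", candidate)
        return 0.0
    return fitness(curve.inhibition, dataset.observed_inhibition)


def evolve(
    bounds: dict[str, tuple[float, float]] | None = None,
    dataset: FitDataset | None = None,
    population: int = 40,
    generations: int = 30,
    seed: int = 0,
    base_params: ModelParams | None = None,
    seed_default: bool = True,
    objective=None,
    mu: int | None = None,
    sigma_frac: float = 0.15,
) -> FitResult:
    """Bounded (mu + lambda) evolution strategy over the fitted parameters.

    Each candidate is evaluated by running the CTOA sweep with its parameter
    vector and scoring the predicted inhibition against ``dataset``
    (or by ``objective(candidate_dict)`` when given, e.g. for self-checks).
    Reproducible for a given ``seed``; all candidates respect ``bounds`` at
    every generation.  When ``seed_default`` is set, the published default
    vector joins the initial population, so the result can never score below
    it.
    """
    bounds = dict(bounds or DEFAULT_BOUNDS)
    if population < 2 or generations < 1:
        raise ValueError("population must be >= 2 and generations >= 1")
    base_params = base_params or ModelParams()
    if objective is None:
        if dataset is None:
            raise ValueError("either a dataset or an objective is required")
        objective = lambda cand: _evaluate(cand, dataset, base_params)  # noqa: E731

    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy low < high")
    span = hi - lo
    mu = mu or max(2, population // 4)
    rng = np.random.default_rng(seed)

    pop = lo + rng.random((population, len(names))) * span
    if seed_default:
        default_vec = np.array(
            [np.clip(getattr(base_params, k), bounds[k][0], bounds[k][1]) for k in names]
        )
        pop[0] = default_vec

    def score(vec: np.ndarray) -> float:
        return objective(dict(zip(names, vec)))

    fits = np.array([score(v) for v in pop])
    history = []
    for gen in range(generations):
        order = np.argsort(-fits)
        parents = pop[order[:mu]]
        parent_fits = fits[order[:mu]]
        children = []
        for _ in range(population - mu):
            p = parents[rng.integers(mu)]
            child = p + rng.normal(0.0, sigma_frac, len(names)) * span
            children.append(np.clip(child, lo, hi))
        children = np.array(children)
        child_fits = np.array([score(v) for v in children])
        pop = np.vstack([parents, children])
        fits = np.concatenate([parent_fits, child_fits])
        best = float(np.max(fits))
        history.append(best)
        logger.info("generation %d: best fitness %.4f", gen + 1, best)

    ibest = int(np.argmax(fits))
    best_vec = pop[ibest]
    best_fit = float(fits[ibest])
    rmse_ms = 1000.0 * (100.0 / best_fit - 1.0) if best_fit > 0 else float("inf")
    return FitResult(
        best_params=dict(zip(names, best_vec)),
        fitness=best_fit,
        rmse=rmse_ms,
        history=history,
    )
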