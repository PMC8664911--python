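"""The eco-genetic index: weighted geometric fusion of habitat-suitability
decline and genetic offset, with the weight chosen by minimizing a
symmetric log-ratio deviation objective.

Given normalized components dei_i, go_i in (0, 1), the index is
egi_i = dei_i^alpha * go_i^(1-alpha).  With A_i = ln egi_i, D_i = ln dei_i,
G_i = ln go_i (all finite and negative by the normalization), the total
deviation is

    Y(alpha) = sum_i [ (-A_i)/(-D_i) + (-D_i)/(-A_i) - 2
                     + (-A_i)/(-G_i) + (-G_i)/(-A_i) - 2 ] >= 0,

zero exactly when dei_i = go_i for all i (a/b + b/a - 2 = (a-b)^2/(ab)).
The minimizing alpha is found with a canonical artificial bee colony
search (and a brute-force grid search as an independent oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import generator

__all__ = [
    "EGIProblem",
    "EGISolution",
    "ABCConfig",
    "wga_combine",
    "objective_Y",
    "abc_minimize",
    "grid_minimize",
    "egi_map",
]


@dataclass
class EGIProblem:
    """Paired normalized components per grid cell.

    Both vectors must lie strictly inside (0, 1) -- the [0.1, 0.9]
    normalization guarantees this -- so every logarithm below is finite and
    strictly negative.  Values outside (0, 1) are rejected, never clamped.
    """

    dei: np.ndarray
    go: np.ndarray
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        self.dei = np.asarray(self.dei, dtype=float)
        self.go = np.asarray(self.go, dtype=float)
        if self.dei.shape != self.go.shape or self.dei.ndim != 1:
            raise ValueError("dei and go must be 1-D vectors of equal length")
        if self.dei.size < 1:
            raise ValueError("problem must contain at least one cell")
        for name, v in (("dei", self.dei), ("go", self.go)):
            if not ((v > 0.0) & (v < 1.0)).all():
                raise ValueError(f"{name} values must lie strictly inside (0, 1)")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.dei.size)]
        elif len(self.cell_ids) != self.dei.size:
            raise ValueError("cell_ids length mismatch")

    @property
    def n(self) -> int:
        return self.dei.size


@dataclass
class EGISolution:
    """Optimizer output: the weight, the objective, and the per-cell index."""

    alpha: float
    Y_min: float
    egi: np.ndarray
    d: np.ndarray
    t: np.ndarray
    trace: np.ndarray
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class ABCConfig:
    """Artificial-bee-colony settings (population 20, 30 iterations,
    abandonment limit 5 are the standard small-problem settings here)."""

    population: int = 20
    iterations: int = 30
    limit: int = 5
    seed: int = 0
    bounds: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be even and >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("bounds must satisfy 0 <= lo < hi <= 1")


def wga_combine(problem: EGIProblem, alpha: float) -> np.ndarray:
    """Weighted geometric average: egi_i = dei_i^alpha * go_i^(1-alpha)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return problem.dei ** alpha * problem.go ** (1.0 - alpha)


def objective_Y(problem: EGIProblem, alpha: float):
    """Total deviation Y and its per-cell components (d_i, t_i)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    D = np.log(problem.dei)
    G = np.log(problem.go)
    A = alpha * D + (1.0 - alpha) * G
    d = A / D + D / A - 2.0
    t = A / G + G / A - 2.0
    return float(np.sum(d + t)), d, t


def _objective_vec(problem: EGIProblem, alphas: np.ndarray) -> np.ndarray:
    """Y evaluated at many alphas at once."""
    D = np.log(problem.dei)[None, :]
    G = np.log(problem.go)[None, :]
    a = np.asarray(alphas, dtype=float)[:, None]
    A = a * D + (1.0 - a) * G
    y = A / D + D / A + A / G + G / A - 4.0
    return y.sum(axis=1)


def _is_degenerate(problem: EGIProblem) -> bool:
    return bool(np.allclose(problem.dei, problem.go))


def _solution_at(problem: EGIProblem, alpha: float, trace: np.ndarray,
                 degenerate: bool = False) -> EGISolution:
    Y, d, t = objective_Y(problem, alpha)
    return EGISolution(alpha=float(alpha), Y_min=Y,
                       egi=wga_combine(problem, alpha), d=d, t=t,
                       trace=np.asarray(trace, dtype=float),
                       degenerate=degenerate)


def abc_minimize(problem: EGIProblem, config: ABCConfig | None = None) -> EGISolution:
    """Minimize Y over alpha in [0, 1] with a canonical artificial bee colony.

    Food sources number population/2.  Employed bees perturb each source via
    v = x + phi * (x - x_k) with phi ~ U(-1, 1) and a random partner k;
    onlookers re-sample sources by 1/(1+Y) roulette fitness; a source
    abandoned ``limit`` times is re-seeded uniformly (scout).  Acceptance is
    greedy, so the best-Y trace is nonincreasing.  Fully reproducible under
    the config seed.

    A degenerate problem (dei = go everywhere, Y constant at 0) returns
    alpha = 0.5 with the degenerate flag set.
    """
    config = config or ABCConfig()
    if _is_degenerate(problem):
        return _solution_at(problem, 0.5,
                            np.zeros(config.iterations), degenerate=True)
    rng = generator(config.seed, "abc")
    lo, hi = config.bounds
    n_src = config.population // 2
    x = rng.uniform(lo, hi, n_src)
    y = _objective_vec(problem, x)
    trials = np.zeros(n_src, dtype=int)
    best_x = float(x[np.argmin(y)])
    best_y = float(y.min())
    trace = np.empty(config.iterations)

    def try_move(i: int) -> None:
        nonlocal best_x, best_y
        k = int(rng.integers(0, n_src - 1))
        if k >= i:
            k += 1
        phi = rng.uniform(-1.0, 1.0)
        v = float(np.clip(x[i] + phi * (x[i] - x[k]), lo, hi))
        yv = _objective_vec(problem, np.array([v]))[0]
        if yv < y[i]:
            x[i], y[i] = v, yv
            trials[i] = 0
            if yv < best_y:
                best_x, best_y = v, float(yv)
        else:
            trials[i] += 1

    for it in range(config.iterations):
        for i in range(n_src):          # employed phase
            try_move(i)
        fitness = 1.0 / (1.0 + y)       # onlooker phase
        probs = fitness / fitness.sum()
        for _ in range(n_src):
            i = int(rng.choice(n_src, p=probs))
            try_move(i)
        worn = np.nonzero(trials > config.limit)[0]
        for i in worn:                  # scout phase
            x[i] = rng.uniform(lo, hi)
            y[i] = _objective_vec(problem, x[i: i + 1])[0]
            trials[i] = 0
            if y[i] < best_y:
                best_x, best_y = float(x[i]), float(y[i])
        trace[it] = best_y
    return _solution_at(problem, best_x, trace)


def grid_minimize(problem: EGIProblem, step: float = 1e-4) -> float:
    """Brute-force oracle: exhaustive Y over alpha in {0, step, ..., 1}.

    Ties go to the smaller alpha (first minimum).  Callers should honour
    the degenerate-problem semantics of :func:`abc_minimize` themselves.
    """
    if not (0.0 < step <= 0.1):
        raise ValueError("step must lie in (0, 0.1]")
    alphas = np.arange(0.0, 1.0 + step / 2, step)
    alphas[-1] = 1.0
    Y = _objective_vec(problem, alphas)
    return float(alphas[int(np.argmin(Y))])


def egi_map(problem: EGIProblem, alpha: float) -> pd.DataFrame:
    """Per-cell table of the combined index at the chosen weight."""
    egi = wga_combine(problem, alpha)
    return pd.DataFrame({
        "cell_id": problem.cell_ids,
        "dei_i": problem.dei,
        "go_i": problem.go,
        "egi_i": egi,
    })
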