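"""Ring Toss Game Optimization (RTGO), a population metaheuristic.

A population of N candidate positions is maintained inside box bounds.
Each iteration, the best 10% of members (at least one) become *score
bars*. Every member throws a ring at one uniformly chosen score bar: per
dimension d, with a single uniform draw r in [0, 1],

    F      = round(1 + r)                      in {1, 2}  (half-up)
    dx_d   = r * (sb_d - F * x_d)   if the bar beats the member
           = r * (x_d - F * sb_d)   otherwise
    cand_d = x_d + dx_d             (clipped to bounds)

and the candidate replaces the member only if it strictly improves the
objective (greedy acceptance), so the best-so-far trace never increases.
Minimization throughout; the classifier-tuning fitness is the validation
error rate in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search space; integral dims are rounded after each move."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    integral: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower/upper must be equal-length 1D sequences")
        if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
            raise ValueError("bounds must be finite")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be below its upper bound")
        if self.integral is not None and len(self.integral) != lo.size:
            raise ValueError("integrality flags must match the dimension")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def clip_round(self, x: np.ndarray) -> np.ndarray:
        out = np.clip(x, self.lower, self.upper)
        if self.integral is not None:
            flags = np.asarray(self.integral, bool)
            out = np.where(flags, np.floor(out + 0.5), out)
            out = np.clip(out, self.lower, self.upper)
        return out

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        return self.clip_round(lo + rng.random(self.dim) * (hi - lo))


@dataclass
class Population:
    X: np.ndarray  # N x m positions
    OF: np.ndarray  # N objective values

    @property
    def size(self) -> int:
        return self.X.shape[0]


@dataclass
class ScoreBars:
    SB: np.ndarray  # N_SB x m
    OF_SB: np.ndarray
    indices: np.ndarray  # population indices of the bars, best first


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_objective: float
    trace: list[float]
    evaluations: int
    seed: int
    history: list[np.ndarray] = field(default_factory=list, repr=False)


def n_score_bars(population_size: int) -> int:
    """10% of the population (round half-up), with a floor of one."""
    return max(1, int(np.floor(0.10 * population_size + 0.5)))


def _evaluate(objective, x: np.ndarray) -> float:
    val = float(objective(np.asarray(x, dtype=float)))
    if not np.isfinite(val):
        raise ValueError(f"objective returned a non-finite value at position {np.asarray(x).tolist()}")
    return val


def init_population(objective, space: SearchSpace, n: int, rng: np.random.Generator) -> Population:
    if n < 2:
        raise ValueError("population size must be >= 2")
    X = np.stack([space.sample(rng) for _ in range(n)])
    OF = np.array([_evaluate(objective, x) for x in X])
    return Population(X=X, OF=OF)


def select_score_bars(population: Population) -> ScoreBars:
    """The N_SB lowest-objective members (stable: ties keep lower index)."""
    k = n_score_bars(population.size)
    order = np.argsort(population.OF, kind="stable")[:k]
    return ScoreBars(SB=population.X[order].copy(), OF_SB=population.OF[order].copy(), indices=order)


def ring_throw(
    x: np.ndarray,
    of_x: float,
    sb: np.ndarray,
    of_sb: float,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """One ring throw: per-dimension displacement toward (or away from) a bar.

    ``r`` may be supplied explicitly for deterministic checks; otherwise one
    uniform draw per dimension is taken from ``rng``.
    """
    x = np.asarray(x, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if x.shape != sb.shape:
        raise ValueError("member and score bar dimensions differ")
    if r is None:
        r = rng.random(x.shape)
    else:
        r = np.asarray(r, dtype=float)
    F = np.floor(1.0 + r + 0.5)  # round half-up: r >= 0.5 -> F = 2
    if of_sb < of_x:
        dx = r * (sb - F * x)
    else:
        dx = r * (x - F * sb)
    cand = x + dx
    if space is not None:
        cand = space.clip_round(cand)
    return cand


def greedy_accept(x, of_x, candidate, of_candidate):
    """Keep the candidate only on strict improvement."""
    if of_candidate < of_x:
        return np.asarray(candidate, dtype=float), float(of_candidate)
    return np.asarray(x, dtype=float), float(of_x)


def rtgo_optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n: int = 30,
    iterations: int = 100,
    seed: int = 0,
    stagnation_window: int | None = None,
    keep_history: bool = False,
) -> OptimizationResult:
    """Run RTGO and return the best-ever member with its trace.

    Evaluation count is n * (iterations + 1) unless early stopping on a
    stagnation window triggers first.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    pop = init_population(objective, space, n, rng)
    evals = n
    best_idx = int(np.argmin(pop.OF))
    best_x, best_of = pop.X[best_idx].copy(), float(pop.OF[best_idx])
    trace: list[float] = []
    history: list[np.ndarray] = []
    since_improve = 0
    for _ in range(iterations):
        bars = select_score_bars(pop)
        assignment = rng.integers(0, bars.indices.size, size=pop.size)
        for i in range(pop.size):
            j = assignment[i]
            cand = ring_throw(pop.X[i], pop.OF[i], bars.SB[j], bars.OF_SB[j], rng, space)
            of_cand = _evaluate(objective, cand)
            evals += 1
            pop.X[i], pop.OF[i] = greedy_accept(pop.X[i], pop.OF[i], cand, of_cand)
        it_best = int(np.argmin(pop.OF))
        if pop.OF[it_best] < best_of:
            best_x, best_of = pop.X[it_best].copy(), float(pop.OF[it_best])
            since_improve = 0
        else:
            since_improve += 1
        trace.append(best_of)
        if keep_history:
            history.append(pop.X.copy())
        if stagnation_window is not None and since_improve >= stagnation_window:
            break
    return OptimizationResult(
        best_position=best_x,
        best_objective=best_of,
        trace=trace,
        evaluations=evals,
        seed=seed,
        history=history,
    )


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_evals: int,
    seed: int = 0,
) -> OptimizationResult:
    """Uniform random search baseline at a matched evaluation budget."""
    rng = np.random.default_rng(seed)
    best_x, best_of = None, np.inf
    trace = []
    for _ in range(n_evals):
        x = space.sample(rng)
        of = _evaluate(objective, x)
        if of < best_of:
            best_x, best_of = x, of
        trace.append(best_of)
    return OptimizationResult(
        best_position=np.asarray(best_x), best_objective=float(best_of),
        trace=trace, evaluations=n_evals, seed=seed,
    )


# -- benchmark objectives ----------------------------------------------------

def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x, dtype=float) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


# -- classifier-error fitness -------------------------------------------------

#: Default 4-D hyperparameter space:
#: (log10 learning rate, coarse-loss weight, LSTM hidden units, batch size).
DEFAULT_TUNING_SPACE = SearchSpace(
    lower=(-3.5, 0.0, 8.0, 8.0),
    upper=(-2.0, 0.6, 48.0, 32.0),
    integral=(False, False, True, True),
)


@dataclass
class TuningContext:
    """Everything a reduced-budget classifier training needs.

    The 4-D hyperparameter vector decodes to (learning rate via log10,
    coarse-loss weight, LSTM hidden units, batch size).
    """

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    spec_template: "object"
    epochs: int = 4
    seed: int = 0
    train_extra: np.ndarray | None = None
    val_extra: np.ndarray | None = None


def decode_hyperparams(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError("hyperparameter vector must have 4 entries")
    return {
        "learning_rate": float(10.0 ** x[0]),
        "coarse_loss_weight": float(x[1]),
        "lstm_hidden": int(round(x[2])),
        "batch_size": int(round(x[3])),
    }


def classifier_error_fitness(x: np.ndarray, context: TuningContext) -> float:
    """Validation error rate (percent) of a reduced-budget training run."""
    from dataclasses import replace

    from .hdl import TrainConfig, predict, train_hdl

    hp = decode_hyperparams(x)
    spec = replace(context.spec_template, lstm_hidden=hp["lstm_hidden"])
    config = TrainConfig(
        epochs=context.epochs,
        batch_size=hp["batch_size"],
        learning_rate=hp["learning_rate"],
        coarse_loss_weight=hp["coarse_loss_weight"],
        seed=context.seed,
    )
    model = train_hdl(
        context.train_images, context.train_labels, spec, config,
        extra_features=context.train_extra,
    )
    fine_pred, _, _ = predict(context.val_images, model, extra_features=context.val_extra)
    wrong = int((fine_pred != np.asarray(context.val_labels, dtype=int)).sum())
    return 100.0 * wrong / len(context.val_labels)


def error_rate(n_wrong: int, n_total: int) -> float:
    """The fitness arithmetic: 100 * misclassified / total."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * n_wrong / n_total
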