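"""Particle-swarm search over gene weights and SVM hyperparameters.

Each particle's position concatenates n raw gene weights a_i in [0, 1] with
the soft-margin penalty C in [0.01, 5000] and the RBF width gamma in
[0.0001, 32].  Velocities follow the classic update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),   x <- x + cf*v,

with fresh componentwise randoms r1, r2 in [0, 1), velocity clamped to a
fraction of each dimension's range, and positions clipped to their bounds
(unclamped swarms with c1 = c2 = 2, w = 0.9 diverge on ranges as wide as
C's).  Fitness of a position is the classification accuracy
(classified/total) of the weighted SVM it encodes, after the raw weights are
passed through the threshold gate

    U_delta(a_i) = 0 if a_i <= delta else a_i

and renormalized to sum to one.  A position whose threshold zeroes every
weight scores 0, the worst fitness, so the swarm moves away from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .wsvm import KernelParams, WeightVector, weighted_rbf_gram

__all__ = [
    "C_BOUNDS",
    "GAMMA_BOUNDS",
    "WEIGHT_BOUNDS",
    "AllWeightsZeroError",
    "PsoConfig",
    "Particle",
    "SwarmState",
    "PsoResult",
    "search_bounds",
    "initialize_swarm",
    "update_particle",
    "decode_particle",
    "encode_particle",
    "apply_threshold",
    "normalize_weights",
    "fitness",
    "optimize",
]

C_BOUNDS = (0.01, 5000.0)
GAMMA_BOUNDS = (0.0001, 32.0)
WEIGHT_BOUNDS = (0.0, 1.0)


class AllWeightsZeroError(ValueError):
    """No gene weight survives the threshold (delta too high)."""


@dataclass
class PsoConfig:
    """Swarm hyperparameters (defaults: swarm 50, w=0.9, c1=c2=2, 70 iters)."""

    swarm_size: int = 50
    inertia: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 70
    constraint_factor: float = 1.0
    vmax_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("learning factors c1, c2 must be >= 0")
        if not 0 < self.vmax_fraction <= 1:
            raise ValueError("vmax_fraction must be in (0, 1]")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = -np.inf


@dataclass
class SwarmState:
    particles: list
    best_position: np.ndarray | None = None
    best_fitness: float = -np.inf
    history: list = field(default_factory=list)


@dataclass
class PsoResult:
    """Decoded global best: thresholded/normalized weights plus (C, gamma).

    ``trace`` holds one row per recorded step: (iteration, global best
    fitness, surviving-gene count of the global best at that point).
    """

    best_position: np.ndarray
    weights: WeightVector
    params: KernelParams
    history: np.ndarray
    best_fitness: float
    trace: np.ndarray | None = None


def search_bounds(n_weights: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (lo, hi) for n raw weights followed by C and gamma."""
    lo = np.concatenate([np.full(n_weights, WEIGHT_BOUNDS[0]), [C_BOUNDS[0], GAMMA_BOUNDS[0]]])
    hi = np.concatenate([np.full(n_weights, WEIGHT_BOUNDS[1]), [C_BOUNDS[1], GAMMA_BOUNDS[1]]])
    return lo, hi


def _init_particles(bounds, config: PsoConfig, rng) -> list:
    lo, hi = bounds
    vmax = config.vmax_fraction * (hi - lo)
    particles = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(lo, hi)
        vel = rng.uniform(-vmax, vmax)
        particles.append(Particle(pos, vel, pos.copy(), -np.inf))
    return particles


def initialize_swarm(n_dims_weights: int, config: PsoConfig, rng=None) -> SwarmState:
    """Random swarm over (n weights, C, gamma); reproducible from the seed."""
    if n_dims_weights < 1:
        raise ValueError("need at least one weight dimension")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return SwarmState(particles=_init_particles(search_bounds(n_dims_weights), config, rng))


def update_particle(p: Particle, gbest_position, config: PsoConfig, rng, bounds=None) -> Particle:
    """One velocity/position update; returns a new particle, bests untouched."""
    gbest_position = np.asarray(gbest_position, dtype=float)
    d = p.position.size
    if gbest_position.size != d:
        raise ValueError("global best dimension mismatch")
    if bounds is None:
        if d < 3:
            raise ValueError("default bounds need >= 3 dimensions (weights + C + gamma)")
        bounds = search_bounds(d - 2)
    lo, hi = bounds
    vmax = config.vmax_fraction * (hi - lo)
    r1 = rng.random(d)
    r2 = rng.random(d)
    v = (
        config.inertia * p.velocity
        + config.c1 * r1 * (p.best_position - p.position)
        + config.c2 * r2 * (gbest_position - p.position)
    )
    v = np.clip(v, -vmax, vmax)
    x = np.clip(p.position + config.constraint_factor * v, lo, hi)
    return Particle(x, v, p.best_position.copy(), p.best_fitness)


def decode_particle(position) -> tuple[np.ndarray, float, float]:
    """Split a position into (raw weights, C, gamma); weights not yet gated."""
    position = np.asarray(position, dtype=float)
    if position.size < 3:
        raise ValueError("position must hold at least one weight plus C and gamma")
    return position[:-2].copy(), float(position[-2]), float(position[-1])


def encode_particle(raw_weights, C: float, gamma: float) -> np.ndarray:
    return np.concatenate([np.asarray(raw_weights, dtype=float), [C, gamma]])


def apply_threshold(a, delta: float) -> np.ndarray:
    """Gate U_delta: weights <= delta are zeroed, larger weights pass as-is."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    a = np.asarray(a, dtype=float)
    return np.where(a > delta, a, 0.0)


def normalize_weights(revised) -> WeightVector:
    """Renormalize gated weights to sum to one (zeros preserved)."""
    revised = np.asarray(revised, dtype=float)
    if np.any(revised < 0):
        raise ValueError("revised weights must be non-negative")
    total = revised.sum()
    if total <= 0:
        raise AllWeightsZeroError(
            "no genes survive the threshold; reduce delta (see delta_search)"
        )
    return WeightVector(revised / total)


def _stratified_index_folds(y: np.ndarray, n_folds: int, seed: int) -> list:
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    pos = 0
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % n_folds].append(int(i))
            pos += 1
    return [np.asarray(f, dtype=int) for f in folds if len(f)]


def _accuracy_from_kernel(K: np.ndarray, y: np.ndarray, C: float,
                          evaluation: str, n_folds: int, seed: int) -> float:
    if evaluation == "training":
        svc = SVC(C=C, kernel="precomputed")
        svc.fit(K, y)
        return float((svc.predict(K) == y).mean())
    if evaluation == "internal-kfold":
        correct = 0
        for test in _stratified_index_folds(y, n_folds, seed):
            train = np.setdiff1d(np.arange(y.size), test)
            if np.unique(y[train]).size < 2:
                continue  # fold unusable; counts as misclassified
            svc = SVC(C=C, kernel="precomputed")
            svc.fit(K[np.ix_(train, train)], y[train])
            pred = svc.predict(K[np.ix_(test, train)])
            correct += int((pred == y[test]).sum())
        return correct / y.size
    raise ValueError(f"unknown fitness evaluation {evaluation!r}")


def _fitness_arrays(
    position,
    X: np.ndarray,
    y: np.ndarray,
    delta: float,
    evaluation: str = "training",
    threshold_in_fitness: bool = True,
    n_folds: int = 5,
    seed: int = 0,
    uniform_weights: bool = False,
) -> float:
    position = np.asarray(position, dtype=float)
    if uniform_weights:
        if position.size != 2:
            raise ValueError("uniform-weight positions hold (C, gamma) only")
        C, gamma = float(position[0]), float(position[1])
        alpha = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        a, C, gamma = decode_particle(position)
        w = apply_threshold(a, delta) if threshold_in_fitness else a
        total = w.sum()
        if total <= 0:
            return 0.0  # degenerate: every gene gated out
        alpha = w / total
    K = weighted_rbf_gram(X, None, alpha, gamma)
    return _accuracy_from_kernel(K, y, C, evaluation, n_folds, seed)


def fitness(
    position,
    train,
    delta: float,
    evaluation: str = "training",
    threshold_in_fitness: bool = True,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Accuracy (classified/total) of the weighted SVM a position encodes.

    ``evaluation="training"`` scores on the training samples themselves (the
    default); ``"internal-kfold"`` scores held-out stratified folds of the
    training set, an overfitting-resistant alternative.
    """
    if np.unique(train.labels).size < 2:
        raise ValueError("fitness requires both classes in the training data")
    return _fitness_arrays(
        position, train.matrix, train.labels, delta,
        evaluation=evaluation, threshold_in_fitness=threshold_in_fitness,
        n_folds=n_folds, seed=seed,
    )


def optimize(
    train,
    config: PsoConfig,
    delta: float,
    evaluation: str = "training",
    threshold_in_fitness: bool = True,
    optimize_weights: bool = True,
    initial_positions=None,
    n_folds: int = 5,
) -> PsoResult:
    """Run the swarm and return the decoded global best.

    ``optimize_weights=False`` searches only (C, gamma) with uniform gene
    weights fixed (the hyperparameter-only ablation).  ``initial_positions``
    overrides the random initial swarm (one row per particle), used e.g. to
    study degenerate limits.  The returned history holds the global best
    fitness after initialization and after every iteration; it is
    non-decreasing by construction.
    """
    X, y = train.matrix, train.labels
    if np.unique(y).size < 2:
        raise ValueError("optimization requires both classes in the training data")
    rng = np.random.default_rng(config.seed)
    if optimize_weights:
        bounds = search_bounds(train.n_genes)
    else:
        bounds = (
            np.array([C_BOUNDS[0], GAMMA_BOUNDS[0]]),
            np.array([C_BOUNDS[1], GAMMA_BOUNDS[1]]),
        )
    particles = _init_particles(bounds, config, rng)
    if initial_positions is not None:
        initial_positions = np.asarray(initial_positions, dtype=float)
        if initial_positions.shape != (config.swarm_size, particles[0].position.size):
            raise ValueError("initial_positions must be (swarm_size, n_dims)")
        for p, pos in zip(particles, initial_positions):
            p.position = pos.copy()
            p.best_position = pos.copy()

    def evaluate(position) -> float:
        return _fitness_arrays(
            position, X, y, delta,
            evaluation=evaluation, threshold_in_fitness=threshold_in_fitness,
            n_folds=n_folds, seed=config.seed,
            uniform_weights=not optimize_weights,
        )

    def n_surviving(position) -> int:
        if not optimize_weights:
            return train.n_genes
        return int((apply_threshold(position[:-2], delta) > 0).sum())

    gbest_pos = None
    gbest_fit = -np.inf
    for p in particles:
        f = evaluate(p.position)
        p.best_fitness = f
        if f > gbest_fit:
            gbest_fit = f
            gbest_pos = p.position.copy()
    history = [gbest_fit]
    trace = [(0, gbest_fit, n_surviving(gbest_pos))]

    for it in range(config.max_iterations):
        for i, p in enumerate(particles):
            p = update_particle(p, gbest_pos, config, rng, bounds=bounds)
            f = evaluate(p.position)
            if f > p.best_fitness:
                p.best_fitness = f
                p.best_position = p.position.copy()
            if f > gbest_fit:
                gbest_fit = f
                gbest_pos = p.position.copy()
            particles[i] = p
        history.append(gbest_fit)
        trace.append((it + 1, gbest_fit, n_surviving(gbest_pos)))

    if optimize_weights:
        a, C, gamma = decode_particle(gbest_pos)
        weights = normalize_weights(apply_threshold(a, delta))
    else:
        C, gamma = float(gbest_pos[0]), float(gbest_pos[1])
        weights = WeightVector.uniform(train.n_genes)
    return PsoResult(
        best_position=gbest_pos,
        weights=weights,
        params=KernelParams(C=C, gamma=gamma),
        history=np.asarray(history),
        best_fitness=float(gbest_fit),
        trace=np.asarray(trace),
    )
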