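"""Sooty tern optimization algorithm (STOA) and a feature-selection wrapper.

STOA is a population metaheuristic with two phases per iteration.  In the
*migration* (exploration) phase each search agent's position is scaled by a
movement coefficient that decays linearly from ``Cfac`` to 0 (collision
avoidance), pulled toward the best agent by a random factor ``0.5 * Ran``
(convergence), and the two contributions are summed into a gap vector.  In
the *attack* (exploitation) phase the agent lands on a 3-D logarithmic
spiral around the best agent: with spiral constants ``u, v`` and a fresh
angle ``a`` per agent per iteration, the radius is ``r = u * exp(v * a)``
and the new position is ``gap * (X' + Y' + Z')`` times the best position,
element-wise, clamped to the search bounds.  The global best is retained
under strict-improvement elitism, so the best-so-far fitness history is
non-increasing.

The optimizer minimizes; pass a negated objective to maximize.

The binary feature-selection wrapper maps continuous positions to feature
subsets through a sigmoid transfer (bit set iff sigmoid > 0.5) and scores a
subset by (1 - cross-validated 1-nearest-neighbour accuracy) plus a
cardinality penalty.  This wrapper fitness is this package's construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StoaParams:
    """Optimizer settings; ``bounds`` is a per-dimension (low, high) array."""

    max_iter: int = 100
    pop_size: int = 30
    cfac: float = 2.0
    u: float = 1.0
    v: float = 1.0
    bounds: tuple = ((-1.0, 1.0),)
    seed: int = 0

    def validate(self) -> None:
        if self.cfac <= 0:
            raise ValueError("cfac must be > 0")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        b = np.asarray(self.bounds, dtype=np.float64)
        if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("bounds must be non-degenerate (low, high) intervals")


@dataclass
class SearchAgent:
    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class SpiralSample:
    angle: float
    radius: float
    x: float
    y: float
    z: float


def movement_coefficient(i: int, p: StoaParams) -> float:
    """Linearly decaying movement coefficient: ``Cfac`` at i=0, 0 at max_iter."""
    if i == 0:
        return float(p.cfac)
    if p.max_iter == 0:
        raise ValueError("iteration index > 0 with max_iter = 0")
    if not 0 <= i <= p.max_iter:
        raise ValueError(f"iteration {i} outside [0, {p.max_iter}]")
    return float(p.cfac - i * p.cfac / p.max_iter)


def collision_avoided(pos: np.ndarray, msa: float) -> np.ndarray:
    """Collision-avoided position: element-wise scaling by the coefficient."""
    return msa * np.asarray(pos, dtype=np.float64)


def toward_best(pos: np.ndarray, best_pos: np.ndarray, ran: float) -> np.ndarray:
    """Pull toward the best agent, scaled by ``0.5 * ran`` with ran ~ U[0, 1]."""
    if not 0.0 <= ran <= 1.0:
        raise ValueError("ran must lie in [0, 1]")
    return (0.5 * ran) * (np.asarray(best_pos, np.float64) - np.asarray(pos, np.float64))


def gap(c: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Gap between an agent and the fittest agent: sum of the two moves."""
    return np.asarray(c, np.float64) + np.asarray(m, np.float64)


def spiral_sample(a: float, p: StoaParams) -> SpiralSample:
    """Point on the 3-D logarithmic attack spiral at angle ``a`` in [0, 2pi]."""
    if not 0.0 <= a <= 2.0 * np.pi + 1e-12:
        raise ValueError("spiral angle must lie in [0, 2*pi]")
    r = p.u * np.exp(p.v * a)
    return SpiralSample(angle=float(a), radius=float(r),
                        x=float(r * np.sin(a)), y=float(r * np.cos(a)),
                        z=float(r * a))


def _clamp(pos: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(pos, bounds[:, 0], bounds[:, 1])


def attack_update(g: np.ndarray, best_pos: np.ndarray, a: float,
                  p: StoaParams) -> np.ndarray:
    """New position: gap times the scalar spiral sum, times best, clamped."""
    sp = spiral_sample(a, p)
    bounds = np.asarray(p.bounds, dtype=np.float64)
    pos = (np.asarray(g, np.float64) * (sp.x + sp.y + sp.z)) * np.asarray(best_pos, np.float64)
    return _clamp(pos, bounds)


def optimize(fitness_fn, dim: int, p: StoaParams) -> tuple[SearchAgent, np.ndarray]:
    """Run STOA; returns the best agent and the best-so-far fitness history.

    The population is initialized uniformly within bounds from ``p.seed``.
    Per iteration every agent (in index order) draws ``Ran`` then ``a`` from
    the single seeded generator and applies the migration + attack update.
    The history has ``max_iter + 1`` entries (initial best included).
    """
    p.validate()
    bounds = np.asarray(p.bounds, dtype=np.float64)
    if bounds.shape[0] == 1 and dim > 1:
        bounds = np.repeat(bounds, dim, axis=0)
    if bounds.shape[0] != dim:
        raise ValueError(f"bounds describe {bounds.shape[0]} dims, expected {dim}")
    rng = np.random.default_rng(p.seed)

    positions = rng.uniform(bounds[:, 0], bounds[:, 1], size=(p.pop_size, dim))

    def _eval(pos: np.ndarray, idx: int) -> float:
        f = float(fitness_fn(pos))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness {f} for agent {idx} at {pos}")
        return f

    fitness = np.array([_eval(positions[j], j) for j in range(p.pop_size)])
    best_idx = int(np.argmin(fitness))
    best = SearchAgent(positions[best_idx].copy(), float(fitness[best_idx]))
    history = [best.fitness]

    pp = StoaParams(max_iter=p.max_iter, pop_size=p.pop_size, cfac=p.cfac,
                    u=p.u, v=p.v, bounds=tuple(map(tuple, bounds)), seed=p.seed)
    for i in range(p.max_iter):
        msa = movement_coefficient(i, pp)
        for j in range(p.pop_size):
            ran = float(rng.uniform(0.0, 1.0))
            a = float(rng.uniform(0.0, 2.0 * np.pi))
            c = collision_avoided(positions[j], msa)
            m = toward_best(positions[j], best.position, ran)
            positions[j] = attack_update(gap(c, m), best.position, a, pp)
            fitness[j] = _eval(positions[j], j)
            if fitness[j] < best.fitness:  # strict-improvement elitism
                best = SearchAgent(positions[j].copy(), float(fitness[j]))
        history.append(best.fitness)
    return best, np.asarray(history)


# ---------------------------------------------------------------------------
# binary wrapper for feature-subset selection


@dataclass
class FeatureMask:
    """Selected feature subset and the wrapper fitness it achieved."""

    mask: np.ndarray
    fitness: float
    names: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


class SubsetScorer:
    """Cross-validated 1-nearest-neighbour accuracy for feature subsets.

    Per-feature squared-difference matrices are precomputed once, so scoring
    a subset reduces to summing a stack slice and one argmin per fold —
    cheap enough for exhaustive enumeration on small problems.  With
    ``n_splits=None`` the CV is leave-one-out (smoothest estimate);
    otherwise folds are assigned round-robin within each class in index
    order (deterministic).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_splits: int | None = 3):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes for wrapper scoring")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.n, self.n_features = X.shape
        # (F, n, n) stack of per-feature squared differences
        self.sq_diff = (X.T[:, :, None] - X.T[:, None, :]) ** 2
        self.y = y
        if n_splits is None:
            self.folds = None  # leave-one-out
        else:
            self.n_splits = int(min(n_splits, counts.min()))
            folds = np.empty(self.n, dtype=int)
            for cls in classes:
                idx = np.nonzero(y == cls)[0]
                folds[idx] = np.arange(len(idx)) % self.n_splits
            self.folds = folds

    def accuracy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 0.0
        dist = self.sq_diff[mask].sum(axis=0)
        if self.folds is None:  # leave-one-out
            dist = dist.copy()
            np.fill_diagonal(dist, np.inf)
            nn = np.argmin(dist, axis=1)
            return float(np.mean(self.y[nn] == self.y))
        correct = 0
        for f in range(self.n_splits):
            test = self.folds == f
            train = ~test
            sub = dist[np.ix_(test, train)]
            nn = np.nonzero(train)[0][np.argmin(sub, axis=1)]
            correct += int(np.sum(self.y[nn] == self.y[test]))
        return correct / self.n


def subset_fitness(mask: np.ndarray, scorer: SubsetScorer, alpha: float) -> float:
    """Wrapper objective: (1 - CV accuracy) + alpha * fraction selected.

    The empty subset is assigned the fixed worst value 2.0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 2.0
    return (1.0 - scorer.accuracy(mask)) + alpha * mask.sum() / len(mask)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def position_to_mask(pos: np.ndarray) -> np.ndarray:
    """Sigmoid transfer: a feature is selected iff sigmoid(position) > 0.5."""
    return _sigmoid(np.asarray(pos, dtype=np.float64)) > 0.5


def select_features(X: np.ndarray, y: np.ndarray, p: StoaParams,
                    alpha: float = 0.01, names: list[str] | None = None,
                    n_splits: int | None = 3) -> FeatureMask:
    """Feature-subset selection with the binary sooty-tern search.

    The continuous attack equation multiplies the gap by the best position
    element-wise; under any sign analysis this can add features to the
    incumbent subset but never remove them, so it cannot search subsets.
    The binary adaptation used here keeps the algorithm's skeleton — a
    population of agents, the movement coefficient annealed linearly from
    ``Cfac`` to 0, attack steps centred on the incumbent best, and
    strict-improvement elitism — and realizes the exploration term as
    per-feature bit flips of the incumbent with probability
    ``0.5 * MSA / Cfac``, floored at ``1/n_features`` so refinement
    continues after the anneal.  Agent positions are the bound values
    realizing the bits under the sigmoid transfer.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one feature")
    p.validate()
    scorer = SubsetScorer(X, y, n_splits=n_splits)
    dim = X.shape[1]
    rng = np.random.default_rng(p.seed)

    masks = rng.random((p.pop_size, dim)) < 0.5
    fits = np.array([subset_fitness(m, scorer, alpha) for m in masks])
    k = int(np.argmin(fits))
    best_mask, best_fit = masks[k].copy(), float(fits[k])
    for i in range(p.max_iter):
        msa = movement_coefficient(i, p) if p.max_iter else p.cfac
        p_flip = max(0.5 * msa / p.cfac, 1.0 / dim)
        for j in range(p.pop_size):
            masks[j] = best_mask ^ (rng.random(dim) < p_flip)
            f = subset_fitness(masks[j], scorer, alpha)
            if f < best_fit:  # strict-improvement elitism
                best_fit, best_mask = f, masks[j].copy()
    return FeatureMask(mask=best_mask, fitness=best_fit, names=names)


def planted_feature_problem(seed: int, n_samples: int = 120, n_features: int = 16,
                            informative: tuple[int, ...] = (4, 11),
                            effect: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic two-class features with a planted informative subset.

    All features are standard normal; the informative ones are shifted by
    ``effect`` standard deviations (alternating sign) in class 1.  The
    default effect makes the planted pair the wrapper-fitness optimum when
    scored with leave-one-out CV and a cardinality penalty exceeding the
    one-CV-sample resolution (alpha >= n_features / n_samples).
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n_samples)
    X = rng.normal(size=(n_samples, n_features))
    for k, feat in enumerate(informative):
        X[:, feat] += effect * y * (1 if k % 2 == 0 else -1)
    return X, y


def exhaustive_best_subset(X: np.ndarray, y: np.ndarray, alpha: float = 0.01,
                           n_splits: int | None = 3) -> FeatureMask:
    """Brute force over all non-empty subsets (small feature counts only)."""
    X = np.asarray(X, dtype=np.float64)
    n_features = X.shape[1]
    if n_features > 16:
        raise ValueError("exhaustive enumeration limited to <= 16 features")
    scorer = SubsetScorer(X, y, n_splits=n_splits)
    best_mask, best_fit = None, np.inf
    for code in range(1, 2**n_features):
        mask = np.array([(code >> b) & 1 for b in range(n_features)], dtype=bool)
        f = subset_fitness(mask, scorer, alpha)
        if f < best_fit:
            best_mask, best_fit = mask, f
    return FeatureMask(mask=best_mask, fitness=best_fit)
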