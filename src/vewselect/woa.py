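"""Binary whale optimization over a candidate gene set.

The whale optimization algorithm (WOA) is a population metaheuristic that
mimics humpback hunting. Each whale is a continuous position
X in [0, 1]^D; positions are stochastically binarized into 0/1 gene masks
(mask_i = 1 iff rand < x_i, one fresh uniform draw per dimension) and each
mask is scored by the fitness

    fitness(mask) = alpha * (1 - KNN_acc) + (1 - alpha) * |R| / |C|

where |R| is the number of selected genes, |C| = D the candidate count, and
KNN_acc the mean accuracy of a k-nearest-neighbour classifier over a
stratified inner cross-validation frozen once per run so every mask is
scored on identical partitions. Lower fitness is better; alpha = 0.99
weights accuracy far above subset size.

Per whale and iteration, with a = 2 - 2t/T decreasing linearly from 2 to 0,
A = 2a*rand1 - a and C = 2*rand2:

* with probability 1/2 (p >= 0.5) the whale spirals toward the best-known
  position X_q:  X <- X_q + |X_q - X| * e^{b*l} * cos(2*pi*l), l ~ U[-1, 1];
* otherwise, if |A| < 1 it encircles the best: X <- X_q - A*|C*X_q - X|
  (exploitation), and if |A| >= 1 it moves relative to a random other whale
  X_rand instead: X <- X_rand - A*|C*X_rand - X| (exploration).

Updated positions are clipped back into [0, 1]. The best-ever MASK (not a
re-binarization of the best position) is archived so the reported subset is
exactly the one that achieved the best fitness; ties prefer fewer genes,
then the earlier discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .datasets import ExpressionDataset
from .errors import EmptySelectionError
from .filters import GeneSubset


@dataclass(frozen=True)
class WOAParams:
    """Search-budget and shape parameters of the whale optimizer.

    ``pop_size`` (N) whales, ``max_iter`` (T) iterations, ``spiral_b`` the
    logarithmic-spiral constant b. Positions live in [``clip_low``,
    ``clip_high``] = [0, 1]; the binarization contract depends on it.
    """

    pop_size: int = 20
    max_iter: int = 100
    spiral_b: float = 1.0
    seed: int = 0
    clip_low: float = 0.0
    clip_high: float = 1.0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class WhalePopulation:
    """Mutable WOA search state: positions plus the elitist best-so-far."""

    positions: np.ndarray
    best_position: np.ndarray | None = None
    best_mask: np.ndarray | None = None
    best_fitness: float = np.inf
    iteration: int = 0
    trace: list[float] = field(default_factory=list)

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]


class FitnessContext:
    """Frozen objects needed to score a mask.

    Holds the dataset restricted to the candidate genes (D = |C| columns),
    the KNN settings, the stratified inner folds (frozen at construction so
    all masks are compared on identical partitions), the accuracy/size
    weight ``alpha`` and the empty-mask penalty.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        alpha: float = 0.99,
        knn_k: int = 5,
        inner_folds: int = 5,
        fold_seed: int = 0,
        empty_penalty: float = 1.0,
    ):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if knn_k < 1 or inner_folds < 2:
            raise ValueError("knn_k >= 1 and inner_folds >= 2 required")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.alpha = float(alpha)
        self.empty_penalty = float(empty_penalty)

        _, class_counts = np.unique(self.y, return_counts=True)
        min_class = int(class_counts.min())
        folds = inner_folds
        if min_class < folds:
            folds = max(2, min_class)
            warnings.warn(
                f"inner folds reduced {inner_folds} -> {folds}: smallest class "
                f"has {min_class} samples",
                stacklevel=2,
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        self.folds = [
            (tr.copy(), te.copy()) for tr, te in splitter.split(self.X, self.y)
        ]
        min_train = min(tr.size for tr, _ in self.folds)
        k = knn_k
        if k >= min_train:
            k = max(1, min_train - 1)
            warnings.warn(
                f"knn_k reduced {knn_k} -> {k}: smallest training fold has "
                f"{min_train} samples",
                stacklevel=2,
            )
        self.knn_k = k
        self.inner_folds = folds
        self._cache: dict[bytes, float] = {}

    @classmethod
    def from_dataset(
        cls,
        ds: ExpressionDataset,
        subset: GeneSubset,
        alpha: float = 0.99,
        knn_k: int = 5,
        inner_folds: int = 5,
        fold_seed: int = 0,
    ) -> "FitnessContext":
        if len(subset) == 0:
            raise EmptySelectionError("candidate subset is empty")
        return cls(subset.restrict(ds.values), ds.labels, alpha=alpha,
                   knn_k=knn_k, inner_folds=inner_folds, fold_seed=fold_seed)

    @property
    def n_candidates(self) -> int:
        """|C|: total number of candidate genes."""
        return self.X.shape[1]

    def knn_accuracy(self, mask: np.ndarray) -> float:
        """Mean KNN accuracy over the frozen inner folds using masked genes only."""
        Xm = self.X[:, mask.astype(bool)]
        accs = []
        for train, test in self.folds:
            clf = KNeighborsClassifier(n_neighbors=self.knn_k)
            clf.fit(Xm[train], self.y[train])
            accs.append(clf.score(Xm[test], self.y[test]))
        return float(np.mean(accs))


def evaluate_fitness(mask: np.ndarray, ctx: FitnessContext) -> float:
    """alpha*(1 - KNN_acc) + (1 - alpha)*|R|/|C|; the all-zero mask costs the penalty."""
    mask = np.asarray(mask)
    if mask.shape != (ctx.n_candidates,):
        raise ValueError(f"mask length {mask.size} != {ctx.n_candidates} candidates")
    n_selected = int(mask.sum())
    if n_selected == 0:
        return ctx.empty_penalty
    key = np.packbits(mask.astype(np.uint8)).tobytes()
    if key in ctx._cache:
        return ctx._cache[key]
    acc = ctx.knn_accuracy(mask)
    fitness = ctx.alpha * (1.0 - acc) + (1.0 - ctx.alpha) * n_selected / ctx.n_candidates
    ctx._cache[key] = fitness
    return fitness


def initialize_population(
    params: WOAParams,
    n_dims: int,
    rng: np.random.Generator | None = None,
    ctx: FitnessContext | None = None,
) -> WhalePopulation:
    """Uniform-random positions in [0, 1]^D; optional initial fitness sweep.

    When a :class:`FitnessContext` is supplied the initial positions are
    binarized (with the same stream) and evaluated so the best fields are
    populated; :func:`run_woa` instead performs that sweep as its first
    iteration.
    """
    if n_dims < 1:
        raise EmptySelectionError("empty search space: no candidate genes")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = WhalePopulation(rng.uniform(0.0, 1.0, size=(params.pop_size, n_dims)))
    if ctx is not None:
        for i in range(params.pop_size):
            mask = binarize_position(pop.positions[i], rng)
            _consider(pop, pop.positions[i], mask, evaluate_fitness(mask, ctx))
    return pop


def binarize_position(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic transfer rule: mask_i = 1 iff a fresh uniform draw < x_i."""
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("position entries outside [0, 1]; clip upstream")
    return (rng.random(x.size) < x).astype(np.int8)


def convergence_coefficient(t: int, max_iter: int) -> float:
    """a = 2 - 2t/T, decreasing linearly from 2 (t=0) to 0 (t=T)."""
    return 2.0 - 2.0 * t / max_iter


def update_position(
    pop: WhalePopulation,
    whale_index: int,
    params: WOAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One whale's move: spiral (p >= 0.5), encircle (|A| < 1) or random search.

    The scalars p, l, rand1, rand2 are drawn once per whale per move (scalar,
    not per-dimension); |.| in the distance terms is element-wise. The result
    is clipped into [0, 1].
    """
    x = pop.positions[whale_index]
    best = pop.best_position if pop.best_position is not None else x
    p = rng.random()
    if p >= 0.5:
        l = rng.uniform(-1.0, 1.0)
        d_prime = np.abs(best - x)
        new = best + d_prime * np.exp(params.spiral_b * l) * np.cos(2.0 * np.pi * l)
    else:
        rand1 = rng.random()
        rand2 = rng.random()
        a = convergence_coefficient(pop.iteration, params.max_iter)
        A = 2.0 * a * rand1 - a
        C = 2.0 * rand2
        if abs(A) < 1.0:
            new = best - A * np.abs(C * best - x)
        else:
            other = int(rng.integers(pop.pop_size - 1))
            if other >= whale_index:
                other += 1  # uniformly chosen OTHER whale
            x_rand = pop.positions[other]
            new = x_rand - A * np.abs(C * x_rand - x)
    return np.clip(new, params.clip_low, params.clip_high)


def _consider(pop: WhalePopulation, position: np.ndarray, mask: np.ndarray,
              fitness: float) -> None:
    """Elitist archive update; ties prefer fewer genes, then earlier discovery."""
    size = int(mask.sum())
    if fitness < pop.best_fitness or (
        fitness == pop.best_fitness
        and pop.best_mask is not None
        and size < int(pop.best_mask.sum())
    ):
        pop.best_fitness = float(fitness)
        pop.best_mask = mask.copy()
        pop.best_position = position.copy()


@dataclass(frozen=True)
class WOAResult:
    """Outcome of one whale-optimization run."""

    mask: np.ndarray
    fitness: float
    trace: tuple[float, ...]
    n_evaluations: int

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected(self, subset: GeneSubset) -> GeneSubset:
        """Map the mask back through a candidate subset to original coordinates."""
        keep = np.flatnonzero(self.mask)
        return GeneSubset(
            subset.indices[keep],
            tuple(subset.gene_ids[i] for i in keep),
            "woa",
        )


def run_woa(ctx: FitnessContext, params: WOAParams) -> WOAResult:
    """Full WOA loop: initialize, then T rounds of binarize/evaluate/move.

    One master seed spawns independent substreams for initialization,
    binarization and position updates, so each component is individually
    reproducible. Returns the best-ever mask, its fitness, and the
    per-iteration best-fitness trace (non-increasing by elitism).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_init, rng_bin, rng_upd = (np.random.default_rng(s) for s in ss.spawn(3))
    pop = initialize_population(params, ctx.n_candidates, rng=rng_init)
    n_evals = 0
    for t in range(params.max_iter):
        pop.iteration = t
        for i in range(params.pop_size):
            mask = binarize_position(pop.positions[i], rng_bin)
            fitness = evaluate_fitness(mask, ctx)
            n_evals += 1
            _consider(pop, pop.positions[i], mask, fitness)
        pop.trace.append(pop.best_fitness)
        for i in range(params.pop_size):
            pop.positions[i] = update_position(pop, i, params, rng_upd)
    if pop.best_mask is None or int(pop.best_mask.sum()) == 0:
        raise EmptySelectionError("every evaluated mask selected zero genes")
    return WOAResult(pop.best_mask, pop.best_fitness, tuple(pop.trace), n_evals)


def exhaustive_minimum(ctx: FitnessContext) -> tuple[np.ndarray, float]:
    """Brute-force minimum fitness over all 2^D masks (same frozen folds).

    Only feasible for small D; used as an independent oracle for the
    optimizer. The tie-break matches the optimizer's: fewer genes, then the
    earlier mask in enumeration order.
    """
    D = ctx.n_candidates
    if D > 20:
        raise ValueError("exhaustive enumeration limited to D <= 20")
    best_mask, best_fit = None, np.inf
    for code in range(2 ** D):
        mask = np.array([(code >> j) & 1 for j in range(D)], dtype=np.int8)
        fit = evaluate_fitness(mask, ctx)
        if fit < best_fit or (
            fit == best_fit and best_mask is not None
            and mask.sum() < best_mask.sum()
        ):
            best_mask, best_fit = mask, fit
    return best_mask, float(best_fit)
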